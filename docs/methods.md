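# Methods

## Model structure

The simulator couples a lumped-parameter (0-D) blood circulation to
four advected chemical species. The state vector holds 8 compartment blood
volumes (ml), 8 × 4 species amounts (glucose mmol; insulin, glucagon and
GLP-1 pmol) and the intestinal-lumen glucose pool — 41 ordinary differential
equations integrated in minutes.

### Circulation

Compartments: systemic arteries, superior-mesenteric (SM) capillary bed,
hepatic sinusoids, splenic & coeliac bed, lungs, somatic bed, renal bed,
systemic veins. Segments: the arterial supplies of the somatic, renal,
splenic and splanchnic beds; the SMA; the hepatic artery; the portal
(presinusoidal) vein SM-cap → sinusoids; the hepatic vein; the venous
returns; the portosystemic shunt SM-cap → systemic veins; and two
ventricular pumps modelled as constant pressure sources in series with
their outflow resistances. Flows are in ml/s with resistances in
mm Hg·s·ml⁻¹; the reporting layer converts to ml/min.

Pressure–volume law: linear, `P = (V − V₀)/C`. Compliances are obtained
from *fractional distensibilities* D (per mm Hg) as `C = D·V_rest`, which
makes the arteries stiff (≈0.55 ml/mm Hg) and the veins compliant
(≈100 ml/mm Hg) and keeps the volume modes' time constants at the scale of
seconds — mild stiffness that LSODA handles comfortably.

**Calibration of the network.** Default resistances, pump pressures and
unstressed volumes are *derived analytically* from a resting design point
rather than tabulated: cardiac output 5.5 L/min, aortic pressure 105 mm Hg,
systemic venous pressure 1.43 mm Hg, SMA flow 500 ml/min, hepatic-artery
flow 700 ml/min, renal flow 1100 ml/min, splenic flow 400 ml/min, somatic
flow 2800 ml/min, portal pressure ≈1.5 mm Hg. Because `R = ΔP/Q` per branch
and `V₀ = V_rest − C·P_rest` per compartment, the fasting design point is an
exact steady state of the circulation by construction; the full model then
re-equilibrates around it once the hormone loops are active. The
presinusoidal (0.005), hepatic-vein (0.0003) and shunt (0.4, control 40)
resistances are held at their nominal values because the disease scenarios
sweep them directly.

**GLP-1 flow control.** `R_SMA = R_SMA(0)·Km/(Km + GLP)` with the
splanchnic-capillary GLP-1 concentration in pM and `Km = 10 pM`. The
half-max constant must sit near the *fasting* splanchnic concentration
(~22 pM): the GLP-1→flow loop is self-limiting (more flow dilutes both the
glucose stimulus and the secreted peptide), so splanchnic GLP-1 rises only
a few-fold after a gavage, and a half-max far above the operating point
would leave the SMA inert.

### Intestinal absorption

Active transport: `V_max·G_lumen/(G_lumen + 17 mM)` (SGLT1, insensitive to
the capillary side). Passive paracellular leak: `P_gl · A_eff · (G_lumen −
G_SMcap)`, signed, where the effective mucosal exchange area `A_eff`
(4.5 mmol·min⁻¹ per µm/s per mM) is a single calibration constant. The
lumen is a well-mixed 2.5 L pool; the 50 g (277.5 mmol) gavage enters it at
13.875 mmol/min for 20 min. Absorbed glucose drags isotonic water
(3.9 ml/mmol) into the SM capillary bed; a renal relief term (time constant
60 min) returns total blood volume to 5 L. This fluid coupling is what
raises portal pressure from ~1.5 to ~7 mm Hg during absorption — with the
printed presinusoidal resistance of 0.005 mm Hg·s·ml⁻¹, the resistive
pressure drop alone could contribute only ~0.1 mm Hg.

### Metabolism and secretion

All saturable terms are Michaelis–Menten in `max(x, 0)`. Concentrations are
amount ÷ (3 × compartment blood volume), so the advected concentration
equals the plasma concentration and e.g. portal glucose flow is simply
portal blood flow × portal glucose (mM).

- **Hepatic:** NHGU = GLUT2/glucokinase uptake (Km 20 mM) × insulin factor
  (Km 200 pM) × sensitivity 0.5 × (1 + 2·GLP/(GLP+3 pM)) − glucagon output
  (V 21.5 and 11 mmol/min; glucagon Km 2 nM). The liver is an unlimited
  gluconeogenic source (short-term assumption, 1–2 days).
- **Peripheral:** insulin-dependent GLUT4 disposal (glucose Km 2.5 mM,
  insulin Km 150 pM, GLP-1 synergy 1 + 4.5·GLP/(GLP+3 pM), coefficient
  21.5 mmol/min) and insulin-independent GLUT1 disposal (Km 1.3 mM,
  0.7 mmol/min), both drawing on the somatic compartment.
- **Renal:** excretion = max(0, 0.1·Q_renal·G − Tm·G/(G+0.1 mM)),
  Tm = 1.2 mmol/min — zero below ~11 mM (no glycosuria in any normal run).
- **Secretion:** insulin and glucagon enter the SM-capillary compartment
  and sense systemic *arterial* glucose; GLP-1 enters the same compartment
  and senses *splanchnic* capillary glucose (Km 16 mM). The beta-cell
  glucose term is a Hill function with n = 2 (Km 17 mM) — see Design
  choices. Glucagon suppression uses n = 2, Km 3 mM. The GLP-1 factor on
  insulin secretion is deliberately shallow, `(GLP+ε)/(GLP+ε+Km)` with
  ε = 15 pM, so that basal secretion survives GLP-1-null scenarios.
- **Degradation:** first-order per territory. Insulin 0.9 min⁻¹ hepatic /
  0.55 min⁻¹ systemic (circulating t½ ≈ 4 min); glucagon 0.25/0.25;
  GLP-1 8.0 hepatic (strong first-pass extraction) / 0.06 systemic.

### Integration

LSODA with rtol 1e-7 and per-block absolute tolerances (1e-6 ml, 1e-9
amount units); integration is split at the gavage on/off times so the
solver never steps across a source discontinuity. Output cadence is 5 s
(1/12 min). Fasting equilibration integrates the no-gavage system for up to
4 × 600 virtual minutes and requires the maximum relative derivative to
fall below 1e-7 min⁻¹; equilibria are cached per parameter set. The model
contains no randomness: reruns are bitwise identical, and halving rtol
changes every reported peak by far less than 0.1%.

## Units

Pressures mm Hg; resistances mm Hg·s·ml⁻¹; volumes ml; glucose mM; insulin
pM; glucagon nM; GLP-1 pM; all rates per minute. Source tables for this
class of model sometimes print kinetic constants on a per-second scale that
contradicts the hormones' minute-scale half-lives, and mix pM/nM for GLP-1;
every constant here is therefore a per-minute, pM-scale quantity fixed by
the calibration described above, recorded in `config.py`-visible parameter
blocks with these units.

## Design choices made where the design was open

- **Ventricular pumps as pressure sources.** Constant-pressure sources in
  series with the aortic / pulmonary-path resistances, with source
  pressures solved from the resting design point. Cardiac output then
  responds passively to total network resistance (it rises ~15% during
  absorption as the SMA dilates), which is what produces the emergent
  hepatic-arterial buffer response.
- **Fluid co-absorption.** Isotonic solvent drag is included because a
  glucose-only gavage cannot move portal pressure through a 0.005
  mm Hg·s·ml⁻¹ presinusoidal resistance; plasma-volume expansion during an
  OGTT is also the physiological reality. With the lumen empty the circuit
  is exactly volume-conserving (to solver round-off).
- **Beta-cell Hill coefficient n = 2.** With a first-order glucose term,
  the GLP-1-deficient fasting state cannot show hyperinsulinaemia: low
  GLP-1 also lowers SMA flow, and the reduced splanchnic washout cancels
  the glucose-driven secretion increase. The sigmoid beta-cell
  dose–response (physiologically well established) restores the observed
  ordering (fasting insulin ≈ 41 pM at sensitivity 0.1 vs ≈ 32 pM at 50).
- **Hormone turnover vs concentration ratios.** With islet secretion into
  the ~500 ml/min SM-capillary stream, minute-scale hormone half-lives
  force splanchnic:arterial ratios well above 2, whereas ratio ≈ 2 would
  force ~20-min half-lives and a sluggish, unphysiological insulin
  response. Fast turnover was chosen; the "≈ 2" anchor is honoured as the
  arterial : peripheral-venous insulin ratio (first-pass + tissue
  extraction), which the calibrated model reproduces (≈ 1.9 at fasting).
- **Hepatic glucagon term subtracted after the insulin/GLP-1 factors**
  (additive output), not folded inside them.
- **Phase sampling.** "Feeding" = time of maximal systemic arterial
  glucose; "fasting" = time of its pre-gavage minimum. Sampling fasting
  before the gavage (rather than at the global minimum, which falls in the
  post-absorptive dip) is what makes the fasting interaction coefficients
  vanish identically.
- **Surface-fit normalization.** Predictors are rescaled to [0, 1] before
  the polynomial fit, so interaction coefficients are comparable across
  sweeps; only their sign/zero classification is unit-independent.

## Problem sizes

The default run simulates 0–180 min (gavage at 100–120 min) at 5-s output
cadence after a ≤600-min fasting equilibration; a run takes ~1 s. The
permeability sweep uses 7 points over 0–0.16 µm/s; interaction surfaces use
a 3 × 3 grid over sensitivity {2, 10, 50} × P_gl {0, 0.08, 0.16}.

## Known limitations

- The calibrated fasting state has a total glucose turnover of ~3 mmol/min
  (glucagon-driven hepatic output balancing peripheral consumption). This
  is above textbook fasting turnover (~1 mmol/min): a true steady state
  cannot simultaneously satisfy the low published fasting output and the
  higher published fasting consumption terms, and the consumption side was
  kept.
- Shunt flow is structurally bounded by SMA inflow to the SM-capillary
  node; very large published shunt flows (exceeding peak SMA flow) are not
  reachable in a Kirchhoff-consistent network (see the shunt scenario test
  for the honest failure).
- No gastric emptying (duodenal gavage by design), no neural or humoral
  reflexes, no glycogen-store accounting or lipid/amino-acid substrates,
  single well-mixed lumen pool, linear compliances, non-pulsatile heart.
- The synthetic scenarios probe the model's own feedback structure; passing
  tests demonstrate internal consistency and reproduction of the published
  operating points, not validation against new clinical data.
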