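"""Source, sink and exchange kinetics for glucose, insulin, glucagon and GLP-1.

Species are tracked as amounts per compartment (glucose in mmol, hormones in
pmol).  Concentrations are amounts divided by the distribution volume, taken
as three times the compartment blood volume: circulating blood is assumed to
be one third of the extracellular space into which glucose and the peptide
hormones equilibrate rapidly.  With that convention the advected
concentration equals the plasma concentration, so e.g. portal-vein glucose
flow is simply (portal blood flow) x (portal glucose, mM).

Unit conventions
----------------
glucose mM, insulin pM, glucagon nM, GLP-1 pM; all rates per minute.

Several Table-2-style constants printed on a per-second scale in the source
material contradict the stated hormone half-lives; here every kinetic
constant is a per-minute quantity fixed by the documented calibration layer
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AbsorptionParameters",
    "HepaticKinetics",
    "PeripheralKinetics",
    "SecretionParameters",
    "RenalParameters",
    "advective_flux",
    "intestinal_absorption_rate",
    "hepatic_metabolic_rate",
    "peripheral_insulin_dependent_rate",
    "insulin_independent_rate",
    "renal_glucose_excretion",
    "insulin_secretion_rate",
    "glucagon_secretion_rate",
    "glp1_secretion_rate",
    "first_order_degradation",
]


def _mm(x: float, km: float) -> float:
    """Michaelis-Menten saturation of max(x, 0)."""
    x = max(x, 0.0)
    return x / (x + km)


@dataclass(frozen=True)
class AbsorptionParameters:
    """Intestinal glucose absorption: active SGLT1 plus paracellular leak.

    sglt1_vmax : mmol/min, maximal active transport rate
    sglt1_km   : mM, operational Km of the activated SGLT1 pump (17 mM)
    p_gl       : um/s, paracellular glucose permeability
    exchange_scale : mmol/min per (um/s) per mM -- effective mucosal exchange
        area folding the permeability x concentration-gradient product into a
        molar flux; a single calibration constant.
    water_per_mmol : ml of water co-absorbed per mmol glucose (isotonic
        solvent drag into the mesenteric capillary bed)
    lumen_volume : ml, fluid volume of the absorbing small-intestinal segment
    """

    sglt1_vmax: float = 2.6
    sglt1_km: float = 17.0
    p_gl: float = 0.15
    exchange_scale: float = 4.5
    water_per_mmol: float = 3.9
    lumen_volume: float = 2500.0


@dataclass(frozen=True)
class HepaticKinetics:
    """Hepatic glucose handling: GLUT2/glucokinase uptake vs glucagon output.

    Net hepatic glucose uptake (NHGU) is the insulin- and GLP-1-sensitised
    GLUT2/glucokinase uptake minus glucagon-driven glucose output
    (gluconeogenesis/glycogenolysis, treated as an unlimited source).
    """

    vmax_glut2: float = 21.5        # mmol/min
    km_glut2: float = 20.0          # mM
    km_insulin: float = 200.0       # pM
    hep_insulin_sensitivity: float = 0.5
    vmax_glp1_boost: float = 2.0    # dimensionless boost amplitude
    km_glp1: float = 3.0            # pM
    glucagon_vmax: float = 11.0     # mmol/min, maximal glucagon-driven output
    km_glucagon: float = 2.0        # nM


@dataclass(frozen=True)
class PeripheralKinetics:
    """Peripheral glucose consumption (GLUT4 insulin-dependent, GLUT1 basal)."""

    insulin_dep_coef: float = 21.5  # mmol/min (GLUT4 pathway)
    km_glut4: float = 2.5           # mM
    km_insulin: float = 150.0       # pM
    glp1_synergy_amp: float = 4.5   # dimensionless amplitude of GLP-1 synergy
    glp1_synergy_km: float = 3.0    # pM
    insulin_indep_coef: float = 0.70  # mmol/min (GLUT1 pathway: brain/skin/bone)
    km_glut1: float = 1.3           # mM


@dataclass(frozen=True)
class SecretionParameters:
    """Hormone secretion laws and first-order loss rates.

    Insulin and glucagon are released by the pancreatic islets into the
    superior-mesenteric capillary compartment and sense *systemic arterial*
    glucose; GLP-1 is released by enteroendocrine L cells into the same
    splanchnic compartment but senses *splanchnic capillary* glucose.
    ``glp1_glc_sensitivity`` is the headline sweep knob (0.1-100).
    """

    insulin_glc_sensitivity: float = 3500.0  # pmol/min at saturation
    beta_cell_km: float = 17.0              # mM
    insulin_glc_exponent: int = 2           # Hill coefficient of beta-cell response
    insulin_glp1_km: float = 20.0           # pM
    insulin_glp1_floor: float = 15.0        # pM floor: basal secretion survives GLP-1 loss
    glucagon_sensitivity: float = 3380.0    # pmol/min at zero glucose
    glucagon_km: float = 3.0                # mM
    glucagon_exponent: int = 2              # n = 1 or 2
    glp1_glc_sensitivity: float = 50.0      # sweep knob
    glp1_km_glut2: float = 16.0             # mM
    glp1_glc_exponent: int = 2              # Hill coefficient of L-cell response
    glp1_secretion_scale: float = 2.10      # pmol/min per unit sensitivity
    # first-order loss rates, per minute
    insulin_loss_hepatic: float = 0.90
    insulin_loss_systemic: float = 0.55
    glucagon_loss_hepatic: float = 0.25
    glucagon_loss_systemic: float = 0.25
    glp1_loss_hepatic: float = 8.00
    glp1_loss_systemic: float = 0.06


@dataclass(frozen=True)
class RenalParameters:
    """Renal glucose filtration and SGLT2 tubular reabsorption."""

    filtration_fraction: float = 0.1
    tm_sglt2: float = 1.2   # mmol/min
    km_sglt2: float = 0.1   # mM


# ---------------------------------------------------------------------------
# rate laws


def advective_flux(flow_ml_min: float, donor_concentration: float) -> float:
    """Species flux (amount/min) carried by a signed blood flow.

    ``donor_concentration`` must already be the concentration of the upstream
    compartment of the signed flow (upwind convention); the caller selects the
    donor by the sign of the flow.
    """
    return flow_ml_min * donor_concentration


def intestinal_absorption_rate(
    lumen_glc: float, smcap_glc: float, p: AbsorptionParameters
) -> float:
    """Glucose absorption (mmol/min) from lumen to mesenteric capillaries.

    Active SGLT1 transport saturates on luminal glucose; the paracellular
    term follows the lumen-to-capillary gradient and reverses sign when the
    capillary concentration exceeds the lumen.
    """
    active = p.sglt1_vmax * _mm(lumen_glc, p.sglt1_km)
    passive = p.p_gl * p.exchange_scale * (max(lumen_glc, 0.0) - max(smcap_glc, 0.0))
    return active + passive


def hepatic_metabolic_rate(
    glc_hep: float, ins_hep: float, glp1_hep: float, gln_hep: float, k: HepaticKinetics
) -> float:
    """Net hepatic glucose uptake, mmol/min (negative = net glucose output)."""
    uptake = (
        k.vmax_glut2
        * _mm(glc_hep, k.km_glut2)
        * _mm(ins_hep, k.km_insulin)
        * k.hep_insulin_sensitivity
        * (1.0 + k.vmax_glp1_boost * _mm(glp1_hep, k.km_glp1))
    )
    output = k.glucagon_vmax * _mm(gln_hep, k.km_glucagon)
    return uptake - output


def peripheral_insulin_dependent_rate(
    glc_sys: float, ins_sys: float, glp1_sys: float, k: PeripheralKinetics
) -> float:
    """Insulin-dependent glucose consumption (muscle/adipose GLUT4), mmol/min."""
    return (
        k.insulin_dep_coef
        * _mm(glc_sys, k.km_glut4)
        * _mm(ins_sys, k.km_insulin)
        * (1.0 + k.glp1_synergy_amp * _mm(glp1_sys, k.glp1_synergy_km))
    )


def insulin_independent_rate(glc_sys: float, k: PeripheralKinetics) -> float:
    """Insulin-independent consumption (brain/skin/bone GLUT1), mmol/min."""
    return k.insulin_indep_coef * _mm(glc_sys, k.km_glut1)


def renal_glucose_excretion(
    renal_art_glc: float, renal_flow_ml_min: float, p: RenalParameters
) -> float:
    """Urinary glucose loss, mmol/min; zero below the SGLT2 reabsorption ceiling."""
    filtered = p.filtration_fraction * renal_flow_ml_min * max(renal_art_glc, 0.0) / 1000.0
    reabsorbed = p.tm_sglt2 * _mm(renal_art_glc, p.km_sglt2)
    return max(0.0, filtered - reabsorbed)


def insulin_secretion_rate(glc_sysa: float, glp1_sysa: float, p: SecretionParameters) -> float:
    """Beta-cell insulin release (pmol/min) into the SM-capillary compartment.

    The glucose term is a Hill function of systemic arterial glucose (the
    beta-cell dose-response is sigmoid); the GLP-1 term is deliberately
    shallow -- a floor keeps basal secretion alive in GLP-1-null scenarios.
    """
    g = max(glc_sysa, 0.0) ** p.insulin_glc_exponent
    km = p.beta_cell_km ** p.insulin_glc_exponent
    glp_eff = max(glp1_sysa, 0.0) + p.insulin_glp1_floor
    return (
        p.insulin_glc_sensitivity * (g / (g + km)) * glp_eff / (glp_eff + p.insulin_glp1_km)
    )


def glucagon_secretion_rate(glc_sysa: float, p: SecretionParameters) -> float:
    """Alpha-cell glucagon release (pmol/min), suppressed by arterial glucose."""
    g = max(glc_sysa, 0.0) ** p.glucagon_exponent
    km = p.glucagon_km ** p.glucagon_exponent
    return p.glucagon_sensitivity * (1.0 - g / (g + km))


def glp1_secretion_rate(glc_smcap: float, p: SecretionParameters) -> float:
    """L-cell GLP-1 release (pmol/min), driven by splanchnic capillary glucose."""
    g = max(glc_smcap, 0.0) ** p.glp1_glc_exponent
    km = p.glp1_km_glut2 ** p.glp1_glc_exponent
    return p.glp1_glc_sensitivity * p.glp1_secretion_scale * g / (g + km)


def first_order_degradation(amount: float, loss_rate: float) -> float:
    """First-order loss (amount/min); exponential decay with t1/2 = ln2/rate."""
    if amount < 0:
        amount = 0.0
    return amount * loss_rate
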