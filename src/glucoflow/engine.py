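"""Full-model assembly, fasting equilibration, gavage protocol and integration.

The complete state vector stacks, in a fixed documented layout:

====================  ==========================================
indices               contents
====================  ==========================================
0:8                   compartment blood volumes, ml
8:16                  glucose amounts, mmol
16:24                 insulin amounts, pmol
24:32                 glucagon amounts, pmol
32:40                 GLP-1 amounts, pmol
40                    intestinal-lumen glucose, mmol
====================  ==========================================

Compartment order follows :data:`glucoflow.circulation.COMPARTMENTS`.
Concentrations are amounts over three times the compartment blood volume
(blood = one third of the extracellular distribution space), so the advected
concentration equals the plasma concentration.

Runs are deterministic: there is no randomness anywhere in the engine, and
identical scenarios produce bitwise-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import species as sp
from .circulation import COMPARTMENTS, CirculationNetwork, build_default_network
from .errors import ConfigurationError, IntegrationError

__all__ = [
    "GavageProtocol",
    "Scenario",
    "ModelParameters",
    "SolverSettings",
    "SimulationResult",
    "assemble_derivatives",
    "equilibrate",
    "run_scenario",
    "run_sweep",
    "initial_state",
]

IX = {name: i for i, name in enumerate(COMPARTMENTS)}
N = len(COMPARTMENTS)
SL_VOL = slice(0, 8)
SL_GLC = slice(8, 16)
SL_INS = slice(16, 24)
SL_GLN = slice(24, 32)
SL_GLP = slice(32, 40)
IX_LUMEN = 40
NSTATE = 41

TOTAL_BLOOD_VOLUME = 5000.0  # ml
VOLUME_RELIEF_TAU = 60.0  # min; renal relief of absorbed-fluid volume excess


@dataclass(frozen=True)
class GavageProtocol:
    """Duodenal glucose gavage: dose (g) delivered at a constant rate."""

    dose_g: float = 50.0
    start_time: float = 100.0  # min
    duration: float = 20.0  # min

    def __post_init__(self) -> None:
        if self.dose_g < 0 or self.duration <= 0:
            raise ConfigurationError("gavage needs dose >= 0 and duration > 0")

    @property
    def dose_mmol(self) -> float:
        return self.dose_g * 1000.0 / 180.156  # glucose molar mass

    @property
    def rate_mmol_min(self) -> float:
        return self.dose_mmol / self.duration


@dataclass(frozen=True)
class Scenario:
    """A simulation scenario: the four headline knobs plus the gavage protocol."""

    glp1_glucose_sensitivity: float = 50.0
    p_gl: float = 0.15  # um/s
    pss_resistance: float = 0.4  # mm Hg.s/ml (40 = shunt absent, 0.005 = wide open)
    presinusoidal_resistance: float = 0.005  # mm Hg.s/ml
    gavage: GavageProtocol = field(default_factory=GavageProtocol)
    overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.pss_resistance <= 0 or self.presinusoidal_resistance <= 0:
            raise ConfigurationError("scenario resistances must be > 0")
        if self.glp1_glucose_sensitivity < 0 or self.p_gl < 0:
            raise ConfigurationError("sensitivity and p_gl must be >= 0")


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic parameter blocks (circulation topology is built separately)."""

    absorption: sp.AbsorptionParameters = field(default_factory=sp.AbsorptionParameters)
    hepatic: sp.HepaticKinetics = field(default_factory=sp.HepaticKinetics)
    peripheral: sp.PeripheralKinetics = field(default_factory=sp.PeripheralKinetics)
    secretion: sp.SecretionParameters = field(default_factory=sp.SecretionParameters)
    renal: sp.RenalParameters = field(default_factory=sp.RenalParameters)


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integration settings; defaults match the accuracy contract."""

    rtol: float = 1e-7
    atol_volume: float = 1e-6  # ml
    atol_amount: float = 1e-9  # mmol / pmol
    method: str = "LSODA"
    output_dt: float = 1.0 / 12.0  # min (5-s cadence)
    t_end: float = 180.0  # min
    equilibration_time: float = 600.0  # min of virtual fasting
    equilibration_tol: float = 1e-7  # max relative derivative, per min


def _apply_overrides(params: ModelParameters, overrides: Iterable[tuple[str, float]]) -> ModelParameters:
    for path, value in overrides:
        block_name, _, leaf = path.partition(".")
        if not leaf:
            raise ConfigurationError(f"override path '{path}' must be '<block>.<name>'")
        try:
            block = getattr(params, block_name)
            block = replace(block, **{leaf: value})
        except (AttributeError, TypeError) as exc:
            raise ConfigurationError(f"unknown override path '{path}'") from exc
        params = replace(params, **{block_name: block})
    return params


def _effective(scenario: Scenario, params: ModelParameters) -> tuple[CirculationNetwork, ModelParameters]:
    """Fold the scenario knobs into a network and a parameter set."""
    params = _apply_overrides(params, scenario.overrides)
    params = replace(
        params,
        absorption=replace(params.absorption, p_gl=scenario.p_gl),
        secretion=replace(
            params.secretion, glp1_glc_sensitivity=scenario.glp1_glucose_sensitivity
        ),
    )
    net = build_default_network(
        pss_resistance=scenario.pss_resistance,
        presinusoidal_resistance=scenario.presinusoidal_resistance,
    )
    return net, params


def build_rhs(
    scenario: Scenario, params: ModelParameters, gavage_on: bool = True
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the full right-hand side f(t, y) for one scenario.

    The derivative is composed exclusively from the circulation and species
    rate operations; there are no inline kinetics here.
    """
    net, prm = _effective(scenario, params)
    absn, hep, per, sec, ren = prm.absorption, prm.hepatic, prm.peripheral, prm.secretion, prm.renal

    v0 = np.array([c.unstressed_volume for c in net.compartments])
    comp = np.array([c.compliance for c in net.compartments])
    src, snk = net._src, net._snk
    res, pump = net._res.copy(), net._pump
    sma_i = net._sma_i
    ctrl = net.glp1_control
    nseg = len(net.segments)
    # signed incidence matrix: dA = M @ flux
    M = np.zeros((N, nseg))
    for j in range(nseg):
        M[snk[j], j] += 1.0
        M[src[j], j] -= 1.0

    i_art, i_sc, i_hep, i_som, i_ren = (
        IX["sys_art"], IX["sm_cap"], IX["hep"], IX["somatic"], IX["renal"],
    )
    j_renal_a = net.segment_index("renal_a")
    gav = scenario.gavage
    g_rate = gav.rate_mmol_min if gavage_on else 0.0
    g_start, g_end = gav.start_time, gav.start_time + gav.duration
    lumen_vol = absn.lumen_volume

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            bad = int(np.argmin(np.isfinite(y)))
            raise IntegrationError(
                f"non-finite state at t={t:.3f} min, index {bad}; state={y!r}"
            )
        vol = y[SL_VOL]
        dist = 3.0 * vol  # distribution volumes, ml
        # concentrations as amount per ml of distribution volume
        E = np.empty((4, N))
        E[0] = y[SL_GLC] / dist
        E[1] = y[SL_INS] / dist
        E[2] = y[SL_GLN] / dist
        E[3] = y[SL_GLP] / dist
        np.maximum(E, 0.0, out=E)
        glc = 1000.0 * E[0]  # mM
        ins = 1000.0 * E[1]  # pM
        gln = E[2]  # nM
        glp = 1000.0 * E[3]  # pM

        # --- circulation ---
        p = (vol - v0) / comp
        r = res
        if sma_i >= 0:
            r = res.copy()
            r[sma_i] = ctrl.r_sma_0 * ctrl.km_glp1 / (ctrl.km_glp1 + glp[i_sc])
        q = (p[src] + pump - p[snk]) / r  # ml/s
        q_min = 60.0 * q  # ml/min
        dvol = M @ q_min

        # --- advection (upwind/donor convention) ---
        donor = np.where(q_min > 0, E[:, src], E[:, snk])
        flux = q_min * donor
        dA = flux @ M.T  # (4, N)

        # --- intestinal absorption ---
        lumen_glc = 1000.0 * max(y[IX_LUMEN], 0.0) / lumen_vol  # mM
        absorption = sp.intestinal_absorption_rate(lumen_glc, glc[i_sc], absn)
        dA[0, i_sc] += absorption
        d_lumen = -absorption
        if g_rate > 0.0 and g_start <= t < g_end:
            d_lumen += g_rate

        # --- metabolism and excretion ---
        nhgu = sp.hepatic_metabolic_rate(glc[i_hep], ins[i_hep], glp[i_hep], gln[i_hep], hep)
        dep = sp.peripheral_insulin_dependent_rate(glc[i_som], ins[i_som], glp[i_som], per)
        indep = sp.insulin_independent_rate(glc[i_som], per)
        urine = sp.renal_glucose_excretion(glc[i_ren], q_min[j_renal_a], ren)
        dA[0, i_hep] -= nhgu
        dA[0, i_som] -= dep + indep
        dA[0, i_ren] -= urine

        # --- hormone secretion (into the SM-capillary compartment) ---
        dA[1, i_sc] += sp.insulin_secretion_rate(glc[i_art], glp[i_art], sec)
        dA[2, i_sc] += sp.glucagon_secretion_rate(glc[i_art], sec)
        dA[3, i_sc] += sp.glp1_secretion_rate(glc[i_sc], sec)

        # --- hormone degradation (hepatic and systemic territories) ---
        dA[1, i_hep] -= sp.first_order_degradation(y[SL_INS][i_hep], sec.insulin_loss_hepatic)
        dA[1, i_som] -= sp.first_order_degradation(y[SL_INS][i_som], sec.insulin_loss_systemic)
        dA[2, i_hep] -= sp.first_order_degradation(y[SL_GLN][i_hep], sec.glucagon_loss_hepatic)
        dA[2, i_som] -= sp.first_order_degradation(y[SL_GLN][i_som], sec.glucagon_loss_systemic)
        dA[3, i_hep] -= sp.first_order_degradation(y[SL_GLP][i_hep], sec.glp1_loss_hepatic)
        dA[3, i_som] -= sp.first_order_degradation(y[SL_GLP][i_som], sec.glp1_loss_systemic)

        # --- fluid coupling: solvent drag of absorbed glucose, renal relief ---
        dvol[i_sc] += absn.water_per_mmol * max(absorption, 0.0)
        excess = vol.sum() - TOTAL_BLOOD_VOLUME
        if excess > 0.0:
            dvol[i_ren] -= excess / VOLUME_RELIEF_TAU

        dy = np.empty(NSTATE)
        dy[SL_VOL] = dvol
        dy[SL_GLC] = dA[0]
        dy[SL_INS] = dA[1]
        dy[SL_GLN] = dA[2]
        dy[SL_GLP] = dA[3]
        dy[IX_LUMEN] = d_lumen
        return dy

    return rhs


def assemble_derivatives(
    t: float, state: np.ndarray, scenario: Scenario, params: ModelParameters
) -> np.ndarray:
    """One-shot evaluation of the full derivative vector (documented layout)."""
    return build_rhs(scenario, params)(t, np.asarray(state, dtype=float))


def initial_state(params: ModelParameters) -> np.ndarray:
    """Nominal pre-equilibration state: design volumes, 5 mM glucose, basal hormones."""
    y = np.zeros(NSTATE)
    net = build_default_network()
    vols = np.array([c.initial_volume for c in net.compartments])
    y[SL_VOL] = vols
    y[SL_GLC] = 0.005 * 3.0 * vols  # 5 mM
    y[SL_INS] = 0.030 * 3.0 * vols  # 30 pM
    y[SL_GLN] = 0.7 * 3.0 * vols  # 0.7 nM
    y[SL_GLP] = 0.020 * 3.0 * vols  # 20 pM
    y[IX_LUMEN] = 0.0
    return y


def _atol(settings: SolverSettings) -> np.ndarray:
    a = np.full(NSTATE, settings.atol_amount)
    a[SL_VOL] = settings.atol_volume
    return a


_EQ_CACHE: dict[tuple, np.ndarray] = {}


def equilibrate(
    scenario: Scenario,
    params: ModelParameters | None = None,
    settings: SolverSettings | None = None,
    y0: np.ndarray | None = None,
    use_cache: bool = True,
) -> np.ndarray:
    """Integrate to the fasting steady state (no gavage) and return the state.

    Convergence is judged on the maximum relative state derivative
    (|dy|/(|y| + atol), per minute).  Raises a diagnostic error naming the
    worst state entries if the fasting run does not settle.
    """
    params = params or ModelParameters()
    settings = settings or SolverSettings()
    fasting = replace(scenario, gavage=GavageProtocol(dose_g=0.0))
    key = (fasting, params, settings.rtol, settings.method)
    if use_cache and y0 is None and key in _EQ_CACHE:
        return _EQ_CACHE[key].copy()

    rhs = build_rhs(fasting, params, gavage_on=False)
    y = initial_state(params) if y0 is None else np.asarray(y0, dtype=float).copy()
    atol = _atol(settings)
    t_chunk = settings.equilibration_time
    worst = None
    for _ in range(4):
        sol = solve_ivp(
            rhs, (0.0, t_chunk), y, method=settings.method,
            rtol=settings.rtol, atol=atol, dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(f"fasting equilibration failed: {sol.message}")
        y = sol.y[:, -1]
        dy = rhs(0.0, y)
        rel = np.abs(dy) / (np.abs(y) + atol)
        worst = rel.max()
        if worst < settings.equilibration_tol:
            break
    else:
        order = np.argsort(rel)[::-1][:5]
        raise IntegrationError(
            "fasting state did not converge; worst relative derivatives: "
            + ", ".join(f"state[{i}]={rel[i]:.2e}/min" for i in order)
        )
    if use_cache and y0 is None:
        _EQ_CACHE[key] = y.copy()
    return y.copy()


# ---------------------------------------------------------------------------
# diagnostics / result assembly

_SPECIES_FLOW_SEGMENTS = ("sma", "portal_v", "hep_a", "hep_v", "hep_shunt")


def _diagnostics_row(
    t: float, y: np.ndarray, net: CirculationNetwork, prm: ModelParameters
) -> dict[str, float]:
    absn, hep, per, sec, ren = prm.absorption, prm.hepatic, prm.peripheral, prm.secretion, prm.renal
    vol = y[SL_VOL]
    dist = 3.0 * vol
    glc = np.maximum(1000.0 * y[SL_GLC] / dist, 0.0)
    ins = np.maximum(1000.0 * y[SL_INS] / dist, 0.0)
    gln = np.maximum(y[SL_GLN] / dist, 0.0)
    glp = np.maximum(1000.0 * y[SL_GLP] / dist, 0.0)
    p = net.pressures(vol)
    q = net.flows(p, glp[IX["sm_cap"]])  # ml/s
    q_min = 60.0 * q

    row: dict[str, float] = {"time_min": t}
    for i, name in enumerate(COMPARTMENTS):
        row[f"P_{name}"] = p[i]
    for j, seg in enumerate(net.segments):
        row[f"Q_{seg.name}"] = q_min[j]
    for i, name in enumerate(COMPARTMENTS):
        row[f"glc_{name}"] = glc[i]
        row[f"ins_{name}"] = ins[i]
        row[f"gln_{name}"] = gln[i]
        row[f"glp1_{name}"] = glp[i]
    lumen_mM = 1000.0 * max(y[IX_LUMEN], 0.0) / absn.lumen_volume
    row["lumen_glc_mM"] = lumen_mM
    row["lumen_glc_mmol"] = y[IX_LUMEN]
    row["total_blood_volume"] = vol.sum()

    i_sc, i_hep, i_som, i_ren, i_art = (
        IX["sm_cap"], IX["hep"], IX["somatic"], IX["renal"], IX["sys_art"],
    )
    absorption = sp.intestinal_absorption_rate(lumen_mM, glc[i_sc], absn)
    row["absorption_rate"] = absorption
    row["NHGU"] = sp.hepatic_metabolic_rate(glc[i_hep], ins[i_hep], glp[i_hep], gln[i_hep], hep)
    row["periph_insulin_dep"] = sp.peripheral_insulin_dependent_rate(
        glc[i_som], ins[i_som], glp[i_som], per
    )
    row["periph_insulin_indep"] = sp.insulin_independent_rate(glc[i_som], per)
    row["renal_excretion"] = sp.renal_glucose_excretion(
        glc[i_ren], q_min[net.segment_index("renal_a")], ren
    )
    row["sec_insulin"] = sp.insulin_secretion_rate(glc[i_art], glp[i_art], sec)
    row["sec_glucagon"] = sp.glucagon_secretion_rate(glc[i_art], sec)
    row["sec_glp1"] = sp.glp1_secretion_rate(glc[i_sc], sec)
    grad = lumen_mM - glc[i_sc]
    row["unidir_permeability_um_s"] = (
        absorption / (absn.exchange_scale * grad) if grad > 0.5 else math.nan
    )

    # species flows through named segments (donor convention), amount/min
    E = np.vstack([glc / 1000.0, ins / 1000.0, gln, glp / 1000.0])
    labels = ("glc", "ins", "gln", "glp1")
    for seg_name in _SPECIES_FLOW_SEGMENTS:
        j = net.segment_index(seg_name)
        s_i, k_i = net._src[j], net._snk[j]
        donor = E[:, s_i] if q_min[j] > 0 else E[:, k_i]
        for lab, conc in zip(labels, donor):
            row[f"{lab}flow_{seg_name}"] = q_min[j] * conc
    return row


@dataclass
class SimulationResult:
    """Time series of pressures, flows, concentrations and metabolic rates."""

    frame: pd.DataFrame
    scenario: Scenario
    params: ModelParameters
    fasting_state: np.ndarray
    states: np.ndarray  # (n_times, NSTATE) raw state trajectory

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"unknown quantity '{name}'")
        return self.frame[name].to_numpy()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series(name)


def run_scenario(
    scenario: Scenario,
    params: ModelParameters | None = None,
    settings: SolverSettings | None = None,
) -> SimulationResult:
    """Equilibrate, apply the gavage protocol, and integrate the full model.

    Integration is split at the gavage switch-on/off times so the stiff
    solver never steps across a source discontinuity.
    """
    params = params or ModelParameters()
    settings = settings or SolverSettings()
    y_fast = equilibrate(scenario, params, settings)
    rhs = build_rhs(scenario, params, gavage_on=True)
    atol = _atol(settings)

    gav = scenario.gavage
    breaks = [0.0]
    for tb in (gav.start_time, gav.start_time + gav.duration):
        if gav.dose_g > 0 and 0.0 < tb < settings.t_end:
            breaks.append(tb)
    breaks.append(settings.t_end)

    n_out = int(round(settings.t_end / settings.output_dt)) + 1
    t_eval_all = np.linspace(0.0, settings.t_end, n_out)

    y = y_fast.copy()
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (t_eval_all >= a) & (t_eval_all <= b)
        te = np.unique(np.concatenate([[a], t_eval_all[mask], [b]]))
        sol = solve_ivp(
            rhs, (a, b), y, method=settings.method,
            rtol=settings.rtol, atol=atol, t_eval=te,
        )
        if not sol.success:
            raise IntegrationError(f"integration failed in [{a}, {b}] min: {sol.message}")
        y = sol.y[:, -1]
        keep = np.isin(sol.t, t_eval_all[mask])
        times.append(sol.t[keep])
        states.append(sol.y[:, keep].T)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    # drop duplicated break points
    _, uniq = np.unique(np.round(t_all, 9), return_index=True)
    t_all, y_all = t_all[uniq], y_all[uniq]

    net, prm = _effective(scenario, params)
    rows = [_diagnostics_row(t, yy, net, prm) for t, yy in zip(t_all, y_all)]
    frame = pd.DataFrame(rows)
    return SimulationResult(frame, scenario, params, y_fast, y_all)


def run_sweep(
    base: Scenario,
    axis1: tuple[str, Iterable[float]],
    axis2: tuple[str, Iterable[float]] | None = None,
    params: ModelParameters | None = None,
    settings: SolverSettings | None = None,
) -> dict[tuple[float, ...], SimulationResult | Exception]:
    """Run one simulation per grid point over one or two scenario axes.

    Returns a dict keyed by the grid point tuple, in deterministic row-major
    order.  A failing point stores its exception instead of aborting the
    whole sweep.
    """
    name1, grid1 = axis1[0], list(axis1[1])
    grids: list[list[float]] = [grid1]
    names = [name1]
    if axis2 is not None:
        names.append(axis2[0])
        grids.append(list(axis2[1]))
    if any(len(g) == 0 for g in grids):
        raise ConfigurationError("sweep grids must be non-empty")

    def set_knob(sc: Scenario, name: str, value: float) -> Scenario:
        if hasattr(sc, name) and name != "overrides":
            return replace(sc, **{name: value})
        return replace(sc, overrides=sc.overrides + ((name, value),))

    out: dict[tuple[float, ...], SimulationResult | Exception] = {}
    points = [(v,) for v in grids[0]] if axis2 is None else [
        (v1, v2) for v1 in grids[0] for v2 in grids[1]
    ]
    for pt in points:
        sc = base
        for name, value in zip(names, pt):
            sc = set_knob(sc, name, value)
        try:
            out[pt] = run_scenario(sc, params, settings)
        except Exception as exc:  # noqa: BLE001 - reported per point by contract
            out[pt] = exc
    return out
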