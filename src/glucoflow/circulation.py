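"""Closed blood-circulation network: compliant compartments joined by resistive vessels.

The systemic and splanchnic circulations are represented as a lumped
resistance--compliance network obeying Kirchhoff's laws.  Eight compliant
compartments (systemic arteries, superior-mesenteric capillary bed, hepatic
sinusoids, splenic & coeliac bed, lungs, somatic bed, renal bed, systemic
veins) are joined by resistive vessel segments; the two ventricles are
pressure sources in series with their outflow resistances.  The superior
mesenteric artery (SMA) is the only glucose-responsive element: its
resistance falls hyperbolically with the local GLP-1 concentration, so every
other flow change in the model is a passive, purely mechanical reaction.

Pressure--volume law: linear, ``P = (V - V_unstressed) / C``.  Compliances
are derived from fractional distensibilities (volume change per unit volume
per mm Hg) applied to the resting compartment volumes, which yields
physiological absolute compliances (stiff arteries, very compliant veins).

Default resistances, pump pressures and unstressed volumes are derived
analytically from a resting design point (cardiac output 5.5 L/min, mean
aortic pressure 105 mm Hg, portal pressure ~1.5 mm Hg, SMA flow 500 ml/min,
hepatic-artery flow 700 ml/min) so that the fasting state of the network is
a steady state by construction.  The presinusoidal (portal vein), hepatic
vein and portosystemic-shunt resistances are the disease knobs and keep
their nominal values (0.005, 0.001, 0.4 mm Hg·s·ml^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InvalidStateError

__all__ = [
    "CompartmentSpec",
    "VesselSegment",
    "GLP1FlowControl",
    "PressureState",
    "CirculationNetwork",
    "compartment_pressure",
    "segment_flow",
    "sma_resistance",
    "volume_derivatives",
    "steady_state_check",
    "build_default_network",
    "COMPARTMENTS",
    "FASTING_DESIGN",
]


@dataclass(frozen=True)
class CompartmentSpec:
    """A compliant blood compartment.

    compliance is in ml per mm Hg; volumes in ml.  ``initial_volume`` is the
    resting (design-point) volume, ``unstressed_volume`` the volume at zero
    transmural pressure.
    """

    name: str
    compliance: float
    initial_volume: float
    unstressed_volume: float

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ConfigurationError(f"compartment {self.name}: compliance must be > 0")
        if not (self.initial_volume >= self.unstressed_volume >= 0):
            raise ConfigurationError(
                f"compartment {self.name}: need initial_volume >= unstressed_volume >= 0"
            )


@dataclass(frozen=True)
class VesselSegment:
    """A resistive vessel segment (optionally with a series pressure source).

    ``resistance`` is in mm Hg·s·ml^-1, so flow = dP/R is in ml/s.
    ``pump_pressure`` (mm Hg) models a ventricle as a pressure source in
    series with its outflow resistance; zero for passive vessels.
    ``glp1_sensitive`` marks the SMA, whose resistance is modulated at run
    time by the splanchnic GLP-1 concentration.
    """

    name: str
    source_node: str
    sink_node: str
    resistance: float
    glp1_sensitive: bool = False
    pump_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ConfigurationError(f"segment {self.name}: resistance must be > 0")
        if self.source_node == self.sink_node:
            raise ConfigurationError(f"segment {self.name}: source equals sink")


@dataclass(frozen=True)
class GLP1FlowControl:
    """Hyperbolic GLP-1 control of SMA resistance.

    R_SMA(GLP) = r_sma_0 * km_glp1 / (km_glp1 + GLP), GLP in pM.
    """

    r_sma_0: float
    km_glp1: float

    def __post_init__(self) -> None:
        if self.r_sma_0 <= 0 or self.km_glp1 <= 0:
            raise ConfigurationError("GLP1FlowControl parameters must be > 0")


@dataclass
class PressureState:
    """Node pressures (mm Hg) and segment flows (ml/s, sign = source->sink)."""

    node_pressures: dict[str, float]
    segment_flows: dict[str, float]


def compartment_pressure(volume: float, spec: CompartmentSpec) -> float:
    """Transmural pressure (mm Hg) of a compartment holding ``volume`` ml."""
    if volume < 0:
        raise InvalidStateError(f"compartment {spec.name}: negative volume {volume}")
    return (volume - spec.unstressed_volume) / spec.compliance


def segment_flow(p_source: float, p_sink: float, resistance: float) -> float:
    """Flow (ml/s) through a passive segment; antisymmetric in its endpoints."""
    if resistance <= 0:
        raise ConfigurationError("segment resistance must be > 0")
    return (p_source - p_sink) / resistance


def sma_resistance(glp1_sm: float, ctrl: GLP1FlowControl) -> float:
    """SMA resistance (mm Hg·s·ml^-1) at splanchnic GLP-1 concentration (pM)."""
    if glp1_sm < 0:
        raise InvalidStateError(f"negative GLP-1 concentration {glp1_sm}")
    return ctrl.r_sma_0 * ctrl.km_glp1 / (ctrl.km_glp1 + glp1_sm)


# ---------------------------------------------------------------------------
# Network container

COMPARTMENTS = (
    "sys_art",
    "sm_cap",
    "hep",
    "splanch",
    "lung",
    "somatic",
    "renal",
    "sys_vein",
)


@dataclass
class CirculationNetwork:
    """The full closed circuit: ordered compartments plus vessel segments."""

    compartments: tuple[CompartmentSpec, ...]
    segments: tuple[VesselSegment, ...]
    glp1_control: GLP1FlowControl

    # derived index arrays, built in __post_init__
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _src: np.ndarray = field(default=None, repr=False)
    _snk: np.ndarray = field(default=None, repr=False)
    _res: np.ndarray = field(default=None, repr=False)
    _pump: np.ndarray = field(default=None, repr=False)
    _sma_i: int = field(default=-1, repr=False)

    def __post_init__(self) -> None:
        self._index = {c.name: i for i, c in enumerate(self.compartments)}
        for seg in self.segments:
            if seg.source_node not in self._index or seg.sink_node not in self._index:
                raise ConfigurationError(
                    f"segment {seg.name}: dangling endpoint "
                    f"({seg.source_node} -> {seg.sink_node})"
                )
        self._src = np.array([self._index[s.source_node] for s in self.segments])
        self._snk = np.array([self._index[s.sink_node] for s in self.segments])
        self._res = np.array([s.resistance for s in self.segments], dtype=float)
        self._pump = np.array([s.pump_pressure for s in self.segments], dtype=float)
        sma = [i for i, s in enumerate(self.segments) if s.glp1_sensitive]
        if len(sma) > 1:
            raise ConfigurationError("only one GLP-1-sensitive segment is supported")
        self._sma_i = sma[0] if sma else -1

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def segment_index(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise KeyError(name)

    def with_resistance(self, name: str, value: float) -> "CirculationNetwork":
        """Return a copy with one segment's resistance replaced."""
        segs = tuple(
            replace(s, resistance=value) if s.name == name else s for s in self.segments
        )
        return CirculationNetwork(self.compartments, segs, self.glp1_control)

    # -- vectorized physics ------------------------------------------------
    def pressures(self, volumes: np.ndarray) -> np.ndarray:
        """Node pressures (mm Hg) from compartment volumes (ml)."""
        if np.any(volumes < 0):
            bad = self.compartments[int(np.argmin(volumes))].name
            raise InvalidStateError(f"negative volume in compartment {bad}")
        v0 = np.array([c.unstressed_volume for c in self.compartments])
        comp = np.array([c.compliance for c in self.compartments])
        return (volumes - v0) / comp

    def flows(self, pressures: np.ndarray, glp1_sm: float) -> np.ndarray:
        """Segment flows (ml/s); the SMA resistance is GLP-1 modulated."""
        res = self._res
        if self._sma_i >= 0:
            res = res.copy()
            res[self._sma_i] = sma_resistance(glp1_sm, self.glp1_control)
        return (pressures[self._src] + self._pump - pressures[self._snk]) / res

    def net_flows(self, flows: np.ndarray) -> np.ndarray:
        """Net inflow (ml/s) per compartment; sums to zero over the circuit."""
        net = np.zeros(self.n_compartments)
        np.add.at(net, self._snk, flows)
        np.add.at(net, self._src, -flows)
        return net

    def pressure_state(self, volumes: np.ndarray, glp1_sm: float) -> PressureState:
        p = self.pressures(volumes)
        q = self.flows(p, glp1_sm)
        return PressureState(
            node_pressures={c.name: p[i] for i, c in enumerate(self.compartments)},
            segment_flows={s.name: q[i] for i, s in enumerate(self.segments)},
        )


def volume_derivatives(network: CirculationNetwork, state: PressureState) -> dict[str, float]:
    """dV/dt (ml/s) per compartment from a set of segment flows."""
    flows = np.array([state.segment_flows[s.name] for s in network.segments])
    net = network.net_flows(flows)
    return {c.name: net[i] for i, c in enumerate(network.compartments)}


def steady_state_check(
    network: CirculationNetwork, state: PressureState, tolerance: float = 0.01
) -> bool:
    """True iff every compartment's net flow magnitude is below ``tolerance`` ml/s."""
    net = volume_derivatives(network, state)
    return all(abs(v) < tolerance for v in net.values())


# ---------------------------------------------------------------------------
# Default network: analytic calibration to the resting design point.
#
# FASTING_DESIGN maps each compartment to (volume ml, distensibility per mmHg,
# design pressure mmHg) and each perfusion branch to its design flow (ml/min).
# Resistances follow as dP/Q; pump pressures close the loop.

FASTING_DESIGN = {
    "cardiac_output": 5500.0,  # ml/min
    "pressures": {
        "sys_art": 105.0,
        "somatic": 15.0,
        "renal": 15.0,
        "splanch": 10.0,
        "lung": 8.0,
        "sys_vein": 1.43,
        # sm_cap and hep follow from the venous pressure and the fixed
        # portal/hepatic-vein resistances (computed below)
    },
    "flows": {  # ml/min at the design point
        "somatic": 2800.0,
        "renal": 1100.0,
        "sma": 500.0,
        "splenic": 400.0,
        "hep_a": 700.0,
    },
    "volumes": {  # resting compartment volumes, ml (total 5000)
        "sys_art": 550.0,
        "sm_cap": 300.0,
        "hep": 450.0,
        "splanch": 300.0,
        "lung": 500.0,
        "somatic": 1600.0,
        "renal": 300.0,
        "sys_vein": 1000.0,
    },
    "distensibility": {  # fractional distensibility, per mm Hg
        "sys_art": 0.001,
        "sm_cap": 0.005,
        "hep": 0.005,
        "splanch": 0.05,
        "lung": 0.01,
        "somatic": 0.01,
        "renal": 0.05,
        "sys_vein": 0.1,
    },
    # fixed "verbatim" resistances (mm Hg.s/ml)
    "portal_v_resistance": 0.005,  # presinusoidal, the NASH knob
    "hep_v_resistance": 0.0003,
    "shunt_resistance": 0.4,  # portosystemic shunt, near-closed default
    "pulmonary_resistance": 0.35,  # vena cava + right-heart + pulmonary path
    "aortic_resistance": 0.04,  # left-heart outflow
    # GLP-1 flow control: fasting splanchnic GLP-1 reference and half-max (pM)
    "glp1_fasting_ref": 22.0,
    "km_glp1_flow": 10.0,
}


def build_default_network(
    pss_resistance: float | None = None,
    presinusoidal_resistance: float | None = None,
) -> CirculationNetwork:
    """Build the default calibrated network, optionally overriding disease knobs."""
    d = FASTING_DESIGN
    p = dict(d["pressures"])
    q = {k: v / 60.0 for k, v in d["flows"].items()}  # ml/s
    co = d["cardiac_output"] / 60.0

    r_pv = d["portal_v_resistance"] if presinusoidal_resistance is None else presinusoidal_resistance
    r_sh = d["shunt_resistance"] if pss_resistance is None else pss_resistance
    r_hv = d["hep_v_resistance"]
    if r_pv <= 0 or r_sh <= 0:
        raise ConfigurationError("shunt and presinusoidal resistances must be > 0")

    # Splanchnic venous pressures consistent with the fixed venous resistances.
    # The design point uses the *default* presinusoidal/shunt resistances; when a
    # scenario overrides them the fasting state re-equilibrates dynamically.
    r_pv0, r_sh0 = d["portal_v_resistance"], d["shunt_resistance"]
    # iterate the tiny shunt/PV split to consistency
    q_shunt = 0.0
    for _ in range(50):
        q_pv = q["sma"] - q_shunt
        q_hv = q_pv + q["hep_a"] + q["splenic"]
        p_hep = p["sys_vein"] + q_hv * r_hv
        p_smcap = p_hep + q_pv * r_pv0
        q_shunt = (p_smcap - p["sys_vein"]) / r_sh0
    p["hep"] = p_hep
    p["sm_cap"] = p_smcap

    # GLP-1 control: the fasting SMA resistance implied by the design point,
    # back-projected to zero GLP-1 through the hyperbolic law.
    km = d["km_glp1_flow"]
    r_sma_fast = (p["sys_art"] - p["sm_cap"]) / q["sma"]
    r_sma_0 = r_sma_fast * (km + d["glp1_fasting_ref"]) / km

    compartments = []
    for name in COMPARTMENTS:
        v = d["volumes"][name]
        c = d["distensibility"][name] * v
        compartments.append(
            CompartmentSpec(
                name=name,
                compliance=c,
                initial_volume=v,
                unstressed_volume=v - c * p[name],
            )
        )

    def r(a: str, b: str, flow: float) -> float:
        return (p[a] - p[b]) / flow

    p_rv = p["lung"] - p["sys_vein"] + co * d["pulmonary_resistance"]
    p_lv = p["sys_art"] - p["lung"] + co * d["aortic_resistance"]

    segments = (
        VesselSegment("left_heart", "lung", "sys_art", d["aortic_resistance"],
                      pump_pressure=p_lv),
        VesselSegment("somatic_a", "sys_art", "somatic", r("sys_art", "somatic", q["somatic"])),
        VesselSegment("somatic_v", "somatic", "sys_vein", r("somatic", "sys_vein", q["somatic"])),
        VesselSegment("renal_a", "sys_art", "renal", r("sys_art", "renal", q["renal"])),
        VesselSegment("renal_v", "renal", "sys_vein", r("renal", "sys_vein", q["renal"])),
        VesselSegment("splenic_a", "sys_art", "splanch", r("sys_art", "splanch", q["splenic"])),
        VesselSegment("splenic_v", "splanch", "hep", r("splanch", "hep", q["splenic"])),
        VesselSegment("sma", "sys_art", "sm_cap", r_sma_fast, glp1_sensitive=True),
        VesselSegment("hep_a", "sys_art", "hep", r("sys_art", "hep", q["hep_a"])),
        VesselSegment("portal_v", "sm_cap", "hep", r_pv),
        VesselSegment("hep_v", "hep", "sys_vein", r_hv),
        VesselSegment("hep_shunt", "sm_cap", "sys_vein", r_sh),
        VesselSegment("right_heart", "sys_vein", "lung", d["pulmonary_resistance"],
                      pump_pressure=p_rv),
    )
    return CirculationNetwork(tuple(compartments), segments, GLP1FlowControl(r_sma_0, km))
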