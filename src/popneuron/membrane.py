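"""Single-compartment Hodgkin-Huxley membrane model.

The model represents a neuronal soma as one cylindrical compartment with a
set of ionic currents, each written in Hodgkin-Huxley form

    I = gbar * prod_j x_j^{p_j} * (V - E_rev)        [mA/cm^2, outward > 0]

where each gating variable relaxes as dx/dt = (x_inf(V) - x) / tau_x(V).
Voltages are in mV, times in ms, conductance densities in S/cm^2 and the
specific capacitance in uF/cm^2, so that

    dV/dt = 1000 * (I_stim / A - sum_i I_i) / C_m    [mV/ms]

with the stimulus current in mA and the membrane area A in cm^2.

Gating kinetics are declarative: each gate carries a small parameter
dictionary (a functional form plus coefficients) from which the x_inf and
tau callables are built, so a model can be defined entirely in a YAML file
and transcribed from published channel kinetics without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "ION_VALENCE",
    "CellGeometry",
    "IonConcentrations",
    "GateSpec",
    "IonicCurrentSpec",
    "NeuronModel",
    "ModelState",
    "ModelDefinitionError",
    "SimulationError",
    "nernst_potential",
    "membrane_area",
    "evaluate_current",
    "reversal_potentials",
    "rhs",
    "initialize",
    "simulate",
    "build_gate",
    "load_model",
    "load_model_dict",
    "dump_model",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
ION_VALENCE = {"na": 1, "k": 1, "ca": 2, "cl": -1}


class ModelDefinitionError(ValueError):
    """Raised when a model definition is internally inconsistent."""


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the model for diagnosis."""

    def __init__(self, message: str, model: "NeuronModel" = None, amplitude_pa: float = None):
        super().__init__(message)
        self.model = model
        self.amplitude_pa = amplitude_pa


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Cylinder geometry and passive membrane properties.

    ``axial_resistivity`` (ohm cm) is stored for completeness but has no
    effect in a single compartment (there is no axial current path).
    """

    length: float  # um
    diameter: float  # um
    axial_resistivity: float = 1.0  # ohm cm, unused in a single compartment
    specific_capacitance: float = 1.0  # uF / cm^2

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ModelDefinitionError("length and diameter must be positive")
        if self.specific_capacitance <= 0:
            raise ModelDefinitionError("specific capacitance must be positive")


@dataclass(frozen=True)
class IonConcentrations:
    """Fixed intra/extracellular ion concentrations (mM) and temperature (C).

    Concentrations are held constant throughout a simulation; they enter the
    model only through the Nernst reversal potentials.  Temperature affects
    the Nernst potentials only — gate kinetics are used as published, with
    no Q10 rescaling.
    """

    na_out: float = 145.0
    na_in: float = 5.0
    k_out: float = 3.0
    k_in: float = 135.0
    temperature: float = 32.0

    def __post_init__(self):
        for name in ("na_out", "na_in", "k_out", "k_in"):
            if getattr(self, name) <= 0:
                raise ModelDefinitionError(f"{name} must be positive")


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: steady state, time constant and exponent."""

    name: str
    exponent: int
    steady_state: Callable[[np.ndarray], np.ndarray]
    time_constant: Callable[[np.ndarray], np.ndarray]
    kinetics: Optional[dict] = None  # declarative source, kept for round-trip

    def __post_init__(self):
        if self.exponent < 0:
            raise ModelDefinitionError("gate exponent must be non-negative")


@dataclass(frozen=True)
class IonicCurrentSpec:
    """One HH-form ionic current: conductance density, reversal, gates.

    ``reversal`` is either a fixed value in mV or the string ``"nernst:<ion>"``
    to compute the reversal once from the fixed concentrations.
    """

    name: str
    baseline_conductance: float  # S / cm^2
    reversal: Union[float, str]
    gates: Tuple[GateSpec, ...] = ()

    def __post_init__(self):
        if self.baseline_conductance < 0:
            raise ModelDefinitionError(
                f"current {self.name!r}: conductance must be non-negative")
        names = [g.name for g in self.gates]
        if len(names) != len(set(names)):
            raise ModelDefinitionError(
                f"current {self.name!r}: duplicate gate names")
        object.__setattr__(self, "gates", tuple(self.gates))


@dataclass(frozen=True)
class NeuronModel:
    """A complete single-compartment model plus per-current scaling factors.

    ``scaling`` maps current names to dimensionless multipliers on the
    baseline conductance (1.0 = as published, 0.0 = full block).  Scaling a
    model returns a new instance; models are immutable.
    """

    geometry: CellGeometry
    concentrations: IonConcentrations
    currents: Tuple[IonicCurrentSpec, ...]
    scaling: Dict[str, float] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        object.__setattr__(self, "currents", tuple(self.currents))
        names = {c.name for c in self.currents}
        if len(names) != len(self.currents):
            raise ModelDefinitionError("duplicate current names")
        for key, val in self.scaling.items():
            if key not in names:
                raise ModelDefinitionError(f"scaling key {key!r} names no current")
            if val < 0:
                raise ModelDefinitionError(f"scaling factor for {key!r} is negative")

    @property
    def current_names(self) -> List[str]:
        return [c.name for c in self.currents]

    def scale_factor(self, name: str) -> float:
        return self.scaling.get(name, 1.0)

    def scaled(self, factors: Dict[str, float], compose: bool = True) -> "NeuronModel":
        """Return a copy with new scaling factors.

        With ``compose=True`` (default) the given factors multiply onto the
        model's existing ones, which is how grid experiments apply a block or
        enhancement on top of a population member's own conductances.
        """
        new = dict(self.scaling)
        for key, val in factors.items():
            if compose:
                new[key] = new.get(key, 1.0) * val
            else:
                new[key] = val
        return replace(self, scaling=new)


@dataclass
class ModelState:
    """Instantaneous state: voltage plus every gate value in [0, 1]."""

    voltage: float
    gate_values: Dict[Tuple[str, str], float]

    def check(self, model: NeuronModel) -> None:
        for cur in model.currents:
            for gate in cur.gates:
                key = (cur.name, gate.name)
                if key not in self.gate_values:
                    raise ModelDefinitionError(f"missing gate value {key}")
                x = self.gate_values[key]
                if not (0.0 <= x <= 1.0):
                    raise ModelDefinitionError(f"gate value {key} = {x} outside [0,1]")


# ---------------------------------------------------------------------------
# Gate kinetics functional forms
# ---------------------------------------------------------------------------

def _rate_function(spec: dict) -> Callable:
    """Build an HH rate function alpha(V) or beta(V) (1/ms) from a spec.

    kinds:
      exp        a * exp((v - b) / c)
      explinear  a * (v - b) / (1 - exp(-(v - b) / c)), limit a*c at v == b
      sigmoid    a / (1 + exp(-(v - b) / c))
    """
    kind = spec["kind"]
    a, b, c = float(spec["a"]), float(spec["b"]), float(spec["c"])
    if kind == "exp":
        return lambda v: a * np.exp((np.asarray(v, float) - b) / c)
    if kind == "explinear":
        def f(v):
            v = np.asarray(v, float)
            x = (v - b) / c
            near = np.abs(x) < 1e-7
            xs = np.where(near, 1.0, x)  # keep the generic branch finite
            with np.errstate(over="ignore"):
                out = np.where(near, a * c * (1.0 + x / 2.0),
                               a * c * xs / (1.0 - np.exp(-np.clip(xs, -500, 500))))
            return out
        return f
    if kind == "sigmoid":
        return lambda v: a / (1.0 + np.exp(-(np.asarray(v, float) - b) / c))
    raise ModelDefinitionError(f"unknown rate kind {kind!r}")


def _inf_function(spec: dict) -> Callable:
    form = spec["form"]
    if form == "boltzmann":
        vhalf, k = float(spec["vhalf"]), float(spec["k"])
        return lambda v: 1.0 / (1.0 + np.exp((vhalf - np.asarray(v, float)) / k))
    if form == "constant":
        val = float(spec["value"])
        if not 0.0 <= val <= 1.0:
            raise ModelDefinitionError("constant steady state must be in [0,1]")
        return lambda v: np.full_like(np.asarray(v, float), val)
    raise ModelDefinitionError(f"unknown steady-state form {form!r}")


def _tau_function(spec: dict) -> Callable:
    form = spec["form"]
    if form == "constant":
        val = float(spec["value"])
        if val <= 0:
            raise ModelDefinitionError("time constant must be positive")
        return lambda v: np.full_like(np.asarray(v, float), val)
    if form == "bell":
        # base + amp / (exp((v - vhalf1)/k1) + exp(-(v - vhalf2)/k2))
        base, amp = float(spec.get("base", 0.0)), float(spec["amp"])
        vh1, k1 = float(spec["vhalf1"]), float(spec["k1"])
        vh2, k2 = float(spec["vhalf2"]), float(spec["k2"])
        def f(v):
            v = np.asarray(v, float)
            return base + amp / (np.exp((v - vh1) / k1) + np.exp(-(v - vh2) / k2))
        return f
    if form == "gaussian":
        base, amp = float(spec.get("base", 0.0)), float(spec["amp"])
        vmax, sigma = float(spec["vmax"]), float(spec["sigma"])
        def f(v):
            v = np.asarray(v, float)
            return base + amp * np.exp(-(((v - vmax) / sigma) ** 2))
        return f
    raise ModelDefinitionError(f"unknown time-constant form {form!r}")


def build_gate(name: str, exponent: int, kinetics: dict) -> GateSpec:
    """Build a :class:`GateSpec` from a declarative kinetics dictionary.

    Two schemas are supported:

    * ``form: alpha_beta`` with ``alpha`` and ``beta`` rate specs; the gate
      then has x_inf = a/(a+b) and tau = 1/(a+b), with an optional
      ``tau_min`` floor in ms.
    * ``form: inf_tau`` with an ``inf`` spec (boltzmann/constant) and a
      ``tau`` spec (constant/bell/gaussian).
    """
    form = kinetics.get("form")
    if form == "alpha_beta":
        alpha = _rate_function(kinetics["alpha"])
        beta = _rate_function(kinetics["beta"])
        tau_min = float(kinetics.get("tau_min", 0.0))

        def steady(v):
            a, b = alpha(v), beta(v)
            return a / (a + b)

        def tau(v):
            a, b = alpha(v), beta(v)
            return np.maximum(1.0 / (a + b), tau_min) if tau_min > 0 else 1.0 / (a + b)

        return GateSpec(name, exponent, steady, tau, kinetics=kinetics)
    if form == "inf_tau":
        return GateSpec(name, exponent, _inf_function(kinetics["inf"]),
                        _tau_function(kinetics["tau"]), kinetics=kinetics)
    raise ModelDefinitionError(f"unknown gate kinetics form {form!r}")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def nernst_potential(ion: str, conc_in: float, conc_out: float,
                     temperature: float) -> float:
    """Nernst reversal potential in mV.

    E = (R T / z F) ln([out]/[in]) with T in kelvin; temperature is given in
    degrees Celsius.
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    ion = ion.lower()
    if ion not in ION_VALENCE:
        raise ValueError(f"unknown ion {ion!r}; valence not known")
    t_kelvin = temperature + 273.15
    z = ION_VALENCE[ion]
    return 1000.0 * GAS_CONSTANT * t_kelvin / (z * FARADAY) * math.log(conc_out / conc_in)


def membrane_area(geometry: CellGeometry) -> float:
    """Lateral cylinder surface area in cm^2 (no end caps).

    pi * diameter * length with both in um; 1 um^2 = 1e-8 cm^2.
    """
    return math.pi * geometry.diameter * geometry.length * 1e-8


def reversal_potentials(model: NeuronModel) -> Dict[str, float]:
    """Resolve every current's reversal potential (mV) once.

    Concentrations are fixed, so reversals are constants of the simulation.
    """
    conc = model.concentrations
    nernst = {
        "na": nernst_potential("na", conc.na_in, conc.na_out, conc.temperature),
        "k": nernst_potential("k", conc.k_in, conc.k_out, conc.temperature),
    }
    out = {}
    for cur in model.currents:
        rev = cur.reversal
        if isinstance(rev, str):
            if not rev.startswith("nernst:"):
                raise ModelDefinitionError(f"bad reversal spec {rev!r}")
            ion = rev.split(":", 1)[1].lower()
            if ion not in nernst:
                raise ModelDefinitionError(f"no concentrations for ion {ion!r}")
            out[cur.name] = nernst[ion]
        else:
            out[cur.name] = float(rev)
    return out


def evaluate_current(spec: IonicCurrentSpec, scaling: float, state: ModelState,
                     reversals: Dict[str, float]) -> float:
    """Instantaneous current density (mA/cm^2, outward positive)."""
    if scaling < 0:
        raise ValueError("scaling factor must be non-negative")
    g = scaling * spec.baseline_conductance
    for gate in spec.gates:
        key = (spec.name, gate.name)
        if key not in state.gate_values:
            raise ModelDefinitionError(f"state missing gate {key}")
        g *= state.gate_values[key] ** gate.exponent
    return g * (state.voltage - reversals[spec.name])


def rhs(model: NeuronModel, state: ModelState, t: float, stimulus=None) -> Tuple[float, Dict]:
    """Time derivatives of the model state (dV/dt in mV/ms, dgate/dt in 1/ms).

    Reference implementation using the exact gate closures; the integrator in
    :mod:`popneuron._engine` uses a tabulated equivalent for speed.
    """
    reversals = reversal_potentials(model)
    area = membrane_area(model.geometry)
    i_ion = 0.0
    for cur in model.currents:
        i_ion += evaluate_current(cur, model.scale_factor(cur.name), state, reversals)
    if stimulus is None:
        i_stim_ma = 0.0
    else:
        from .protocols import stimulus_current
        i_stim_ma = stimulus_current(stimulus, t) * 1e-9  # pA -> mA
    dvdt = 1000.0 * (i_stim_ma / area - i_ion) / model.geometry.specific_capacitance
    dgates = {}
    v = state.voltage
    for cur in model.currents:
        for gate in cur.gates:
            x = state.gate_values[(cur.name, gate.name)]
            inf = float(gate.steady_state(v))
            tau = float(gate.time_constant(v))
            dgates[(cur.name, gate.name)] = (inf - x) / tau
    return dvdt, dgates


def initialize(model: NeuronModel, v_init: float = -65.0) -> ModelState:
    """State at ``v_init`` with every gate at its steady-state value.

    Note the settled rest of the model is generally not ``v_init``: the
    resting membrane potential biomarker is measured from a zero-stimulus
    simulation, not from this initial condition.
    """
    if not np.isfinite(v_init):
        raise ValueError("v_init must be finite")
    gates = {}
    for cur in model.currents:
        for gate in cur.gates:
            x = float(gate.steady_state(v_init))
            gates[(cur.name, gate.name)] = min(1.0, max(0.0, x))
    return ModelState(voltage=float(v_init), gate_values=gates)


def simulate(model: NeuronModel, protocol, t_stop: Optional[float] = None,
             record_currents: bool = False, v_init: float = -65.0,
             rtol: float = 1e-7, atol: float = 1e-8):
    """Integrate the model under a stimulus protocol and return a Trace.

    The system is solved with an adaptive, stiff-capable solver (LSODA),
    sampled on a uniform 40 kHz grid and then decimated to 20 kHz, matching
    the record-then-downsample convention of patch-clamp acquisition.
    """
    from ._engine import run_simulation
    return run_simulation(model, protocol, t_stop=t_stop,
                          record_currents=record_currents, v_init=v_init,
                          rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# Model definition files
# ---------------------------------------------------------------------------

def load_model_dict(data: dict) -> NeuronModel:
    """Build a :class:`NeuronModel` from a parsed model-definition mapping."""
    try:
        geo = data["geometry"]
        geometry = CellGeometry(
            length=float(geo["length_um"]),
            diameter=float(geo["diameter_um"]),
            axial_resistivity=float(geo.get("axial_resistivity_ohm_cm", 1.0)),
            specific_capacitance=float(geo.get("capacitance_uf_cm2", 1.0)),
        )
        conc_data = data.get("concentrations", {})
        conc = IonConcentrations(
            na_out=float(conc_data.get("na_out_mm", 145.0)),
            na_in=float(conc_data.get("na_in_mm", 5.0)),
            k_out=float(conc_data.get("k_out_mm", 3.0)),
            k_in=float(conc_data.get("k_in_mm", 135.0)),
            temperature=float(conc_data.get("temperature_c", 32.0)),
        )
        currents = []
        for cur in data["currents"]:
            if cur.get("gbar") is None:
                raise ModelDefinitionError(
                    f"current {cur.get('name')!r} has no conductance; "
                    "is this an untranscribed template?")
            gates = tuple(
                build_gate(g["name"], int(g.get("exponent", 1)), g["kinetics"])
                for g in cur.get("gates", []) or ()
            )
            rev = cur["reversal"]
            currents.append(IonicCurrentSpec(
                name=str(cur["name"]),
                baseline_conductance=float(cur["gbar"]),
                reversal=rev if isinstance(rev, str) else float(rev),
                gates=gates,
            ))
    except KeyError as exc:
        raise ModelDefinitionError(f"model definition missing key {exc}") from exc
    return NeuronModel(geometry=geometry, concentrations=conc,
                       currents=tuple(currents),
                       name=str(data.get("name", "model")))


def load_model(path) -> NeuronModel:
    """Load a model definition from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ModelDefinitionError(f"{path}: not a model definition mapping")
    return load_model_dict(data)


def dump_model(model: NeuronModel, path) -> None:
    """Write a model definition back to YAML (requires declarative kinetics)."""
    currents = []
    for cur in model.currents:
        gates = []
        for gate in cur.gates:
            if gate.kinetics is None:
                raise ModelDefinitionError(
                    f"gate {cur.name}/{gate.name} has no declarative kinetics")
            gates.append({"name": gate.name, "exponent": gate.exponent,
                          "kinetics": gate.kinetics})
        currents.append({"name": cur.name,
                         "gbar": cur.baseline_conductance,
                         "reversal": cur.reversal,
                         "gates": gates})
    conc = model.concentrations
    data = {
        "name": model.name,
        "geometry": {
            "length_um": model.geometry.length,
            "diameter_um": model.geometry.diameter,
            "axial_resistivity_ohm_cm": model.geometry.axial_resistivity,
            "capacitance_uf_cm2": model.geometry.specific_capacitance,
        },
        "concentrations": {
            "na_out_mm": conc.na_out, "na_in_mm": conc.na_in,
            "k_out_mm": conc.k_out, "k_in_mm": conc.k_in,
            "temperature_c": conc.temperature,
        },
        "currents": currents,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
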