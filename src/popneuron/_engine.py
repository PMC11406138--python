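"""Fast integration backend for the membrane model.

Gate kinetics are tabulated on a dense voltage grid once per model and the
right-hand side is evaluated by linear interpolation into those tables, so
integration speed is independent of the functional forms used in the model
definition.  The tables span -150..+100 mV at 0.02 mV resolution; outside
that range the edge value is used (gating curves are flat there).

The ODE system is solved with LSODA (adaptive, stiff-capable) via
``scipy.integrate.odeint``, sampled on a uniform 40 kHz grid and decimated
by a factor of two to 20 kHz.  Stimulus on/off times are passed to the
solver as critical points so steps never straddle a discontinuity.

If numba is importable the RHS kernel is JIT-compiled; otherwise an
equivalent vectorised numpy kernel is used.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.integrate import odeint

from .membrane import (NeuronModel, SimulationError, membrane_area,
                       reversal_potentials)
from .trace import Trace

V_GRID_LO = -150.0
V_GRID_HI = 100.0
V_GRID_STEP = 0.02
DT_RECORD = 0.025  # ms, 40 kHz acquisition grid
DOWNSAMPLE = 2  # 40 kHz -> 20 kHz

_STIM_KINDS = {"step": 0, "ramp": 1}


def _rhs_numpy(y, t, v0, dv, inf_tab, tau_tab, expo, seg, gbar, erev, cm_uf,
               kind, delay, dur, amp_dens, interval, nstim):
    nv = inf_tab.shape[1]
    v = y[0]
    pos = (v - v0) / dv
    if pos < 0.0:
        pos = 0.0
    elif pos > nv - 1.000001:
        pos = nv - 1.000001
    i0 = int(pos)
    f = pos - i0
    x = y[1:]
    inf = inf_tab[:, i0] * (1.0 - f) + inf_tab[:, i0 + 1] * f
    tau = tau_tab[:, i0] * (1.0 - f) + tau_tab[:, i0 + 1] * f
    dy = np.empty_like(y)
    dy[1:] = (inf - x) / tau
    xc = np.clip(x, 0.0, 1.0)
    powers = xc ** expo
    nc = gbar.shape[0]
    prods = np.empty(nc)
    for c in range(nc):
        prods[c] = powers[seg[c]:seg[c + 1]].prod()
    i_ion = float(np.sum(gbar * prods * (v - erev)))
    i_stim = 0.0
    if amp_dens != 0.0 and t >= delay:
        period = dur + interval
        k = int((t - delay) // period) if period > 0 else 0
        if k > nstim - 1:
            k = nstim - 1
        onset = delay + k * period
        if onset <= t < onset + dur:
            i_stim = amp_dens if kind == 0 else amp_dens * (t - onset) / dur
    dy[0] = 1000.0 * (i_stim - i_ion) / cm_uf
    return dy


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _rhs_numba(y, t, v0, dv, inf_tab, tau_tab, expo, seg, gbar, erev,
                   cm_uf, kind, delay, dur, amp_dens, interval, nstim):
        nv = inf_tab.shape[1]
        ng = expo.shape[0]
        nc = gbar.shape[0]
        v = y[0]
        pos = (v - v0) / dv
        if pos < 0.0:
            pos = 0.0
        elif pos > nv - 1.000001:
            pos = nv - 1.000001
        i0 = int(pos)
        f = pos - i0
        dy = np.empty_like(y)
        for g in range(ng):
            x = y[1 + g]
            inf = inf_tab[g, i0] * (1.0 - f) + inf_tab[g, i0 + 1] * f
            tau = tau_tab[g, i0] * (1.0 - f) + tau_tab[g, i0 + 1] * f
            dy[1 + g] = (inf - x) / tau
        i_ion = 0.0
        for c in range(nc):
            p = 1.0
            for g in range(seg[c], seg[c + 1]):
                x = y[1 + g]
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                for _ in range(expo[g]):
                    p *= x
            i_ion += gbar[c] * p * (v - erev[c])
        i_stim = 0.0
        if amp_dens != 0.0 and t >= delay:
            period = dur + interval
            if period > 0.0:
                k = int((t - delay) // period)
            else:
                k = 0
            if k > nstim - 1:
                k = nstim - 1
            onset = delay + k * period
            if onset <= t < onset + dur:
                if kind == 0:
                    i_stim = amp_dens
                else:
                    i_stim = amp_dens * (t - onset) / dur
        dy[0] = 1000.0 * (i_stim - i_ion) / cm_uf
        return dy

    _RHS = _rhs_numba
    _NUMBA = True
except Exception:  # pragma: no cover
    _RHS = _rhs_numpy
    _NUMBA = False


class CompiledModel:
    """Per-model arrays and gate tables used by the RHS kernel."""

    def __init__(self, model: NeuronModel):
        self.model = model
        self.area_cm2 = membrane_area(model.geometry)
        self.cm_uf = model.geometry.specific_capacitance
        revs = reversal_potentials(model)
        vgrid = np.arange(V_GRID_LO, V_GRID_HI + V_GRID_STEP / 2, V_GRID_STEP)
        self.v0 = float(vgrid[0])
        self.dv = V_GRID_STEP
        gbar, erev, expo, seg = [], [], [], [0]
        inf_rows, tau_rows = [], []
        self.gate_labels = []
        self.gate_closures = []
        for cur in model.currents:
            gbar.append(model.scale_factor(cur.name) * cur.baseline_conductance)
            erev.append(revs[cur.name])
            for gate in cur.gates:
                expo.append(gate.exponent)
                inf = np.clip(np.asarray(gate.steady_state(vgrid), float), 0.0, 1.0)
                tau = np.asarray(gate.time_constant(vgrid), float)
                if np.any(~np.isfinite(inf)) or np.any(~np.isfinite(tau)) or np.any(tau <= 0):
                    raise SimulationError(
                        f"gate {cur.name}/{gate.name} kinetics invalid on the "
                        f"voltage grid", model=model)
                inf_rows.append(inf)
                tau_rows.append(tau)
                self.gate_labels.append((cur.name, gate.name))
                self.gate_closures.append(gate)
            seg.append(len(expo))
        ng = len(expo)
        self.gbar = np.asarray(gbar, float)
        self.erev = np.asarray(erev, float)
        self.expo = np.asarray(expo, np.int64)
        # gates of current c occupy slots seg[c]..seg[c+1]-1 (empty for leak)
        self.seg = np.asarray(seg, np.int64)
        self.inf_tab = np.ascontiguousarray(np.vstack(inf_rows)) if ng else np.zeros((0, vgrid.size))
        self.tau_tab = np.ascontiguousarray(np.vstack(tau_rows)) if ng else np.zeros((0, vgrid.size))
        self.n_gates = ng
        self.names = model.current_names

    # -- state vector helpers -------------------------------------------------
    def initial_vector(self, v_init: float) -> np.ndarray:
        y0 = np.empty(1 + self.n_gates)
        y0[0] = v_init
        for i, gate in enumerate(self.gate_closures):
            y0[1 + i] = min(1.0, max(0.0, float(gate.steady_state(v_init))))
        return y0

    def currents_from_solution(self, v: np.ndarray, gates: np.ndarray) -> dict:
        """Per-current densities (mA/cm^2) at recorded samples."""
        out = {}
        xc = np.clip(gates, 0.0, 1.0)
        for c, name in enumerate(self.names):
            g = np.full_like(v, self.gbar[c])
            for gi in range(self.seg[c], self.seg[c + 1]):
                g = g * xc[:, gi] ** self.expo[gi]
            out[name] = g * (v - self.erev[c])
        return out


def compile_model(model: NeuronModel) -> CompiledModel:
    return CompiledModel(model)


def _stim_args(cmodel: CompiledModel, protocol) -> tuple:
    if protocol is None:
        return (0, 0.0, 1.0, 0.0, 0.0, 1)
    kind = _STIM_KINDS.get(protocol.kind)
    if kind is None:
        raise SimulationError(f"unknown stimulus kind {protocol.kind!r}",
                              model=cmodel.model)
    amp_dens = protocol.amplitude * 1e-9 / cmodel.area_cm2  # pA -> mA/cm^2
    return (kind, float(protocol.delay), float(protocol.duration), amp_dens,
            float(protocol.interval), int(protocol.num_stims))


def _breakpoints(protocol, t0: float, t_stop: float) -> np.ndarray:
    if protocol is None or protocol.amplitude == 0:
        return np.empty(0)
    pts = []
    for k in range(protocol.num_stims):
        onset = protocol.delay + k * (protocol.duration + protocol.interval)
        pts.extend((onset, onset + protocol.duration))
    pts = [p for p in pts if t0 < p < t_stop]
    return np.asarray(sorted(set(pts)))


def integrate_grid(cmodel: CompiledModel, protocol, y0: np.ndarray, t0: float,
                   t_stop: float, rtol: float = 1e-7, atol: float = 1e-8
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate from (t0, y0) and return (t, Y) on the 40 kHz grid."""
    n = int(np.floor((t_stop - t0) / DT_RECORD + 1e-9)) + 1
    t = t0 + DT_RECORD * np.arange(n)
    if n < 2:
        return t, np.tile(y0, (n, 1))
    args = (cmodel.v0, cmodel.dv, cmodel.inf_tab, cmodel.tau_tab, cmodel.expo,
            cmodel.seg, cmodel.gbar, cmodel.erev, cmodel.cm_uf,
            *_stim_args(cmodel, protocol))
    tcrit = _breakpoints(protocol, t0, float(t[-1]))
    import warnings
    from scipy.integrate import ODEintWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)  # reported as exceptions
        sol, info = odeint(_RHS, y0, t, args=args, rtol=rtol, atol=atol,
                           tcrit=tcrit if tcrit.size else None,
                           mxstep=20000, full_output=True)
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"ODE solver failed for model {cmodel.model.name!r}: "
            f"{info['message']} (scaling={cmodel.model.scaling})",
            model=cmodel.model,
            amplitude_pa=getattr(protocol, "amplitude", None))
    return t, sol


def _to_trace(cmodel: CompiledModel, t: np.ndarray, sol: np.ndarray,
              protocol, record_currents: bool) -> Trace:
    t20 = t[::DOWNSAMPLE]
    sol20 = sol[::DOWNSAMPLE]
    v = sol20[:, 0]
    gates = np.clip(sol20[:, 1:], 0.0, 1.0)  # guard solver overshoot ~1e-9
    currents = cmodel.currents_from_solution(v, gates) if record_currents else None
    return Trace(t=t20, v=v, currents=currents, protocol=protocol)


def run_simulation(model: NeuronModel, protocol, t_stop: Optional[float] = None,
                   record_currents: bool = False, v_init: float = -65.0,
                   rtol: float = 1e-7, atol: float = 1e-8) -> Trace:
    cmodel = compile_model(model)
    if t_stop is None:
        t_stop = getattr(protocol, "t_stop", None) or 1500.0
    y0 = cmodel.initial_vector(v_init)
    t, sol = integrate_grid(cmodel, protocol, y0, 0.0, float(t_stop),
                            rtol=rtol, atol=atol)
    return _to_trace(cmodel, t, sol, protocol, record_currents)


class ModelRunner:
    """Repeated simulations of one model with a cached pre-stimulus settle.

    The segment of a run before the stimulus onset does not depend on the
    stimulus amplitude, so during a rheobase scan it is integrated once and
    re-used for every scanned amplitude.
    """

    def __init__(self, model: NeuronModel, v_init: float = -65.0,
                 rtol: float = 1e-7, atol: float = 1e-8):
        self.model = model
        self.v_init = v_init
        self.rtol = rtol
        self.atol = atol
        self.cmodel = compile_model(model)
        self._settle: dict = {}

    def _settled(self, t_end: float) -> Tuple[np.ndarray, np.ndarray]:
        key = round(t_end / DT_RECORD)
        if key not in self._settle:
            y0 = self.cmodel.initial_vector(self.v_init)
            self._settle[key] = integrate_grid(
                self.cmodel, None, y0, 0.0, key * DT_RECORD,
                rtol=self.rtol, atol=self.atol)
        return self._settle[key]

    def run(self, protocol, t_stop: Optional[float] = None,
            record_currents: bool = False) -> Trace:
        if t_stop is None:
            t_stop = getattr(protocol, "t_stop", None) or 1500.0
        t_stop = float(t_stop)
        delay = float(getattr(protocol, "delay", 0.0)) if protocol is not None else 0.0
        amp = float(getattr(protocol, "amplitude", 0.0)) if protocol is not None else 0.0
        # settle up to the last grid point at or before stimulus onset
        t_split = DT_RECORD * np.floor(min(delay, t_stop) / DT_RECORD)
        if amp == 0.0 or t_split < DT_RECORD:
            t, sol = integrate_grid(self.cmodel, protocol,
                                    self.cmodel.initial_vector(self.v_init),
                                    0.0, t_stop, rtol=self.rtol, atol=self.atol)
        else:
            t1, sol1 = self._settled(t_split)
            t2, sol2 = integrate_grid(self.cmodel, protocol, sol1[-1].copy(),
                                      float(t1[-1]), t_stop,
                                      rtol=self.rtol, atol=self.atol)
            t = np.concatenate([t1[:-1], t2])
            sol = np.concatenate([sol1[:-1], sol2])
        return _to_trace(self.cmodel, t, sol, protocol, record_currents)
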