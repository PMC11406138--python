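"""Current-clamp stimulus protocols and the rheobase search.

Rheobase is found the way it is measured at the rig: step simulations at
increasing amplitude (100 pA increments up to 5000 pA by default) until the
first simulation containing at least one detected action potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .membrane import NeuronModel, SimulationError
from .trace import Trace

__all__ = ["StimulusProtocol", "RheobaseResult", "stimulus_current",
           "find_rheobase", "step_protocol", "ramp_protocol"]

DEFAULT_T_STOP = 1500.0  # ms
RHEOBASE_INCREMENT = 100.0  # pA
RHEOBASE_MAX = 5000.0  # pA


@dataclass(frozen=True)
class StimulusProtocol:
    """A repeated step or ramp current injection.

    ``amplitude`` is in pA; a ramp rises linearly from 0 to ``amplitude``
    over each stimulus epoch.  ``t_stop`` is the default simulation length
    used when none is given explicitly, long enough that post-stimulus
    behaviour (e.g. the AHP) is captured.
    """

    kind: str  # "step" or "ramp"
    delay: float = 500.0  # ms
    duration: float = 800.0  # ms
    amplitude: float = 0.0  # pA
    interval: float = 0.0  # ms between repeats
    num_stims: int = 1
    t_stop: float = DEFAULT_T_STOP  # ms

    def __post_init__(self):
        if self.kind not in ("step", "ramp"):
            raise ValueError(f"kind must be 'step' or 'ramp', got {self.kind!r}")
        if self.delay < 0 or self.duration <= 0 or self.num_stims < 1:
            raise ValueError("delay >= 0, duration > 0, num_stims >= 1 required")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def with_amplitude(self, amplitude: float) -> "StimulusProtocol":
        return replace(self, amplitude=float(amplitude))

    @property
    def offset(self) -> float:
        """End of the last stimulus epoch (ms)."""
        return (self.delay + (self.num_stims - 1) * (self.duration + self.interval)
                + self.duration)


def step_protocol(amplitude: float = 0.0, delay: float = 500.0,
                  duration: float = 800.0, t_stop: float = DEFAULT_T_STOP,
                  **kw) -> StimulusProtocol:
    """The standard 800-ms step protocol."""
    return StimulusProtocol("step", delay=delay, duration=duration,
                            amplitude=amplitude, t_stop=t_stop, **kw)


def ramp_protocol(amplitude: float = 0.0, delay: float = 500.0,
                  duration: float = 500.0, t_stop: float = DEFAULT_T_STOP,
                  **kw) -> StimulusProtocol:
    """The standard 500-ms ramp protocol (linear rise from 0 to amplitude)."""
    return StimulusProtocol("ramp", delay=delay, duration=duration,
                            amplitude=amplitude, t_stop=t_stop, **kw)


def stimulus_current(protocol: StimulusProtocol, t) -> np.ndarray:
    """Injected current (pA) at time ``t`` (ms); vectorised over ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    if protocol.amplitude == 0:
        return out if out.ndim else float(out)
    period = protocol.duration + protocol.interval
    for k in range(protocol.num_stims):
        onset = protocol.delay + k * period
        inside = (t >= onset) & (t < onset + protocol.duration)
        if protocol.kind == "step":
            out = np.where(inside, protocol.amplitude, out)
        else:
            out = np.where(inside,
                           protocol.amplitude * (t - onset) / protocol.duration,
                           out)
    return out if out.ndim else float(out)


@dataclass
class RheobaseResult:
    """Outcome of a rheobase scan."""

    found: bool
    amplitude: Optional[float]  # pA, a multiple of the scan increment
    trace: Optional[Trace]  # trace at the returned amplitude
    scanned: List[float] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.found


def find_rheobase(model: NeuronModel, protocol_template: Optional[StimulusProtocol] = None,
                  increment: float = RHEOBASE_INCREMENT,
                  max_amp: float = RHEOBASE_MAX,
                  v_init: float = -65.0,
                  detection_level: float = 0.0,
                  runner=None) -> RheobaseResult:
    """Scan stimulus amplitudes upward until an AP is detected.

    The scan visits ``increment, 2*increment, ... , max_amp`` and returns the
    first amplitude whose simulation contains at least one action potential
    (0 pA cannot evoke a stimulus-driven AP, so the scan starts one increment
    above it).  For a ramp template the scanned quantity is the ramp's final
    amplitude.  Returns ``found=False`` after an AP-free scan to ``max_amp``.
    """
    from ._engine import ModelRunner
    from .biomarkers import detect_aps

    if protocol_template is None:
        protocol_template = step_protocol()
    if increment <= 0 or max_amp < increment:
        raise ValueError("need 0 < increment <= max_amp")
    if runner is None:
        runner = ModelRunner(model, v_init=v_init)
    scanned: List[float] = []
    n_steps = int(round(max_amp / increment))
    for i in range(1, n_steps + 1):
        amp = i * increment
        scanned.append(amp)
        protocol = protocol_template.with_amplitude(amp)
        try:
            trace = runner.run(protocol)
        except SimulationError as exc:
            raise SimulationError(
                f"rheobase scan failed at {amp} pA: {exc}", model=model,
                amplitude_pa=amp) from exc
        if detect_aps(trace, level=detection_level):
            return RheobaseResult(found=True, amplitude=amp, trace=trace,
                                  scanned=scanned)
    return RheobaseResult(found=False, amplitude=None, trace=None,
                          scanned=scanned)
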