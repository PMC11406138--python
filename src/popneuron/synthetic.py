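"""Self-contained fixtures: a toy conductance model and analytic spike traces.

The toy model is the classic three-current squid-axon model wired through
the same declarative gate machinery as any transcribed DRG model, so every
stage of the pipeline can run and be checked without external channel
kinetics.  The synthetic spike generator produces piecewise-analytic traces
whose biomarkers are known in closed form, giving the biomarker extractors
an exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .biomarkers import BiomarkerSet
from .membrane import NeuronModel, load_model_dict
from .population import CalibrationRange
from .protocols import StimulusProtocol, step_protocol
from .trace import Trace

__all__ = ["toy_hh_model", "toy_model_path", "hdrg_template_path",
           "SyntheticSpikeSpec", "generate_trace",
           "synthetic_calibration_ranges"]


def _model_resource(name: str) -> dict:
    text = (resources.files("popneuron") / "models" / name).read_text()
    return yaml.safe_load(text)


def toy_hh_model(scaling: Optional[Dict[str, float]] = None) -> NeuronModel:
    """The packaged three-current (NaT, Kdr, leak) toy model.

    Classic squid-axon kinetics on the DRG-soma cylinder geometry; an
    optional scaling dict multiplies the conductances, as in the population
    machinery.
    """
    model = load_model_dict(_model_resource("toy_hh.yaml"))
    if scaling:
        model = model.scaled(scaling, compose=False)
    return model


def toy_model_path() -> str:
    return str(resources.files("popneuron") / "models" / "toy_hh.yaml")


def hdrg_template_path() -> str:
    """The annotated eight-current template awaiting user transcription."""
    return str(resources.files("popneuron") / "models" / "hdrg_template.yaml")


@dataclass(frozen=True)
class SyntheticSpikeSpec:
    """Piecewise-analytic AP train with closed-form biomarkers.

    Each spike: a slow linear 'foot' from baseline to the threshold-break
    voltage, a fast linear rise to the peak, a linear fall to the AHP
    trough, then a single-exponential recovery toward baseline.  Slopes are
    in mV/ms, times in ms.
    """

    spike_times: Sequence[float] = ()  # foot onsets, ms
    baseline: float = -65.0
    threshold: float = -40.0
    peak: float = 40.0
    foot_slope: float = 2.0
    rise_slope: float = 100.0
    fall_slope: float = 50.0
    ahp_depth: float = 10.0
    ahp_tau: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0
    t_stop: float = 1500.0
    sampling_hz: float = 20000.0

    def __post_init__(self):
        if self.ahp_tau <= 0:
            raise ValueError("ahp_tau must be positive")
        if not (self.baseline < self.threshold < self.peak):
            raise ValueError("need baseline < threshold < peak")
        for s in (self.foot_slope, self.rise_slope, self.fall_slope):
            if s <= 0:
                raise ValueError("slopes must be positive")

    @property
    def foot_duration(self) -> float:
        return (self.threshold - self.baseline) / self.foot_slope

    @property
    def rise_duration(self) -> float:
        return (self.peak - self.threshold) / self.rise_slope

    @property
    def fall_duration(self) -> float:
        trough = self.baseline - self.ahp_depth
        return (self.peak - trough) / self.fall_slope

    @property
    def spike_span(self) -> float:
        """Foot onset to AHP trough."""
        return self.foot_duration + self.rise_duration + self.fall_duration


def generate_trace(spec: SyntheticSpikeSpec,
                   protocol: Optional[StimulusProtocol] = None
                   ) -> Tuple[Trace, Dict[str, float]]:
    """Render the spec to a sampled trace plus its ground-truth biomarkers.

    Ground-truth widths are the exact piecewise-linear crossing times, the
    AHP tau is the generating tau, and the firing rate counts spikes whose
    peak falls inside the protocol's stimulus window (the whole trace if no
    protocol is given).  Raises if consecutive spikes overlap.
    """
    times = sorted(spec.spike_times)
    for a, b in zip(times, times[1:]):
        if a + spec.spike_span > b:
            raise ValueError("spikes overlap; space spike_times further apart")
    if times and times[-1] + spec.spike_span > spec.t_stop:
        raise ValueError("last spike extends past t_stop")
    dt = 1000.0 / spec.sampling_hz
    t = np.arange(0.0, spec.t_stop, dt)
    v = np.full_like(t, spec.baseline)
    trough = spec.baseline - spec.ahp_depth
    for k, t0 in enumerate(times):
        t_thr = t0 + spec.foot_duration
        t_peak = t_thr + spec.rise_duration
        t_trough = t_peak + spec.fall_duration
        recover_until = times[k + 1] if k + 1 < len(times) else spec.t_stop
        m = (t >= t0) & (t < t_thr)
        v[m] = spec.baseline + spec.foot_slope * (t[m] - t0)
        m = (t >= t_thr) & (t < t_peak)
        v[m] = spec.threshold + spec.rise_slope * (t[m] - t_thr)
        m = (t >= t_peak) & (t < t_trough)
        v[m] = spec.peak - spec.fall_slope * (t[m] - t_peak)
        m = (t >= t_trough) & (t < recover_until)
        v[m] = spec.baseline - spec.ahp_depth * np.exp(-(t[m] - t_trough) / spec.ahp_tau)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    # closed-form biomarkers
    dv = spec.peak - spec.threshold
    if protocol is not None:
        w0, w1 = protocol.delay, protocol.delay + protocol.duration
        peaks = [t0 + spec.foot_duration + spec.rise_duration for t0 in times]
        n_in = sum(1 for p in peaks if w0 <= p <= w1)
        rate = n_in / (protocol.duration / 1000.0)
    else:
        rate = len(times) / (spec.t_stop / 1000.0)
    n_tail = max(1, t.size // 10)
    truth = {
        "threshold_voltage": spec.threshold if spec.foot_slope < 5.0 else spec.baseline,
        "peak_voltage": spec.peak,
        "slope_max": spec.rise_slope,
        "slope_min": -spec.fall_slope,
        "full_width": dv / spec.rise_slope + dv / spec.fall_slope,
        "half_width": 0.5 * dv / spec.rise_slope + 0.5 * dv / spec.fall_slope,
        "ahp_tau": spec.ahp_tau,
        "rmp": float(np.min(v[t.size - n_tail:])) if spec.noise_sd == 0 else spec.baseline,
        "firing_rate": rate,
    }
    return Trace(t=t, v=v, protocol=protocol), truth


#: the eight biomarkers used for population calibration (half width and
#: firing rate are measured but not calibrated on)
CALIBRATION_BIOMARKERS = ("threshold_voltage", "peak_voltage", "slope_max",
                          "slope_min", "full_width", "ahp_tau", "rmp",
                          "rheobase")


def synthetic_calibration_ranges(biomarkers: BiomarkerSet, rel_sd: float = 0.2,
                                 multiplier: float = 1.5,
                                 names: Optional[Sequence[str]] = CALIBRATION_BIOMARKERS
                                 ) -> List[CalibrationRange]:
    """Ranges centred on a given biomarker set with sd = rel_sd * |mean|.

    Mirrors the structure of experimentally derived mean +/- k*SD ranges but
    with synthetic spreads, so a pipeline can be calibrated around a model
    whose biomarkers are known to be achievable.  By default the eight
    calibration biomarkers get ranges; the default ``rel_sd`` of 0.2 is in
    the ballpark of the between-neuron coefficients of variation reported
    for AP biomarkers in sensory-neuron recordings.  Pass ``names=None`` to
    range every valid biomarker.
    """
    out = []
    for name, value in biomarkers.as_dict().items():
        if names is not None and name not in names:
            continue
        if math.isnan(value):
            if names is not None:
                raise ValueError(f"biomarker {name!r} is invalid in the centre set")
            continue
        sd = rel_sd * abs(value) if value != 0 else rel_sd
        out.append(CalibrationRange(name=name, mean=value, sd=sd,
                                    multiplier=multiplier))
    return out
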