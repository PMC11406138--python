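"""Building an experimentally calibrated population of models.

Candidate models share the baseline model's equations and kinetics but have
every maximal conductance multiplied by an independently sampled scaling
factor (Latin hypercube sampling, by default over 0-2x baseline).  Each
candidate is simulated to find its rheobase, its AP biomarkers are measured
at rheobase, and the candidate is accepted only if *every* calibrated
biomarker falls inside its experimental range (mean +/- multiplier * SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import qmc

from . import __version__ as _engine_version
from ._engine import ModelRunner
from .biomarkers import BIOMARKER_COLUMNS, BiomarkerSet, compute_biomarkers
from .membrane import NeuronModel, SimulationError
from .protocols import (RHEOBASE_INCREMENT, RHEOBASE_MAX, StimulusProtocol,
                        find_rheobase, ramp_protocol, step_protocol)

__all__ = ["SamplingRanges", "CalibrationRange", "ProtocolSuite", "Population",
           "lhs_sample", "evaluate_candidate", "calibrate", "build_population"]


@dataclass(frozen=True)
class SamplingRanges:
    """Per-conductance sampling intervals for the scaling factors."""

    ranges: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if not (0 <= lo < hi):
                raise ValueError(f"range for {name!r} must satisfy 0 <= min < max")

    @classmethod
    def uniform(cls, names: Iterable[str], lo: float = 0.0, hi: float = 2.0
                ) -> "SamplingRanges":
        """The default design: every conductance sampled over [0, 2]x baseline."""
        return cls({name: (lo, hi) for name in names})

    @property
    def names(self) -> List[str]:
        return list(self.ranges)


@dataclass(frozen=True)
class CalibrationRange:
    """Acceptance interval for one biomarker: mean +/- multiplier * SD."""

    name: str
    mean: float
    sd: float
    multiplier: float = 1.5

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def lower(self) -> float:
        return self.mean - self.multiplier * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.multiplier * self.sd

    def contains(self, value: float) -> bool:
        """Inclusive at both bounds; NaN is never inside."""
        return (not math.isnan(value)) and self.lower <= value <= self.upper


@dataclass(frozen=True)
class ProtocolSuite:
    """The simulations run per candidate: step/ramp at rheobase + quiescent."""

    step: StimulusProtocol = field(default_factory=step_protocol)
    ramp: StimulusProtocol = field(default_factory=ramp_protocol)
    v_init: float = -65.0
    rheobase_increment: float = RHEOBASE_INCREMENT
    rheobase_max: float = RHEOBASE_MAX


@dataclass
class Population:
    """Accepted parameter sets with their biomarkers and provenance.

    ``params``: one row per accepted model, one column per conductance
    scaling factor.  ``biomarkers``: matching rows of biomarker values.
    """

    params: pd.DataFrame
    biomarkers: pd.DataFrame
    provenance: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.params)

    def model(self, baseline: NeuronModel, model_id) -> NeuronModel:
        """Instantiate one member by applying its scalings to the baseline."""
        factors = self.params.loc[model_id].to_dict()
        return baseline.scaled(factors, compose=False)

    def biomarker_sets(self) -> List[BiomarkerSet]:
        return [BiomarkerSet(**{k: float(row[k]) for k in BIOMARKER_COLUMNS})
                for _, row in self.biomarkers.iterrows()]


def lhs_sample(ranges: SamplingRanges, n: int, seed: Optional[int] = None
               ) -> pd.DataFrame:
    """Latin hypercube sample of ``n`` scaling-factor sets.

    For each parameter independently, exactly one sample falls in each of
    the ``n`` equal-width bins of its range.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = ranges.names
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges.ranges[k][0] for k in names])
    hi = np.array([ranges.ranges[k][1] for k in names])
    return pd.DataFrame(qmc.scale(unit, lo, hi), columns=names)


def evaluate_candidate(baseline: NeuronModel, scaling: Dict[str, float],
                       protocols: Optional[ProtocolSuite] = None
                       ) -> BiomarkerSet:
    """Full biomarker set for one candidate scaling set.

    Applies the scalings, searches the step and ramp rheobases, simulates
    the at-rheobase step and ramp plus a zero-stimulus run, and measures all
    biomarkers.  Candidates that never spike come back with the AP fields
    flagged NaN (rheobase included).
    """
    if protocols is None:
        protocols = ProtocolSuite()
    model = baseline.scaled(scaling, compose=False)
    runner = ModelRunner(model, v_init=protocols.v_init)
    quiescent = runner.run(None, t_stop=protocols.step.t_stop)
    step_res = find_rheobase(model, protocols.step,
                             increment=protocols.rheobase_increment,
                             max_amp=protocols.rheobase_max, runner=runner)
    ramp_res = find_rheobase(model, protocols.ramp,
                             increment=protocols.rheobase_increment,
                             max_amp=protocols.rheobase_max, runner=runner)
    return compute_biomarkers(step_trace=step_res.trace,
                              ramp_trace=ramp_res.trace,
                              quiescent_trace=quiescent,
                              rheobase=step_res.amplitude)


def calibrate(biomarkers: BiomarkerSet, ranges: Sequence[CalibrationRange]
              ) -> Tuple[bool, Dict[str, bool]]:
    """Accept/reject one candidate against its biomarker ranges.

    Accept iff every configured biomarker lies inside its inclusive
    [lower, upper] interval; a flagged (NaN) biomarker rejects.  A range
    naming a biomarker the set does not have is a configuration error.
    """
    verdicts: Dict[str, bool] = {}
    for rng in ranges:
        if rng.name not in BIOMARKER_COLUMNS:
            raise ValueError(f"calibration range names unknown biomarker {rng.name!r}")
        verdicts[rng.name] = rng.contains(getattr(biomarkers, rng.name))
    return all(verdicts.values()), verdicts


def _evaluate_one(baseline, scaling, protocols):
    try:
        return evaluate_candidate(baseline, scaling, protocols), None
    except SimulationError as exc:
        return None, str(exc)


def build_population(baseline: NeuronModel, ranges: SamplingRanges,
                     calibration: Sequence[CalibrationRange],
                     n_candidates: int = 20000,
                     seed: Optional[int] = None,
                     protocols: Optional[ProtocolSuite] = None,
                     n_jobs: int = 1) -> Population:
    """Sample, evaluate and calibrate candidates; return the accepted set.

    Candidates whose simulation fails outright are treated as rejected and
    recorded in the provenance failure report.  Acceptance order follows
    candidate order and is independent of ``n_jobs``.
    """
    if protocols is None:
        protocols = ProtocolSuite()
    samples = lhs_sample(ranges, n_candidates, seed=seed)
    rows = [samples.iloc[i].to_dict() for i in range(len(samples))]
    if n_jobs == 1:
        results = [_evaluate_one(baseline, row, protocols) for row in rows]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_one)(baseline, row, protocols) for row in rows)
    accepted_idx: List[int] = []
    bio_rows: List[Dict[str, float]] = []
    failures: Dict[int, str] = {}
    n_rejected = 0
    for i, (bset, err) in enumerate(results):
        if bset is None:
            failures[i] = err
            continue
        ok, _ = calibrate(bset, calibration)
        if ok:
            accepted_idx.append(i)
            bio_rows.append(bset.as_dict())
        else:
            n_rejected += 1
    params = samples.iloc[accepted_idx].copy()
    params.index.name = "model_id"
    biomarkers = pd.DataFrame(bio_rows, columns=BIOMARKER_COLUMNS,
                              index=params.index)
    provenance = {
        "engine": f"popneuron {_engine_version}",
        "seed": seed,
        "n_candidates": int(n_candidates),
        "n_accepted": len(accepted_idx),
        "n_rejected": int(n_rejected),
        "n_failed": len(failures),
        "failures": failures,
        "sampling_ranges": {k: list(v) for k, v in ranges.ranges.items()},
        "calibration": [
            {"name": r.name, "mean": r.mean, "sd": r.sd, "multiplier": r.multiplier}
            for r in calibration
        ],
        "protocols": {
            "step": vars(protocols.step).copy(),
            "ramp": vars(protocols.ramp).copy(),
            "v_init": protocols.v_init,
            "rheobase_increment": protocols.rheobase_increment,
            "rheobase_max": protocols.rheobase_max,
        },
    }
    return Population(params=params, biomarkers=biomarkers, provenance=provenance)
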