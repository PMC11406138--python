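"""Conductance-scaling grid experiments over a population of models.

A grid design crosses per-conductance scaling-factor lists with a list of
step-stimulus amplitudes.  Every model in the population is simulated in
every cell, with the cell's factors multiplied onto the model's own, and
firing rate / AP half width are recorded.  Aggregations reproduce the
standard population summaries: per-cell means, averaging out one
conductance, and splitting the population by how often models fire
rapidly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._engine import ModelRunner
from .biomarkers import (AP_DETECTION_LEVEL, detect_aps, firing_rate,
                         half_width, _event_bounds)
from .membrane import NeuronModel, SimulationError
from .population import Population
from .protocols import StimulusProtocol, step_protocol
from .trace import Trace

__all__ = ["GridDesign", "GridResult", "run_grid", "mean_firing_rate",
           "rapid_firing_split", "collapse_over_conductance",
           "detect_repolarisation_failure", "four_parameter_design"]


@dataclass(frozen=True)
class GridDesign:
    """Factorial design: scaling-factor lists x stimulus amplitudes (pA)."""

    scalings: Dict[str, Sequence[float]]
    amplitudes: Sequence[float]
    protocol: StimulusProtocol = field(default_factory=step_protocol)

    def __post_init__(self):
        for name, levels in self.scalings.items():
            if len(levels) == 0 or any(f < 0 for f in levels):
                raise ValueError(f"scaling levels for {name!r} must be non-negative")
        if len(self.amplitudes) == 0 or any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_cells(self) -> int:
        n = len(self.amplitudes)
        for levels in self.scalings.values():
            n *= len(levels)
        return n

    def cells(self) -> List[Dict[str, float]]:
        """All design cells in a deterministic order.

        Each cell is a dict with key ``amp_pA`` plus one key per scaled
        conductance.  Amplitude varies fastest, then the conductances in
        declaration order.
        """
        names = list(self.scalings)
        out = []
        for combo in itertools.product(*(self.scalings[n] for n in names)):
            for amp in self.amplitudes:
                cell = {"amp_pA": float(amp)}
                cell.update({n: float(f) for n, f in zip(names, combo)})
                out.append(cell)
        return out


def four_parameter_design(conductances: Sequence[str] = ("Nav1.8", "Kdr", "KM"),
                          amp_max: float = 6000.0, amp_step: float = 1000.0,
                          scale_max: float = 2.0, scale_step: float = 0.5,
                          protocol: Optional[StimulusProtocol] = None
                          ) -> GridDesign:
    """The coarse four-parameter co-variation design.

    Amplitude runs 0..amp_max in amp_step increments and each named
    conductance runs 0..scale_max in scale_step increments; with the
    defaults that is 7 amplitudes x 5^3 scaling combinations = 875 cells.
    """
    amps = list(np.arange(0.0, amp_max + amp_step / 2, amp_step))
    levels = list(np.arange(0.0, scale_max + scale_step / 2, scale_step))
    return GridDesign(scalings={name: levels for name in conductances},
                      amplitudes=amps,
                      protocol=protocol if protocol is not None else step_protocol())


@dataclass
class GridResult:
    """Long-format per-(cell, model) outcomes of a grid run.

    ``table`` columns: model_id, amp_pA, one column per scaled conductance,
    firing_rate, half_width, repol_failure, failed.
    """

    table: pd.DataFrame
    design: GridDesign
    population: Population

    @property
    def cell_columns(self) -> List[str]:
        return ["amp_pA"] + list(self.design.scalings)


def detect_repolarisation_failure(trace: Trace, protocol: Optional[StimulusProtocol] = None,
                                  level: float = AP_DETECTION_LEVEL) -> bool:
    """True if the voltage never repolarises after the last AP.

    After the final AP peak, the voltage must return below the AP detection
    level before the stimulus switches off; if it does not (depolarisation
    block), the model has failed to repolarise.  Traces with no AP at all
    return False.
    """
    if protocol is None:
        protocol = trace.protocol
    events = detect_aps(trace, level=level)
    if not events:
        return False
    offset = protocol.offset if protocol is not None else float(trace.t[-1])
    last = events[-1]
    after = slice(last.peak_index + 1, len(trace))
    below = np.flatnonzero(trace.v[after] < level)
    if below.size == 0:
        return True
    t_first_below = trace.t[last.peak_index + 1 + below[0]]
    return bool(t_first_below > offset)


def _run_cell_model(baseline: NeuronModel, factors: Dict[str, float],
                    cell: Dict[str, float], protocol: StimulusProtocol,
                    threshold: float) -> Dict[str, float]:
    cell_scales = {k: v for k, v in cell.items() if k != "amp_pA"}
    model = baseline.scaled(factors, compose=False).scaled(cell_scales, compose=True)
    proto = protocol.with_amplitude(cell["amp_pA"])
    try:
        trace = ModelRunner(model).run(proto)
    except SimulationError:
        return {"firing_rate": math.nan, "half_width": math.nan,
                "repol_failure": False, "failed": True}
    rate = firing_rate(trace, proto)
    events = detect_aps(trace)
    if events:
        hw = half_width(events[0], trace, threshold,
                        bounds=_event_bounds(trace, events, 0))
    else:
        hw = math.nan
    return {"firing_rate": rate, "half_width": hw,
            "repol_failure": detect_repolarisation_failure(trace, proto),
            "failed": False}


def run_grid(population: Population, baseline: NeuronModel, design: GridDesign,
             n_jobs: int = 1) -> GridResult:
    """Simulate every design cell on every model in the population.

    Half width uses each model's ramp-derived threshold voltage measured
    once at baseline (from the population's stored biomarkers).  Cell
    scaling factors multiply onto each model's own factors.  Per-simulation
    failures are recorded, not fatal.
    """
    if len(population) == 0 or design.n_cells == 0:
        raise ValueError("need a non-empty population and design")
    cells = design.cells()
    thresholds = population.biomarkers["threshold_voltage"]
    jobs = []
    for cell in cells:
        for model_id in population.params.index:
            jobs.append((cell, model_id))

    def _one(cell, model_id):
        factors = population.params.loc[model_id].to_dict()
        return _run_cell_model(baseline, factors, cell, design.protocol,
                               float(thresholds.loc[model_id]))

    if n_jobs == 1:
        outcomes = [_one(cell, mid) for cell, mid in jobs]
    else:
        outcomes = Parallel(n_jobs=n_jobs)(
            delayed(_one)(cell, mid) for cell, mid in jobs)
    records = []
    for (cell, model_id), outcome in zip(jobs, outcomes):
        rec = {"model_id": model_id}
        rec.update(cell)
        rec.update(outcome)
        records.append(rec)
    return GridResult(table=pd.DataFrame(records), design=design,
                      population=population)


def mean_firing_rate(result: GridResult) -> pd.DataFrame:
    """Arithmetic mean firing rate over non-failed models, per design cell.

    Cells where every model failed get NaN and are flagged in the
    ``n_models`` column (zero contributing models).
    """
    cols = result.cell_columns
    ok = result.table[~result.table["failed"]]
    grouped = ok.groupby(cols, sort=False)["firing_rate"].agg(["mean", "count"])
    grouped = grouped.rename(columns={"mean": "firing_rate", "count": "n_models"})
    all_cells = pd.DataFrame(result.design.cells())[cols].drop_duplicates()
    out = all_cells.merge(grouped.reset_index(), on=cols, how="left")
    out["n_models"] = out["n_models"].fillna(0).astype(int)
    return out


def rapid_firing_split(result: GridResult, rate_threshold: float = 20.0,
                       top_fraction: float = 0.25
                       ) -> Tuple[List, List, pd.DataFrame]:
    """Split the population by how often each model fires rapidly.

    Counts, per model, the design cells where its rate exceeded
    ``rate_threshold`` AP/s; ranks models by that count (descending, ties
    broken by stable model order) and assigns the top
    ``ceil(top_fraction * N)`` to the rapidly-firing group.  Returns
    (rapid ids, other ids, per-group per-conductance mean/SD table).
    """
    tab = result.table
    rapid = tab["firing_rate"] > rate_threshold
    counts = rapid.groupby(tab["model_id"], sort=False).sum()
    counts = counts.reindex(result.population.params.index, fill_value=0)
    order = np.argsort(-counts.to_numpy(), kind="stable")
    k = math.ceil(top_fraction * len(counts))
    top_ids = list(counts.index[order[:k]])
    rest_ids = list(counts.index[order[k:]])
    params = result.population.params
    stats = []
    for label, ids in (("rapid", top_ids), ("other", rest_ids)):
        sub = params.loc[ids]
        for name in params.columns:
            stats.append({"group": label, "conductance": name,
                          "mean": float(sub[name].mean()) if len(sub) else math.nan,
                          "sd": float(sub[name].std(ddof=1)) if len(sub) > 1 else math.nan,
                          "n": len(sub)})
    return top_ids, rest_ids, pd.DataFrame(stats)


def collapse_over_conductance(result: GridResult, conductance: str,
                              over_amplitude: bool = True) -> pd.DataFrame:
    """Average per-cell mean firing rate over all levels of one conductance.

    Optionally also averages over stimulus amplitudes, producing summary
    curves of mean rate against the remaining scaled conductances.
    """
    if conductance not in result.design.scalings:
        raise ValueError(f"{conductance!r} is not scaled in this design")
    means = mean_firing_rate(result)
    keep = [c for c in result.cell_columns if c != conductance]
    if over_amplitude:
        keep = [c for c in keep if c != "amp_pA"]
    if not keep:
        return pd.DataFrame({"firing_rate": [means["firing_rate"].mean()]})
    out = means.groupby(keep, sort=False)["firing_rate"].mean().reset_index()
    return out
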