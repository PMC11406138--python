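"""Persistence and run configuration.

Populations are stored as an open tabular archive — a directory holding
``params.csv`` (one column per conductance scaling factor, one row per
model, first row the parameter names), ``biomarkers.csv`` and
``provenance.json`` — rather than opaque binary blobs.  Run configurations
are YAML files mirroring the simulator's parameter names (sim_name,
stim_func, amp, delay, dur, interval, num_stims, t_stop, v_init, ...).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .biomarkers import BIOMARKER_COLUMNS, compute_biomarkers, detect_aps
from ._engine import ModelRunner
from .membrane import NeuronModel, SimulationError, load_model
from .population import Population
from .protocols import StimulusProtocol, find_rheobase
from .trace import Trace

__all__ = ["save_population", "load_population", "PopulationFormatError",
           "RunConfig", "SimulationBlock", "load_run_config",
           "run_from_config", "RunExistsError"]

_FORMAT_VERSION = 1


class PopulationFormatError(ValueError):
    """Raised when a stored population does not match the expected schema."""


class RunExistsError(RuntimeError):
    """Raised when a run would overwrite existing results without rerun=True."""


# ---------------------------------------------------------------------------
# Population archive
# ---------------------------------------------------------------------------

def save_population(population: Population, path) -> Path:
    """Write a population archive directory (params, biomarkers, provenance)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    population.params.to_csv(path / "params.csv")
    population.biomarkers.to_csv(path / "biomarkers.csv")
    prov = dict(population.provenance)
    prov["format_version"] = _FORMAT_VERSION
    prov["parameters"] = list(population.params.columns)
    with open(path / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    return path


def load_population(path) -> Population:
    """Load a population archive; columns are matched by name.

    A params file missing a conductance column named in the provenance
    raises :class:`PopulationFormatError` naming the column.
    """
    path = Path(path)
    try:
        with open(path / "provenance.json") as fh:
            prov = json.load(fh)
    except FileNotFoundError as exc:
        raise PopulationFormatError(f"{path}: not a population archive") from exc
    version = prov.get("format_version")
    if version != _FORMAT_VERSION:
        raise PopulationFormatError(
            f"{path}: unsupported population format version {version!r}")
    params = pd.read_csv(path / "params.csv", index_col="model_id")
    expected = prov.get("parameters", list(params.columns))
    missing = [c for c in expected if c not in params.columns]
    if missing:
        raise PopulationFormatError(
            f"{path}: params.csv is missing conductance column(s) {missing}")
    params = params[expected]  # canonical order regardless of column shuffling
    biomarkers = pd.read_csv(path / "biomarkers.csv", index_col="model_id")
    biomarkers = biomarkers[[c for c in BIOMARKER_COLUMNS if c in biomarkers.columns]]
    prov.pop("format_version", None)
    prov.pop("parameters", None)
    return Population(params=params, biomarkers=biomarkers, provenance=prov)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"pop_filename", "model_filename", "name", "save_type", "save_dir",
             "rerun", "outputs", "simulations", "seed"}
_SIM_KEYS = {"sim_name", "sim_type", "amp", "celsius", "delay", "dur",
             "interval", "num_stims", "sampling_freq", "stim_func", "t_stop",
             "v_init", "flags", "outputs"}


@dataclass
class SimulationBlock:
    """One simulation over the population (step or ramp, fixed or auto amp)."""

    sim_name: str
    stim_func: str = "step"  # "step" or "ramp"
    amp: object = "auto"  # pA, or "auto" for a rheobase search
    delay: float = 500.0
    dur: float = 800.0
    interval: float = 0.0
    num_stims: int = 1
    t_stop: float = 1500.0
    v_init: float = -65.0
    sim_type: str = "iclamp"
    celsius: float = 32.0  # stored; kinetics are not temperature-scaled
    sampling_freq: float = 20000.0
    flags: Dict = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)

    def protocol(self, amplitude: Optional[float] = None) -> StimulusProtocol:
        amp = amplitude if amplitude is not None else (
            0.0 if self.amp == "auto" else float(self.amp))
        return StimulusProtocol(kind=self.stim_func, delay=self.delay,
                                duration=self.dur, amplitude=amp,
                                interval=self.interval, num_stims=self.num_stims,
                                t_stop=self.t_stop)


@dataclass
class RunConfig:
    """A full run: population + model definition + simulation blocks."""

    pop_filename: str
    model_filename: str
    name: str = "run"
    save_type: str = "fig"  # fig | trace | both | none
    save_dir: str = "."
    rerun: bool = False
    outputs: List[str] = field(default_factory=list)
    simulations: List[SimulationBlock] = field(default_factory=list)

    def __post_init__(self):
        if self.save_type not in ("fig", "trace", "both", "none"):
            raise ValueError(f"save_type {self.save_type!r} not one of "
                             "fig/trace/both/none")


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    sims = []
    for block in data.get("simulations", []):
        bad = set(block) - _SIM_KEYS
        if bad:
            raise ValueError(
                f"{path}: simulation {block.get('sim_name')!r} has unknown "
                f"keys {sorted(bad)}")
        if block.get("sim_type", "iclamp") != "iclamp":
            raise ValueError("only current-clamp (iclamp) simulations are supported")
        sims.append(SimulationBlock(**block))
    kwargs = {k: v for k, v in data.items() if k != "simulations"}
    kwargs.pop("seed", None)
    return RunConfig(simulations=sims, **kwargs)


def run_from_config(config: RunConfig, cores: int = 1) -> Path:
    """Execute every simulation block over the population and persist results.

    Refuses to overwrite an existing run directory unless ``rerun`` is set.
    Per simulation block a biomarker table (CSV, one row per model) is
    written; traces and/or trace figures are written according to
    ``save_type``.  Returns the run directory.
    """
    out_dir = Path(config.save_dir) / config.name
    if out_dir.exists() and not config.rerun:
        raise RunExistsError(
            f"{out_dir} already exists; set rerun: true to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    baseline = load_model(config.model_filename)
    population = load_population(config.pop_filename)
    t0 = time.time()
    report = {"simulations": {}, "cores": cores}
    for block in config.simulations:
        rows = []
        failures = {}
        for model_id in population.params.index:
            model = population.model(baseline, model_id)
            runner = ModelRunner(model, v_init=block.v_init)
            try:
                if block.amp == "auto":
                    res = find_rheobase(model, block.protocol(), runner=runner)
                    trace, amp = res.trace, res.amplitude
                else:
                    amp = float(block.amp)
                    trace = runner.run(block.protocol(amp), t_stop=block.t_stop)
            except SimulationError as exc:
                failures[str(model_id)] = str(exc)
                continue
            quiescent = runner.run(None, t_stop=block.t_stop)
            step_tr = trace if block.stim_func == "step" else None
            ramp_tr = trace if block.stim_func == "ramp" else None
            bset = compute_biomarkers(step_tr, ramp_tr, quiescent, amp)
            row = {"model_id": model_id, "amp_pA": amp,
                   "n_aps": len(detect_aps(trace)) if trace is not None else 0}
            row.update(bset.as_dict())
            rows.append(row)
            if trace is not None and config.save_type in ("trace", "both"):
                trace.to_csv(out_dir / f"{block.sim_name}_model{model_id}_trace.csv")
            if trace is not None and config.save_type in ("fig", "both"):
                _save_trace_figure(trace, out_dir /
                                   f"{block.sim_name}_model{model_id}.png")
        table = pd.DataFrame(rows)
        table.to_csv(out_dir / f"{block.sim_name}_biomarkers.csv", index=False)
        report["simulations"][block.sim_name] = {
            "n_models": int(len(population)),
            "n_failed": len(failures),
            "failures": failures,
        }
    report["elapsed_s"] = round(time.time() - t0, 3)
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return out_dir


def _save_trace_figure(trace: Trace, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(trace.t, trace.v, lw=0.7, color="k")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
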