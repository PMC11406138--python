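"""Currentscape: per-timepoint decomposition of the membrane current.

At each sample, every ionic current is classified by its instantaneous sign
(positive = outward, negative = inward; a current that changes sign
contributes to either side at different times).  Each side's currents are
normalised to fractions of that side's total magnitude, giving the stacked
share plot introduced for visualising which currents dominate each phase of
the action potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = ["Currentscape", "compute_currentscape", "render_currentscape"]

_PALETTE = ["#d62728", "#1f77b4", "#2ca02c", "#9467bd", "#ff7f0e",
            "#bcbd22", "#e377c2", "#8c564b", "#17becf", "#7f7f7f"]


def current_colors(names: List[str]) -> dict:
    """Stable per-current colours: assigned by sorted name, so the same
    current gets the same colour in every figure."""
    return {name: _PALETTE[i % len(_PALETTE)]
            for i, name in enumerate(sorted(names))}


@dataclass
class Currentscape:
    """Fractional inward/outward current shares over time.

    ``outward_fractions`` and ``inward_fractions`` are (n_currents, n_t)
    arrays in [0, 1]; at samples where a side's total is zero its fractions
    are NaN (undefined, rendered as gaps).  ``total_outward`` and
    ``total_inward`` are the side totals as positive magnitudes (mA/cm^2).
    """

    t: np.ndarray
    v: np.ndarray
    names: List[str]
    outward_fractions: np.ndarray
    inward_fractions: np.ndarray
    total_outward: np.ndarray
    total_inward: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.t, "v_mv": self.v,
                "total_outward": self.total_outward,
                "total_inward": self.total_inward}
        for i, name in enumerate(self.names):
            data[f"out_frac_{name}"] = self.outward_fractions[i]
            data[f"in_frac_{name}"] = self.inward_fractions[i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_currentscape(trace: Trace) -> Currentscape:
    """Decompose a currents-recorded trace into fractional contributions.

    Raises ``ValueError`` if the trace was simulated without current
    recording.  The returned object satisfies, at every sample where a
    side's total is positive, sum(fractions) == 1 to within 1e-9.
    """
    if not trace.currents:
        raise ValueError("trace has no recorded currents; "
                         "simulate with record_currents=True")
    names = list(trace.currents)
    currents = np.vstack([np.asarray(trace.currents[n], float) for n in names])
    outward = np.clip(currents, 0.0, None)
    inward = np.clip(-currents, 0.0, None)
    total_out = outward.sum(axis=0)
    total_in = inward.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out_frac = np.where(total_out > 0, outward / total_out, np.nan)
        in_frac = np.where(total_in > 0, inward / total_in, np.nan)
    cs = Currentscape(t=trace.t, v=trace.v, names=names,
                      outward_fractions=out_frac, inward_fractions=in_frac,
                      total_outward=total_out, total_inward=total_in)
    _check_normalisation(cs)
    return cs


def _check_normalisation(cs: Currentscape) -> None:
    for frac, total in ((cs.outward_fractions, cs.total_outward),
                        (cs.inward_fractions, cs.total_inward)):
        active = total > 0
        if active.any():
            sums = np.nansum(frac[:, active], axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise AssertionError("currentscape fractions do not sum to 1")


def render_currentscape(cs: Currentscape, path, dpi: int = 150) -> None:
    """Write the stacked-share figure to ``path`` (PNG/SVG by extension).

    Panels from top to bottom: voltage, total outward current (log scale),
    outward fractions, inward fractions, total inward current (log scale).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = current_colors(cs.names)
    fig, axes = plt.subplots(5, 1, figsize=(8, 9), sharex=True,
                             gridspec_kw={"height_ratios": [2, 1, 2, 2, 1]})
    ax_v, ax_out_tot, ax_out, ax_in, ax_in_tot = axes
    ax_v.plot(cs.t, cs.v, color="k", lw=0.8)
    ax_v.set_ylabel("V (mV)")
    floor = 1e-9
    ax_out_tot.semilogy(cs.t, np.maximum(cs.total_outward, floor), color="k", lw=0.6)
    ax_out_tot.set_ylabel("out\n(mA/cm$^2$)")
    ax_in_tot.semilogy(cs.t, np.maximum(cs.total_inward, floor), color="k", lw=0.6)
    ax_in_tot.set_ylabel("in\n(mA/cm$^2$)")
    for ax, frac in ((ax_out, cs.outward_fractions), (ax_in, cs.inward_fractions)):
        stack = np.nan_to_num(frac, nan=0.0)  # zero-total samples render as gaps
        ax.stackplot(cs.t, stack, labels=cs.names,
                     colors=[colors[n] for n in cs.names])
        ax.set_ylim(0, 1)
        ax.set_ylabel("fraction")
    ax_out.legend(loc="upper right", fontsize=6, ncol=2)
    ax_in_tot.set_xlabel("time (ms)")
    fig.align_ylabels(axes)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
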