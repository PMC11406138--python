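"""Uniformly sampled voltage (and per-current) records from one simulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .protocols import StimulusProtocol


@dataclass
class Trace:
    """A uniformly sampled time/voltage record.

    Attributes
    ----------
    t : ndarray
        Sample times in ms, strictly increasing and uniform.
    v : ndarray
        Membrane voltage in mV, one sample per entry of ``t``.
    currents : dict or None
        Optional per-current densities (mA/cm^2) on the same time base,
        keyed by current name.  Positive values are outward.
    protocol : StimulusProtocol or None
        The stimulus that produced this trace, if any.
    """

    t: np.ndarray
    v: np.ndarray
    currents: Optional[dict] = None
    protocol: Optional["StimulusProtocol"] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniform")
        if self.currents is not None:
            for name, i in self.currents.items():
                if np.shape(i) != self.t.shape:
                    raise ValueError(f"current {name!r} length mismatch")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        if self.t.size < 2:
            raise ValueError("trace too short to define a sample interval")
        return float(self.t[1] - self.t[0])

    @property
    def sampling_hz(self) -> float:
        return 1000.0 / self.dt

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: time_ms, v_mv, plus one column per recorded current."""
        data = {"time_ms": self.t, "v_mv": self.v}
        if self.currents is not None:
            for name, i in self.currents.items():
                data[name] = np.asarray(i, dtype=float)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        extra = [c for c in df.columns if c not in ("time_ms", "v_mv")]
        currents = {c: df[c].to_numpy() for c in extra} or None
        return cls(df["time_ms"].to_numpy(), df["v_mv"].to_numpy(), currents)
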