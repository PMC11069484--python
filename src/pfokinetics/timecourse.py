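"""Sampled (t, s, c) trajectories shared by all model routes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "default_time_grid"]

#: Decay horizon: the slow mode has decayed to exp(-12) ~ 6e-6 of its
#: initial amplitude at T = 12/|lambda_slow|.
DEFAULT_HORIZON_EFOLDS = 12.0
DEFAULT_N_POINTS = 400


@dataclass
class TimeCourse:
    """A sampled trajectory of substrate and complex concentrations.

    Attributes
    ----------
    t : ndarray
        Strictly increasing time grid with ``t[0] == 0``.
    s, c : ndarray
        Substrate and complex concentration series.
    model_label : str
        One of ``{"full", "linear", "lower_G", "upper_H", "reduced"}``.
    meta : dict
        Parameters and solver settings used to produce the trajectory.
    """

    t: np.ndarray
    s: np.ndarray
    c: np.ndarray
    model_label: str = "full"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.s.shape or self.t.shape != self.c.shape:
            raise ValueError("t, s, c must be 1-d arrays of equal length")
        if len(self.t) and self.t[0] != 0.0:
            raise ValueError(f"time grid must start at 0, got t[0]={self.t[0]}")
        if np.any(np.diff(self.t) <= 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise ValueError(f"time grid not strictly increasing at index {bad}")
        if not (np.all(np.isfinite(self.s)) and np.all(np.isfinite(self.c))):
            raise ValueError("non-finite concentration values")

    def __len__(self) -> int:
        return len(self.t)

    def total(self) -> np.ndarray:
        """Total substrate (free + bound), s + c."""
        return self.s + self.c

    def product(self, s0: float | None = None) -> np.ndarray:
        """Product concentration p = s0 - s - c (mass balance)."""
        if s0 is None:
            s0 = self.meta.get("s0", self.s[0] + self.c[0])
        return s0 - self.s - self.c

    def observable(self, kind: str, s0: float | None = None) -> np.ndarray:
        if kind == "s":
            return self.s
        if kind == "c":
            return self.c
        if kind == "total":
            return self.total()
        if kind == "product":
            return self.product(s0)
        raise ValueError(f"unknown observable {kind!r}; expected s, c, total or product")

    def to_dataframe(self, include_derived: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "s": self.s, "c": self.c})
        if include_derived:
            df["total"] = self.total()
            df["product"] = self.product()
        return df


def default_time_grid(lambda_slow: float,
                      n_points: int = DEFAULT_N_POINTS,
                      horizon_efolds: float = DEFAULT_HORIZON_EFOLDS,
                      t_min_fraction: float = 1e-4) -> np.ndarray:
    """Geometric time grid resolving both the fast transient and slow tail.

    Returns ``t[0] = 0`` followed by ``n_points`` geometrically spaced
    samples on ``[t_min_fraction*T, T]`` with ``T = horizon_efolds /
    |lambda_slow|``.  One grid serves both timescales because the
    geometric spacing places roughly a quarter of the samples inside the
    first percent of the horizon.
    """
    if lambda_slow == 0:
        raise ValueError("lambda_slow must be nonzero to set a horizon")
    T = horizon_efolds / abs(lambda_slow)
    grid = np.geomspace(t_min_fraction * T, T, n_points)
    return np.concatenate(([0.0], grid))
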