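"""Saturation-offset schedules for broad-band Z-spectrum acquisition.

Broad-band MT Z-spectra are sampled over a symmetric range of offsets
(here +/-30 kHz by default) with increments that shrink toward resonance:
the restricted-pool component is tens of kHz wide and needs only coarse
outer sampling, while the free-pool peak is a few hundred Hz wide and needs
dense points near zero.  Schedules are built from *bands*: each band is an
(outer edge, step) pair and is stepped inward from its edge until the next
band takes over, after which the positive half is mirrored and 0 appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OffsetSchedule",
    "default_schedule",
    "custom_schedule",
    "subsample_schedule",
    "DEFAULT_BANDS",
]

# Banded layout of the default 53-point schedule: (outer edge Hz, step Hz),
# stepped inward until the next band's edge.  Honors 3000 Hz increments at
# the +/-30 kHz limits and 50 Hz increments near resonance.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (30000.0, 3000.0),
    (12000.0, 2000.0),
    (4000.0, 1000.0),
    (2000.0, 400.0),
    (800.0, 100.0),
    (300.0, 50.0),
)

DEFAULT_N_POINTS = 53


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered, symmetric list of saturation offsets in Hz.

    Attributes
    ----------
    offsets : np.ndarray
        Strictly increasing offsets; contains 0 and is symmetric about it.
    design : tuple of (edge, step)
        The increment bands the schedule was built from, if known.
    """

    offsets: np.ndarray
    design: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.offsets, dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.allclose(x, -x[::-1]):
            raise ValueError("schedule must be symmetric about 0")
        if 0.0 not in x:
            raise ValueError("schedule must contain 0")
        object.__setattr__(self, "offsets", x)

    def __len__(self) -> int:
        return len(self.offsets)

    def __iter__(self):
        return iter(self.offsets)

    @property
    def max_offset(self) -> float:
        return float(self.offsets[-1])

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.offsets)

    def to_csv(self, path: str | Path) -> None:
        """Write as single-column CSV with header ``offset_hz``."""
        pd.DataFrame({"offset_hz": self.offsets}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OffsetSchedule":
        df = pd.read_csv(path)
        if "offset_hz" not in df.columns:
            raise ValueError(f"{path}: expected a column named 'offset_hz'")
        return cls(offsets=np.sort(df["offset_hz"].to_numpy(dtype=float)))


def _positive_half(bands: Sequence[tuple[float, float]]) -> np.ndarray:
    """Step each band inward from its edge, stopping above the next edge."""
    bands = sorted(((float(e), float(s)) for e, s in bands), reverse=True)
    for edge, step in bands:
        if step <= 0 or edge <= 0:
            raise ValueError("band edges and steps must be positive")
    edges = [e for e, _ in bands]
    if len(set(edges)) != len(edges):
        raise ValueError("band edges must be distinct")
    points: list[float] = []
    for i, (edge, step) in enumerate(bands):
        inner = edges[i + 1] if i + 1 < len(bands) else 0.0
        x = edge
        while x > inner:
            points.append(x)
            x -= step
    return np.array(sorted(set(points)))


def custom_schedule(bands: Sequence[tuple[float, float]]) -> OffsetSchedule:
    """Build a symmetric schedule from (outer edge Hz, step Hz) bands.

    Each band is stepped from its outer edge toward 0 until the next band's
    edge is reached; 0 is always included and the positive half mirrored.

    Examples
    --------
    >>> custom_schedule([(30000, 15000)]).offsets
    array([-30000., -15000.,      0.,  15000.,  30000.])
    """
    pos = _positive_half(bands)
    if pos.size == 0:
        raise ValueError("bands produced no offsets")
    offsets = np.concatenate([-pos[::-1], [0.0], pos])
    return OffsetSchedule(offsets=offsets, design=tuple((e, s) for e, s in bands))


def default_schedule() -> OffsetSchedule:
    """The default 53-point schedule spanning +/-30 kHz.

    Increments run from 3000 Hz at the outer limits down to 50 Hz near
    resonance; spacing is non-increasing toward 0.
    """
    sched = custom_schedule(DEFAULT_BANDS)
    assert len(sched) == DEFAULT_N_POINTS, "default band design must give 53 points"
    return sched


def subsample_schedule(schedule: OffsetSchedule, n_target: int) -> OffsetSchedule:
    """Pick a symmetric ``n_target``-point subset of ``schedule``.

    Always retains 0 and the outermost offsets; the remaining points are
    chosen approximately log-uniformly in |x|, since the two fitted
    linewidths span roughly two decades.

    Parameters
    ----------
    n_target : int
        Odd count with 5 <= n_target <= len(schedule).
    """
    n = len(schedule)
    if n_target % 2 == 0:
        raise ValueError("n_target must be odd to keep 0 and symmetry")
    if not 5 <= n_target <= n:
        raise ValueError(f"n_target must be in [5, {n}]")
    if n_target == n:
        return schedule
    pos = schedule.offsets[schedule.offsets > 0]
    k = (n_target - 1) // 2
    targets = np.geomspace(pos[0], pos[-1], k)
    logp = np.log(pos)
    chosen: list[int] = []
    # greedy nearest-in-log assignment, endpoints first so they always survive
    order = [k - 1, 0] + list(range(1, k - 1))
    picked = np.zeros(len(pos), dtype=bool)
    sel = {}
    for j in order:
        d = np.abs(logp - np.log(targets[j]))
        d[picked] = np.inf
        i = int(np.argmin(d))
        picked[i] = True
        sel[j] = i
    chosen = sorted(sel.values())
    sub = pos[chosen]
    offsets = np.concatenate([-sub[::-1], [0.0], sub])
    return OffsetSchedule(offsets=offsets, design=schedule.design)
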