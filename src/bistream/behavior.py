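"""Percept dominance-duration statistics.

Dominance durations (time between consecutive switch reports) are extracted
per block, the first percept of each block and the final open-ended interval
are dropped, durations are normalized to unit mean per group, and the
normalized histograms are summarized by a maximum-likelihood gamma fit —
bistable perception characteristically yields gamma-like distributions with
shape near 2.  Conditions and groups are compared with two-sided Wilcoxon
rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .embedding import rank_sum
from .stimulus import PerceptTimeline

__all__ = ["DurationSet", "extract_durations", "fit_gamma", "compare_groups"]


@dataclass
class DurationSet:
    """Retained dominance durations of one block (seconds)."""

    durations: np.ndarray
    percepts: np.ndarray  # percept each duration belongs to

    def normalized(self, by_percept: bool = True) -> np.ndarray:
        """Durations scaled to unit mean (per percept type by default)."""
        out = np.empty_like(self.durations)
        groups = np.unique(self.percepts) if by_percept else [None]
        for g in groups:
            sel = slice(None) if g is None else self.percepts == g
            out[sel] = self.durations[sel] / self.durations[sel].mean()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percept": self.percepts, "duration_s": self.durations})


def extract_durations(timeline: PerceptTimeline) -> DurationSet:
    """Dominance durations from a press timeline.

    Duration k is ``press[k+1] - press[k]``; the final open-ended interval
    (truncated by the block end) is dropped, and so is the first percept of
    the block.  Fewer than 2 presses yields an empty set.
    """
    if timeline.n_presses < 2:
        return DurationSet(np.array([]), np.array([], dtype=int))
    durations = np.diff(timeline.press_times)
    percepts = timeline.percepts[:-1]
    return DurationSet(durations[1:], percepts[1:])


def fit_gamma(durations: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood gamma fit; returns (shape, mean).

    Intended for normalized durations (unit mean); the location is fixed at
    zero.  Degenerate samples (constant or nonpositive durations) raise.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 durations for a stable fit")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    if np.ptp(x) == 0:
        raise ValueError("constant durations: gamma fit is degenerate")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return float(shape), float(shape * scale)


def compare_groups(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p value between two duration sets."""
    return rank_sum(a, b)
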