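"""Triplet stimulus timeline and percept-report timeline.

The streaming stimulus is a sequence of ``ABA_`` triplets: two pure tones A
and B separated by ``df`` semitones, each 100 ms long, with 50 ms silent gaps
inside the triplet and 200 ms of silence before the next one (600 ms per
triplet).  Listeners report spontaneous alternations between hearing one
integrated stream (``1-stream``) and two segregated streams (``2-stream``)
with button presses; the press timeline is what labels neural trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TripletStimulus",
    "PerceptTimeline",
    "semitone_frequency",
    "build_triplet_sequence",
    "percept_label_at",
]

#: Percept codes used throughout: 1 = integrated single stream, 2 = segregated
#: two streams, 0 = unlabeled (before the first report).
ONE_STREAM = 1
TWO_STREAM = 2
UNLABELED = 0


def semitone_frequency(f_b: float, df: float, *, rounded: bool = True) -> float:
    """Frequency of tone A, ``df`` semitones above the base tone B.

    Parameters
    ----------
    f_b
        Base (B tone) frequency in Hz; must be positive.
    df
        Separation in semitones (12 semitones = one octave, i.e. a factor 2).
    rounded
        Round to the nearest integer Hz (the convention used when reporting
        stimulus frequencies).  Pass ``False`` to get the exact value for
        synthesis.
    """
    if f_b <= 0:
        raise ValueError(f"base frequency must be positive, got {f_b}")
    f_a = f_b * 2.0 ** (df / 12.0)
    return float(round(f_a)) if rounded else float(f_a)


@dataclass(frozen=True)
class TripletStimulus:
    """Timing and frequency parameters of an ``ABA_`` triplet sequence.

    Durations are in seconds.  The triplet duration is derived:
    3 tones + 2 intra-triplet gaps + the inter-triplet gap.
    """

    f_b: float = 1000.0
    df: float = 6.0
    n_triplets: int = 500
    tone_dur: float = 0.100
    intra_gap: float = 0.050
    inter_gap: float = 0.200

    def __post_init__(self) -> None:
        if self.f_b <= 0:
            raise ValueError("f_b must be positive")
        if self.n_triplets < 1:
            raise ValueError("n_triplets must be >= 1")
        for name in ("tone_dur", "intra_gap", "inter_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def f_a(self) -> float:
        """A-tone frequency in Hz (rounded to integer Hz for reporting)."""
        return semitone_frequency(self.f_b, self.df)

    @property
    def f_a_exact(self) -> float:
        """Unrounded A-tone frequency used for synthesis."""
        return semitone_frequency(self.f_b, self.df, rounded=False)

    @property
    def triplet_dur(self) -> float:
        return 3 * self.tone_dur + 2 * self.intra_gap + self.inter_gap

    @property
    def total_dur(self) -> float:
        return self.n_triplets * self.triplet_dur

    def triplet_onsets(self) -> np.ndarray:
        """Onset time of each triplet (s)."""
        return np.arange(self.n_triplets) * self.triplet_dur


def build_triplet_sequence(stim: TripletStimulus) -> pd.DataFrame:
    """Enumerate every tone event of the stimulus.

    Returns a frame with one row per tone: columns ``onset_s``, ``dur_s``,
    ``freq_hz``, ``role`` (``A``, ``B`` or ``A2``) and ``triplet``.  Within a
    triplet the three tones start at 0, 150 and 300 ms; successive A tones are
    therefore 300 ms apart and successive B tones 600 ms apart.
    """
    step = stim.tone_dur + stim.intra_gap
    starts = stim.triplet_onsets()
    roles = ["A", "B", "A2"]
    freqs = [stim.f_a_exact, stim.f_b, stim.f_a_exact]
    rows = []
    for k, t0 in enumerate(starts):
        for i, role in enumerate(roles):
            rows.append((t0 + i * step, stim.tone_dur, freqs[i], role, k))
    return pd.DataFrame(rows, columns=["onset_s", "dur_s", "freq_hz", "role", "triplet"])


@dataclass
class PerceptTimeline:
    """Button-press reports of the currently dominant percept.

    Parameters
    ----------
    press_times
        Strictly increasing press times (s).
    percepts
        Reported percept at each press (1 or 2); consecutive reports must
        alternate, since pressing signals a perceptual *change*.
    block_dur
        Duration of the stimulus block (s).
    stim_changes
        For the control block (df2-12), times at which the stimulus itself
        switched between the df=2 and df=12 sub-sequences.  Empty for
        bistable blocks.
    """

    press_times: np.ndarray
    percepts: np.ndarray
    block_dur: float
    stim_changes: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)
        self.percepts = np.asarray(self.percepts, dtype=int)
        self.stim_changes = np.asarray(self.stim_changes, dtype=float)
        if self.press_times.shape != self.percepts.shape:
            raise ValueError("press_times and percepts must have equal length")
        if self.press_times.size and np.any(np.diff(self.press_times) <= 0):
            raise ValueError("press times must be strictly increasing")
        if not np.all(np.isin(self.percepts, (ONE_STREAM, TWO_STREAM))):
            raise ValueError("percepts must be 1 or 2")
        if self.percepts.size > 1 and np.any(np.diff(self.percepts) == 0):
            raise ValueError("consecutive percept reports must alternate")

    @property
    def n_presses(self) -> int:
        return int(self.press_times.size)

    def to_frame(self) -> pd.DataFrame:
        """Event-table form (columns: onset_s, duration_s, kind, value)."""
        rows = [(float(t), 0.0, "press", int(p)) for t, p in zip(self.press_times, self.percepts)]
        rows += [(float(t), 0.0, "stim_change", "") for t in self.stim_changes]
        frame = pd.DataFrame(rows, columns=["onset_s", "duration_s", "kind", "value"])
        return frame.sort_values("onset_s", kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, block_dur: float) -> "PerceptTimeline":
        presses = frame[frame["kind"] == "press"].sort_values("onset_s")
        changes = frame[frame["kind"] == "stim_change"]["onset_s"].to_numpy(dtype=float)
        return cls(
            press_times=presses["onset_s"].to_numpy(dtype=float),
            percepts=presses["value"].astype(int).to_numpy(),
            block_dur=float(block_dur),
            stim_changes=changes,
        )


def percept_label_at(timeline: PerceptTimeline, t) -> np.ndarray | int:
    """Percept in effect at time(s) ``t``.

    The label is the percept reported by the most recent press at or before
    ``t`` (a press marks the onset of the newly reported percept, so the
    boundary is inclusive on the right of the press).  Times before the first
    press return 0 (unlabeled).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(timeline.press_times, t_arr, side="right") - 1
    labels = np.where(idx >= 0, timeline.percepts[np.clip(idx, 0, None)], UNLABELED)
    if np.isscalar(t) or np.ndim(t) == 0:
        return int(labels[0])
    return labels
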