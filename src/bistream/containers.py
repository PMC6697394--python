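"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimulus import PerceptTimeline, TripletStimulus

__all__ = ["RecordingBlock", "LabeledEpochs"]


@dataclass
class RecordingBlock:
    """Continuous multi-site voltage recording with its metadata.

    Attributes
    ----------
    data
        sites x samples voltage matrix (microvolts).
    fs
        Sampling rate in Hz.
    site_table
        One row per site: ``site_id`` (1-based), ``area`` (anatomical label,
        e.g. HGPM, HGAL, PT, PP, STG, MTG, other) and optional MNI ``x, y, z``.
    stim
        The triplet stimulus presented during the block.
    timeline
        Behavioral report timeline (may be None for unlabeled data).
    """

    data: np.ndarray
    fs: float
    site_table: pd.DataFrame
    stim: TripletStimulus | None = None
    timeline: PerceptTimeline | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be sites x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.site_table) != self.data.shape[0]:
            raise ValueError(
                f"site_table has {len(self.site_table)} rows but data has "
                f"{self.data.shape[0]} sites"
            )

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def areas(self) -> np.ndarray:
        return self.site_table["area"].to_numpy()

    def copy_with(self, **kwargs) -> "RecordingBlock":
        return replace(self, **kwargs)


@dataclass
class LabeledEpochs:
    """Triplet-locked trials with percept labels and per-site keep masks.

    Attributes
    ----------
    trials
        trial x site x time array (microvolts, or normalized band power).
    labels
        Per-trial percept label: 1, 2, or 0 for unlabeled.
    kept
        trial x site boolean mask; False marks a site-trial removed by the
        artifact rejection rule or excluded around button presses.
    trial_onsets
        Stimulus-time onset of each trial's triplet (s).
    window
        (pre_ms, dur_ms, post_ms) of the extraction window around the triplet
        onset; the time axis has (pre+dur+post) * fs / 1000 samples.
    fs
        Sampling rate of the time axis (Hz).
    site_table
        Copied from the source block.
    """

    trials: np.ndarray
    labels: np.ndarray
    kept: np.ndarray
    trial_onsets: np.ndarray
    window: tuple[float, float, float]
    fs: float
    site_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.kept = np.asarray(self.kept, dtype=bool)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        n_trials, n_sites, n_time = self.trials.shape
        if self.labels.shape != (n_trials,):
            raise ValueError("labels must be per-trial")
        if self.kept.shape != (n_trials, n_sites):
            raise ValueError("kept mask must be trial x site")
        expected = round(sum(self.window) * self.fs / 1000.0)
        if n_time != expected:
            raise ValueError(
                f"time axis has {n_time} samples but window {self.window} at "
                f"fs={self.fs} implies {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_sites(self) -> int:
        return self.trials.shape[1]

    @property
    def n_time(self) -> int:
        return self.trials.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to the triplet onset."""
        pre = self.window[0]
        return np.arange(self.n_time) * 1000.0 / self.fs - pre

    def select_trials(self, idx) -> "LabeledEpochs":
        return LabeledEpochs(
            trials=self.trials[idx],
            labels=self.labels[idx],
            kept=self.kept[idx],
            trial_onsets=self.trial_onsets[idx],
            window=self.window,
            fs=self.fs,
            site_table=self.site_table,
        )

    def copy(self) -> "LabeledEpochs":
        return LabeledEpochs(
            trials=self.trials.copy(),
            labels=self.labels.copy(),
            kept=self.kept.copy(),
            trial_onsets=self.trial_onsets.copy(),
            window=self.window,
            fs=self.fs,
            site_table=self.site_table.copy(),
        )
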