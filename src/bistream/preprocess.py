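"""From continuous recordings to labeled, artifact-screened, triplet-locked trials.

The chain is: resample to 1 kHz, zero-phase band-pass 1.5-70 Hz, removal of
the narrow 2.2-2.7 Hz interference band (temporal band-stop plus a spatial
SVD filter on the band-limited signal), cutting 600 ms triplet-locked trials,
a 4-SD per-site amplitude rejection rule, and percept labeling with exclusion
of the epochs contaminated by the reaction-time lag before each button press.
The labeled trial sets per percept are the input to all statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import LabeledEpochs, RecordingBlock
from .stimulus import PerceptTimeline, percept_label_at

__all__ = [
    "resample_to_1khz",
    "bandpass_lfp",
    "remove_narrowband",
    "epoch_triplets",
    "reject_trials",
    "label_and_filter",
    "preswitch_discard_count",
    "select_preswitch_trials",
    "preprocess_block",
]

log = logging.getLogger(__name__)

TRIPLET_S = 0.6


def _sos_filtfilt(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def _spectral_band(data: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-phase extraction of a narrow frequency band via an FFT mask."""
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(data, axis=-1)
    spec[..., ~mask] = 0.0
    return np.fft.irfft(spec, n, axis=-1)


def resample_to_1khz(block: RecordingBlock) -> RecordingBlock:
    """Anti-aliased resampling of the recording to 1000 Hz.

    Uses polyphase rational resampling (the ratio 1000/fs approximated to
    within one part in 1e6).  Recordings already at 1000 Hz pass through
    unchanged.
    """
    if block.fs < 1000:
        raise ValueError(f"sampling rate {block.fs} Hz is below the 1 kHz target")
    if block.fs == 1000:
        return block
    frac = Fraction(1000 / block.fs).limit_denominator(10_000)
    out = signal.resample_poly(block.data, frac.numerator, frac.denominator, axis=-1)
    return block.copy_with(data=out, fs=1000.0)


def bandpass_lfp(
    block: RecordingBlock, band: tuple[float, float] = (1.5, 70.0), order: int = 4
) -> RecordingBlock:
    """Zero-phase Butterworth band-pass; removes DC and high frequencies."""
    sos = signal.butter(order, band, btype="bandpass", fs=block.fs, output="sos")
    return block.copy_with(data=_sos_filtfilt(block.data, sos))


def remove_narrowband(
    block: RecordingBlock,
    stopband: tuple[float, float] = (2.2, 2.7),
    n_discard: int = 30,
) -> RecordingBlock:
    """Suppress the 2.2-2.7 Hz interference with spatial and temporal filters.

    The band-limited (2.2-2.7 Hz) component of the data is decomposed via the
    eigenvectors of its normalized (unit-diagonal) spatial correlation matrix;
    the projection onto the leading ``min(n_discard, n_sites-1)`` spatial
    components is subtracted from the broadband signal, removing interference
    that is coherent across sites.  A per-site zero-phase temporal notch
    (subtraction of the band-limited component) then removes what remains.
    The narrow band is isolated with an exact spectral mask — an IIR notch
    this narrow at a 1 kHz rate is numerically unstable — so signal outside
    the stop band is untouched.
    """
    n_sites = block.n_sites
    if n_sites < 2:
        raise ValueError("spatial filtering requires at least 2 sites")
    k = min(n_discard, n_sites - 1)
    if n_discard >= n_sites:
        warnings.warn(
            f"n_discard={n_discard} >= n_sites={n_sites}; removing {k} components",
            stacklevel=2,
        )
    nb = _spectral_band(block.data, stopband, block.fs)

    # Normalized spatial correlation of the narrow-band component.
    sd = nb.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    nb_std = nb / sd
    corr = (nb_std @ nb_std.T) / nb.shape[1]
    eigval, eigvec = np.linalg.eigh(corr)
    lead = eigvec[:, ::-1][:, :k]  # descending-eigenvalue order
    recon = sd * (lead @ (lead.T @ nb_std))
    data = block.data - recon

    # Temporal notch: subtract the remaining band-limited component per site.
    data = data - _spectral_band(data, stopband, block.fs)
    return block.copy_with(data=data)


def epoch_triplets(
    block: RecordingBlock, window: tuple[float, float, float] = (0.0, 600.0, 0.0)
) -> LabeledEpochs:
    """Cut one trial per triplet, time-locked to the triplet onset.

    ``window`` is (pre_ms, dur_ms, post_ms); the default (0, 600, 0) yields
    the 600 ms trials of the univariate analysis, while (700, 600, 700)
    yields the 2-s windows of the group-level embedding.  Trials whose window
    falls outside the recording are dropped (and logged).  Labels start out
    unlabeled; see :func:`label_and_filter`.
    """
    if block.stim is None:
        raise ValueError("block has no stimulus timeline to epoch against")
    pre, dur, post = window
    fs = block.fs
    n_time = int(round((pre + dur + post) * fs / 1000.0))
    onsets = block.stim.triplet_onsets()
    start_idx = np.round((onsets - pre / 1000.0) * fs).astype(int)
    ok = (start_idx >= 0) & (start_idx + n_time <= block.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d trials whose window exceeds the recording", n_dropped)
    starts = start_idx[ok]
    idx = starts[:, None] + np.arange(n_time)[None, :]
    trials = block.data[:, idx].transpose(1, 0, 2)  # trial x site x time
    n_trials = trials.shape[0]
    return LabeledEpochs(
        trials=trials,
        labels=np.zeros(n_trials, dtype=int),
        kept=np.ones((n_trials, block.n_sites), dtype=bool),
        trial_onsets=onsets[ok],
        window=window,
        fs=fs,
        site_table=block.site_table.copy(),
    )


def reject_trials(ep: LabeledEpochs, n_sd: float = 4.0) -> LabeledEpochs:
    """Mask site-trials containing samples beyond ``n_sd`` SDs of the block mean.

    Mean and SD are per site over the whole block (all trials, including ones
    already masked), which makes the rule deterministic and idempotent.  A
    site with zero variance rejects nothing.
    """
    flat = ep.trials.transpose(1, 0, 2).reshape(ep.n_sites, -1)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    thresh = np.where(sd > 0, n_sd * sd, np.inf)
    exceed = np.abs(ep.trials - mean[None, :, None]) > thresh[None, :, None]
    out = ep.copy()
    out.kept &= ~exceed.any(axis=2)
    return out


def preswitch_discard_count(rt: float, triplet_s: float = TRIPLET_S) -> int:
    """Number of epochs to discard immediately before each button press.

    ``k = max(2, ceil(rt / 0.6))``: at least two 600 ms epochs, more for
    slower responders, so that every epoch overlapping the reaction-time lag
    (when the new percept had begun but was not yet reported) is excluded.
    """
    if rt < 0:
        raise ValueError("reaction time must be nonnegative")
    return max(2, math.ceil(rt / triplet_s - 1e-9))


def label_and_filter(
    ep: LabeledEpochs, timeline: PerceptTimeline, rt: float = 0.6
) -> LabeledEpochs:
    """Label trials by the reported percept and excise ambiguous epochs.

    Each trial takes the percept reported at its onset.  Excluded entirely
    (label reset to 0): trials before the first press, the ``k`` epochs whose
    onset falls within ``k * 600 ms`` before any press (reaction-time lag,
    :func:`preswitch_discard_count`), and — for control blocks carrying
    stimulus-change events — trials between a stimulus change and the
    behavioral response to it.
    """
    k = preswitch_discard_count(rt)
    out = ep.copy()
    onsets = out.trial_onsets
    labels = np.asarray(percept_label_at(timeline, onsets))
    drop = labels == 0
    for p in timeline.press_times:
        drop |= (onsets >= p - k * TRIPLET_S) & (onsets < p)
    for c in timeline.stim_changes:
        after = timeline.press_times[timeline.press_times > c]
        resp = after[0] if after.size else np.inf
        drop |= (onsets >= c) & (onsets < resp)
    labels[drop] = 0
    out.labels = labels
    out.kept[drop] = False
    return out


def select_preswitch_trials(
    ep: LabeledEpochs, timeline: PerceptTimeline
) -> LabeledEpochs:
    """One trial per press: the last complete triplet before the report.

    The selected triplet is the last whose full 600 ms window ends at or
    before the press time; it is labeled with the percept being switched
    *into* (the percept reported at that press).  Presses earlier than the
    first complete triplet contribute nothing.
    """
    onset_of = {round(o / TRIPLET_S): i for i, o in enumerate(ep.trial_onsets)}
    idx, labels = [], []
    for p, percept in zip(timeline.press_times, timeline.percepts):
        j = math.floor((p - TRIPLET_S) / TRIPLET_S + 1e-9)
        if j < 0 or j not in onset_of:
            continue
        idx.append(onset_of[j])
        labels.append(percept)
    out = ep.select_trials(np.array(idx, dtype=int))
    out.labels = np.array(labels, dtype=int)
    return out


def preprocess_block(
    block: RecordingBlock,
    rt: float = 0.6,
    window: tuple[float, float, float] = (0.0, 600.0, 0.0),
    band: tuple[float, float] = (1.5, 70.0),
    stopband: tuple[float, float] = (2.2, 2.7),
    n_discard: int = 30,
    reject_sd: float = 4.0,
) -> LabeledEpochs:
    """Full LFP preprocessing chain for one block."""
    if block.timeline is None:
        raise ValueError("block has no behavioral timeline")
    b = resample_to_1khz(block)
    b = bandpass_lfp(b, band=band)
    b = remove_narrowband(b, stopband=stopband, n_discard=n_discard)
    ep = epoch_triplets(b, window=window)
    ep = reject_trials(ep, n_sd=reject_sd)
    return label_and_filter(ep, block.timeline, rt=rt)
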