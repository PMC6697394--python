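"""Synthetic recordings and behavior with the structure the analysis assumes.

The generator emulates a 5-minute streaming block: 500 ``ABA_`` triplets,
gamma-distributed percept dominance durations reported with a reaction-time
delay, tone-locked evoked deflections whose latency and width depend on the
anatomical site class (short-latency sharp responses in core auditory cortex,
slower and broader ones elsewhere), an additive percept-dependent difference
in the tone-B response confined to a configurable post-onset window,
1/f background noise, optional narrow-band ~2.5 Hz interference shared
across sites, and sporadic high-amplitude artifact transients.

Everything is driven by one seeded generator: the ground truth (which sites
carry an effect, each trial's true percept) is consistent with the emitted
voltages by construction, so every downstream stage can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .containers import RecordingBlock
from .stimulus import (
    ONE_STREAM,
    TWO_STREAM,
    PerceptTimeline,
    TripletStimulus,
    build_triplet_sequence,
    percept_label_at,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticBlock",
    "AREA_PARAMS",
    "simulate_percept_sequence",
    "simulate_button_presses",
    "simulate_lfp_block",
    "simulate_block",
]

#: Evoked-response parameterization per site class: (latency s, width s,
#: amplitude uV, oscillation Hz).  Core auditory cortex (HGPM) responds early
#: with large sharp deflections; lateral temporal sites respond later with
#: broader, smaller peaks.
AREA_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "HGPM": (0.030, 0.012, 40.0, 20.0),
    "HGAL": (0.050, 0.020, 25.0, 12.0),
    "PT": (0.035, 0.014, 30.0, 18.0),
    "PP": (0.055, 0.022, 20.0, 12.0),
    "STG": (0.080, 0.030, 15.0, 8.0),
    "MTG": (0.085, 0.035, 10.0, 8.0),
    "other": (0.090, 0.040, 5.0, 6.0),
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the emulated experiment.

    ``percept_mean_dur`` defaults to the long dominance durations typical of
    the recorded group (tens of seconds); ``effect_amp`` sits in the middle of
    the 4-18 uV range of observed evoked-potential differences, injected as an
    additive bump 60-130 ms after tone-B onset at ``effect_sites``.
    """

    n_sites: int = 8
    site_areas: tuple[str, ...] | None = None
    fs: float = 1000.0
    effect_sites: tuple[int, ...] = ()
    effect_window: tuple[float, float] = (60.0, 130.0)  # ms after tone-B onset
    effect_amp: float = 8.0  # uV
    noise_sd: float = 30.0  # uV; single-trial LFP noise dwarfs the evoked mean
    pink_exponent: float = 1.0
    line_freq: float = 2.5  # Hz
    line_amp: float = 5.0  # uV, common across sites
    artifact_rate: float = 0.5  # transients per minute per site
    percept_mean_dur: tuple[float, float] = (22.9, 32.6)  # s, (1-stream, 2-stream)
    gamma_shape: float = 2.0
    rt_mean: float = 0.6  # s
    rt_sd: float = 0.15  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_areas is None:
            cycle = list(AREA_PARAMS)
            self.site_areas = tuple(cycle[i % len(cycle)] for i in range(self.n_sites))
        if len(self.site_areas) != self.n_sites:
            raise ValueError("site_areas length must equal n_sites")
        unknown = set(self.site_areas) - set(AREA_PARAMS)
        if unknown:
            raise ValueError(f"unknown area labels: {sorted(unknown)}")
        if not (0 <= self.effect_window[0] < self.effect_window[1] <= 600):
            raise ValueError("effect_window must lie within the 600 ms triplet")
        for name in ("noise_sd", "fs", "gamma_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if min(self.percept_mean_dur) <= 0:
            raise ValueError("percept mean durations must be positive")
        if any(not 0 <= s < self.n_sites for s in self.effect_sites):
            raise ValueError("effect_sites out of range")

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": np.arange(1, self.n_sites + 1), "area": list(self.site_areas)}
        )


@dataclass
class SyntheticBlock:
    """A generated recording plus the ground truth that produced it."""

    block: RecordingBlock
    true_timeline: PerceptTimeline
    effect_sites: tuple[int, ...]
    effect_window: tuple[float, float]
    true_trial_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_percept_sequence(
    cfg: SyntheticConfig, block_dur: float, rng=None
) -> PerceptTimeline:
    """Alternating 1-stream / 2-stream dominance periods.

    Durations are gamma with shape ``cfg.gamma_shape`` and the per-percept
    mean from ``cfg.percept_mean_dur``; the sequence is truncated at the block
    end.  The returned press times are the *true* percept onsets (no reaction
    time); the first percept starts at t = 0 with a random identity.
    """
    if block_dur <= 0:
        raise ValueError("block_dur must be positive")
    rng = _as_rng(cfg.seed if rng is None else rng)
    percept = int(rng.choice((ONE_STREAM, TWO_STREAM)))
    t = 0.0
    times, percepts = [], []
    while t < block_dur:
        times.append(t)
        percepts.append(percept)
        mean = cfg.percept_mean_dur[percept - 1]
        t += rng.gamma(cfg.gamma_shape, mean / cfg.gamma_shape)
        percept = TWO_STREAM if percept == ONE_STREAM else ONE_STREAM
    return PerceptTimeline(
        press_times=np.array(times), percepts=np.array(percepts), block_dur=block_dur
    )


def simulate_button_presses(
    timeline: PerceptTimeline, rt_mean: float, rng=None, rt_sd: float = 0.15
) -> PerceptTimeline:
    """Delay each true percept onset by a nonnegative reaction-time latency.

    Latencies are truncated-normal (mean ``rt_mean``, sd ``rt_sd``, clipped at
    zero); a draw that would reorder two presses is resampled.  The first
    onset (the block start, not an actual switch report) is delayed too, so
    trials before the first press stay unlabeled as in the real task.
    """
    if rt_mean < 0:
        raise ValueError("rt_mean must be nonnegative")
    rng = _as_rng(rng)
    if rt_mean == 0:
        return timeline
    delayed = np.empty_like(timeline.press_times)
    prev = -np.inf
    for i, t in enumerate(timeline.press_times):
        upper = timeline.press_times[i + 1] if i + 1 < timeline.n_presses else np.inf
        while True:
            d = rng.normal(rt_mean, rt_sd)
            cand = t + max(d, 0.0)
            if prev < cand < upper + rt_mean:  # keep order; allow spill past block
                break
        delayed[i] = cand
        prev = cand
    return PerceptTimeline(
        press_times=delayed,
        percepts=timeline.percepts.copy(),
        block_dur=timeline.block_dur,
        stim_changes=timeline.stim_changes.copy(),
    )


def _gabor(lat: float, width: float, amp: float, f_osc: float, fs: float) -> np.ndarray:
    """Damped-oscillation evoked template, time-locked to a tone onset."""
    t = np.arange(0.0, lat + 4 * width, 1.0 / fs)
    return amp * np.exp(-0.5 * ((t - lat) / width) ** 2) * np.cos(2 * np.pi * f_osc * (t - lat))


def _effect_template(window_ms: tuple[float, float], amp: float, fs: float) -> np.ndarray:
    """Additive percept-difference bump inside ``window_ms`` after tone-B onset."""
    t0, t1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    c, w = 0.5 * (t0 + t1), (t1 - t0) / 6.0
    t = np.arange(0.0, t1 + 3 * w, 1.0 / fs)
    return amp * np.exp(-0.5 * ((t - c) / w) ** 2)


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def simulate_lfp_block(
    cfg: SyntheticConfig, stim: TripletStimulus, timeline: PerceptTimeline, rng=None
) -> SyntheticBlock:
    """Render the continuous voltage matrix for one block.

    ``timeline`` is the *true* percept sequence (no reaction-time delay): it
    decides which triplets receive the percept-difference bump at the effect
    sites.  Attach the behaviorally delayed timeline to the returned block
    separately (see :func:`simulate_block`).
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    fs = cfg.fs
    n = int(round(max(stim.total_dur, timeline.block_dur) * fs))
    tones = build_triplet_sequence(stim)
    data = np.zeros((cfg.n_sites, n))

    # Evoked deflections: one convolution per area class, shared by its sites.
    onset_idx = np.round(tones["onset_s"].to_numpy() * fs).astype(int)
    impulses = np.zeros(n)
    np.add.at(impulses, onset_idx[onset_idx < n], 1.0)
    for area in set(cfg.site_areas):
        lat, width, amp, f_osc = AREA_PARAMS[area]
        evoked = fftconvolve(impulses, _gabor(lat, width, amp, f_osc, fs))[:n]
        rows = [i for i, a in enumerate(cfg.site_areas) if a == area]
        data[rows] += evoked

    # Percept effect: the tone-B response differs between percepts by
    # effect_amp inside effect_window.  Injected symmetrically (-amp/2 for
    # 1-stream triplets, +amp/2 for 2-stream) so the AEP difference equals
    # effect_amp while neither class carries extreme single-sample values
    # that would interact with the downstream amplitude-rejection rule.
    triplet_onsets = stim.triplet_onsets()
    true_labels = np.asarray(percept_label_at(timeline, triplet_onsets))
    if cfg.effect_sites and cfg.effect_amp != 0:
        b_onsets = triplet_onsets + stim.tone_dur + stim.intra_gap
        signs = np.where(true_labels == TWO_STREAM, 0.5, -0.5)
        b_idx = np.round(b_onsets * fs).astype(int)
        ok = b_idx < n
        eff_impulses = np.zeros(n)
        np.add.at(eff_impulses, b_idx[ok], signs[ok])
        eff = fftconvolve(eff_impulses, _effect_template(cfg.effect_window, cfg.effect_amp, fs))[:n]
        data[list(cfg.effect_sites)] += eff

    # Background noise: equal-power pink + white mixture per site.
    if cfg.noise_sd > 0:
        for i in range(cfg.n_sites):
            pink = pink_noise(n, cfg.pink_exponent, rng)
            white = rng.standard_normal(n)
            data[i] += cfg.noise_sd * np.sqrt(0.5) * (pink + white)

    # Narrow-band interference: one waveform shared by all sites, so the
    # spatial (SVD) filter can identify it as a common component.
    if cfg.line_amp > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * t + phase)

    # Artifacts: 50 ms bipolar transients at 8-12x the noise floor.
    if cfg.artifact_rate > 0 and cfg.noise_sd > 0:
        width_smp = int(round(0.050 * fs))
        shape = np.sin(2 * np.pi * np.arange(width_smp) / width_smp)
        minutes = n / fs / 60.0
        for i in range(cfg.n_sites):
            n_art = rng.poisson(cfg.artifact_rate * minutes)
            starts = rng.integers(0, max(n - width_smp, 1), size=n_art)
            for s in starts:
                data[i, s : s + width_smp] += rng.uniform(8, 12) * cfg.noise_sd * shape

    block = RecordingBlock(
        data=data, fs=fs, site_table=cfg.site_table(), stim=stim, timeline=timeline
    )
    return SyntheticBlock(
        block=block,
        true_timeline=timeline,
        effect_sites=tuple(cfg.effect_sites),
        effect_window=cfg.effect_window,
        true_trial_labels=true_labels,
    )


def simulate_block(
    cfg: SyntheticConfig, stim: TripletStimulus | None = None
) -> SyntheticBlock:
    """Full behavioral + neural simulation of one experimental block.

    Draws the true percept sequence, renders the voltages from it, then
    attaches the reaction-time-delayed button-press timeline to the block
    (the only behavior the analysis is allowed to see).
    """
    rng = np.random.default_rng(cfg.seed)
    if stim is None:
        stim = TripletStimulus()
    true_tl = simulate_percept_sequence(cfg, stim.total_dur, rng)
    synth = simulate_lfp_block(cfg, stim, true_tl, rng)
    pressed = simulate_button_presses(true_tl, cfg.rt_mean, rng, rt_sd=cfg.rt_sd)
    synth.block.timeline = pressed
    return synth
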