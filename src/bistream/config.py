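"""Pipeline configuration: every tunable with its default in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline.

    Defaults follow the analysis conventions this package implements: 1 kHz
    working rate, 1.5-70 Hz LFP band with the 2.2-2.7 Hz interference band
    removed (30 spatial components discarded), 4-SD artifact rejection,
    clusters of at least 20 ms, 10,000 permutations, pointwise and cluster
    alpha 0.05, BH-FDR at 1%, 12 bins of 50 ms for classification with 100
    repetitions and a 0.3 feature-probability threshold, 70-150 Hz high
    gamma smoothed over 1.5-40 Hz, 2-s embedding windows with lambda 0.2.
    """

    fs: float = 1000.0
    band: tuple[float, float] = (1.5, 70.0)
    stopband: tuple[float, float] = (2.2, 2.7)
    n_discard: int = 30
    reject_sd: float = 4.0
    rt: float = 0.6
    min_cluster_ms: float = 20.0
    n_perm: int = 10_000
    alpha_point: float = 0.05
    alpha_cluster: float = 0.05
    q_fdr: float = 0.01
    n_bins: int = 12
    bin_ms: float = 50.0
    train_frac: float = 0.8
    n_rep: int = 100
    prob_thresh: float = 0.3
    svm_c: float = 1.0
    gamma_band: tuple[float, float] = (70.0, 150.0)
    smooth_band: tuple[float, float] = (1.5, 40.0)
    embed_window: tuple[float, float, float] = (700.0, 600.0, 700.0)
    lam: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must be in (0, 1)")
        for name in ("alpha_point", "alpha_cluster", "prob_thresh", "train_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("fs", "reject_sd", "min_cluster_ms", "bin_ms", "lam", "svm_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rt < 0:
            raise ValueError("rt must be nonnegative")
        for name in ("band", "stopband", "gamma_band", "smooth_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be an increasing positive pair")

    @property
    def min_cluster_samples(self) -> int:
        return int(round(self.min_cluster_ms * self.fs / 1000.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Short stable hash of the configuration, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
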