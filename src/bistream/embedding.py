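"""One-dimensional diffusion-map embedding of 2-s trials and group statistics.

Single-trial LFPs from auditory-cortex sites are standardized per trial and
site, pairwise cosine similarities (angle folded into [0, 90] degrees) are
mapped through the affinity kernel ``a = exp(-lambda * tan(theta))`` — 1 for
collinear trials, ~0 for orthogonal ones — one kernel per area group (HGPM;
HGAL+PT+PP; STG), the kernels are averaged, and the first nontrivial
eigenvector of the row-normalized (Markov) affinity matrix gives each trial
a scalar coordinate.  Wilcoxon rank-sum tests on those coordinates compare
1-stream vs 2-stream trials during percept maintenance, and trials preceding
switches into each percept, with BH-FDR over the family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.stats import mannwhitneyu

from .cluster import fdr_across_sites
from .containers import LabeledEpochs

__all__ = [
    "AREA_GROUPS",
    "TrialEmbedding",
    "zscore_trials",
    "cosine_affinity",
    "mean_area_kernel",
    "embed_1d",
    "embed_epochs",
    "rank_sum",
    "maintenance_test",
    "switch_test",
]

log = logging.getLogger(__name__)

#: Auditory-cortex area groups whose affinity kernels are averaged: core
#: (HGPM), non-core superior temporal plane (HGAL, PT, PP), and lateral STG.
AREA_GROUPS: tuple[tuple[str, ...], ...] = (("HGPM",), ("HGAL", "PT", "PP"), ("STG",))


def zscore_trials(trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each (trial, site) trace over its own time axis.

    Returns ``(z, valid)`` where ``valid`` marks trials whose every site
    trace had nonzero variance; invalid traces are zero-filled and logged.
    The z score makes the embedding invariant to per-trial affine amplitude
    changes.
    """
    trials = np.asarray(trials, dtype=float)
    mu = trials.mean(axis=-1, keepdims=True)
    sd = trials.std(axis=-1, keepdims=True)
    bad = sd[..., 0] == 0
    valid = ~bad.any(axis=-1) if trials.ndim == 3 else ~bad
    n_bad = int(np.count_nonzero(~valid))
    if n_bad:
        log.info("excluded %d trials with a zero-variance trace", n_bad)
    sd = np.where(sd == 0, 1.0, sd)
    return (trials - mu) / sd, valid


def cosine_affinity(z: np.ndarray, lam: float) -> np.ndarray:
    """Affinity kernel ``exp(-lambda * tan(theta))`` over trial pairs.

    ``z`` is trials x dimensions (site traces concatenated).  The cosine is
    taken in absolute value, folding the pairwise angle into [0, 90] degrees,
    so antiphase trials count as orthogonal-or-closer and tan(theta) stays
    finite and nonnegative; an exactly orthogonal pair maps to affinity 0
    (the limit value).  The diagonal is exactly 1.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    z = np.asarray(z, dtype=float).reshape(z.shape[0], -1)
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    zn = z / norms
    cos = np.abs(np.clip(zn @ zn.T, -1.0, 1.0))
    with np.errstate(divide="ignore"):
        tan = np.where(cos > 0, np.sqrt(np.clip(1 - cos**2, 0, None)) / cos, np.inf)
    a = np.zeros_like(cos)
    finite = np.isfinite(tan)
    a[finite] = np.exp(-lam * tan[finite])
    np.fill_diagonal(a, 1.0)
    return a


def mean_area_kernel(kernels: list[np.ndarray | None]) -> np.ndarray:
    """Elementwise mean over the available area-group kernels."""
    present = [k for k in kernels if k is not None]
    if not present:
        raise ValueError("no auditory-cortex area group available")
    if len(present) < len(kernels):
        log.warning(
            "only %d of %d area groups available; averaging those",
            len(present), len(kernels),
        )
    return np.mean(present, axis=0)


@dataclass
class TrialEmbedding:
    """Per-trial scalar coordinates from the affinity eigen-decomposition."""

    coord: np.ndarray
    labels: np.ndarray
    eigenvalue: float = np.nan
    trial_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    informative: bool = True


def embed_1d(a: np.ndarray) -> tuple[np.ndarray, float]:
    """First nontrivial eigenvector of the row-normalized affinity matrix.

    The affinity matrix is normalized to a Markov (row-stochastic) operator,
    whose leading eigenvector is constant (trivial); the returned coordinate
    is the right eigenvector of the second-largest eigenvalue, with the sign
    fixed so the largest-magnitude entry is positive.  A disconnected kernel
    has no meaningful diffusion coordinate and raises an error naming the
    components.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity matrix must be symmetric")
    if np.any(a < 0):
        raise ValueError("affinity matrix must be nonnegative")
    n_comp, comp = connected_components(a > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"affinity kernel is disconnected: {n_comp} components of sizes "
            f"{sizes.tolist()}"
        )
    d = a.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(d)
    sym = d_isqrt[:, None] * a * d_isqrt[None, :]
    eigval, eigvec = np.linalg.eigh(sym)
    # Second-largest eigenvalue; right eigenvector of the Markov operator is
    # D^{-1/2} times the symmetric one.
    v = d_isqrt * eigvec[:, -2]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v, float(eigval[-2])


def embed_epochs(
    ep: LabeledEpochs,
    lam: float = 0.2,
    area_groups: tuple[tuple[str, ...], ...] = AREA_GROUPS,
) -> TrialEmbedding:
    """Embed labeled 2-s trials using the area-averaged affinity kernel.

    Only retained, labeled trials with valid (nonzero-variance) traces over
    the auditory sites enter.  Coordinates near machine zero across the
    board (a degenerate, structureless kernel) are flagged uninformative.
    """
    areas = ep.site_table["area"].to_numpy()
    group_sites = [np.flatnonzero(np.isin(areas, group)) for group in area_groups]
    aud_sites = np.unique(np.concatenate(group_sites)) if group_sites else np.array([], int)
    if aud_sites.size == 0:
        raise ValueError("no auditory-cortex sites available for the embedding")
    # keep trials that are labeled and artifact-free at every auditory site,
    # so all kernels are built from the same trial set
    keep_trial = np.isin(ep.labels, (1, 2)) & ep.kept[:, aud_sites].all(axis=1)
    trials = ep.trials[keep_trial]
    z, valid = zscore_trials(trials)
    kernels: list[np.ndarray | None] = []
    for sites in group_sites:
        if sites.size == 0:
            kernels.append(None)
            continue
        zg = z[valid][:, sites, :].reshape(valid.sum(), -1)
        kernels.append(cosine_affinity(zg, lam))
    a = mean_area_kernel(kernels)
    coord, eigenvalue = embed_1d(a)
    informative = bool(np.max(np.abs(coord)) > 1e-8 and eigenvalue > 1e-8)
    return TrialEmbedding(
        coord=coord,
        labels=ep.labels[keep_trial][valid],
        eigenvalue=eigenvalue,
        trial_onsets=ep.trial_onsets[keep_trial][valid],
        informative=informative,
    )


def rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p value (exact for small untied samples)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


def maintenance_test(
    embeddings: dict[str, TrialEmbedding], q: float = 0.01
) -> dict[str, object]:
    """Percept-maintenance separation per subject/condition and pooled.

    Rank-sum of 1-stream vs 2-stream coordinates for every embedding in the
    family plus the pooled group (all coordinates concatenated), with BH-FDR
    at ``q`` over the resulting p values.  Embeddings missing a class are
    reported untestable and skipped.
    """
    p_values: dict[str, float] = {}
    untestable: list[str] = []
    pooled1, pooled2 = [], []
    for key, emb in embeddings.items():
        c1 = emb.coord[emb.labels == 1]
        c2 = emb.coord[emb.labels == 2]
        pooled1.append(c1)
        pooled2.append(c2)
        if c1.size == 0 or c2.size == 0:
            untestable.append(key)
            log.warning("embedding %s has a single percept class; untestable", key)
            continue
        p_values[key] = rank_sum(c1, c2)
    g1, g2 = np.concatenate(pooled1), np.concatenate(pooled2)
    if g1.size and g2.size:
        p_values["group"] = rank_sum(g1, g2)
    keys = list(p_values)
    reject = fdr_across_sites(np.array([p_values[k] for k in keys]), q=q)
    return {
        "p_values": p_values,
        "fdr_reject": dict(zip(keys, map(bool, reject))),
        "untestable": untestable,
    }


def switch_test(embeddings: list[TrialEmbedding]) -> float:
    """Pre-switch separation: rank-sum between coordinates of trials before
    switches into 1-stream vs into 2-stream, pooled across subjects.

    Each embedding's labels give the percept switched *into*.  Fewer than 2
    switches into either percept is untestable.
    """
    c1 = np.concatenate([e.coord[e.labels == 1] for e in embeddings])
    c2 = np.concatenate([e.coord[e.labels == 2] for e in embeddings])
    if c1.size < 2 or c2.size < 2:
        raise ValueError(
            f"too few switches for the test ({c1.size} into 1-stream, "
            f"{c2.size} into 2-stream)"
        )
    return rank_sum(c1, c2)
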