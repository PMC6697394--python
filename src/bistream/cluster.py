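"""Site-wise cluster-level-mass permutation test on evoked-potential differences.

For each recording site, the averaged evoked potentials of the two percepts
are compared with a pointwise two-sample t test; temporally adjacent
suprathreshold points of the same sign form clusters, a cluster's mass is the
sum of its t values, and the observed masses are referred to a null
distribution of the most extreme (max |mass|) cluster mass under random
relabeling of trials.  The Monte-Carlo p value is (r + 1)/(n + 1).  Each
cluster's p is assigned to all its member time points (1 elsewhere), the
site-level p is the minimum over the trial window, and Benjamini-Hochberg
FDR across sites controls the expected fraction of falsely selected sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LabeledEpochs

__all__ = [
    "Cluster",
    "PointwiseStats",
    "SiteClusterResult",
    "SiteStatMap",
    "pointwise_t",
    "form_clusters",
    "cluster_mass",
    "max_cluster_mass",
    "permutation_null",
    "monte_carlo_p",
    "assign_adjusted_p",
    "fdr_across_sites",
    "cluster_test_site",
    "aep_cluster_test",
]

DEFAULT_MIN_LEN = 20  # samples at 1 kHz = the 20 ms minimum cluster extent
DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 10_000


# ---------------------------------------------------------------------------
# pointwise statistics


def _pooled_t(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample pooled-variance t and two-tailed p along axis 0."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    p = np.where(denom > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, p


@dataclass
class PointwiseStats:
    """Per-site, per-time AEP means and two-sample t statistics."""

    aep1: np.ndarray  # site x time mean over percept-1 trials
    aep2: np.ndarray
    tmat: np.ndarray  # t_{j, tau}
    praw: np.ndarray  # uncorrected two-tailed p
    n1: np.ndarray  # per-site retained trial counts
    n2: np.ndarray
    testable: np.ndarray  # per-site: both classes have >= 2 retained trials


def pointwise_t(ep: LabeledEpochs) -> PointwiseStats:
    """Pointwise percept-1 vs percept-2 t test at every site and time point.

    Uses only retained (kept-mask) trials with a percept label; a site where
    either class has fewer than 2 retained trials is flagged untestable and
    its rows are NaN/1.
    """
    n_sites, n_time = ep.n_sites, ep.n_time
    aep1 = np.full((n_sites, n_time), np.nan)
    aep2 = np.full((n_sites, n_time), np.nan)
    tmat = np.full((n_sites, n_time), np.nan)
    praw = np.ones((n_sites, n_time))
    n1 = np.zeros(n_sites, dtype=int)
    n2 = np.zeros(n_sites, dtype=int)
    testable = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        keep = ep.kept[:, j]
        s1 = keep & (ep.labels == 1)
        s2 = keep & (ep.labels == 2)
        n1[j], n2[j] = int(s1.sum()), int(s2.sum())
        if n1[j] >= 2 and n2[j] >= 2:
            testable[j] = True
            x1, x2 = ep.trials[s1, j, :], ep.trials[s2, j, :]
            aep1[j], aep2[j] = x1.mean(axis=0), x2.mean(axis=0)
            tmat[j], praw[j] = _pooled_t(x1, x2)
    return PointwiseStats(aep1, aep2, tmat, praw, n1, n2, testable)


# ---------------------------------------------------------------------------
# clusters


@dataclass(frozen=True)
class Cluster:
    """A maximal run of adjacent suprathreshold same-sign time points."""

    start: int  # sample index, inclusive
    stop: int  # exclusive
    sign: int
    mass: float

    def __len__(self) -> int:
        return self.stop - self.start


def form_clusters(
    tvals: np.ndarray,
    praw: np.ndarray,
    min_len: int = DEFAULT_MIN_LEN,
    alpha: float = DEFAULT_ALPHA,
) -> list[Cluster]:
    """Group suprathreshold points into temporal clusters.

    Maximal runs of adjacent points with ``praw < alpha`` and a common t sign;
    runs shorter than ``min_len`` samples are discarded.  Points with exactly
    zero t (e.g. zero-variance points) never enter a cluster.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    s = np.where((praw < alpha) & (tvals != 0) & np.isfinite(tvals), np.sign(tvals), 0.0)
    clusters: list[Cluster] = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            if s[start] != 0 and (i - start) >= min_len:
                clusters.append(
                    Cluster(start, i, int(s[start]), float(tvals[start:i].sum()))
                )
            start = i
    return clusters


def cluster_mass(cluster: Cluster, tvals: np.ndarray) -> float:
    """Cluster-level mass: the sum of t values over the cluster's members."""
    return float(tvals[cluster.start : cluster.stop].sum())


def max_cluster_mass(clusters: list[Cluster]) -> float:
    """The most extreme (maximum absolute) cluster mass; 0 with no clusters."""
    if not clusters:
        return 0.0
    return max((c.mass for c in clusters), key=abs)


# ---------------------------------------------------------------------------
# permutation null


def _t_from_indicators(
    b: np.ndarray, x: np.ndarray, x2: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Pooled t for many label assignments at once.

    ``b`` is (perms x trials) 0/1 class-1 indicators, ``x`` the (trials x
    time) data, ``x2`` its elementwise square.  Returns (perms x time) t.
    """
    s_all = x.sum(axis=0)
    q_all = x2.sum(axis=0)
    s1 = b @ x
    q1 = b @ x2
    s2 = s_all - s1
    q2 = q_all - q1
    m1, m2 = s1 / n1, s2 / n2
    ss1 = q1 - n1 * m1**2
    ss2 = q2 - n2 * m2**2
    df = n1 + n2 - 2
    sp = (ss1 + ss2) / df
    np.clip(sp, 0.0, None, out=sp)  # guard tiny negative round-off
    denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def _max_mass_rows(
    t: np.ndarray, t_crit: float, min_len: int
) -> np.ndarray:
    """Signed max-|mass| cluster statistic for each row of a t matrix."""
    n_rows, n_time = t.shape
    sig = np.abs(t) > t_crit
    s = np.where(sig, np.sign(t), 0.0)
    # Flatten with a zero separator so runs cannot straddle rows.
    sep = np.zeros((n_rows, 1))
    s_flat = np.concatenate([s, sep], axis=1).ravel()
    t_flat = np.concatenate([t, sep], axis=1).ravel()
    change = np.empty(s_flat.size, dtype=bool)
    change[0] = True
    np.not_equal(s_flat[1:], s_flat[:-1], out=change[1:])
    starts = np.flatnonzero(change)
    run_sign = s_flat[starts]
    lengths = np.diff(np.append(starts, s_flat.size))
    masses = np.add.reduceat(t_flat, starts)
    valid = (run_sign != 0) & (lengths >= min_len)
    out = np.zeros(n_rows)
    if not np.any(valid):
        return out
    rows = starts[valid] // (n_time + 1)
    m = masses[valid]
    out_abs = np.zeros(n_rows)
    np.maximum.at(out_abs, rows, np.abs(m))
    hit = np.abs(m) == out_abs[rows]
    u, first = np.unique(rows[hit], return_index=True)
    out[u] = m[hit][first]
    return out


def permutation_null(
    x: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    min_len: int = DEFAULT_MIN_LEN,
    alpha: float = DEFAULT_ALPHA,
    rng=None,
    batch: int = 500,
) -> np.ndarray:
    """Null distribution of the max-|mass| cluster statistic at one site.

    Percept labels are randomly reassigned to the site's retained trials
    (class sizes preserved); for every permutation the full pipeline —
    pointwise t, thresholding at the two-tailed ``alpha``, clustering with the
    ``min_len`` rule, cluster masses — is recomputed and the most extreme
    mass recorded (0 when no cluster survives).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n2 = int((labels == 2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 trials per class")
    x2 = x * x
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    base = np.zeros(x.shape[0])
    base[:n1] = 1.0
    null = np.empty(n_perm)
    for lo in range(0, n_perm, batch):
        hi = min(lo + batch, n_perm)
        b = rng.permuted(np.tile(base, (hi - lo, 1)), axis=1)
        t = _t_from_indicators(b, x, x2, n1, n2)
        null[lo:hi] = _max_mass_rows(t, t_crit, min_len)
    return null


def monte_carlo_p(t_obs: float, null: np.ndarray) -> float:
    """Monte-Carlo p value (r + 1)/(n + 1).

    ``r`` counts null statistics at least as extreme (in absolute value) as
    the observed one; the estimate therefore can never be 0.
    """
    null = np.asarray(null)
    r = int(np.count_nonzero(np.abs(null) >= abs(t_obs)))
    return (r + 1) / (null.size + 1)


def assign_adjusted_p(
    clusters: list[Cluster], p_obs: list[float], n_time: int
) -> np.ndarray:
    """Spread each cluster's p over its member time points; 1 elsewhere."""
    p_row = np.ones(n_time)
    for c, p in zip(clusters, p_obs):
        p_row[c.start : c.stop] = p
    return p_row


def fdr_across_sites(p_values: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up across sites at level ``q``.

    NaN entries (untestable sites) are never rejected and do not count
    toward the number of tests.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum():
        reject[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return reject


# ---------------------------------------------------------------------------
# site-level driver


@dataclass
class SiteClusterResult:
    """Observed clusters and their Monte-Carlo p values at one site."""

    clusters: list[Cluster]
    p_clusters: list[float]
    p_row: np.ndarray  # adjusted p_{j, tau}
    null: np.ndarray | None
    p_site: float  # min over tau (1 with no clusters)
    testable: bool = True


@dataclass
class SiteStatMap:
    """Per-site cluster significance and the FDR decision across sites."""

    table: pd.DataFrame
    results: list[SiteClusterResult] = field(default_factory=list)
    stats: PointwiseStats | None = None


def cluster_test_site(
    x: np.ndarray,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    min_len: int = DEFAULT_MIN_LEN,
    alpha: float = DEFAULT_ALPHA,
    rng=None,
    keep_null: bool = False,
) -> SiteClusterResult:
    """Cluster-mass permutation test for one site's trials (trials x time)."""
    labels = np.asarray(labels)
    x1, x2 = x[labels == 1], x[labels == 2]
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        return SiteClusterResult([], [], np.ones(x.shape[1]), None, np.nan, testable=False)
    tvals, praw = _pooled_t(x1, x2)
    # Permutations operate on class-sorted data so the indicator matrix maps
    # cleanly onto class sizes; sorting does not change the test.
    x_sorted = np.concatenate([x1, x2], axis=0)
    lab_sorted = np.concatenate([np.ones(len(x1), int), np.full(len(x2), 2)])
    clusters = form_clusters(tvals, praw, min_len=min_len, alpha=alpha)
    null = permutation_null(
        x_sorted, lab_sorted, n_perm=n_perm, min_len=min_len, alpha=alpha, rng=rng
    )
    p_clusters = [monte_carlo_p(c.mass, null) for c in clusters]
    p_row = assign_adjusted_p(clusters, p_clusters, x.shape[1])
    p_site = float(min(p_clusters)) if p_clusters else 1.0
    return SiteClusterResult(
        clusters, p_clusters, p_row, null if keep_null else None, p_site
    )


def aep_cluster_test(
    ep: LabeledEpochs,
    n_perm: int = DEFAULT_N_PERM,
    q: float = 0.01,
    min_len: int = DEFAULT_MIN_LEN,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    keep_null: bool = False,
) -> SiteStatMap:
    """Run the cluster-mass permutation test at every site, then BH-FDR.

    Per site, only retained labeled trials enter; label shuffling is within
    site over those trials.  The site table gains columns ``p_site``,
    ``q_reject`` and the best (smallest-p, then largest-|mass|) cluster's
    extent in ms relative to the triplet onset.
    """
    pw = pointwise_t(ep)
    children = np.random.SeedSequence(seed).spawn(ep.n_sites)
    results: list[SiteClusterResult] = []
    for j in range(ep.n_sites):
        keep = ep.kept[:, j] & np.isin(ep.labels, (1, 2))
        x = ep.trials[keep, j, :]
        labels = ep.labels[keep]
        results.append(
            cluster_test_site(
                x,
                labels,
                n_perm=n_perm,
                min_len=min_len,
                alpha=alpha,
                rng=np.random.default_rng(children[j]),
                keep_null=keep_null,
            )
        )
    p_site = np.array([r.p_site for r in results])
    reject = fdr_across_sites(p_site, q=q)
    times = ep.times_ms
    rows = []
    for j, r in enumerate(results):
        best = None
        if r.clusters:
            order = sorted(
                range(len(r.clusters)),
                key=lambda i: (r.p_clusters[i], -abs(r.clusters[i].mass)),
            )
            best = r.clusters[order[0]]
        rows.append(
            {
                "site_id": ep.site_table["site_id"].iat[j]
                if "site_id" in ep.site_table
                else j + 1,
                "area": ep.site_table["area"].iat[j] if "area" in ep.site_table else "",
                "n1": pw.n1[j],
                "n2": pw.n2[j],
                "n_clusters": len(r.clusters),
                "p_site": r.p_site,
                "q_reject": bool(reject[j]),
                "best_cluster_start_ms": times[best.start] if best else np.nan,
                "best_cluster_end_ms": times[best.stop - 1] if best else np.nan,
                "best_cluster_sign": best.sign if best else 0,
                "best_cluster_mass": best.mass if best else np.nan,
            }
        )
    return SiteStatMap(table=pd.DataFrame(rows), results=results, stats=pw)
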