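"""Trial-level percept decoding: F-score feature selection + linear SVM.

Each 600 ms trial is summarized by the mean LFP in twelve 50-ms bins at
every site.  Per repetition: a random 4/5-1/5 train/test split, per-set
z-scaling, undersampling of the majority class, an F-score ranking of
features, a recursive backward-elimination loop choosing the optimal feature
dimension by validation error, a final SVM fit, and the balanced test
accuracy.  Over 100 repetitions this yields an accuracy distribution and a
per-feature selection probability; features above probability 0.3 define the
classifier-driven spatial map of percept-informative sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import LinearSVC

from .containers import LabeledEpochs

__all__ = [
    "FeatureTable",
    "ClassificationResult",
    "bin_features",
    "f_score",
    "balance_training",
    "recursive_select_and_train",
    "balanced_accuracy",
    "run_classification",
]

N_BINS = 12
BIN_MS = 50.0


@dataclass
class FeatureTable:
    """Per-trial binned-LFP features with their (site, bin) identity."""

    x: np.ndarray  # trials x features
    y: np.ndarray  # labels, 1 or 2
    site_of: np.ndarray  # per-feature site index
    bin_of: np.ndarray  # per-feature time-bin index (0..11)
    site_table: pd.DataFrame

    @property
    def n_features(self) -> int:
        return self.x.shape[1]


def bin_features(ep: LabeledEpochs, bin_ms: float = BIN_MS) -> FeatureTable:
    """Mean LFP over nonoverlapping 50 ms bins at every site.

    Requires the plain (0, 600, 0) trial window at 1 kHz, giving exactly 12
    bins per site.  Trials with any masked site or without a percept label
    are dropped so the feature matrix stays complete and aligned.
    """
    if ep.window[0] != 0 or ep.window[2] != 0:
        raise ValueError("features are defined on the (0, 600, 0) triplet window")
    bin_len = int(round(bin_ms * ep.fs / 1000.0))
    if ep.n_time % bin_len:
        raise ValueError("trial length is not a whole number of bins")
    n_bins = ep.n_time // bin_len
    keep = np.isin(ep.labels, (1, 2)) & ep.kept.all(axis=1)
    trials = ep.trials[keep]
    x = trials.reshape(trials.shape[0], ep.n_sites, n_bins, bin_len).mean(axis=3)
    x = x.reshape(trials.shape[0], ep.n_sites * n_bins)
    site_of = np.repeat(np.arange(ep.n_sites), n_bins)
    bin_of = np.tile(np.arange(n_bins), ep.n_sites)
    return FeatureTable(
        x=x, y=ep.labels[keep].copy(), site_of=site_of, bin_of=bin_of,
        site_table=ep.site_table,
    )


def f_score(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher-style feature score: between-class over within-class spread.

    ``F = [(m+ - m)^2 + (m- - m)^2] / [var+ + var-]`` with unbiased per-class
    variances.  Zero within-class variance in both classes yields +inf, which
    ranks such a (perfectly separating or degenerate) feature first.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(y)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("f_score needs exactly two classes present")
    xp, xm = x[labels == classes[0]], x[labels == classes[1]]
    m = x.mean(axis=0)
    num = (xp.mean(axis=0) - m) ** 2 + (xm.mean(axis=0) - m) ** 2
    den = xp.var(axis=0, ddof=1) + xm.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return f


def balance_training(
    x: np.ndarray, y: np.ndarray, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly undersample the majority class down to the minority size."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < 5:
        raise ValueError(f"smallest class has only {counts.min()} trials (< 5)")
    n_keep = counts.min()
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        if members.size > n_keep:
            members = rng.choice(members, size=n_keep, replace=False)
        idx.append(members)
    idx = np.sort(np.concatenate(idx))
    return x[idx], y[idx]


def _fit_svm(x: np.ndarray, y: np.ndarray, c: float) -> LinearSVC:
    return LinearSVC(C=c, dual=False, tol=1e-3).fit(x, y)


def recursive_select_and_train(
    x: np.ndarray,
    y: np.ndarray,
    d: int,
    rng=None,
    n_inner: int = 5,
    val_frac: float = 0.2,
    c: float = 1.0,
) -> tuple[int, LinearSVC, np.ndarray]:
    """Backward elimination over the top-``d`` F-ranked features.

    For k = d, d-1, ..., 1 the lowest-F feature is dropped; at each k the
    training set is split ``n_inner`` times into subtraining/validation
    parts, a linear SVM is fit on the top-k features and the mean validation
    error recorded.  The optimal dimension D* is the smallest k attaining the
    minimum mean error; the returned model is refit on the full training set
    with the top-D* features.  Returns (D*, model, selected feature indices).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = x.shape[0]
    order = np.argsort(f_score(x, y))[::-1]  # descending F
    d = min(d, x.shape[1])
    n_val = max(1, int(round(val_frac * n)))
    # Pre-draw the inner splits once; the same splits score every k so the
    # validation-error curve over k is not confounded by split noise.
    splits = []
    for _ in range(n_inner):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            val, sub = perm[:n_val], perm[n_val:]
            if np.unique(y[sub]).size == 2 and sub.size >= 2:
                break
        else:
            raise ValueError("cannot form a two-class subtraining split")
        splits.append((sub, val))
    mean_err = np.empty(d)
    for k in range(d, 0, -1):
        feats = order[:k]
        errs = []
        for sub, val in splits:
            model = _fit_svm(x[np.ix_(sub, feats)], y[sub], c)
            pred = model.predict(x[np.ix_(val, feats)])
            errs.append(np.mean(pred != y[val]))
        mean_err[k - 1] = np.mean(errs)
    d_star = int(np.argmin(mean_err) + 1)  # argmin returns the smallest k on ties
    selected = order[:d_star]
    model = _fit_svm(x[:, selected], y, c)
    return d_star, model, selected


def balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean of per-class correct-classification fractions."""
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("truth must contain both classes")
    return float(balanced_accuracy_score(truth, pred))


def _zscale(x: np.ndarray) -> np.ndarray:
    """Per-feature z scaling with this set's own statistics."""
    m = x.mean(axis=0)
    s = x.std(axis=0, ddof=0)
    s = np.where(s > 0, s, 1.0)
    return (x - m) / s


@dataclass
class ClassificationResult:
    """Accuracy distribution and feature-probability map over repetitions."""

    accuracies: np.ndarray
    feature_prob: np.ndarray  # per-feature probability of entering the optimal set
    d_stars: np.ndarray
    site_of: np.ndarray
    bin_of: np.ndarray
    site_table: pd.DataFrame
    prob_thresh: float = 0.3

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    def t_vs_chance(self) -> tuple[float, float]:
        """One-tailed one-sample t of the accuracies against chance (0.5)."""
        t, p = stats.ttest_1samp(self.accuracies, 0.5, alternative="greater")
        return float(t), float(p)

    def feature_map(self) -> pd.DataFrame:
        """Per-feature (site, bin) selection probabilities."""
        return pd.DataFrame(
            {
                "site": self.site_of,
                "bin": self.bin_of,
                "probability": self.feature_prob,
            }
        )

    def selected_sites(self) -> np.ndarray:
        """Sites with any feature above the probability threshold."""
        hot = self.feature_prob > self.prob_thresh
        return np.unique(self.site_of[hot])


def run_classification(
    ft: FeatureTable,
    n_rep: int = 100,
    seed: int = 0,
    train_frac: float = 0.8,
    prob_thresh: float = 0.3,
    c: float = 1.0,
    d_frac: float = 0.10,
) -> ClassificationResult:
    """Repeat the train/select/test cycle and aggregate.

    Each repetition draws a random ``train_frac`` / rest split (redrawn until
    both classes appear on both sides), z-scales train and test separately,
    balances the training classes by undersampling, caps the candidate
    feature count at ``ceil(d_frac * training size)``, runs the recursive
    selection, and scores the held-out trials with the balanced accuracy.
    """
    rng = np.random.default_rng(seed)
    n = ft.x.shape[0]
    counts = np.bincount(ft.y, minlength=3)[1:]
    if n < 20 or counts.min() < 10:
        raise ValueError(
            f"too few complete labeled trials to classify ({n} trials, class "
            f"counts {counts.tolist()}); check rejection masks and labeling"
        )
    n_train = int(round(train_frac * n))
    accs = np.empty(n_rep)
    d_stars = np.empty(n_rep, dtype=int)
    sel_counts = np.zeros(ft.n_features)
    for rep in range(n_rep):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if np.unique(ft.y[tr]).size == 2 and np.unique(ft.y[te]).size == 2:
                break
        else:
            raise ValueError("cannot form a two-class train/test split")
        x_tr, x_te = _zscale(ft.x[tr]), _zscale(ft.x[te])
        y_tr, y_te = ft.y[tr], ft.y[te]
        x_bal, y_bal = balance_training(x_tr, y_tr, rng)
        d = max(1, math.ceil(d_frac * x_bal.shape[0]))
        d_star, model, selected = recursive_select_and_train(
            x_bal, y_bal, d, rng, c=c
        )
        sel_counts[selected] += 1
        pred = model.predict(x_te[:, selected])
        accs[rep] = balanced_accuracy(pred, y_te)
        d_stars[rep] = d_star
    return ClassificationResult(
        accuracies=accs,
        feature_prob=sel_counts / n_rep,
        d_stars=d_stars,
        site_of=ft.site_of,
        bin_of=ft.bin_of,
        site_table=ft.site_table,
        prob_thresh=prob_thresh,
    )
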