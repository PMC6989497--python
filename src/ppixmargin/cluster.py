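"""Model-order selection and repeated unsupervised classification.

The number of tissue clusters is chosen data-driven, by the minimum of the
Bayesian information criterion and the maximum of the gap statistic, for
both K-means and Gaussian-mixture clustering.  Because both clusterers are
randomly initialized, classification is repeated (20 runs by default) and
summarized as an averaged confusion matrix with per-cell standard
deviations, after aligning each run's arbitrary cluster indices to the
histological classes by optimal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .synth import CLASS_ORDER

__all__ = [
    "ClusterRun",
    "ModelOrderResult",
    "ConfusionSummary",
    "ClusterCountSelector",
    "kmeans_fit",
    "gmm_fit",
    "bic_curve",
    "gap_statistic",
    "repeated_runs",
    "align_clusters",
    "confusion_summary",
    "accuracy",
    "MERGE_SCHEMES",
]

#: class-merging schemes for accuracy reporting, as groups of true classes
MERGE_SCHEMES = {
    "four_class": (("core",), ("hd_margin",), ("ld_margin",), ("healthy",)),
    "merge_margins": (("core",), ("hd_margin", "ld_margin"), ("healthy",)),
    "healthy_vs_rest": (("core", "hd_margin", "ld_margin"), ("healthy",)),
}


@dataclass
class ClusterRun:
    """One clustering solution on a fixed feature matrix."""

    method: str  # kmeans | gmm
    k: int
    seed: int
    labels: np.ndarray
    inertia: float  # W_k: total within-cluster sum of squared distances
    loglik: float | None = None  # total log-likelihood (gmm only)


def _check_k(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k={k} must lie in [1, n_samples={X.shape[0]}]")
    return X


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def kmeans_fit(X, k: int, seed: int = 0, n_restarts: int = 10) -> ClusterRun:
    """Best-of-restarts K-means; deterministic for a fixed seed."""
    X = _check_k(X, k)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterRun(method="kmeans", k=k, seed=seed, labels=labels,
                      inertia=float(km.inertia_))


def gmm_fit(
    X, k: int, seed: int = 0, n_restarts: int = 10, reg_covar: float = 1e-6
) -> ClusterRun:
    """Full-covariance Gaussian mixture fitted by EM (tol 1e-6, <=500 iters).

    Labels are maximum-responsibility assignments; a covariance floor
    (``reg_covar``) guards against singular clusters.
    """
    X = _check_k(X, k)
    gm = GaussianMixture(
        n_components=k,
        n_init=n_restarts,
        random_state=seed,
        reg_covar=reg_covar,
        tol=1e-6,
        max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = gm.fit_predict(X)
    if not gm.converged_:
        warnings.warn(f"GMM with k={k} did not converge within 500 iterations")
    loglik = float(gm.score(X)) * X.shape[0]
    run = ClusterRun(method="gmm", k=k, seed=seed, labels=labels,
                     inertia=_within_dispersion(X, labels), loglik=loglik)
    run.model = gm  # kept for BIC; not part of the dataclass contract
    return run


@dataclass
class ModelOrderResult:
    """BIC / gap curves over candidate cluster counts and the selected k."""

    k_range: np.ndarray
    method: str
    bic: np.ndarray | None = None
    gap: np.ndarray | None = None
    s_k: np.ndarray | None = None
    k_star_bic: int | None = None
    k_star_gap: int | None = None


def _kmeans_bic(X: np.ndarray, labels: np.ndarray, centers: np.ndarray,
                w_k: float) -> float:
    """BIC of the spherical equal-variance Gaussian mixture underlying K-means.

    The fitted K-means solution is read as a mixture of k isotropic
    Gaussians sharing one variance (sigma^2 = W_k / (d (n - k))), with
    centroid means and empirical cluster weights; the log-likelihood is the
    proper mixture likelihood at those parameters.  (The hard-assignment
    "classification likelihood" is avoided: at finite n it rewards every
    extra split so strongly that the criterion has no interior minimum.)
    The free parameters are the k centroids plus the shared variance,
    p = k d + 1.
    """
    n, d = X.shape
    k = centers.shape[0]
    dof = d * max(n - k, 1)
    sigma2 = max(w_k / dof, 1e-12 * max(float(X.var()), 1e-300))
    counts = np.bincount(labels, minlength=k).astype(float)
    log_w = np.full(k, -np.inf)
    log_w[counts > 0] = np.log(counts[counts > 0] / n)
    sq = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    log_comp = log_w[None, :] - 0.5 * d * np.log(2.0 * np.pi * sigma2) - sq / (2.0 * sigma2)
    m = log_comp.max(axis=1)
    loglik = float(np.sum(m + np.log(np.exp(log_comp - m[:, None]).sum(axis=1))))
    p = k * d + 1
    return float(-2.0 * loglik + p * np.log(n))


def bic_curve(
    X, k_range=range(1, 9), method: str = "kmeans", seed: int = 0, n_restarts: int = 10
) -> ModelOrderResult:
    """BIC = -2 logL + p log n over candidate k; k* is the argmin (ties ->
    smaller k)."""
    X = np.asarray(X, dtype=float)
    ks = np.asarray(list(k_range), dtype=int)
    bics = np.empty(ks.size)
    for i, k in enumerate(ks):
        if method == "kmeans":
            run = kmeans_fit(X, int(k), seed=seed, n_restarts=n_restarts)
            centers = np.vstack([
                X[run.labels == c].mean(axis=0) if np.any(run.labels == c)
                else X.mean(axis=0)
                for c in range(int(k))
            ])
            bics[i] = _kmeans_bic(X, run.labels, centers, run.inertia)
        elif method == "gmm":
            run = gmm_fit(X, int(k), seed=seed, n_restarts=n_restarts)
            bics[i] = float(run.model.bic(X))
        else:
            raise ValueError(f"unknown method {method!r}")
    k_star = int(ks[int(np.argmin(bics))])
    return ModelOrderResult(k_range=ks, method=method, bic=bics, k_star_bic=k_star)


def _fit_dispersion(X, k, method, seed, n_restarts):
    if method == "kmeans":
        return kmeans_fit(X, k, seed=seed, n_restarts=n_restarts).inertia
    if method == "gmm":
        return gmm_fit(X, k, seed=seed, n_restarts=n_restarts).inertia
    raise ValueError(f"unknown method {method!r}")


def gap_statistic(
    X,
    k_range=range(1, 9),
    B: int = 50,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = 10,
    rule: str = "argmax",
) -> ModelOrderResult:
    """Gap statistic with a uniform bounding-box reference distribution.

    gap(k) = mean_b log W_k(ref_b) - log W_k(X), with reference sets drawn
    uniformly over each feature's observed range; s_k is the reference
    standard deviation inflated by sqrt(1 + 1/B).  ``rule`` selects k* as the
    plain argmax (default, matching the criterion-curve reading) or by the
    one-standard-error rule (``"tibshirani"``: smallest k with
    gap(k) >= gap(k+1) - s_{k+1}).
    """
    X = np.asarray(X, dtype=float)
    if B < 10:
        raise ValueError(f"B must be >= 10, got {B}")
    ks = np.asarray(list(k_range), dtype=int)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)  # constant features stay constant
    refs = [lo + (hi - lo) * rng.random((n, d)) for _ in range(B)]

    log_w_obs = np.empty(ks.size)
    gap = np.empty(ks.size)
    s_k = np.empty(ks.size)
    for i, k in enumerate(ks):
        k = int(k)
        log_w_obs[i] = np.log(max(_fit_dispersion(X, k, method, seed, n_restarts), 1e-300))
        log_w_ref = np.array([
            np.log(max(_fit_dispersion(ref, k, method, seed + 1 + b, n_restarts), 1e-300))
            for b, ref in enumerate(refs)
        ])
        gap[i] = log_w_ref.mean() - log_w_obs[i]
        s_k[i] = log_w_ref.std() * np.sqrt(1.0 + 1.0 / B)

    if rule == "argmax":
        k_star = int(ks[int(np.argmax(gap))])
    elif rule == "tibshirani":
        k_star = int(ks[-1])
        for i in range(ks.size - 1):
            if gap[i] >= gap[i + 1] - s_k[i + 1]:
                k_star = int(ks[i])
                break
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return ModelOrderResult(k_range=ks, method=method, gap=gap, s_k=s_k,
                            k_star_gap=k_star)


class ClusterCountSelector(BaseEstimator):
    """Estimator that selects the number of clusters from the data.

    fit(X) computes the BIC curve and/or the gap-statistic curve for the
    configured clustering method and exposes ``bic_``, ``gap_``, ``s_k_``,
    ``k_star_bic_``, ``k_star_gap_`` and the combined ``best_k_``
    (gap selection when computed, else BIC).
    """

    def __init__(self, method: str = "kmeans", k_min: int = 1, k_max: int = 8,
                 criterion: str = "both", B: int = 50, n_restarts: int = 10,
                 gap_rule: str = "argmax", seed: int = 0):
        self.method = method
        self.k_min = k_min
        self.k_max = k_max
        self.criterion = criterion
        self.B = B
        self.n_restarts = n_restarts
        self.gap_rule = gap_rule
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.criterion not in ("bic", "gap", "both"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        ks = range(self.k_min, min(self.k_max, X.shape[0]) + 1)
        self.k_range_ = np.asarray(list(ks), dtype=int)
        self.bic_ = self.gap_ = self.s_k_ = None
        self.k_star_bic_ = self.k_star_gap_ = None
        if self.criterion in ("bic", "both"):
            res = bic_curve(X, ks, method=self.method, seed=self.seed,
                            n_restarts=self.n_restarts)
            self.bic_, self.k_star_bic_ = res.bic, res.k_star_bic
        if self.criterion in ("gap", "both"):
            res = gap_statistic(X, ks, B=self.B, method=self.method,
                                seed=self.seed, n_restarts=self.n_restarts,
                                rule=self.gap_rule)
            self.gap_, self.s_k_ = res.gap, res.s_k
            self.k_star_gap_ = res.k_star_gap
        self.best_k_ = self.k_star_gap_ if self.k_star_gap_ is not None else self.k_star_bic_
        return self


def repeated_runs(
    X, k: int, method: str = "kmeans", n_runs: int = 20, base_seed: int = 0,
    n_restarts: int = 1,
) -> list[ClusterRun]:
    """Repeat the randomly-initialized clustering ``n_runs`` times.

    Run i uses seed ``base_seed + i``; with the default single restart the
    runs genuinely differ through their initialization, which is what the
    averaged confusion summary quantifies.
    """
    fit = kmeans_fit if method == "kmeans" else gmm_fit
    return [fit(X, k, seed=base_seed + i, n_restarts=n_restarts) for i in range(n_runs)]


def _contingency(pred: np.ndarray, true: np.ndarray, n_pred: int, n_true: int) -> np.ndarray:
    table = np.zeros((n_pred, n_true), dtype=float)
    for p, t in zip(pred, true):
        table[p, t] += 1
    return table


def align_clusters(pred_labels, true_labels, n_classes: int | None = None) -> np.ndarray:
    """Relabel arbitrary cluster indices to true-class indices.

    The cluster -> class mapping maximizes total agreement on the
    contingency table via optimal (rectangular) assignment; when there are
    more clusters than classes, leftover clusters map to their majority
    class.  The result is invariant to any permutation of the input cluster
    indices.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("pred and true label arrays differ in length")
    n_pred = int(pred.max()) + 1 if pred.size else 0
    n_true = n_classes if n_classes is not None else int(true.max()) + 1
    table = _contingency(pred, true, n_pred, n_true)
    rows, cols = linear_sum_assignment(-table)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    for c in range(n_pred):  # clusters beyond the class count
        if c not in mapping:
            mapping[c] = int(np.argmax(table[c]))
    return np.asarray([mapping[int(p)] for p in pred])


@dataclass
class ConfusionSummary:
    """Confusion statistics averaged over repeated clustering runs.

    Rows are true classes (canonical order), columns predicted classes after
    alignment.  ``mean_counts[i, j]`` is the average number of class-i
    samples predicted as class j; ``percent`` is that count as a percentage
    of the true-class size; ``sigma`` is the population standard deviation
    of the count across runs.
    """

    classes: tuple[str, ...]
    mean_counts: np.ndarray
    percent: np.ndarray
    sigma: np.ndarray
    n_runs: int
    row_totals: np.ndarray = field(default=None)  # type: ignore[assignment]


def confusion_summary(
    runs: list[ClusterRun],
    true_labels,
    classes: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionSummary:
    """Align every run against the true classes and average the confusion
    matrices; sigma uses the population convention (divisor n_runs), so a
    cell constant across runs reports sigma = 0."""
    true = np.asarray(true_labels)
    if true.dtype.kind in "UO":
        idx = {c: i for i, c in enumerate(classes)}
        true = np.asarray([idx[t] for t in true])
    n_classes = len(classes)
    mats = []
    for run in runs:
        if run.labels.shape != true.shape:
            raise ValueError("run labels and true labels differ in length")
        aligned = align_clusters(run.labels, true, n_classes=n_classes)
        mats.append(_contingency(true, aligned, n_classes, n_classes))
    stack = np.stack(mats)
    mean_counts = stack.mean(axis=0)
    sigma = stack.std(axis=0)  # population sd over runs
    row_totals = mean_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(row_totals[:, None] > 0,
                           100.0 * mean_counts / row_totals[:, None], 0.0)
    return ConfusionSummary(
        classes=tuple(classes),
        mean_counts=mean_counts,
        percent=percent,
        sigma=sigma,
        n_runs=len(runs),
        row_totals=row_totals,
    )


def _merge_matrix(counts: np.ndarray, classes: tuple[str, ...], scheme: str) -> np.ndarray:
    if scheme not in MERGE_SCHEMES:
        raise ValueError(f"unknown merge scheme {scheme!r}; use one of {sorted(MERGE_SCHEMES)}")
    groups = MERGE_SCHEMES[scheme]
    idx = {c: i for i, c in enumerate(classes)}
    merged = np.zeros((len(groups), len(groups)))
    for gi, gr in enumerate(groups):
        for gj, gc in enumerate(groups):
            rows = [idx[c] for c in gr if c in idx]
            cols = [idx[c] for c in gc if c in idx]
            merged[gi, gj] = counts[np.ix_(rows, cols)].sum()
    return merged


def accuracy(summary, scheme: str = "four_class",
             classes: tuple[str, ...] = CLASS_ORDER) -> float:
    """Fraction of samples on the (merged) confusion diagonal.

    ``summary`` may be a :class:`ConfusionSummary` or a raw square confusion
    matrix whose rows/columns follow ``classes``.
    """
    if isinstance(summary, ConfusionSummary):
        counts, classes = summary.mean_counts, summary.classes
    else:
        counts = np.asarray(summary, dtype=float)
    merged = _merge_matrix(counts, tuple(classes), scheme)
    total = merged.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(merged) / total)
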