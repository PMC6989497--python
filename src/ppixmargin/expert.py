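"""Expert-based baseline: dual-state PpIX spectral unmixing.

The classical biomarker model fits each normalized, background-corrected
emission spectrum over a 585-640 nm window with the two in-vitro PpIX basis
spectra (peaks at 620 and 634 nm) and reports their relative contributions
alpha_620 and alpha_634 (which sum to 1 per channel).  With three excitation
channels this yields a 6-descriptor feature space, which is then put through
the same t-SNE + repeated-K-means protocol as the full-spectrum machine
learning arm for a like-for-like comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .cluster import MERGE_SCHEMES, ConfusionSummary, accuracy, confusion_summary, kmeans_fit
from .dimred import tsne_embed
from .preprocess import FeatureMatrix, build_feature_matrix, process_acquisition
from .synth import (
    AUTOFLUORESCENCE,
    CLASS_ORDER,
    PPIX620,
    PPIX634,
    ReferenceSpectrum,
    SampleAcquisition,
    WavelengthGrid,
)

__all__ = [
    "FitWindow",
    "ChannelFit",
    "PpIXStateUnmixer",
    "fit_ppix_states",
    "expert_feature_matrix",
    "standardize_columns",
    "ComparisonResult",
    "compare_pipelines",
]


@dataclass(frozen=True)
class FitWindow:
    """Wavelength window used for the dual-state fit (default 585-640 nm)."""

    low_nm: float = 585.0
    high_nm: float = 640.0

    def __post_init__(self) -> None:
        if not self.low_nm < self.high_nm:
            raise ValueError("fit window must satisfy low < high")

    def mask(self, grid: WavelengthGrid) -> np.ndarray:
        m = (grid.values >= self.low_nm) & (grid.values <= self.high_nm)
        if not np.any(m):
            raise ValueError("fit window does not intersect the wavelength grid")
        return m


@dataclass
class ChannelFit:
    """Dual-state fit result for one excitation channel."""

    alpha_620: float
    alpha_634: float
    residual_norm: float
    window: FitWindow
    flagged: bool  # True when no PpIX signal was found (both coefficients 0)


def fit_ppix_states(
    intensity: np.ndarray,
    grid: WavelengthGrid,
    refs: dict[str, ReferenceSpectrum],
    window: FitWindow | None = None,
    subtract_autofluorescence: bool = False,
) -> ChannelFit:
    """Nonnegative least-squares unmixing of one spectrum in the fit window.

    The autofluorescence basis is included as a free nonnegative regressor
    so that non-PpIX fluorophores emitting below 620 nm do not bias the
    state coefficients; its coefficient is discarded.  Alternatively
    (``subtract_autofluorescence=True``) an autofluorescence amplitude is
    estimated on the 585-605 nm leading edge and subtracted before a
    two-basis fit.
    """
    if window is None:
        window = FitWindow()
    y = np.asarray(intensity, dtype=float)
    if y.shape != (grid.n_points,):
        raise ValueError("spectrum length does not match the grid")
    mask = window.mask(grid)
    af = refs[AUTOFLUORESCENCE].intensity

    if subtract_autofluorescence:
        edge = (grid.values >= window.low_nm) & (grid.values <= window.low_nm + 20.0)
        denom = float(af[edge] @ af[edge])
        amp = max(float(y[edge] @ af[edge]) / denom, 0.0) if denom > 0 else 0.0
        y = np.clip(y - amp * af, 0.0, None)
        A = np.column_stack([refs[PPIX620].intensity[mask], refs[PPIX634].intensity[mask]])
        coef, res = nnls(A, y[mask])
        c620, c634 = coef
    else:
        A = np.column_stack(
            [refs[PPIX620].intensity[mask], refs[PPIX634].intensity[mask], af[mask]]
        )
        coef, res = nnls(A, y[mask])
        c620, c634 = coef[0], coef[1]

    total = c620 + c634
    # numerically-zero PpIX contribution counts as absent
    if total <= 1e-6 * float(np.max(np.abs(y))):
        return ChannelFit(alpha_620=np.nan, alpha_634=np.nan,
                          residual_norm=float(res), window=window, flagged=True)
    return ChannelFit(
        alpha_620=float(c620 / total),
        alpha_634=float(c634 / total),
        residual_norm=float(res),
        window=window,
        flagged=False,
    )


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance columns; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    ok = sd > 1e-12
    out[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return out


class PpIXStateUnmixer(BaseEstimator, TransformerMixin):
    """Transformer from full-spectrum rows to the 6-D expert feature space.

    Input rows are concatenated normalized per-channel spectra (ascending
    channel order); output columns are (alpha_620, alpha_634) per channel.
    """

    def __init__(self, refs=None, grid: WavelengthGrid | None = None,
                 channel_centers: tuple[int, ...] = (385, 405, 420),
                 window: FitWindow | None = None,
                 subtract_autofluorescence: bool = False):
        self.refs = refs
        self.grid = grid
        self.channel_centers = channel_centers
        self.window = window
        self.subtract_autofluorescence = subtract_autofluorescence

    def _resolved(self):
        from .synth import default_references, make_wavelength_grid

        grid = self.grid if self.grid is not None else make_wavelength_grid()
        refs = self.refs if self.refs is not None else default_references(grid)
        window = self.window if self.window is not None else FitWindow()
        return grid, refs, window

    def fit(self, X, y=None):
        grid, _, _ = self._resolved()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.channel_centers) * grid.n_points:
            raise ValueError("input rows must concatenate one spectrum per channel")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "n_features_in_"):
            raise RuntimeError("PpIXStateUnmixer is not fitted")
        grid, refs, window = self._resolved()
        X = np.asarray(X, dtype=float)
        p = grid.n_points
        out = np.empty((X.shape[0], 2 * len(self.channel_centers)))
        self.flagged_ = np.zeros(X.shape[0], dtype=bool)
        for i, row in enumerate(X):
            for j, _c in enumerate(self.channel_centers):
                fit = fit_ppix_states(
                    row[j * p : (j + 1) * p], grid, refs, window,
                    self.subtract_autofluorescence,
                )
                out[i, 2 * j] = fit.alpha_620
                out[i, 2 * j + 1] = fit.alpha_634
                self.flagged_[i] |= fit.flagged
        return out


def expert_feature_matrix(
    samples: list[SampleAcquisition],
    refs: dict[str, ReferenceSpectrum],
    window: FitWindow | None = None,
    energy: str = "l1",
    standardize: bool = False,
    subtract_autofluorescence: bool = False,
) -> FeatureMatrix:
    """Per-sample (alpha_620, alpha_634) for each channel -> n x 6 matrix.

    Samples with a flagged channel (no detectable PpIX) are excluded with a
    warning.  ``standardize=True`` applies the zero-mean/unit-variance column
    scaling used before embedding.
    """
    if not samples:
        raise ValueError("no samples given")
    centers = sorted(c.center_nm for c in samples[0].channels)
    rows, ids, classes, dropped = [], [], [], []
    for sample in samples:
        spectra = process_acquisition(sample, energy)
        feats, flagged = [], False
        for c in centers:
            fit = fit_ppix_states(spectra[c], sample.grid, refs, window,
                                  subtract_autofluorescence)
            flagged |= fit.flagged
            feats.extend([fit.alpha_620, fit.alpha_634])
        if flagged:
            dropped.append(sample.sample_id)
            continue
        rows.append(feats)
        ids.append(sample.sample_id)
        classes.append(sample.true_class)
    if dropped:
        warnings.warn(f"excluded {len(dropped)} sample(s) with no PpIX signal: {dropped}")
    if not rows:
        raise ValueError("every sample was flagged; no expert features to report")
    values = np.asarray(rows, dtype=float)
    if standardize:
        values = standardize_columns(values)
    columns = [f"ch{c}_alpha{state}" for c in centers for state in (620, 634)]
    return FeatureMatrix(values=values, feature_space="expert", sample_ids=ids,
                         columns=columns, true_classes=classes)


@dataclass
class ComparisonResult:
    """Paired full-spectrum vs expert-baseline clustering outcome."""

    ml: ConfusionSummary
    expert: ConfusionSummary
    accuracies: dict[str, dict[str, float]]  # scheme -> {ml, expert, delta}
    seeds: list[int]
    k: int
    dim: int
    perplexity: float


def _protocol_runs(X, k, n_runs, base_seed, dim, perplexity, n_restarts):
    runs = []
    seeds = []
    for i in range(n_runs):
        seed = base_seed + i
        emb = tsne_embed(X, d=dim, perplexity=perplexity, seed=seed)
        runs.append(kmeans_fit(emb.coords, k, seed=seed, n_restarts=n_restarts))
        seeds.append(seed)
    return runs, seeds


def compare_pipelines(
    samples: list[SampleAcquisition],
    refs: dict[str, ReferenceSpectrum],
    k: int = 4,
    n_runs: int = 20,
    dim: int = 3,
    perplexity: float = 10.0,
    base_seed: int = 0,
    energy: str = "l1",
    window: FitWindow | None = None,
    n_restarts: int = 10,
    classes: tuple[str, ...] = CLASS_ORDER,
) -> ComparisonResult:
    """Run both arms through the identical t-SNE + repeated-K-means protocol.

    Run i of either arm embeds with t-SNE seed ``base_seed + i`` and clusters
    with the same K-means seed, so the two feature spaces — 2700-D full
    spectrum vs 6-D standardized expert descriptors — are the only
    difference between the arms.
    """
    X_full = build_feature_matrix(samples, energy)
    expert_fm = expert_feature_matrix(samples, refs, window, energy, standardize=True)
    if expert_fm.n_samples != X_full.n_samples:
        keep = set(expert_fm.sample_ids)
        mask = [sid in keep for sid in X_full.sample_ids]
        X_full = FeatureMatrix(
            values=X_full.values[np.asarray(mask)],
            feature_space=X_full.feature_space,
            sample_ids=[s for s, m in zip(X_full.sample_ids, mask) if m],
            columns=X_full.columns,
            true_classes=[c for c, m in zip(X_full.true_classes, mask) if m],
        )
    true = X_full.true_classes

    ml_runs, seeds = _protocol_runs(X_full.values, k, n_runs, base_seed, dim,
                                    perplexity, n_restarts)
    ex_runs, ex_seeds = _protocol_runs(expert_fm.values, k, n_runs, base_seed, dim,
                                       perplexity, n_restarts)
    assert seeds == ex_seeds  # equal-protocol fairness

    present = tuple(c for c in classes if c in set(true))
    ml_summary = confusion_summary(ml_runs, true, classes=present)
    ex_summary = confusion_summary(ex_runs, true, classes=present)

    accuracies = {}
    for scheme in MERGE_SCHEMES:
        a_ml = accuracy(ml_summary, scheme)
        a_ex = accuracy(ex_summary, scheme)
        accuracies[scheme] = {"ml": a_ml, "expert": a_ex, "delta": a_ml - a_ex}
    return ComparisonResult(ml=ml_summary, expert=ex_summary, accuracies=accuracies,
                            seeds=seeds, k=k, dim=dim, perplexity=perplexity)
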