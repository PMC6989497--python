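"""Dimension reduction and spectral-feature identification.

PCA (with a fixed sign convention so component plots are reproducible) is
used to count the statistically relevant spectral components — via the
scree-test elbow and the 95% cumulative-variance rule — and to inspect the
components back in emission-spectrum space, where each is expected to show a
PpIX-band peak between 620 and 636 nm.  t-SNE provides the 3-D embedding
used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .preprocess import FeatureMatrix
from .synth import WavelengthGrid

__all__ = [
    "PCAResult",
    "Embedding",
    "ComponentSpectra",
    "SignFixedPCA",
    "pca_fit",
    "n_components_cumvar",
    "scree_elbow",
    "components_in_spectral_space",
    "tsne_embed",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return X


@dataclass
class PCAResult:
    """Centered PCA decomposition with deterministic component signs."""

    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_samples, n_components)
    mean: np.ndarray


class SignFixedPCA(BaseEstimator, TransformerMixin):
    """PCA whose component signs are fixed so the largest-|loading| entry is
    positive, making loading plots reproducible across library versions."""

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        X = _as_array(X)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 samples")
        if not np.any(np.ptp(X, axis=0) > 0):
            raise ValueError("constant matrix: no variance to decompose")
        pca = PCA(n_components=self.n_components)
        scores = pca.fit_transform(X)
        components = pca.components_.copy()
        flip = np.sign(
            components[np.arange(components.shape[0]),
                       np.argmax(np.abs(components), axis=1)]
        )
        flip[flip == 0] = 1.0
        components *= flip[:, None]
        scores *= flip[None, :]
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_.copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.mean_ = pca.mean_.copy()
        self.n_features_in_ = X.shape[1]
        return scores

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise RuntimeError("SignFixedPCA is not fitted")
        return (_as_array(X) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        return np.asarray(scores) @ self.components_ + self.mean_


def pca_fit(X, n_components: int | None = None) -> PCAResult:
    """Fit a centered, sign-fixed PCA and return the full result bundle."""
    est = SignFixedPCA(n_components=n_components)
    scores = est.fit_transform(X)
    return PCAResult(
        components=est.components_,
        explained_variance=est.explained_variance_,
        explained_variance_ratio=est.explained_variance_ratio_,
        scores=scores,
        mean=est.mean_,
    )


def n_components_cumvar(pca: PCAResult | np.ndarray, threshold: float = 0.95) -> int:
    """Smallest number of leading components whose cumulative explained
    variance ratio reaches ``threshold`` (default: the 95% rule)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    ratios = pca.explained_variance_ratio if isinstance(pca, PCAResult) else np.asarray(pca)
    cum = np.cumsum(ratios)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    if hit.size == 0:
        raise ValueError(
            f"cumulative variance of the stored components ({cum[-1]:.4f}) "
            f"never reaches {threshold}"
        )
    return int(hit[0]) + 1


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Scree-test elbow: the index (1-based) of maximum perpendicular
    distance to the chord joining the first and last eigenvalue.

    A strictly linear decay has no curvature; by convention 1 is returned.
    Ties break toward the smaller index.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("scree test needs at least 3 eigenvalues")
    if np.any(lam < 0) or np.any(np.diff(lam) > 1e-12 * max(lam[0], 1.0)):
        raise ValueError("eigenvalues must be nonnegative and nonincreasing")
    p = lam.size
    x = np.arange(1, p + 1, dtype=float)
    # distance from (x_i, lam_i) to the line through (1, lam_1) and (p, lam_p)
    dx, dy = p - 1.0, lam[-1] - lam[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (lam - lam[0]) - dy * (x - 1.0)) / norm
    scale = max(lam[0] - lam[-1], 1.0e-300)
    if dist.max() <= 1e-12 * scale:
        return 1
    return int(np.argmax(dist)) + 1


@dataclass
class ComponentSpectra:
    """One principal component viewed in emission-spectrum space."""

    index: int  # 1-based component number
    blocks: dict[int, np.ndarray]  # channel center -> raw loading block
    peak_nm: dict[int, float]  # channel center -> argmax in the PpIX window
    window_nm: tuple[float, float]

    def normalized_blocks(self) -> dict[int, np.ndarray]:
        """Max-|loading|-normalized blocks for plotting."""
        return {
            c: b / np.max(np.abs(b)) if np.max(np.abs(b)) > 0 else b
            for c, b in self.blocks.items()
        }

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.blocks[c] for c in sorted(self.blocks)])


def components_in_spectral_space(
    pca: PCAResult,
    m: int,
    grid: WavelengthGrid,
    channel_centers: tuple[int, ...] = (385, 405, 420),
    window_nm: tuple[float, float] = (600.0, 660.0),
) -> list[ComponentSpectra]:
    """Split the first ``m`` loading vectors into per-channel spectra and
    report each block's peak wavelength inside the PpIX window."""
    if m > pca.components.shape[0]:
        raise ValueError(f"only {pca.components.shape[0]} components stored, asked for {m}")
    n_ch = len(channel_centers)
    p = grid.n_points
    if pca.components.shape[1] != n_ch * p:
        raise ValueError("component length does not match n_channels x grid size")
    in_window = (grid.values >= window_nm[0]) & (grid.values <= window_nm[1])
    if not np.any(in_window):
        raise ValueError("PpIX window does not intersect the grid")
    out = []
    for i in range(m):
        loading = pca.components[i]
        blocks = {
            c: loading[j * p : (j + 1) * p] for j, c in enumerate(channel_centers)
        }
        peaks = {}
        for c, block in blocks.items():
            windowed = np.where(in_window, block, -np.inf)
            peaks[c] = float(grid.values[int(np.argmax(windowed))])
        out.append(ComponentSpectra(index=i + 1, blocks=blocks, peak_nm=peaks,
                                    window_nm=window_nm))
    return out


@dataclass
class Embedding:
    """Low-dimensional embedding of the samples."""

    coords: np.ndarray  # (n_samples, d)
    method: str
    params: dict = field(default_factory=dict)


def tsne_embed(
    X,
    d: int = 3,
    perplexity: float = 10.0,
    seed: int = 0,
    max_iter: int = 3000,
) -> Embedding:
    """Seeded t-SNE embedding to ``d`` in {2, 3} dimensions.

    Uses the exact method (at tens of samples the Barnes-Hut approximation
    buys nothing) with a random, seed-dependent initialization and a long,
    gently-exaggerated optimization: at n ~ 50 the stock schedule leaves the
    embedding visibly underconverged, and a deterministic initialization
    would make every "repeated prediction" embed identically.
    """
    X = _as_array(X)
    n = X.shape[0]
    if d not in (2, 3):
        raise ValueError(f"d must be 2 or 3, got {d}")
    if not perplexity < (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; need perplexity < (n-1)/3 "
            f"= {(n - 1) / 3:.1f}"
        )
    tsne = TSNE(
        n_components=d,
        perplexity=perplexity,
        random_state=seed,
        init="random",
        learning_rate=50.0,
        early_exaggeration=4.0,
        method="exact",
        max_iter=max_iter,
    )
    coords = tsne.fit_transform(X)
    return Embedding(
        coords=coords,
        method="tsne",
        params={"perplexity": perplexity, "seed": seed, "d": d, "max_iter": max_iter},
    )
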