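"""Raw on/off frames -> normalized full-spectrum feature matrix.

Background (ambient operating-room light) is removed by subtracting the
mean LED-off frame from the mean LED-on frame; each channel's spectrum is
then divided by its global energy so that classification sees only spectral
shape, not absolute intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import SampleAcquisition, WavelengthGrid

__all__ = [
    "DegenerateSpectrumError",
    "FeatureMatrix",
    "subtract_background",
    "normalize_energy",
    "process_acquisition",
    "build_feature_matrix",
    "EnergyNormalizer",
]


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum carries no usable signal (e.g. all zeros)."""


@dataclass
class FeatureMatrix:
    """n_samples x n_features matrix with provenance and column metadata.

    ``columns`` is a list of ``(channel_center_nm, wavelength_nm)`` tuples
    for the full-spectrum space or descriptor-name strings for the expert
    space.
    """

    values: np.ndarray
    feature_space: str  # full_spectrum | expert | reduced
    sample_ids: list[str]
    columns: list
    true_classes: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count does not match column metadata")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            f"ch{c[0]}_{c[1]:.2f}nm" if isinstance(c, tuple) else str(c)
            for c in self.columns
        ]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


def subtract_background(
    on_frames: np.ndarray, off_frames: np.ndarray, grid: WavelengthGrid | None = None
) -> np.ndarray:
    """mean(on) - mean(off), pointwise, with negative residuals clipped to 0."""
    on = np.atleast_2d(np.asarray(on_frames, dtype=float))
    off = np.atleast_2d(np.asarray(off_frames, dtype=float))
    if on.shape[0] < 1 or off.shape[0] < 1:
        raise ValueError("need at least one on-frame and one off-frame")
    if on.shape[1] != off.shape[1]:
        raise ValueError(
            f"on/off frames are on different grids ({on.shape[1]} vs {off.shape[1]} points)"
        )
    if grid is not None and on.shape[1] != grid.n_points:
        raise ValueError("frames do not match the supplied wavelength grid")
    return np.clip(on.mean(axis=0) - off.mean(axis=0), 0.0, None)


def _energy(intensity: np.ndarray, grid_values: np.ndarray, energy: str) -> float:
    if energy == "l1":
        return float(np.trapezoid(intensity, grid_values))
    if energy == "l2":
        return float(np.sqrt(np.trapezoid(intensity**2, grid_values)))
    raise ValueError(f"unknown energy definition {energy!r}; use 'l1' or 'l2'")


def normalize_energy(
    intensity: np.ndarray, grid: WavelengthGrid, energy: str = "l1"
) -> np.ndarray:
    """Divide a spectrum by its global energy (area under the curve by default)."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != (grid.n_points,):
        raise ValueError("spectrum length does not match the grid")
    norm = _energy(intensity, grid.values, energy)
    if norm <= 0 or not np.any(intensity > 0):
        raise DegenerateSpectrumError("spectrum has no positive signal; cannot normalize")
    return intensity / norm


def process_acquisition(
    sample: SampleAcquisition, energy: str = "l1"
) -> dict[int, np.ndarray]:
    """Background-subtract and energy-normalize each channel of one sample."""
    out = {}
    for ch in sorted(sample.channels, key=lambda c: c.center_nm):
        on, off = sample.frames[ch.center_nm]
        corrected = subtract_background(on, off, sample.grid)
        out[ch.center_nm] = normalize_energy(corrected, sample.grid, energy)
    return out


def build_feature_matrix(
    samples: list[SampleAcquisition], energy: str = "l1"
) -> FeatureMatrix:
    """Concatenate each sample's normalized per-channel spectra (ascending
    channel order) into the full-spectrum feature matrix.

    With the default three channels and 900-point grid this is the
    50 x 2700 matrix the clustering operates on.
    """
    if not samples:
        raise ValueError("no samples given")
    channel_sets = {tuple(sorted(c.center_nm for c in s.channels)) for s in samples}
    if len(channel_sets) != 1:
        raise ValueError(f"inconsistent channel sets across samples: {channel_sets}")
    centers = sorted(channel_sets.pop())
    grid = samples[0].grid

    rows = []
    for sample in samples:
        spectra = process_acquisition(sample, energy)
        rows.append(np.concatenate([spectra[c] for c in centers]))
    columns = [(c, float(w)) for c in centers for w in grid.values]
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_space="full_spectrum",
        sample_ids=[s.sample_id for s in samples],
        columns=columns,
        true_classes=[s.true_class for s in samples],
    )


class EnergyNormalizer(BaseEstimator, TransformerMixin):
    """Stateless per-channel-block energy normalization for spectrum matrices.

    Expects rows that are concatenations of ``n_channels`` blocks of
    ``grid.n_points`` values each (background-corrected spectra) and returns
    the same layout with each block scaled to unit energy.
    """

    def __init__(self, grid: WavelengthGrid | None = None, n_channels: int = 3,
                 energy: str = "l1"):
        self.grid = grid
        self.n_channels = n_channels
        self.energy = energy

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        grid = self.grid
        if grid is None:
            from .synth import make_wavelength_grid

            grid = make_wavelength_grid()
        if X.shape[1] != self.n_channels * grid.n_points:
            raise ValueError(
                f"expected {self.n_channels} x {grid.n_points} columns, got {X.shape[1]}"
            )
        self.grid_ = grid
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "grid_"):
            raise RuntimeError("EnergyNormalizer is not fitted")
        X = np.asarray(X, dtype=float)
        p = self.grid_.n_points
        out = np.empty_like(X)
        for i, row in enumerate(X):
            for b in range(self.n_channels):
                block = row[b * p : (b + 1) * p]
                out[i, b * p : (b + 1) * p] = normalize_energy(block, self.grid_, self.energy)
        return out
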