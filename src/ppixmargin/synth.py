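"""Forward model for multi-excitation 5-ALA/PpIX fluorescence acquisitions.

Emulates the intraoperative probe protocol: three excitation LEDs
(385/405/420 nm), each delivering alternating LED-on / LED-off frames of a
900-point emission spectrum on a 435-840 nm grid.  Tissue classes (tumor
core, high-density margin, low-density margin, healthy) differ in total PpIX
signal, in the fraction of PpIX emitting in the blue-shifted 620 nm state,
and in the autofluorescence-to-PpIX ratio, which is the class structure the
downstream clustering is expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ReferenceSpectrum",
    "ExcitationChannel",
    "TissueClassParams",
    "SampleAcquisition",
    "DatasetSpec",
    "ConfigurationError",
    "CLASS_ORDER",
    "PPIX634",
    "PPIX620",
    "AUTOFLUORESCENCE",
    "make_wavelength_grid",
    "make_reference_spectrum",
    "default_references",
    "default_channels",
    "default_class_params",
    "simulate_sample",
    "simulate_dataset",
    "simulate_component_mixtures",
    "acquisition_time",
]

#: canonical tissue-class ordering (worst to best prognosis), used everywhere
#: a confusion matrix or parameter table is indexed by class.
CLASS_ORDER = ("core", "hd_margin", "ld_margin", "healthy")

PPIX634 = "ppix634"
PPIX620 = "ppix620"
AUTOFLUORESCENCE = "autofluorescence"
REFERENCE_KINDS = (PPIX634, PPIX620, AUTOFLUORESCENCE)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, inclusive emission-wavelength grid in nanometres."""

    values: np.ndarray

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def stop_nm(self) -> float:
        return float(self.values[-1])

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def spacing_nm(self) -> float:
        return (self.stop_nm - self.start_nm) / (self.n_points - 1)


def make_wavelength_grid(
    start_nm: float = 435.0, stop_nm: float = 840.0, n_points: int = 900
) -> WavelengthGrid:
    """Build the emission grid; defaults give 900 points over 435-840 nm."""
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if not stop_nm > start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must exceed start_nm ({start_nm})")
    values = np.linspace(start_nm, stop_nm, n_points)
    values.setflags(write=False)
    return WavelengthGrid(values=values)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Unit-area emission basis spectrum on a fixed grid."""

    kind: str
    grid: WavelengthGrid
    intensity: np.ndarray

    @property
    def peak_nm(self) -> float:
        return float(self.grid.values[int(np.argmax(self.intensity))])


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _lognormal_band(
    x: np.ndarray, center: float, fwhm: float, asymmetry: float
) -> np.ndarray:
    """Skewed (red-tailed) band with mode at ``center`` and the given FWHM.

    Standard log-normal peak-shape parameterisation used for broad
    autofluorescence humps; ``asymmetry`` > 1 stretches the red flank.
    """
    rho = asymmetry
    a = (rho**2 - 1.0) / (rho * fwhm)
    arg = a * (x - center) + 1.0
    out = np.zeros_like(x)
    ok = arg > 0
    out[ok] = np.exp(-math.log(2.0) / math.log(rho) ** 2 * np.log(arg[ok]) ** 2)
    return out


_DEFAULT_SHAPES = {
    # main peak center/FWHM plus a weaker red-side vibronic band
    PPIX634: dict(center_nm=634.0, fwhm_nm=20.0, secondary_center_nm=705.0,
                  secondary_fwhm_nm=45.0, secondary_rel_amp=0.2),
    PPIX620: dict(center_nm=620.0, fwhm_nm=20.0, secondary_center_nm=682.0,
                  secondary_fwhm_nm=45.0, secondary_rel_amp=0.2),
    # broad skewed endogenous-fluorophore hump (NADH/FAD/lipofuscin)
    AUTOFLUORESCENCE: dict(center_nm=520.0, fwhm_nm=120.0, asymmetry=1.8),
}


def make_reference_spectrum(
    kind: str, grid: WavelengthGrid | None = None, **shape_params
) -> ReferenceSpectrum:
    """Build a nonnegative unit-area basis spectrum of the given kind.

    Parameters
    ----------
    kind:
        One of ``"ppix634"``, ``"ppix620"``, ``"autofluorescence"``.
    grid:
        Emission grid; defaults to the standard 435-840 nm / 900-point grid.
    **shape_params:
        Overrides for the default peak parameters (``center_nm``,
        ``fwhm_nm``; for PpIX kinds also ``secondary_center_nm``,
        ``secondary_fwhm_nm``, ``secondary_rel_amp``; for autofluorescence
        ``asymmetry``).
    """
    if kind not in REFERENCE_KINDS:
        raise ValueError(f"unknown reference kind {kind!r}; expected one of {REFERENCE_KINDS}")
    if grid is None:
        grid = make_wavelength_grid()
    params = dict(_DEFAULT_SHAPES[kind])
    unknown = set(shape_params) - set(params)
    if unknown:
        raise ValueError(f"unknown shape parameters for {kind}: {sorted(unknown)}")
    params.update(shape_params)
    for name, value in params.items():
        if name != "center_nm" and value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")

    x = grid.values
    if kind == AUTOFLUORESCENCE:
        intensity = _lognormal_band(x, params["center_nm"], params["fwhm_nm"],
                                    params["asymmetry"])
    else:
        intensity = _gaussian(x, params["center_nm"], params["fwhm_nm"])
        intensity = intensity + params["secondary_rel_amp"] * _gaussian(
            x, params["secondary_center_nm"], params["secondary_fwhm_nm"]
        )
    area = np.trapezoid(intensity, x)
    if area <= 0:
        raise ValueError(f"reference spectrum {kind} has nonpositive area on this grid")
    intensity = intensity / area
    intensity.setflags(write=False)
    return ReferenceSpectrum(kind=kind, grid=grid, intensity=intensity)


def default_references(grid: WavelengthGrid | None = None) -> dict[str, ReferenceSpectrum]:
    """The three default basis spectra keyed by kind."""
    if grid is None:
        grid = make_wavelength_grid()
    return {kind: make_reference_spectrum(kind, grid) for kind in REFERENCE_KINDS}


@dataclass(frozen=True)
class ExcitationChannel:
    """One excitation LED and its acquisition sub-protocol.

    ``irradiance`` is a relative gain (output irradiance x effective PpIX
    absorption lumped into one scalar); defaults are proportional to the
    80/30/50 W/m LED outputs.
    """

    center_nm: int
    fwhm_nm: float = 7.0
    irradiance: float = 1.0
    n_frames: int = 6
    frame_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError(f"n_frames must be positive, got {self.n_frames}")
        if self.frame_ms <= 0:
            raise ValueError(f"frame_ms must be positive, got {self.frame_ms}")


def default_channels() -> tuple[ExcitationChannel, ...]:
    """The 385/405/420 nm protocol: 6/12/6 frames, gains proportional to 80/30/50."""
    return (
        ExcitationChannel(center_nm=385, irradiance=1.0, n_frames=6),
        ExcitationChannel(center_nm=405, irradiance=0.375, n_frames=12),
        ExcitationChannel(center_nm=420, irradiance=0.625, n_frames=6),
    )


def acquisition_time(channels: tuple[ExcitationChannel, ...] | list[ExcitationChannel]) -> float:
    """Total protocol duration in seconds (each frame = on + equal off time)."""
    return sum(ch.n_frames * 2.0 * ch.frame_ms / 1000.0 for ch in channels)


@dataclass(frozen=True)
class TissueClassParams:
    """Per-class generative parameters of the forward model (arbitrary units)."""

    class_label: str
    ppix_amount: float
    f620: float
    af_amount: float
    dispersion: float = 0.05
    noise_sd: float = 0.005
    ambient_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.f620 <= 1.0:
            raise ValueError(f"f620 must lie in [0, 1], got {self.f620}")
        for name in ("ppix_amount", "af_amount", "dispersion", "noise_sd", "ambient_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def default_class_params() -> dict[str, TissueClassParams]:
    """Default four-class table.

    PpIX amount decreases core -> margins -> healthy; the 620 nm blue-shifted
    fraction is larger in margins than in core; healthy tissue is
    autofluorescence-dominated.  Mean total signal (PpIX + autofluorescence)
    is the same for every class: absolute brightness mostly reflects probe
    coupling and is discarded by the energy normalization anyway, and equal
    class energies keep the normalized detector noise comparable across
    classes.
    """
    return {
        "core": TissueClassParams("core", ppix_amount=9.0, f620=0.15, af_amount=1.5),
        "hd_margin": TissueClassParams("hd_margin", ppix_amount=5.5, f620=0.45, af_amount=5.0),
        "ld_margin": TissueClassParams("ld_margin", ppix_amount=3.5, f620=0.60, af_amount=7.0),
        "healthy": TissueClassParams("healthy", ppix_amount=0.5, f620=0.50, af_amount=10.0),
    }


@dataclass
class SampleAcquisition:
    """Raw on/off frames for one tissue sample across all excitation channels.

    ``frames`` maps channel center wavelength -> (on, off) arrays of shape
    (n_frames, n_points).
    """

    sample_id: str
    patient_id: str
    true_class: str
    grid: WavelengthGrid
    channels: tuple[ExcitationChannel, ...]
    frames: dict[int, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for ch in self.channels:
            on, off = self.frames[ch.center_nm]
            if on.shape != (ch.n_frames, self.grid.n_points) or off.shape != on.shape:
                raise ValueError(
                    f"frame block for channel {ch.center_nm} has shape {on.shape}, "
                    f"expected ({ch.n_frames}, {self.grid.n_points})"
                )


@dataclass(frozen=True)
class DatasetSpec:
    """Size and composition of a synthetic cohort."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: {"core": 10, "hd_margin": 24, "ld_margin": 9, "healthy": 7}
    )
    n_patients: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for label, count in self.class_counts.items():
            if label not in CLASS_ORDER:
                raise ValueError(f"unknown class label {label!r}")
            if count < 0:
                raise ValueError(f"count for {label} must be >= 0, got {count}")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())


def _lognormal_factor(rng: np.random.Generator, dispersion: float) -> float:
    if dispersion == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, dispersion)))


def simulate_sample(
    class_params: TissueClassParams,
    channels: tuple[ExcitationChannel, ...],
    refs: dict[str, ReferenceSpectrum],
    grid: WavelengthGrid,
    rng: np.random.Generator,
    sample_id: str = "s0",
    patient_id: str = "p0",
) -> SampleAcquisition:
    """Simulate one acquisition.

    Off-frames contain the ambient operating-room light plus detector noise;
    on-frames add the excitation-gain-scaled fluorescence: a PpIX term mixing
    the 634 nm and blue-shifted 620 nm states according to the per-sample
    f620 draw, plus tissue autofluorescence.  Per-sample amounts are the
    class means perturbed multiplicatively (log-normal, sigma=dispersion);
    per-frame noise is additive Gaussian; intensities clip at zero.
    """
    missing = [k for k in REFERENCE_KINDS if k not in refs]
    if missing:
        raise ConfigurationError(f"missing reference spectra: {missing}")
    for kind in REFERENCE_KINDS:
        if refs[kind].grid.n_points != grid.n_points or not np.allclose(
            refs[kind].grid.values, grid.values
        ):
            raise ConfigurationError(f"reference {kind} is not on the sample grid")

    p = class_params
    ppix = p.ppix_amount * _lognormal_factor(rng, p.dispersion)
    af = p.af_amount * _lognormal_factor(rng, p.dispersion)
    f620 = float(np.clip(p.f620 * _lognormal_factor(rng, p.dispersion), 0.0, 1.0))
    ambient = p.ambient_level * _lognormal_factor(rng, p.dispersion)

    ppix_mix = (1.0 - f620) * refs[PPIX634].intensity + f620 * refs[PPIX620].intensity
    fluo = ppix * ppix_mix + af * refs[AUTOFLUORESCENCE].intensity
    flat = np.ones(grid.n_points)

    frames: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ch in channels:
        signal = ambient * flat + ch.irradiance * fluo
        background = ambient * flat
        shape = (ch.n_frames, grid.n_points)
        on = signal[None, :] + (rng.normal(0.0, p.noise_sd, shape) if p.noise_sd else 0.0)
        off = background[None, :] + (rng.normal(0.0, p.noise_sd, shape) if p.noise_sd else 0.0)
        frames[ch.center_nm] = (
            np.clip(np.broadcast_to(on, shape).copy(), 0.0, None),
            np.clip(np.broadcast_to(off, shape).copy(), 0.0, None),
        )
    return SampleAcquisition(
        sample_id=sample_id,
        patient_id=patient_id,
        true_class=p.class_label,
        grid=grid,
        channels=tuple(channels),
        frames=frames,
    )


def simulate_dataset(
    spec: DatasetSpec | None = None,
    class_param_table: dict[str, TissueClassParams] | None = None,
    channels: tuple[ExcitationChannel, ...] | None = None,
    grid: WavelengthGrid | None = None,
    refs: dict[str, ReferenceSpectrum] | None = None,
) -> list[SampleAcquisition]:
    """Simulate a full cohort; deterministic for a fixed ``spec.seed``.

    Samples are emitted class by class in canonical class order and assigned
    to patients round-robin.
    """
    if spec is None:
        spec = DatasetSpec()
    if class_param_table is None:
        class_param_table = default_class_params()
    if channels is None:
        channels = default_channels()
    if grid is None:
        grid = make_wavelength_grid()
    if refs is None:
        refs = default_references(grid)

    rng = np.random.default_rng(spec.seed)
    samples: list[SampleAcquisition] = []
    index = 0
    for label in CLASS_ORDER:
        count = spec.class_counts.get(label, 0)
        if count and label not in class_param_table:
            raise ConfigurationError(f"no class parameters for {label!r}")
        for _ in range(count):
            samples.append(
                simulate_sample(
                    class_param_table[label],
                    channels,
                    refs,
                    grid,
                    rng,
                    sample_id=f"s{index:04d}",
                    patient_id=f"p{index % spec.n_patients:02d}",
                )
            )
            index += 1
    return samples


def simulate_component_mixtures(
    n_samples: int = 50,
    grid: WavelengthGrid | None = None,
    peak_centers_nm: tuple[float, ...] = (560.0, 590.0, 620.0, 650.0, 700.0),
    fwhm_nm: float = 25.0,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectra that are nonnegative mixtures of a few fixed basis peaks.

    Each sample mixes the unit-area Gaussian bases with independent
    coefficients drawn uniformly on [0.5, 1.5] (comparable variance per
    component), plus additive Gaussian noise at ``noise_frac`` of the mean
    signal scale.  Returns ``(X, bases)`` with X of shape
    (n_samples, n_points) and bases (n_bases, n_points).
    """
    if grid is None:
        grid = make_wavelength_grid()
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    x = grid.values
    bases = np.stack([_gaussian(x, c, fwhm_nm) for c in peak_centers_nm])
    bases /= np.trapezoid(bases, x, axis=1)[:, None]
    coeffs = rng.uniform(0.5, 1.5, size=(n_samples, bases.shape[0]))
    X = coeffs @ bases
    scale = float(np.mean(np.abs(X)))
    if noise_frac:
        X = X + rng.normal(0.0, noise_frac * scale, X.shape)
    return X, bases


def scale_acquisition(sample: SampleAcquisition, factor: float) -> SampleAcquisition:
    """Return a copy of the acquisition with every raw frame scaled by ``factor``."""
    frames = {
        ch: (on * factor, off * factor) for ch, (on, off) in sample.frames.items()
    }
    return replace(sample, frames=frames)
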