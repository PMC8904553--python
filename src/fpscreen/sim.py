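"""Fabry-Perot interferogram simulation.

A reflective fiber-optic Fabry-Perot cavity of geometrical length ``l`` filled
with a medium of refractive index ``n`` produces a two-beam interference
pattern whose phase at vacuum wavelength ``lambda`` is ``phi = 4*pi*n*l/lambda``.
Recorded against a broadband (low-coherence) source this gives the spectral
fringe pattern

    T(lambda) = 1 + cos(4*pi*n*l / lambda)

used here both as the theoretical reference signal and, multiplied by a
source envelope and degraded by finite visibility and additive noise, as the
generator of synthetic optical-spectrum-analyzer traces.  The study design
emulated by :func:`generate_study_design` is a panel of certified
refractive-index liquids spanning 1.30-1.50 in 0.01 steps, ten replicate
spectra per liquid, in a 280 um cavity probed by a source centered at
1550 nm with 35 nm spectral width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .exceptions import InvalidModelError

__all__ = [
    "CavityModel",
    "Interferogram",
    "LiquidPanel",
    "default_wavelength_grid",
    "theoretical_interferogram",
    "synthetic_interferogram",
    "generate_study_design",
    "analytic_maxima",
    "fringe_visibility",
    "NM_PER_UM",
]

#: conversion factor: cavity length is specified in um, wavelengths in nm.
NM_PER_UM = 1000.0

# Default study parameters (cavity geometry and source of the measurement setup).
DEFAULT_CAVITY_LENGTH_UM = 280.0
DEFAULT_CENTER_WAVELENGTH_NM = 1550.0
DEFAULT_SPECTRAL_WIDTH_NM = 35.0
DEFAULT_VISIBILITY = 0.9956
DEFAULT_NOISE_SD = 0.01
DEFAULT_NOISE_CORRELATION_NM = 0.5
DEFAULT_GRID_MIN_NM = 1530.0
DEFAULT_GRID_MAX_NM = 1570.0
DEFAULT_GRID_POINTS = 2001


def default_wavelength_grid(
    lo: float = DEFAULT_GRID_MIN_NM,
    hi: float = DEFAULT_GRID_MAX_NM,
    num: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Uniform wavelength grid [nm] covering the source band (1550 +/- 20 nm)."""
    return np.linspace(lo, hi, num)


@dataclass(frozen=True)
class CavityModel:
    """Physical parameters generating one interferogram.

    Parameters
    ----------
    refractive_index
        Refractive index ``n`` of the medium filling the cavity at the
        operating wavelength (dimensionless, > 1).
    cavity_length_um
        Geometrical cavity length ``l`` in micrometers.
    center_wavelength_nm
        Center of the source envelope (nm).
    spectral_width_nm
        Full width at half maximum of the source envelope (nm).
    visibility
        Target fringe contrast ``V`` in [0, 1]; 1 is ideal two-beam
        interference.
    noise_sd
        Standard deviation of additive Gaussian amplitude noise, relative to
        the peak power of the clean signal.
    noise_correlation_nm
        Correlation length of the noise along the wavelength axis (nm).  An
        optical-spectrum-analyzer trace is acquired through a finite
        resolution bandwidth, so its noise is spectrally smooth rather than
        independent per sample; 0 requests white per-sample noise.
    wavelength_grid
        Strictly increasing sampling grid (nm); must cover the center
        wavelength.
    """

    refractive_index: float
    cavity_length_um: float = DEFAULT_CAVITY_LENGTH_UM
    center_wavelength_nm: float = DEFAULT_CENTER_WAVELENGTH_NM
    spectral_width_nm: float = DEFAULT_SPECTRAL_WIDTH_NM
    visibility: float = DEFAULT_VISIBILITY
    noise_sd: float = DEFAULT_NOISE_SD
    noise_correlation_nm: float = DEFAULT_NOISE_CORRELATION_NM
    wavelength_grid: np.ndarray = field(default_factory=default_wavelength_grid)

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_grid, dtype=float)
        object.__setattr__(self, "wavelength_grid", grid)
        if not self.refractive_index > 1.0:
            raise InvalidModelError(
                f"refractive index must exceed 1, got {self.refractive_index}"
            )
        if not self.cavity_length_um > 0:
            raise InvalidModelError(
                f"cavity length must be positive, got {self.cavity_length_um}"
            )
        if not 0.0 <= self.visibility <= 1.0:
            raise InvalidModelError(f"visibility must be in [0, 1], got {self.visibility}")
        if self.noise_sd < 0:
            raise InvalidModelError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.noise_correlation_nm < 0:
            raise InvalidModelError("noise_correlation_nm must be non-negative")
        if grid.size == 0:
            raise InvalidModelError("wavelength grid is empty")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise InvalidModelError("wavelength grid must be strictly increasing")
        if not (grid[0] <= self.center_wavelength_nm <= grid[-1]):
            raise InvalidModelError("wavelength grid span must cover the center wavelength")
        if self.spectral_width_nm <= 0:
            raise InvalidModelError("spectral width must be positive")

    @property
    def optical_path_nm(self) -> float:
        """Round-trip optical path 2*n*l in nm."""
        return 2.0 * self.refractive_index * self.cavity_length_um * NM_PER_UM

    def with_index(self, n: float) -> "CavityModel":
        return replace(self, refractive_index=n)


@dataclass
class Interferogram:
    """A sampled optical spectrum: paired wavelength [nm] / power sequences."""

    wavelength: np.ndarray
    power: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.wavelength.shape != self.power.shape:
            raise InvalidModelError("wavelength and power sequences differ in length")
        if self.wavelength.ndim != 1:
            raise InvalidModelError("spectrum arrays must be one-dimensional")
        if self.wavelength.size > 1 and not np.all(np.diff(self.wavelength) > 0):
            raise InvalidModelError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.power)):
            raise InvalidModelError("power values must be finite")

    def __len__(self) -> int:
        return int(self.wavelength.size)


@dataclass(frozen=True)
class LiquidPanel:
    """Panel of certified refractive-index liquids.

    Each liquid carries a *label* index (datasheet value at 589.3 nm, used to
    name the sample and to assign the class) and an *operating* index (value
    at the 1550 nm source wavelength, used in the physics).  Datasheet
    dispersion values are not generally available, so the default mapping is
    the identity; pass ``operating_indices`` to override per liquid.
    """

    label_indices: tuple[float, ...] = tuple(np.round(np.arange(1.30, 1.501, 0.01), 2))
    operating_indices: tuple[float, ...] | None = None
    replicates: int = 10

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidModelError("replicates must be >= 1")
        if len(self.label_indices) == 0:
            raise InvalidModelError("panel must contain at least one liquid")
        if self.operating_indices is not None and len(self.operating_indices) != len(
            self.label_indices
        ):
            raise InvalidModelError("operating_indices must match label_indices in length")

    @property
    def entries(self) -> list[tuple[float, float]]:
        """List of (label index, operating index) pairs."""
        ops = self.operating_indices or self.label_indices
        return list(zip(self.label_indices, ops))

    def __len__(self) -> int:
        return len(self.label_indices)


def theoretical_interferogram(model: CavityModel) -> Interferogram:
    """Noiseless two-beam reference signal T = 1 + cos(4*pi*n*l/lambda).

    Power values lie in [0, 2]; the result is deterministic for a fixed model.
    """
    grid = model.wavelength_grid
    if grid.size == 0 or model.cavity_length_um <= 0:
        raise InvalidModelError("invalid model for theoretical interferogram")
    phase = 2.0 * np.pi * model.optical_path_nm / grid
    power = 1.0 + np.cos(phase)
    return Interferogram(
        wavelength=grid.copy(),
        power=power,
        metadata={
            "kind": "theoretical",
            "refractive_index": model.refractive_index,
            "cavity_length_um": model.cavity_length_um,
        },
    )


def _source_envelope(grid: np.ndarray, center_nm: float, fwhm_nm: float) -> np.ndarray:
    """Gaussian source envelope with the stated FWHM, peak 1 at the center."""
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((grid - center_nm) / sigma) ** 2)


def _correlated_noise(
    rng: np.random.Generator, grid: np.ndarray, sd: float, correlation_nm: float
) -> np.ndarray:
    """Zero-mean Gaussian noise with the given sd and correlation length.

    White Gaussian samples are convolved with a Gaussian kernel of standard
    deviation ``correlation_nm`` and rescaled by the kernel's l2 norm so the
    marginal standard deviation stays ``sd``.  A correlation length of zero
    (or one shorter than the grid spacing) degenerates to white noise.
    """
    white = rng.normal(0.0, sd, size=grid.size)
    if correlation_nm <= 0 or grid.size < 2:
        return white
    dlam = float(np.median(np.diff(grid)))
    sigma_pts = correlation_nm / dlam
    if sigma_pts < 0.5:
        return white
    radius = int(np.ceil(4 * sigma_pts))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma_pts) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(white, radius, mode="reflect")
    smooth = np.convolve(padded, kernel, mode="valid")
    return smooth / np.linalg.norm(kernel)


def synthetic_interferogram(
    model: CavityModel,
    seed: int | np.random.SeedSequence,
    *,
    flat_envelope: bool = False,
) -> Interferogram:
    """Synthetic OSA-style trace emulating one measurement.

    power = envelope(lambda) * [1 + V*cos(4*pi*n*l/lambda)] + noise,

    with a Gaussian envelope centered at the source wavelength (FWHM = the
    spectral width) and zero-mean additive Gaussian noise of standard
    deviation ``noise_sd`` relative to the peak of the clean signal,
    correlated over ``noise_correlation_nm`` along the wavelength axis the
    way a finite-resolution-bandwidth trace is.  Identical (model, seed)
    pairs produce bitwise-identical spectra.
    """
    grid = model.wavelength_grid
    phase = 2.0 * np.pi * model.optical_path_nm / grid
    if flat_envelope:
        envelope = np.ones_like(grid)
    else:
        envelope = _source_envelope(grid, model.center_wavelength_nm, model.spectral_width_nm)
    clean = envelope * (1.0 + model.visibility * np.cos(phase))
    rng = np.random.default_rng(seed)
    if model.noise_sd > 0:
        noise = _correlated_noise(
            rng, grid, model.noise_sd * clean.max(), model.noise_correlation_nm
        )
    else:
        noise = 0.0
    return Interferogram(
        wavelength=grid.copy(),
        power=clean + noise,
        metadata={
            "kind": "synthetic",
            "refractive_index": model.refractive_index,
            "cavity_length_um": model.cavity_length_um,
            "visibility": model.visibility,
            "noise_sd": model.noise_sd,
        },
    )


def generate_study_design(
    panel: LiquidPanel,
    base_model: CavityModel,
    seed: int,
) -> list[Interferogram]:
    """Generate the full replicated panel (default 21 liquids x 10 = 210 spectra).

    Per-spectrum seeds are spawned deterministically from the master seed, so
    one integer reproduces the entire dataset.  Each spectrum's metadata
    records the liquid's label index (class-defining datasheet value), the
    operating index actually used in the physics, and the replicate number.
    """
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(panel) * panel.replicates)
    spectra: list[Interferogram] = []
    i = 0
    for label_n, operating_n in panel.entries:
        model = base_model.with_index(operating_n)
        for rep in range(panel.replicates):
            igram = synthetic_interferogram(model, children[i])
            igram.metadata.update(
                label_index=float(label_n),
                operating_index=float(operating_n),
                replicate=rep,
                spectrum_id=i,
            )
            spectra.append(igram)
            i += 1
    return spectra


def analytic_maxima(model: CavityModel, lo_nm: float, hi_nm: float) -> np.ndarray:
    """Closed-form fringe maxima positions lambda_m = 2*n*l/m inside [lo, hi].

    The two-beam signal peaks where the phase is an integer multiple of 2*pi,
    i.e. at wavelengths 2*n*l/m for integer fringe order m.  Returned in
    increasing wavelength order.
    """
    opl = model.optical_path_nm
    m_lo = int(np.ceil(opl / hi_nm))
    m_hi = int(np.floor(opl / lo_nm))
    orders = np.arange(m_hi, m_lo - 1, -1)  # decreasing m -> increasing lambda
    lam = opl / orders
    return lam[(lam >= lo_nm) & (lam <= hi_nm)]


def fringe_visibility(igram: Interferogram, center_nm: float, span_nm: float) -> float:
    """Counted fringe contrast (Imax - Imin)/(Imax + Imin) in a window.

    Measured over ``center_nm +/- span_nm/2``, wide enough to contain at
    least one full fringe.
    """
    lam, p = igram.wavelength, igram.power
    mask = (lam >= center_nm - span_nm / 2) & (lam <= center_nm + span_nm / 2)
    if not mask.any():
        raise InvalidModelError("visibility window contains no samples")
    w = p[mask]
    return float((w.max() - w.min()) / (w.max() + w.min()))
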