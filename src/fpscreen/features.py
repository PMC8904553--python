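"""Mapping of one interferogram to the 18-slot feature row.

Each recorded spectrum is compared against the noiseless theoretical fringe
pattern generated from the same cavity model and condensed into 17 numeric
features plus a target slot:

==== =================================================================
F1   number of local maxima after threshold filtering
F2   global maximum power
F3   threshold (fraction of the global maximum used to reject noise)
F4   amplitude normalization factor f = ssmax / global max
F5   average wavelength distance between consecutive local maxima [nm]
F6   maximum of those distances [nm]
F7   minimum of those distances [nm]
F8   median of those distances [nm]
F9   distortion D = |(1 - area_exp * f) / area_sym| (Simpson areas)
F10  axial shift of the global maximum, experimental - simulated [nm]
F11  RMSE between the rescaled experimental and the simulated signal
F12  cavity length [um]
F13  minimum wavelength of the spectrum [nm]
F14  maximum wavelength of the spectrum [nm]
F15  amplitude = max - min power
F16  wavelength of the maximum power [nm]
F17  wavelength of the maximum power of the theoretical signal [nm]
F18  target (1 = cancer analog, 0 = healthy analog); unset here
==== =================================================================

The distortion formula is applied literally in its printed asymmetric form;
see :func:`distortion`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .exceptions import DegenerateInputError, IncompatibleDomainError
from .sim import CavityModel, Interferogram, theoretical_interferogram

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_THRESHOLD",
    "FilteredSpectrum",
    "filter_by_threshold",
    "find_local_maxima",
    "maxima_distance_stats",
    "amplitude_factor",
    "distortion",
    "axial_shift",
    "rmse",
    "extract_features",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 19))

#: default noise-rejection threshold: 5% of the global maximum.
DEFAULT_THRESHOLD = 0.05


@dataclass
class FilteredSpectrum:
    """A spectrum with low-power samples flagged out of the maxima analysis.

    Power values are retained in full; ``retained`` marks the samples whose
    power reaches ``threshold x global maximum``.
    """

    spectrum: Interferogram
    retained: np.ndarray  # boolean mask, same length as the spectrum
    threshold: float
    global_max: float


def filter_by_threshold(spectrum: Interferogram, threshold: float) -> FilteredSpectrum:
    """Flag samples below ``threshold x global maximum`` out of maxima analysis.

    The noisy low-power part of the trace (fringe troughs, envelope tails) is
    excluded from peak detection; the power values themselves are untouched
    and the global maximum is unchanged.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if len(spectrum) == 0:
        raise DegenerateInputError("empty spectrum")
    gmax = float(spectrum.power.max())
    if gmax <= 0 and np.all(spectrum.power == 0):
        raise DegenerateInputError("all-zero spectrum")
    if threshold == 0.0:
        retained = np.ones(len(spectrum), dtype=bool)
    else:
        retained = spectrum.power >= threshold * gmax
    return FilteredSpectrum(
        spectrum=spectrum, retained=retained, threshold=threshold, global_max=gmax
    )


def find_local_maxima(filtered: FilteredSpectrum | Interferogram) -> list[tuple[float, float]]:
    """Local maxima of the retained samples, sorted by wavelength.

    A retained sample is a local maximum when it is strictly greater than
    both neighboring retained samples; plateaus are reported once, at their
    leftmost point.  Fewer than three retained samples yield no maxima.
    """
    if isinstance(filtered, Interferogram):
        filtered = filter_by_threshold(filtered, 0.0)
    lam = filtered.spectrum.wavelength[filtered.retained]
    p = filtered.spectrum.power[filtered.retained]
    n = p.size
    if n < 3:
        return []
    out: list[tuple[float, float]] = []
    i = 1
    while i < n - 1:
        if p[i] > p[i - 1]:
            # scan a potential plateau starting at i
            j = i
            while j < n - 1 and p[j + 1] == p[j]:
                j += 1
            if j < n - 1 and p[j + 1] < p[j]:
                out.append((float(lam[i]), float(p[i])))  # leftmost plateau point
            i = j + 1
        else:
            i += 1
    return out


def maxima_distance_stats(maxima: list[tuple[float, float]]) -> tuple[float, float, float, float]:
    """(average, maximum, minimum, median) consecutive maxima spacing [nm].

    With fewer than two maxima there is no spacing to measure; all four
    statistics fall back to the sentinel 0 and the event is logged.
    """
    if len(maxima) < 2:
        logger.debug("fewer than two maxima; distance statistics set to 0 sentinel")
        return (0.0, 0.0, 0.0, 0.0)
    lam = np.array([w for w, _ in maxima], dtype=float)
    d = np.diff(lam)
    return (float(d.mean()), float(d.max()), float(d.min()), float(np.median(d)))


def amplitude_factor(experimental: Interferogram, simulated: Interferogram) -> float:
    """Amplitude normalization factor f = ssmax / global max.

    ``ssmax`` is the maximum of the simulated (theoretical) signal and
    ``global max`` the maximum of the experimental one; multiplying the
    experimental power by f brings the two traces to a common scale.
    """
    if len(experimental) == 0 or len(simulated) == 0:
        raise DegenerateInputError("empty spectrum")
    gmax = float(experimental.power.max())
    if gmax <= 0:
        raise DegenerateInputError("experimental global maximum is not positive")
    return float(simulated.power.max()) / gmax


def _common_grid(
    experimental: Interferogram, simulated: Interferogram
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample both signals onto a shared uniform grid over their overlap.

    Composite Simpson integration needs uniform spacing; both signals are
    linearly interpolated onto an odd-count uniform grid spanning the
    overlapping wavelength window.
    """
    lo = max(experimental.wavelength[0], simulated.wavelength[0])
    hi = min(experimental.wavelength[-1], simulated.wavelength[-1])
    if hi <= lo:
        raise IncompatibleDomainError(
            f"no overlapping wavelength window: [{experimental.wavelength[0]}, "
            f"{experimental.wavelength[-1]}] vs [{simulated.wavelength[0]}, "
            f"{simulated.wavelength[-1]}]"
        )
    npts = max(len(experimental), len(simulated))
    if npts % 2 == 0:
        npts += 1
    grid = np.linspace(lo, hi, npts)
    pe = np.interp(grid, experimental.wavelength, experimental.power)
    ps = np.interp(grid, simulated.wavelength, simulated.power)
    return grid, pe, ps


def distortion(experimental: Interferogram, simulated: Interferogram, f: float) -> float:
    """Distortion level D = |(1 - area_exp * f) / area_sym|.

    The areas under the experimental and simulated traces are computed by
    composite Simpson quadrature over their common wavelength window (nm).
    The formula is applied literally in its printed asymmetric form — the
    experimental area is rescaled by f and compared against unity, then
    normalized by the simulated area — with no symmetrization.
    """
    grid, pe, ps = _common_grid(experimental, simulated)
    area_exp = float(simpson(pe, x=grid))
    area_sym = float(simpson(ps, x=grid))
    if area_sym == 0:
        raise DegenerateInputError("simulated signal has zero area")
    return abs((1.0 - area_exp * f) / area_sym)


def axial_shift(experimental: Interferogram, simulated: Interferogram) -> float:
    """Signed wavelength shift [nm] between the two global maxima.

    F10 = lambda(global max, experimental) - lambda(global max, simulated).
    Ties for the global maximum are broken toward the lowest wavelength
    (np.argmax returns the first occurrence on the increasing grid).
    """
    if len(experimental) == 0 or len(simulated) == 0:
        raise DegenerateInputError("empty spectrum")
    le = float(experimental.wavelength[int(np.argmax(experimental.power))])
    ls = float(simulated.wavelength[int(np.argmax(simulated.power))])
    return le - ls


def rmse(experimental: Interferogram, simulated: Interferogram, f: float) -> float:
    """Root-mean-square difference between f x experimental and simulated.

    The experimental trace is rescaled by the amplitude factor before
    differencing, so the result is expressed in simulation units.  Signals
    sampled on the same grid are differenced pointwise; otherwise both are
    resampled to the shared uniform grid of the overlap window.
    """
    if np.array_equal(experimental.wavelength, simulated.wavelength):
        pe, ps = experimental.power, simulated.power
    else:
        _, pe, ps = _common_grid(experimental, simulated)
    return float(np.sqrt(np.mean((f * pe - ps) ** 2)))


def extract_features(
    experimental: Interferogram,
    model: CavityModel,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, float]:
    """Map one spectrum (plus its theoretical reference) to the feature row.

    Returns a dict with keys F1..F17 populated and F18 (the target) set to
    NaN; the row is either complete or an error is raised — no partial rows.
    The theoretical reference is generated from ``model``, so F12 is the
    model's cavity length and F17 the reference's peak wavelength.
    """
    reference = theoretical_interferogram(model)
    filtered = filter_by_threshold(experimental, threshold)
    maxima = find_local_maxima(filtered)
    f5, f6, f7, f8 = maxima_distance_stats(maxima)
    f = amplitude_factor(experimental, reference)
    row = {
        "F1": float(len(maxima)),
        "F2": filtered.global_max,
        "F3": float(threshold),
        "F4": f,
        "F5": f5,
        "F6": f6,
        "F7": f7,
        "F8": f8,
        "F9": distortion(experimental, reference, f),
        "F10": axial_shift(experimental, reference),
        "F11": rmse(experimental, reference, f),
        "F12": model.cavity_length_um,
        "F13": float(experimental.wavelength[0]),
        "F14": float(experimental.wavelength[-1]),
        "F15": float(experimental.power.max() - experimental.power.min()),
        "F16": float(experimental.wavelength[int(np.argmax(experimental.power))]),
        "F17": float(reference.wavelength[int(np.argmax(reference.power))]),
        "F18": float("nan"),
    }
    return row
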