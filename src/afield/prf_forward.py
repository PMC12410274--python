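"""Linear population receptive field (pRF) forward model.

A voxel's pRF is an isotropic 2-D Gaussian in visual-field degrees.  The
predicted BOLD response to a binary aperture movie is the per-TR overlap
of the Gaussian with the aperture, convolved with a hemodynamic response
function (HRF), scaled by an amplitude and shifted by a baseline — a model
that is exactly affine in (amplitude, baseline), which the fitter exploits.

Overlap convention: the Gaussian is evaluated with unit peak and the
pixel sum is multiplied by the pixel area, so overlap approximates the
integral of the Gaussian over the aperture in deg^2 and is independent of
pixel resolution.  Amplitude is therefore in percent-signal units per
deg^2 of Gaussian-weighted aperture; any consistent alternative convention
only rescales amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend, fftconvolve
from scipy.stats import gamma as gamma_dist

from .exceptions import InvalidParameterError
from .stimulus_design import ApertureMovie

__all__ = [
    "PRF2D",
    "HRFParams",
    "HRFKernel",
    "canonical_hrf",
    "overlap_timecourse",
    "overlap_timecourses",
    "predicted_timecourse",
    "convolve_hrf",
    "preprocess",
    "average_runs",
]


@dataclass(frozen=True)
class PRF2D:
    """Isotropic 2-D Gaussian pRF: center (x, y) and sd in degrees."""

    x: float
    y: float
    sd: float
    amplitude: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise InvalidParameterError(f"pRF sd must be positive, got {self.sd}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def polar_angle(self) -> float:
        return float(np.arctan2(self.y, self.x))


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameterization (seconds).

    The response gamma peaks at ``peak_delay_s`` and the undershoot gamma at
    ``undershoot_delay_s``; the undershoot is scaled by ``ratio``.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    ratio: float = 1.0 / 6.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0


@dataclass(frozen=True)
class HRFKernel:
    values: np.ndarray
    tr_s: float
    params: HRFParams


def canonical_hrf(
    tr_s: float, params: HRFParams | None = None, duration_s: float = 32.0
) -> HRFKernel:
    """Canonical double-gamma HRF sampled at TR resolution, sum-normalized.

    Each gamma has shape ``delay/dispersion + 1`` and scale ``dispersion``,
    so its mode sits exactly at the configured delay; the kernel vanishes
    at lag 0 and its samples sum to 1, making convolution amplitude-
    preserving for sustained inputs.
    """
    if tr_s <= 0:
        raise InvalidParameterError(f"tr_s must be positive, got {tr_s}")
    if duration_s < 32.0:
        raise InvalidParameterError("HRF kernel must cover at least 32 s")
    p = params or HRFParams()
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    peak = gamma_dist.pdf(t, a=p.peak_delay_s / p.peak_dispersion + 1.0, scale=p.peak_dispersion)
    under = gamma_dist.pdf(
        t, a=p.undershoot_delay_s / p.undershoot_dispersion + 1.0, scale=p.undershoot_dispersion
    )
    h = peak - p.ratio * under
    return HRFKernel(values=h / h.sum(), tr_s=tr_s, params=p)


def _gauss_pixels(xs, ys, sds, px, py):
    """Unit-peak Gaussian values of each pRF at each pixel, shape (n_prf, n_px)."""
    dx = px[None, :] - np.asarray(xs, dtype=float)[:, None]
    dy = py[None, :] - np.asarray(ys, dtype=float)[:, None]
    inv = 1.0 / (2.0 * np.asarray(sds, dtype=float)[:, None] ** 2)
    return np.exp(-(dx**2 + dy**2) * inv)


def overlap_timecourses(
    xs, ys, sds, movie: ApertureMovie, chunk: int = 2048
) -> np.ndarray:
    """Per-TR Gaussian-aperture overlap (deg^2) for many pRFs at once.

    Returns an array of shape (n_prf, n_trs).  Computation is restricted to
    pixels the bar ever touches and chunked over pRFs to bound memory.
    """
    if movie.frames.size == 0:
        raise InvalidParameterError("empty aperture movie")
    mask = movie.active_mask
    xx, yy = np.meshgrid(movie.x, movie.y)
    px, py = xx[mask], yy[mask]
    frames = movie.frames[:, mask].astype(float)  # (T, n_px)
    area = movie.pixel_area_deg2()
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    out = np.empty((xs.size, frames.shape[0]))
    for lo in range(0, xs.size, chunk):
        hi = min(lo + chunk, xs.size)
        g = _gauss_pixels(xs[lo:hi], ys[lo:hi], sds[lo:hi], px, py)
        out[lo:hi] = g @ frames.T * area
    return out


def overlap_timecourse(prf: PRF2D, movie: ApertureMovie) -> np.ndarray:
    """Per-TR Gaussian-aperture overlap (deg^2) for one pRF."""
    return overlap_timecourses([prf.x], [prf.y], [prf.sd], movie)[0]


def convolve_hrf(series: np.ndarray, hrf: HRFKernel) -> np.ndarray:
    """Causal convolution with the HRF, truncated to the input length.

    Accepts a 1-D series or a (n, T) stack (convolved along the last axis).
    """
    series = np.asarray(series, dtype=float)
    kernel = hrf.values if series.ndim == 1 else hrf.values[None, :]
    full = fftconvolve(series, kernel, axes=series.ndim - 1)
    return full[..., : series.shape[-1]]


def predicted_timecourse(prf: PRF2D, movie: ApertureMovie, hrf: HRFKernel) -> np.ndarray:
    """Predicted BOLD time series (percent signal) for one pRF and movie."""
    overlap = overlap_timecourse(prf, movie)
    return prf.baseline + prf.amplitude * convolve_hrf(overlap, hrf)


def preprocess(series: np.ndarray) -> np.ndarray:
    """Convert a raw series to percent signal change and remove a linear trend.

    Percent signal change is computed about the series mean; the output has
    zero mean and zero best-fit slope.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise InvalidParameterError("series must have at least 3 samples")
    mean = series.mean()
    scale = np.max(np.abs(series))
    if scale == 0 or abs(mean) < 1e-9 * scale:
        raise InvalidParameterError(
            "series mean is (near) zero; percent signal change is undefined"
        )
    psc = 100.0 * (series - mean) / mean
    return detrend(psc, type="linear")


def average_runs(runs) -> np.ndarray:
    """Average a sequence of equal-length runs sample-wise (done before fitting)."""
    runs = np.asarray(list(runs), dtype=float)
    if runs.ndim != 2:
        raise InvalidParameterError("expected a sequence of equal-length 1-D runs")
    return runs.mean(axis=0)
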