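"""Gaussian attention-field (AF) models of receptive-field attraction.

Spatial attention is modeled as a Gaussian gain field A centered on the
attended location, whose standard deviation encodes attentional precision
(focused attention = small sd, distributed attention = large sd).  The
stimulus-driven receptive field S is a second Gaussian.  Their interaction
is a pointwise multiplication; the attention-driven receptive field R is
the Gaussian description of that product.

Two variants are provided:

* **AF model** (``offset == 0``): the product of two Gaussians is itself a
  Gaussian, so center and sd of R have closed forms::

      mu3    = (mu1 * sd2**2 + mu2 * sd1**2) / (sd2**2 + sd1**2)
      sd3**2 = (sd2**2 * sd1**2) / (sd2**2 + sd1**2)

  The center mu3 is a convex combination of the AF center mu1 and the
  receptive-field center mu2: narrower attention fields (small sd1) pull
  R more strongly toward the attended location.  Amplitude information is
  discarded downstream; only positions and sizes are used.

* **AF+ model** (``offset > 0``): a constant b is added to the (scaled)
  attention field before multiplication, ``R(x) = (a*A(x) + b) * S(x)``.
  The product is no longer Gaussian, so R is estimated by fitting a
  Gaussian to the profile evaluated on a dense grid.  The offset bounds
  attentional influence: when the receptive field is far from the attended
  locus the a*A term vanishes relative to b and R approaches S, instead of
  shrinking to an infinitesimally small bump pinned between the two.

Both variants operate along the radial (eccentricity) axis: the
experimental attention fields are isotropic and centered at fixation, so
the interaction is applied on the 1-D line through fixation and the
receptive-field center, leaving polar angle unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateProfileError, InvalidParameterError

__all__ = [
    "GaussianProfile1D",
    "AFParams",
    "SizeEccRelation",
    "AFFitResult",
    "GridSpec",
    "evaluate_gaussian",
    "af_interaction_analytic",
    "af_interaction_offset",
    "predict_difference_curve",
    "fit_af_to_differences",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianProfile1D:
    """A 1-D Gaussian profile: ``amplitude * exp(-(x - center)**2 / (2 sd**2))``.

    Represents the attention field, the stimulus-driven receptive field, or
    the attention-driven receptive field along the radial axis.  Positions
    are in degrees of visual angle; ``amplitude`` is the (unit-less) peak
    gain attained at ``center``.
    """

    center: float
    sd: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise InvalidParameterError(f"center must be finite, got {self.center}")
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise InvalidParameterError(f"sd must be positive and finite, got {self.sd}")
        if not np.isfinite(self.amplitude):
            raise InvalidParameterError(f"amplitude must be finite, got {self.amplitude}")

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        return self.amplitude * np.exp(-((grid - self.center) ** 2) / (2.0 * self.sd**2))


@dataclass(frozen=True)
class AFParams:
    """Parameters of an attention field.

    ``center`` and ``sd`` are in degrees; ``gain`` (a) scales the Gaussian
    and ``offset`` (b) is the constant added to it in the AF+ variant.
    ``offset == 0`` recovers the plain AF model.
    """

    center: float = 0.0
    sd: float = 1.0
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise InvalidParameterError(f"AF sd must be positive, got {self.sd}")
        if not np.isfinite(self.gain) or self.gain < 0:
            raise InvalidParameterError(f"AF gain must be >= 0, got {self.gain}")
        if not np.isfinite(self.offset) or self.offset < 0:
            raise InvalidParameterError(f"AF offset must be >= 0, got {self.offset}")

    def profile(self) -> GaussianProfile1D:
        """The Gaussian part of the field (unit peak before gain scaling)."""
        return GaussianProfile1D(self.center, self.sd, 1.0)


@dataclass(frozen=True)
class SizeEccRelation:
    """Linear pRF size-eccentricity relation for one visual area.

    ``sd(ecc) = intercept + slope * ecc``; slopes grow up the visual
    hierarchy (V1 smallest, parietal areas largest).
    """

    slope: float
    intercept: float
    roi_label: str = ""

    def __post_init__(self) -> None:
        # size must stay positive over the mapped eccentricity range [0, 5]
        if self.intercept <= 0 or self.intercept + self.slope * 5.0 <= 0:
            raise InvalidParameterError(
                f"size-eccentricity relation for {self.roi_label!r} predicts "
                "non-positive sd on [0, 5]"
            )

    def sd_at(self, ecc):
        return self.intercept + self.slope * np.asarray(ecc, dtype=float)


@dataclass
class AFFitResult:
    """Result of fitting a shared AF pair to observed difference curves."""

    focused: AFParams
    distributed: AFParams
    loss: float
    variant: str
    success: bool = True
    message: str = ""
    n_starts: int = 1

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "loss": self.loss,
            "success": self.success,
            "message": self.message,
            "focused": vars(self.focused) | {},
            "distributed": vars(self.distributed) | {},
        }


@dataclass(frozen=True)
class GridSpec:
    """Evaluation-grid contract for the numeric (AF+) interaction.

    When ``extent``/``spacing`` are omitted they are derived from the
    profiles: the grid spans both centers with an 8*sd2 margin — the
    product ``(a*A + b)*S`` is bounded above by a multiple of S, so its
    mass beyond a few sd2 of the receptive field is negligible regardless
    of the AF width — and the spacing is ``min(sd1, sd2)/25`` (at most
    ``sd2/20``), fine enough for the Gaussian refit to agree with the
    analytic solution to 1e-3.
    """

    extent: tuple[float, float] | None = None
    spacing: float | None = None
    max_points: int = 400_001

    def build(self, af: AFParams, sdprf: GaussianProfile1D) -> np.ndarray:
        spacing = self.spacing
        if spacing is None:
            spacing = min(af.sd, sdprf.sd) / 25.0
        spacing = min(spacing, sdprf.sd / 20.0)
        if self.extent is not None:
            lo, hi = self.extent
        else:
            margin = 8.0 * sdprf.sd
            lo = min(af.center, sdprf.center) - margin
            hi = max(af.center, sdprf.center) + margin
        n = int(np.ceil((hi - lo) / spacing)) + 1
        if n > self.max_points:
            n = self.max_points
        return np.linspace(lo, hi, n)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def evaluate_gaussian(profile: GaussianProfile1D, grid) -> np.ndarray:
    """Evaluate a Gaussian profile on an ordered grid of positions (degrees)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("grid must be nonempty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidParameterError("grid must be strictly increasing")
    return profile(grid)


def af_interaction_analytic(af: AFParams, sdprf: GaussianProfile1D) -> GaussianProfile1D:
    """Closed-form attention-driven receptive field for the plain AF model.

    Valid only when the attention field has no offset; the product of two
    Gaussians is then itself Gaussian with::

        mu3    = (mu1 sd2^2 + mu2 sd1^2) / (sd2^2 + sd1^2)
        sd3^2  = sd1^2 sd2^2 / (sd1^2 + sd2^2)

    The returned amplitude is the peak of the product, ``gain * amp_S *
    exp(-(mu1-mu2)^2 / (2 (sd1^2+sd2^2)))``; downstream analyses use only
    center and sd.
    """
    if af.offset != 0:
        raise InvalidParameterError(
            "af_interaction_analytic requires offset == 0; "
            "use af_interaction_offset for the AF+ model"
        )
    v1, v2 = af.sd**2, sdprf.sd**2
    mu3 = (af.center * v2 + sdprf.center * v1) / (v1 + v2)
    sd3 = np.sqrt(v1 * v2 / (v1 + v2))
    amp = af.gain * sdprf.amplitude * np.exp(-((af.center - sdprf.center) ** 2) / (2.0 * (v1 + v2)))
    return GaussianProfile1D(float(mu3), float(sd3), float(amp))


def _fit_gaussian_rows(
    grids: np.ndarray, values: np.ndarray, n_iter: int = 50, tol: float = 1e-11
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise best-fit Gaussians by damped (Levenberg-Marquardt) least squares.

    ``grids`` and ``values`` are (m, n): each row holds one profile sampled
    on its own grid.  Fits are initialized at each profile's center of mass
    and second-moment width.  Returns arrays (center, sd, amplitude).
    """
    peak = values.max(axis=1, keepdims=True)
    w = values / peak
    mass = w.sum(axis=1)
    c = (grids * w).sum(axis=1) / mass
    var = (((grids - c[:, None]) ** 2) * w).sum(axis=1) / mass
    dx = grids[:, 1] - grids[:, 0]
    sd = np.maximum(np.sqrt(var), dx)
    a = np.ones_like(c)
    lam = np.full_like(c, 1e-3)

    def cost(c_, sd_, a_):
        r = a_[:, None] * np.exp(-((grids - c_[:, None]) ** 2) / (2.0 * sd_[:, None] ** 2)) - w
        return (r * r).sum(axis=1)

    f = cost(c, sd, a)
    done = np.zeros(c.shape, dtype=bool)
    for _ in range(n_iter):
        d = grids - c[:, None]
        g = np.exp(-(d**2) / (2.0 * sd[:, None] ** 2))
        r = a[:, None] * g - w
        j_c = a[:, None] * g * d / sd[:, None] ** 2
        j_s = a[:, None] * g * d**2 / sd[:, None] ** 3
        J = np.stack([j_c, j_s, g], axis=2)  # (m, n, 3)
        H = np.einsum("mni,mnj->mij", J, J)
        grad = np.einsum("mni,mn->mi", J, r)
        diag = np.maximum(np.diagonal(H, axis1=1, axis2=2), 1e-12)  # (m, 3)
        Hd = H + lam[:, None, None] * np.eye(3)[None, :, :] * diag[:, :, None]
        try:
            step = np.linalg.solve(Hd, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Hd[i], grad[i], rcond=None)[0] for i in range(len(c))])
        c_t = c - step[:, 0]
        sd_t = np.maximum(sd - step[:, 1], dx / 4.0)
        a_t = np.maximum(a - step[:, 2], 1e-12)
        f_t = cost(c_t, sd_t, a_t)
        better = (f_t <= f) & ~done
        c = np.where(better, c_t, c)
        sd = np.where(better, sd_t, sd)
        a = np.where(better, a_t, a)
        lam = np.where(done, lam, np.where(better, lam * 0.3, lam * 10.0))
        f = np.where(better, f_t, f)
        # a row is finished when its accepted step is a negligible move
        scale = np.stack([sd, sd, np.abs(a) + 1e-12], axis=1)
        tiny = np.all(np.abs(step) <= 1e-6 * scale, axis=1)
        done |= (better & tiny) | (lam > 1e10)
        if done.all():
            break
    return c, sd, a * peak[:, 0]


def _offset_interaction_rows(
    af: AFParams,
    mu2: np.ndarray,
    sd2: np.ndarray,
    grid_spec: GridSpec | None = None,
    max_batch_points: int = 12_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AF+ interaction for many unit-amplitude receptive fields at once.

    Builds one evaluation grid per (mu2, sd2) row following the
    :class:`GridSpec` rules, evaluates ``(gain*A + offset)*S``, and fits
    Gaussians row-wise.  ``max_batch_points`` caps the shared per-row grid
    length so extreme width ratios stay affordable.  Returns (center, sd,
    amplitude) arrays.
    """
    if af.gain == 0 and af.offset == 0:
        raise DegenerateProfileError("AF with gain 0 and offset 0 yields an all-zero profile")
    spec = grid_spec or GridSpec()
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    sd2 = np.atleast_1d(np.asarray(sd2, dtype=float))
    if mu2.size > 512:  # chunk so one fine-grid row cannot inflate the whole batch
        parts = [
            _offset_interaction_rows(af, mu2[i : i + 512], sd2[i : i + 512], grid_spec)
            for i in range(0, mu2.size, 512)
        ]
        return tuple(np.concatenate([p[k] for p in parts]) for k in range(3))
    if spec.extent is not None:
        lo = np.full_like(mu2, spec.extent[0])
        hi = np.full_like(mu2, spec.extent[1])
    else:
        margin = 8.0 * sd2
        lo = np.minimum(af.center, mu2) - margin
        hi = np.maximum(af.center, mu2) + margin
    spacing = np.minimum(
        spec.spacing if spec.spacing is not None else np.minimum(af.sd, sd2) / 25.0,
        sd2 / 20.0,
    )
    n = int(np.ceil(((hi - lo) / spacing).max())) + 1
    n = min(n, spec.max_points, max_batch_points)
    grids = lo[:, None] + (hi - lo)[:, None] * np.linspace(0.0, 1.0, n)[None, :]
    A = np.exp(-((grids - af.center) ** 2) / (2.0 * af.sd**2))
    S = np.exp(-((grids - mu2[:, None]) ** 2) / (2.0 * sd2[:, None] ** 2))
    profiles = (af.gain * A + af.offset) * S
    if not np.all(profiles.max(axis=1) > 0):
        raise DegenerateProfileError("profile underflowed to zero everywhere on the grid")
    return _fit_gaussian_rows(grids, profiles)


def af_interaction_offset(
    af: AFParams,
    sdprf: GaussianProfile1D,
    grid_spec: GridSpec | None = None,
) -> GaussianProfile1D:
    """Attention-driven receptive field for the AF+ model.

    Evaluates ``(gain * A(x) + offset) * S(x)`` on a dense grid and returns
    the best-fit Gaussian (the estimate of the profile's center of mass and
    spread), fit by nonlinear least squares initialized at the profile's
    center of mass.  With ``offset == 0`` and ``gain == 1`` this agrees
    with :func:`af_interaction_analytic` to about 1e-3 in center and sd.
    """
    c, sd, a = _offset_interaction_rows(
        af, np.array([sdprf.center]), np.array([sdprf.sd]), grid_spec
    )
    return GaussianProfile1D(float(c[0]), float(sd[0]), float(a[0]) * sdprf.amplitude)


def predict_difference_curve(
    af_focused: AFParams,
    af_distributed: AFParams,
    relation: SizeEccRelation,
    ecc_grid,
    grid_spec: GridSpec | None = None,
) -> np.ndarray:
    """Predicted eccentricity difference (distributed minus focused) per eccentricity.

    For each eccentricity e, a stimulus-driven receptive field is built with
    center e and sd from the size-eccentricity relation, each condition's AF
    is applied, and the difference of resulting centers is returned.  Both
    attention fields must be centered at fixation (0), matching the
    experimental conditions.  Positive values mean focused attention pulled
    the receptive field closer to fixation than distributed attention did.
    """
    for af in (af_focused, af_distributed):
        if af.center != 0:
            raise InvalidParameterError("difference-curve prediction assumes AFs centered at 0")
    ecc_grid = np.atleast_1d(np.asarray(ecc_grid, dtype=float))
    sd2 = np.asarray(relation.sd_at(ecc_grid), dtype=float)
    centers = []
    for af in (af_focused, af_distributed):
        if af.offset == 0:
            # closed form: gain only rescales amplitude, not position
            v1, v2 = af.sd**2, sd2**2
            centers.append(ecc_grid * v1 / (v1 + v2))
        else:
            c, _, _ = _offset_interaction_rows(af, ecc_grid, sd2, grid_spec)
            centers.append(c)
    return centers[1] - centers[0]


# --------------------------------------------------------------------------
# AF fitting
# --------------------------------------------------------------------------


def _series_to_xy(series) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Extract (ecc, mean difference, weight, measured sd) from an
    EccBinSeries or a plain ``(ecc, values)`` tuple.

    Bin means pool very different voxel counts and scatter, so each bin is
    weighted by the inverse of the standard error of its across-participant
    mean (clipped below at a fifth of the median standard error, so a bin
    that happens to scatter near zero cannot dominate).  Tuples — and
    series with too few participants to estimate a standard error — get
    unit weights.  When the series carries measured mean pRF sizes per bin
    they are returned for use in place of a size-eccentricity relation.
    """
    if hasattr(series, "bin_centers") and hasattr(series, "participant_mean"):
        centers = np.asarray(series.bin_centers, dtype=float)
        y = np.asarray(series.participant_mean(), dtype=float)
        table = series.values.to_numpy()
        n_obs = np.isfinite(table).sum(axis=0)
        sem = np.full(table.shape[1], np.nan)
        multi = n_obs >= 2
        if multi.any():
            with np.errstate(invalid="ignore"):
                sem[multi] = np.nanstd(table[:, multi], axis=0, ddof=1) / np.sqrt(n_obs[multi])
        ok_sem = np.isfinite(sem) & (sem > 0)
        if ok_sem.any():
            floor = 0.2 * np.median(sem[ok_sem])
            w = np.where(ok_sem, 1.0 / np.maximum(sem, floor), np.nan)
            w = np.where(np.isfinite(w), w, np.nanmedian(w))
        else:
            w = np.ones_like(y)
        sd2 = np.asarray(series.bin_sd, dtype=float) if series.bin_sd is not None else None
    else:
        centers, y = series
        centers = np.asarray(centers, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones_like(y)
        sd2 = None
    keep = np.isfinite(y) & np.isfinite(centers)
    if sd2 is not None and not np.all(np.isfinite(sd2[keep])):
        sd2 = None  # incomplete size information: fall back to the relation
    return centers[keep], y[keep], w[keep], (sd2[keep] if sd2 is not None else None)


def fit_af_to_differences(
    observed: Mapping[str, object],
    relations: Mapping[str, SizeEccRelation],
    variant: str = "af_plus",
    sd_bounds: tuple[float, float] = (0.05, 50.0),
    gain_bounds: tuple[float, float] = (0.0, 100.0),
    offset_bounds: tuple[float, float] = (0.0, 100.0),
    n_starts: int = 5,
    grid_spec: GridSpec | None = None,
) -> AFFitResult:
    """Fit one shared focused/distributed AF pair to eccentricity-difference curves.

    Parameters
    ----------
    observed
        Mapping from ROI label to an ``EccBinSeries`` (or a plain
        ``(ecc_centers, mean_differences)`` tuple) of distributed-minus-
        focused eccentricity differences.
    relations
        Size-eccentricity relation per ROI, used to build the
        stimulus-driven receptive fields at each eccentricity.
    variant
        ``"af"`` fits only the two AF sds (gain fixed at 1, offset at 0);
        ``"af_plus"`` additionally fits a shared gain and offset.

    A single AF pair (and, for AF+, a single gain/offset) is shared across
    all ROIs within each condition; the fit minimizes the summed squared
    error across every ROI's curve.  The optimizer restarts from
    ``n_starts`` log-spaced focused-sd initializations to avoid local
    minima; if no start converges the result is flagged rather than raised.
    """
    if variant not in ("af", "af_plus"):
        raise InvalidParameterError(f"unknown variant {variant!r}")
    rois = [r for r in observed if r in relations]
    missing = set(observed) - set(rois)
    if missing:
        raise InvalidParameterError(f"no size-eccentricity relation for ROIs {sorted(missing)}")
    data = {r: _series_to_xy(observed[r]) for r in rois}
    data = {r: xyw for r, xyw in data.items() if xyw[0].size > 0}
    if not data:
        raise InvalidParameterError("no finite difference values to fit")
    mean_w = np.concatenate([w for _, _, w, _ in data.values()]).mean()
    if mean_w > 0:  # normalize so the loss scale is comparable across weightings
        data = {r: (e, y, w / mean_w, s) for r, (e, y, w, s) in data.items()}

    def unpack(params) -> tuple[AFParams, AFParams]:
        if variant == "af":
            sd_f, sd_d = params
            gain, off = 1.0, 0.0
        else:
            sd_f, sd_d, gain, off = params
        return (
            AFParams(0.0, float(sd_f), float(gain), float(off)),
            AFParams(0.0, float(sd_d), float(gain), float(off)),
        )

    # measured mean pRF size per bin when available, else the ROI relation
    sd2_of = {
        r: (s if s is not None else np.asarray(relations[r].sd_at(e), dtype=float))
        for r, (e, _, _, s) in data.items()
    }

    # memoize per-condition centers: finite-difference jacobian columns
    # perturb one parameter at a time, leaving the other condition unchanged
    memo: dict[tuple, np.ndarray] = {}

    def centers_for(af: AFParams, roi: str, ecc: np.ndarray) -> np.ndarray:
        key = (af.sd, af.gain, af.offset, roi)
        if key not in memo:
            sd2 = sd2_of[roi]
            if af.offset == 0:
                v1 = af.sd**2
                memo[key] = ecc * v1 / (v1 + sd2**2)
            else:
                memo[key] = _offset_interaction_rows(af, ecc, sd2, grid_spec)[0]
        return memo[key]

    def residual(params):
        af_f, af_d = unpack(params)
        parts = []
        for r, (ecc, y, w, _) in data.items():
            pred = centers_for(af_d, r, ecc) - centers_for(af_f, r, ecc)
            parts.append(w * (pred - y))
        return np.concatenate(parts)

    lo_sd, hi_sd = sd_bounds
    if variant == "af":
        lb, ub = [lo_sd, lo_sd], [hi_sd, hi_sd]
    else:
        lb = [lo_sd, lo_sd, gain_bounds[0], offset_bounds[0]]
        ub = [hi_sd, hi_sd, gain_bounds[1], offset_bounds[1]]

    best = None
    any_success = False
    messages = []
    for sd_f0 in np.geomspace(0.25, 8.0, n_starts):
        sd_d0 = np.clip(4.0 * sd_f0, lo_sd, hi_sd)
        x0 = [np.clip(sd_f0, lo_sd, hi_sd), sd_d0]
        if variant == "af_plus":
            x0 += [1.0, 0.1]
        sol = least_squares(residual, x0=x0, bounds=(lb, ub), x_scale="jac", xtol=1e-6, ftol=1e-9)
        any_success = any_success or sol.success
        messages.append(sol.message)
        loss = float(np.sum(sol.fun**2))
        if best is None or loss < best[0]:
            best = (loss, sol.x)
    loss, x = best
    af_f, af_d = unpack(x)
    return AFFitResult(
        focused=af_f,
        distributed=af_d,
        loss=loss,
        variant=variant,
        success=any_success,
        message="converged" if any_success else "; ".join(set(messages)),
        n_starts=n_starts,
    )
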