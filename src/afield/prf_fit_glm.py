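"""pRF fitting (grid + iterative refinement) and the nested task GLM.

Fitting inverts the linear forward model on the truncated task segment of
a run: an exhaustive grid over (x, y, sd) with amplitude and baseline
solved linearly at each node, followed by bounded nonlinear refinement
from the best node.  Estimates are filtered on variance explained
(R^2 >= 0.1) and eccentricity (< 5 deg) before any group analysis.

The task GLM runs on the full, untruncated series with ordinary least
squares over five regressors: an intercept, the pRF-predicted time
course, the HRF-convolved task boxcar, and HRF-convolved impulses at task
onset and offset.  The boxcar beta is the "task response" — the
attention-task-induced baseline shift of the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .exceptions import CollinearDesignError, InvalidParameterError
from .prf_forward import HRFKernel
from .stimulus_design import ApertureMovie, RunDesign
from .synthetic_data import task_regressors

__all__ = [
    "PRFEstimate",
    "TaskGLMResult",
    "GridConfig",
    "truncate_to_task",
    "precompute_grid",
    "fit_prf",
    "fit_prf_batch",
    "filter_estimates",
    "fit_task_glm",
    "estimates_frame",
]


@dataclass
class PRFEstimate:
    voxel_id: int
    x: float
    y: float
    sd: float
    amplitude: float
    baseline: float
    r_squared: float
    condition: str = ""

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))


@dataclass
class TaskGLMResult:
    voxel_id: int
    beta_prf: float
    beta_task: float
    beta_onset: float
    beta_offset: float
    intercept: float
    residual_variance: float
    condition: str = ""


@dataclass(frozen=True)
class GridConfig:
    """Search grid for the exhaustive stage and bounds for refinement.

    Positions step ``xy_step`` over ``xy_range``; sizes are log-spaced.
    Refinement is bounded to one grid step around the best node in
    position and to ``refine_sd_bounds`` in size.
    """

    xy_range: tuple[float, float] = (-5.5, 5.5)
    xy_step: float = 0.25
    sd_range: tuple[float, float] = (0.1, 6.0)
    n_sd: int = 20

    def nodes(self) -> np.ndarray:
        lo, hi = self.xy_range
        xs = np.arange(lo, hi + self.xy_step / 2, self.xy_step)
        sds = np.geomspace(*self.sd_range, self.n_sd)
        xx, yy, ss = np.meshgrid(xs, xs, sds, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), ss.ravel()])


#: number of TRs trimmed from each end of the task block to drop onset/offset transients
DEFAULT_TRIM_TRS = 4
REFINE_SD_BOUNDS = (0.05, 10.0)


def truncate_to_task(series: np.ndarray, design: RunDesign, trim_trs: int = DEFAULT_TRIM_TRS):
    """Extract the task-block samples, dropping ``trim_trs`` at each end."""
    series = np.asarray(series)
    if series.shape[-1] < design.n_trs:
        raise InvalidParameterError(
            f"series has {series.shape[-1]} samples but the design spans {design.n_trs} TRs"
        )
    if 2 * trim_trs >= design.task_trs:
        raise InvalidParameterError(
            f"trim of {trim_trs} TRs per side exceeds the {design.task_trs}-TR task block"
        )
    return series[..., design.task_start + trim_trs : design.task_end - trim_trs]


class _ForwardEngine:
    """Cached pixel/frame matrices for repeated forward evaluations on one movie."""

    def __init__(self, movie: ApertureMovie, hrf: HRFKernel, design: RunDesign | None, trim_trs: int):
        mask = movie.active_mask
        xx, yy = np.meshgrid(movie.x, movie.y)
        self.px, self.py = xx[mask], yy[mask]
        frames = movie.frames[:, mask]
        self.n_trs = frames.shape[0]
        # only sweep TRs carry aperture; skip the all-zero rows in matmuls
        self.nz_rows = np.flatnonzero(frames.any(axis=1))
        self.frames_nz = frames[self.nz_rows].astype(float)
        self.area = movie.pixel_area_deg2()
        self.kernel = hrf.values
        self.design = design
        self.trim = trim_trs

    def _convolve_truncate(self, overlap_nz: np.ndarray) -> np.ndarray:
        overlap = np.zeros(overlap_nz.shape[:-1] + (self.n_trs,))
        overlap[..., self.nz_rows] = overlap_nz
        kernel = self.kernel if overlap.ndim == 1 else self.kernel[None, :]
        conv = fftconvolve(overlap, kernel, axes=overlap.ndim - 1)[..., : self.n_trs]
        if self.design is not None:
            conv = truncate_to_task(conv, self.design, self.trim)
        return conv

    def predict(self, x: float, y: float, sd: float) -> np.ndarray:
        """Unit-amplitude overlap-convolved prediction on the fitted segment."""
        g = np.exp(-((self.px - x) ** 2 + (self.py - y) ** 2) / (2.0 * sd**2))
        return self._convolve_truncate(self.frames_nz @ g * self.area)

    def predict_many(self, nodes: np.ndarray, chunk: int = 1024) -> np.ndarray:
        out = None
        for lo in range(0, nodes.shape[0], chunk):
            part = nodes[lo : lo + chunk]
            dx = self.px[None, :] - part[:, 0:1]
            dy = self.py[None, :] - part[:, 1:2]
            g = np.exp(-(dx**2 + dy**2) / (2.0 * part[:, 2:3] ** 2))
            conv = self._convolve_truncate(g @ self.frames_nz.T * self.area)
            if out is None:
                out = np.empty((nodes.shape[0], conv.shape[1]))
            out[lo : lo + part.shape[0]] = conv
        return out


@dataclass
class GridPredictions:
    """Precomputed grid-stage predictions shared across voxels and conditions."""

    nodes: np.ndarray  # (n, 3): x, y, sd
    pred_norm: np.ndarray  # demeaned, L2-normalized predictions, (n, T)
    engine: _ForwardEngine
    config: GridConfig


def precompute_grid(
    movie: ApertureMovie,
    hrf: HRFKernel,
    design: RunDesign | None = None,
    trim_trs: int = DEFAULT_TRIM_TRS,
    grid_config: GridConfig | None = None,
) -> GridPredictions:
    """Build the grid-stage prediction bank for a movie (reusable across voxels)."""
    config = grid_config or GridConfig()
    engine = _ForwardEngine(movie, hrf, design, trim_trs)
    nodes = config.nodes()
    preds = engine.predict_many(nodes)
    preds -= preds.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(preds, axis=1)
    ok = norms > 1e-12
    preds[ok] /= norms[ok, None]
    preds[~ok] = 0.0
    return GridPredictions(nodes=nodes, pred_norm=preds, engine=engine, config=config)


def _linear_solve(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best (baseline, amplitude >= 0) for y ~ baseline + amplitude * pred."""
    var = np.var(pred)
    if var <= 0:
        return float(y.mean()), 0.0
    amp = float(np.cov(pred, y, bias=True)[0, 1] / var)
    if amp < 0:
        return float(y.mean()), 0.0
    return float(y.mean() - amp * pred.mean()), amp


def _refine(
    engine: _ForwardEngine,
    y: np.ndarray,
    start: np.ndarray,
    xy_step: float,
    sd_bounds: tuple[float, float],
) -> tuple[np.ndarray, float, float, float]:
    lb = [start[0] - xy_step, start[1] - xy_step, sd_bounds[0]]
    ub = [start[0] + xy_step, start[1] + xy_step, sd_bounds[1]]
    x0 = np.clip(start, lb, ub)

    def residual(p):
        pred = engine.predict(*p)
        base, amp = _linear_solve(pred, y)
        return y - (base + amp * pred)

    sol = least_squares(
        residual, x0=x0, bounds=(lb, ub), x_scale=[0.1, 0.1, 0.1], xtol=1e-9, ftol=1e-9
    )
    pred = engine.predict(*sol.x)
    base, amp = _linear_solve(pred, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - base - amp * pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return sol.x, amp, base, r2


def _grid_best(Y: np.ndarray, grid: GridPredictions) -> tuple[np.ndarray, np.ndarray]:
    """Best grid node and its R^2 for every row of Y (one matmul for all voxels)."""
    Yc = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Yc, axis=1)
    safe = np.where(norms > 1e-12, norms, 1.0)
    corr = grid.pred_norm @ (Yc / safe[:, None]).T  # (n_nodes, n_vox)
    best = np.argmax(corr, axis=0)  # positive corr preferred: amplitudes are positive
    r2 = np.maximum(corr[best, np.arange(Y.shape[0])], 0.0) ** 2
    r2[norms <= 1e-12] = np.nan  # constant series: nothing to explain
    return best, r2


def _fit_one(
    y: np.ndarray,
    grid: GridPredictions,
    voxel_id: int,
    condition: str,
    refine: bool = True,
    grid_best: tuple[int, float] | None = None,
) -> PRFEstimate:
    y = np.asarray(y, dtype=float)
    if grid_best is None:
        best, r2 = _grid_best(y[None, :], grid)
        grid_best = (int(best[0]), float(r2[0]))
    best, grid_r2 = grid_best
    if np.isnan(grid_r2):
        return PRFEstimate(voxel_id, 0.0, 0.0, 1.0, 0.0, float(y.mean()), 0.0, condition)
    node = grid.nodes[best]
    pred = grid.engine.predict(*node)
    base, amp = _linear_solve(pred, y)
    result = (node, amp, base, grid_r2)
    if refine:
        refined = _refine(grid.engine, y, node, grid.config.xy_step, REFINE_SD_BOUNDS)
        if refined[3] >= grid_r2:  # refinement may never worsen the fit
            result = refined
    (x, yy, sd), amp, base, r2 = result
    return PRFEstimate(voxel_id, float(x), float(yy), float(sd), amp, base, r2, condition)


def fit_prf(
    series: np.ndarray,
    movie: ApertureMovie,
    hrf: HRFKernel,
    design: RunDesign | None = None,
    trim_trs: int = DEFAULT_TRIM_TRS,
    grid_config: GridConfig | None = None,
    grid: GridPredictions | None = None,
    voxel_id: int = 0,
    condition: str = "",
    refine: bool = True,
) -> PRFEstimate:
    """Fit one voxel's pRF to its (full-run or pre-truncated) time series.

    If ``design`` is given, both the series and the internal predictions
    are truncated to the task block minus ``trim_trs`` per side; otherwise
    the series is taken as already aligned with the movie frames.
    """
    series = np.asarray(series, dtype=float)
    if grid is None:
        grid = precompute_grid(movie, hrf, design, trim_trs, grid_config)
    if design is not None:
        series = truncate_to_task(series, design, trim_trs)
    return _fit_one(series, grid, voxel_id, condition, refine)


def fit_prf_batch(
    series: np.ndarray,
    movie: ApertureMovie,
    hrf: HRFKernel,
    design: RunDesign | None = None,
    trim_trs: int = DEFAULT_TRIM_TRS,
    grid_config: GridConfig | None = None,
    grid: GridPredictions | None = None,
    voxel_ids: Sequence[int] | None = None,
    condition: str = "",
    refine: bool = True,
) -> pd.DataFrame:
    """Fit every row of ``series`` (n_voxels, n_trs); returns a tidy table."""
    series = np.asarray(series, dtype=float)
    if grid is None:
        grid = precompute_grid(movie, hrf, design, trim_trs, grid_config)
    if design is not None:
        series = truncate_to_task(series, design, trim_trs)
    ids = list(voxel_ids) if voxel_ids is not None else list(range(series.shape[0]))
    best, r2 = _grid_best(series, grid)
    estimates = [
        _fit_one(
            series[i], grid, ids[i], condition, refine,
            grid_best=(int(best[i]), float(r2[i])),
        )
        for i in range(series.shape[0])
    ]
    return estimates_frame(estimates)


def estimates_frame(estimates: Sequence[PRFEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "voxel_id": [e.voxel_id for e in estimates],
            "x": [e.x for e in estimates],
            "y": [e.y for e in estimates],
            "sd": [e.sd for e in estimates],
            "amplitude": [e.amplitude for e in estimates],
            "baseline": [e.baseline for e in estimates],
            "r_squared": [e.r_squared for e in estimates],
            "eccentricity": [e.eccentricity for e in estimates],
            "condition": [e.condition for e in estimates],
        }
    )


def filter_estimates(estimates, r2_min: float = 0.1, ecc_max: float = 5.0):
    """Keep estimates with R^2 >= ``r2_min`` and eccentricity < ``ecc_max``.

    The variance-explained bound is inclusive, the eccentricity bound
    strict.  Accepts a DataFrame (as from :func:`fit_prf_batch`) or a
    sequence of :class:`PRFEstimate`.
    """
    if isinstance(estimates, pd.DataFrame):
        keep = (estimates["r_squared"] >= r2_min) & (estimates["eccentricity"] < ecc_max)
        return estimates.loc[keep].reset_index(drop=True)
    return [e for e in estimates if e.r_squared >= r2_min and e.eccentricity < ecc_max]


def fit_task_glm(
    full_series: np.ndarray,
    prf_prediction: np.ndarray,
    design: RunDesign,
    hrf: HRFKernel,
    voxel_id: int = 0,
    condition: str = "",
) -> TaskGLMResult:
    """Estimate the task-response beta on the full (untruncated) series.

    Ordinary least squares over [intercept, pRF prediction, task boxcar,
    task-onset impulse, task-offset impulse], the last three convolved
    with the HRF.  The boxcar beta is the task response.
    """
    y = np.asarray(full_series, dtype=float)
    if y.size != design.n_trs:
        raise InvalidParameterError(
            f"series has {y.size} samples but the design spans {design.n_trs} TRs"
        )
    regs = task_regressors(design, hrf)
    names = ["intercept", "prf", "task", "onset", "offset"]
    X = np.column_stack(
        [np.ones(y.size), np.asarray(prf_prediction, dtype=float), regs["task"], regs["onset"], regs["offset"]]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise CollinearDesignError(f"design matrix is rank deficient; collinear columns: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(y.size - X.shape[1], 1)
    return TaskGLMResult(
        voxel_id=voxel_id,
        beta_prf=float(beta[1]),
        beta_task=float(beta[2]),
        beta_onset=float(beta[3]),
        beta_offset=float(beta[4]),
        intercept=float(beta[0]),
        residual_variance=float(resid @ resid / dof),
        condition=condition,
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns involved in a rank deficiency (near-unit pairwise correlation)."""
    flagged = set()
    for i in range(X.shape[1]):
        if np.allclose(X[:, i], X[:, i].mean()):
            if i != 0:
                flagged.update({names[0], names[i]})
            continue
        for j in range(i + 1, X.shape[1]):
            if np.allclose(X[:, j], X[:, j].mean()):
                continue
            c = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(c) > 1 - 1e-10:
                flagged.update({names[i], names[j]})
    return sorted(flagged) or list(names)
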