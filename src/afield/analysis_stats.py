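"""Group-level statistics for attention-modulated pRF experiments.

Covers the analysis battery applied to the simulated experiments:
signal-detection sensitivity (d') with a permutation null, eccentricity
binning on an independent mapping condition, distributed-minus-focused
condition differences, exponential fits with bootstrapped confidence
bands, and Wilcoxon signed-rank tests with Benjamini-Hochberg FDR
correction across visual areas.

Binning convention: voxels are assigned to half-open bins [lo, hi) by
their *independent-condition* eccentricity — never by either attention
condition's own estimate — which prevents circular selection and
regression to the mean.  Default bins are a foveal bin [0, 0.3) deg
(the focused-task extent) plus eight log-spaced bins over [0.3, 5.0) deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, wilcoxon
from statsmodels.stats.multitest import multipletests

from .exceptions import DataMismatchError, InvalidParameterError
from .synthetic_data import BehavioralRun

__all__ = [
    "EccBinSeries",
    "ExpFitResult",
    "PermutationResult",
    "default_bin_edges",
    "dprime",
    "dprime_from_counts",
    "dprime_permutation",
    "bin_by_independent_ecc",
    "fit_exponential",
    "wilcoxon_fdr",
]


def default_bin_edges(boundary: float = 0.3, ecc_max: float = 5.0, n_log: int = 8) -> np.ndarray:
    """Foveal bin [0, boundary) plus ``n_log`` log-spaced bins up to ``ecc_max``."""
    return np.concatenate([[0.0], np.geomspace(boundary, ecc_max, n_log + 1)])


@dataclass
class EccBinSeries:
    """Per-bin, per-participant condition differences for one visual area.

    ``values`` is a participants x bins table of mean distributed-minus-
    focused differences (eccentricity or task beta); empty bins hold NaN,
    not zero.  ``bin_centers`` are the mean independent eccentricities of
    the member voxels (midpoints where a bin is empty everywhere), which
    keeps downstream curve fits anchored to where the data actually sit.
    """

    roi_label: str
    bin_edges: np.ndarray
    values: pd.DataFrame
    n: pd.DataFrame
    bin_centers: np.ndarray = field(default=None)
    #: mean independent pRF size of member voxels per bin (NaN if unknown);
    #: model fits prefer these measured sizes over a size-ecc relation
    bin_sd: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size < 2 or not np.all(np.diff(edges) > 0):
            raise InvalidParameterError("bin edges must be strictly increasing")
        if self.bin_centers is None:
            self.bin_centers = 0.5 * (edges[:-1] + edges[1:])

    def participant_mean(self) -> np.ndarray:
        """Across-participant mean difference per bin (NaN where empty)."""
        with np.errstate(invalid="ignore"):
            return self.values.mean(axis=0, skipna=True).to_numpy()


@dataclass
class ExpFitResult:
    """Three-parameter exponential fit ``y(e) = amp * exp(-e / decay) + asymptote``."""

    amp: float
    decay_const: float
    asymptote: float
    eval_grid: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    success: bool = True
    message: str = ""

    def curve(self, ecc) -> np.ndarray:
        ecc = np.asarray(ecc, dtype=float)
        return self.amp * np.exp(-ecc / self.decay_const) + self.asymptote


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float


# --------------------------------------------------------------------------
# signal detection
# --------------------------------------------------------------------------


def dprime_from_counts(hits: int, n_targets: int, fas: int, n_nontargets: int) -> float:
    """d' from raw counts, with the log-linear correction at extreme rates.

    d' = Phi^{-1}(hit rate) - Phi^{-1}(false-alarm rate).  When any rate is
    exactly 0 or 1, 0.5 is added to every cell count (and 1 to every trial
    count) so both rates stay strictly inside (0, 1).
    """
    if n_targets <= 0 or n_nontargets <= 0:
        raise InvalidParameterError("need at least one target and one non-target trial")
    hr = hits / n_targets
    fr = fas / n_nontargets
    if hr in (0.0, 1.0) or fr in (0.0, 1.0):
        hr = (hits + 0.5) / (n_targets + 1)
        fr = (fas + 0.5) / (n_nontargets + 1)
    return float(norm.ppf(hr) - norm.ppf(fr))


def dprime(run: BehavioralRun) -> float:
    """Sensitivity of one behavioral run."""
    t = np.asarray(run.is_target, dtype=bool)
    r = np.asarray(run.responded, dtype=bool)
    return dprime_from_counts(
        int((t & r).sum()), int(t.sum()), int((~t & r).sum()), int((~t).sum())
    )


def dprime_permutation(
    run: BehavioralRun, n_perm: int = 1000, seed: int | np.random.Generator | None = None
) -> PermutationResult:
    """Permutation null for d': shuffle target labels, hold responses fixed.

    The exceedance p uses the add-one correction,
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise InvalidParameterError(f"n_perm must be at least 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    observed = dprime(run)
    t = np.asarray(run.is_target, dtype=bool)
    r = np.asarray(run.responded, dtype=bool)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(t)
        null[i] = dprime_from_counts(
            int((perm & r).sum()), int(perm.sum()), int((~perm & r).sum()), int((~perm).sum())
        )
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(observed=observed, null=null, p_value=float(p))


# --------------------------------------------------------------------------
# eccentricity binning
# --------------------------------------------------------------------------


def bin_by_independent_ecc(
    independent_estimates: pd.DataFrame,
    per_condition_values: pd.DataFrame,
    bin_edges=None,
    roi_label: str = "",
    min_voxels_per_cell: int = 1,
) -> EccBinSeries:
    """Bin distributed-minus-focused differences by independent eccentricity.

    Parameters
    ----------
    independent_estimates
        Columns ``participant``, ``voxel_id``, ``eccentricity`` — the
        binning variable, from the independent mapping condition.  An
        optional ``sd`` column (independent pRF size) is averaged per bin
        into ``bin_sd`` for downstream model fits.
    per_condition_values
        Long table with columns ``participant``, ``voxel_id``,
        ``condition`` ("focused"/"distributed"), ``value``.  Every
        (participant, voxel) present here must have an independent
        estimate.

    For each participant and bin the value is
    ``mean(distributed) - mean(focused)`` over member voxels; bins with no
    members are NaN.  ``min_voxels_per_cell`` marks cells built from fewer
    member voxels as missing too — a mean difference of noisy estimates
    from one or two voxels carries no usable information and would
    otherwise dominate downstream fits.
    """
    edges = np.asarray(default_bin_edges() if bin_edges is None else bin_edges, dtype=float)
    indep_cols = ["participant", "voxel_id", "eccentricity"]
    if "sd" in independent_estimates.columns:
        indep_cols.append("sd")
    indep = independent_estimates[indep_cols]
    merged = per_condition_values.merge(indep, on=["participant", "voxel_id"], how="left")
    missing = merged.loc[merged["eccentricity"].isna(), ["participant", "voxel_id"]]
    if len(missing):
        ids = sorted(map(tuple, missing.drop_duplicates().to_numpy()))
        raise DataMismatchError(
            f"no independent estimate for (participant, voxel_id) pairs: {ids[:20]}"
        )
    # half-open [lo, hi): a voxel exactly on an interior edge joins the upper bin
    merged["bin"] = np.digitize(merged["eccentricity"], edges) - 1
    merged = merged[(merged["bin"] >= 0) & (merged["bin"] < edges.size - 1)]

    means = merged.pivot_table(
        index="participant", columns=["bin", "condition"], values="value", aggfunc="mean"
    )
    participants = means.index
    n_bins = edges.size - 1
    values = pd.DataFrame(np.nan, index=participants, columns=range(n_bins))
    counts = pd.DataFrame(0, index=participants, columns=range(n_bins))
    for b in range(n_bins):
        if (b, "distributed") in means.columns and (b, "focused") in means.columns:
            values[b] = means[(b, "distributed")] - means[(b, "focused")]
        sub = merged[merged["bin"] == b]
        counts[b] = sub.groupby("participant")["voxel_id"].nunique().reindex(participants, fill_value=0)
    values = values.where(counts >= max(min_voxels_per_cell, 1))

    centers = 0.5 * (edges[:-1] + edges[1:])
    member_mean = merged.groupby("bin")["eccentricity"].mean()
    for b, c in member_mean.items():
        centers[b] = c
    bin_sd = np.full(n_bins, np.nan)
    if "sd" in merged.columns:
        for b, s in merged.groupby("bin")["sd"].mean().items():
            bin_sd[b] = s
    return EccBinSeries(
        roi_label=roi_label,
        bin_edges=edges,
        values=values,
        n=counts,
        bin_centers=centers,
        bin_sd=bin_sd,
    )


# --------------------------------------------------------------------------
# exponential fits with bootstrap bands
# --------------------------------------------------------------------------


def _fit_exp_params(ecc: np.ndarray, y: np.ndarray, x0=None):
    """Least-squares (amp, decay, asymptote); multi-start over decay unless
    an explicit initialization (e.g. the point fit, for bootstrap refits)
    is supplied."""
    amp0 = y[0] - y[-1]
    starts = (
        [x0]
        if x0 is not None
        else [[amp0 if amp0 != 0 else 1e-3, d0, y[-1]] for d0 in (0.2, 0.5, 1.0, 2.0, 4.0)]
    )
    best = None
    for start in starts:
        sol = least_squares(
            lambda p: p[0] * np.exp(-ecc / p[1]) + p[2] - y,
            x0=start,
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e3, np.inf]),
            xtol=1e-12,
        )
        loss = float(np.sum(sol.fun**2))
        if best is None or loss < best[0]:
            best = (loss, sol)
    return best[1]


def _fit_exp_rows(ecc: np.ndarray, Y: np.ndarray, x0, n_iter: int = 60) -> np.ndarray:
    """Row-wise damped least squares for ``amp*exp(-e/decay)+asy``.

    Each row of ``Y`` is one bootstrap resample's bin means (NaN = missing
    bin, handled by zero weighting).  All rows start from the point fit
    ``x0`` and iterate together.  Returns (n_rows, 3) parameters.
    """
    m = Y.shape[0]
    w = np.isfinite(Y).astype(float)
    y = np.where(w > 0, Y, 0.0)
    amp = np.full(m, x0[0])
    dec = np.full(m, max(x0[1], 1e-3))
    asy = np.full(m, x0[2])
    lam = np.full(m, 1e-3)

    def cost(a, d, s):
        r = w * (a[:, None] * np.exp(-ecc[None, :] / d[:, None]) + s[:, None] - y)
        return (r * r).sum(axis=1)

    f = cost(amp, dec, asy)
    done = np.zeros(m, dtype=bool)
    for _ in range(n_iter):
        e = np.exp(-ecc[None, :] / dec[:, None])
        r = w * (amp[:, None] * e + asy[:, None] - y)
        j_a = w * e
        j_d = w * amp[:, None] * e * ecc[None, :] / dec[:, None] ** 2
        J = np.stack([j_a, j_d, w], axis=2)
        H = np.einsum("mni,mnj->mij", J, J)
        grad = np.einsum("mni,mn->mi", J, r)
        diag = np.maximum(np.diagonal(H, axis1=1, axis2=2), 1e-12)
        Hd = H + lam[:, None, None] * np.eye(3)[None, :, :] * diag[:, :, None]
        step = np.linalg.solve(Hd, grad[:, :, None])[:, :, 0]
        a_t = amp - step[:, 0]
        d_t = np.clip(dec - step[:, 1], 1e-3, 1e3)
        s_t = asy - step[:, 2]
        f_t = cost(a_t, d_t, s_t)
        better = (f_t <= f) & ~done
        amp = np.where(better, a_t, amp)
        dec = np.where(better, d_t, dec)
        asy = np.where(better, s_t, asy)
        lam = np.where(done, lam, np.where(better, lam * 0.3, lam * 10.0))
        f = np.where(better, f_t, f)
        scale = np.stack([np.abs(amp) + 1e-9, dec, np.abs(asy) + 1e-9], axis=1)
        done |= (better & np.all(np.abs(step) <= 1e-8 * scale, axis=1)) | (lam > 1e10)
        if done.all():
            break
    return np.column_stack([amp, dec, asy])


def fit_exponential(
    series: EccBinSeries,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    eval_grid: np.ndarray | None = None,
) -> ExpFitResult:
    """Fit ``amp * exp(-e/decay) + asymptote`` to across-participant bin means.

    The point fit uses the participant-mean value per (non-missing) bin.
    Uncertainty comes from resampling participants with replacement,
    refitting, and taking pointwise 2.5/97.5 percentiles of the resampled
    curves on ``eval_grid``.  Non-convergence is flagged in the result
    rather than raised.
    """
    centers = np.asarray(series.bin_centers, dtype=float)
    mean = series.participant_mean()
    ok = np.isfinite(mean)
    if ok.sum() < 4:
        raise InvalidParameterError("need at least 4 non-missing bins for an exponential fit")
    ecc, y = centers[ok], mean[ok]
    sol = _fit_exp_params(ecc, y)
    amp, decay, asy = sol.x
    grid = (
        np.linspace(series.bin_edges[0], series.bin_edges[-1], 50)
        if eval_grid is None
        else np.asarray(eval_grid, dtype=float)
    )
    rng = np.random.default_rng(seed)
    table = series.values.to_numpy()
    n_part = table.shape[0]
    resampled = table[rng.integers(0, n_part, (n_boot, n_part))]
    with np.errstate(invalid="ignore"):
        ym = np.nanmean(resampled, axis=1)  # (n_boot, n_bins)
    usable = np.isfinite(ym).sum(axis=1) >= 4
    params = _fit_exp_rows(centers, ym[usable], x0=sol.x)
    curves = np.full((n_boot, grid.size), np.nan)
    curves[usable] = (
        params[:, 0:1] * np.exp(-grid[None, :] / params[:, 1:2]) + params[:, 2:3]
    )
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(curves, 2.5, axis=0)
        hi = np.nanpercentile(curves, 97.5, axis=0)
    return ExpFitResult(
        amp=float(amp),
        decay_const=float(decay),
        asymptote=float(asy),
        eval_grid=grid,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        success=bool(sol.success),
        message=sol.message,
    )


# --------------------------------------------------------------------------
# Wilcoxon + FDR
# --------------------------------------------------------------------------


def wilcoxon_fdr(per_roi_samples: Mapping[str, object], q: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank per ROI with Benjamini-Hochberg FDR.

    ``per_roi_samples`` maps ROI label to either paired arrays ``(a, b)``
    (one pair per participant) or a single array of paired differences.
    The exact null distribution is used for n <= 25 (falling back to the
    normal approximation with continuity correction when zeros or ties
    make the exact null unavailable).  ROIs whose differences are all zero
    are flagged (the test is undefined) and excluded from the FDR family.
    """
    if not 0 < q < 1:
        raise InvalidParameterError(f"q must be in (0, 1), got {q}")
    rows = []
    for roi, samples in per_roi_samples.items():
        if isinstance(samples, tuple) and len(samples) == 2:
            d = np.asarray(samples[0], dtype=float) - np.asarray(samples[1], dtype=float)
        else:
            d = np.asarray(samples, dtype=float)
        if d.size < 5:
            raise InvalidParameterError(f"ROI {roi!r}: need at least 5 pairs, got {d.size}")
        if np.all(d == 0):
            rows.append({"roi": roi, "n": d.size, "statistic": np.nan, "p": np.nan,
                         "note": "all differences zero; test undefined"})
            continue
        method = "exact" if d.size <= 25 else "approx"
        try:
            res = wilcoxon(d, alternative="two-sided", method=method, correction=(method == "approx"))
        except ValueError:
            res = wilcoxon(d, alternative="two-sided", method="approx", correction=True)
        rows.append({"roi": roi, "n": d.size, "statistic": float(res.statistic),
                     "p": float(res.pvalue), "note": ""})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    out["reject"] = False
    tested = out["p"].notna()
    if tested.any():
        reject, p_adj, _, _ = multipletests(out.loc[tested, "p"], alpha=q, method="fdr_bh")
        out.loc[tested, "p_adj"] = p_adj
        out.loc[tested, "reject"] = reject
    return out
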