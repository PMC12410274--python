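"""Synthetic populations, BOLD time series, and behavioral streams.

Everything the downstream pipeline measures is generated here with known
ground truth: per-area pRF populations with size-eccentricity scaling,
attention-driven pRFs displaced by the AF+ interaction, noisy BOLD series
with condition- and eccentricity-dependent task baseline shifts, and
trial streams from an equal-variance signal-detection observer.

Default study conditions
------------------------
* Six retinotopic areas (V1, V2, V3, hV4, LO, IPS) with linear
  size-eccentricity relations whose slopes grow up the hierarchy.
* Attention fields centered at fixation with gain 1 and offset 0.1:
  focused sd 0.5 deg (a task confined to a 0.1 deg-radius circle recruits
  an attention field somewhat wider than the stimulus itself) and
  distributed sd 5.0 deg (attention spread over the whole display).
* pRF eccentricities sampled area-uniformly on [0.05, 5.0] deg, sizes
  from the area's relation with 20% lognormal scatter, peak responses of
  3 percent signal, and task-block baseline shifts whose
  distributed-minus-focused difference changes sign at the 0.3 deg
  boundary between the two task extents.
* Behavioral trials at a 1-in-12 target rate with true sensitivity
  d' = 2.7 and a neutral criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import InvalidParameterError
from .gaussian_af import (
    AFParams,
    GaussianProfile1D,
    GridSpec,
    SizeEccRelation,
    _offset_interaction_rows,
    af_interaction_analytic,
)
from .prf_forward import (
    HRFKernel,
    PRF2D,
    canonical_hrf,
    convolve_hrf,
    overlap_timecourses,
)
from .stimulus_design import ApertureMovie, RunDesign

__all__ = [
    "VoxelRecord",
    "BehavioralRun",
    "DEFAULT_RELATIONS",
    "DEFAULT_AF_FOCUSED",
    "DEFAULT_AF_DISTRIBUTED",
    "default_task_profile",
    "sample_population",
    "apply_attention",
    "simulate_bold",
    "simulate_behavior",
    "jittered_af_pairs",
    "population_frame",
    "task_regressors",
]

CONDITIONS = ("focused", "distributed")

DEFAULT_RELATIONS: dict[str, SizeEccRelation] = {
    "V1": SizeEccRelation(0.12, 0.25, "V1"),
    "V2": SizeEccRelation(0.16, 0.30, "V2"),
    "V3": SizeEccRelation(0.20, 0.35, "V3"),
    "hV4": SizeEccRelation(0.35, 0.55, "hV4"),
    "LO": SizeEccRelation(0.50, 0.80, "LO"),
    "IPS": SizeEccRelation(0.75, 1.00, "IPS"),
}

DEFAULT_AF_FOCUSED = AFParams(center=0.0, sd=0.5, gain=1.0, offset=0.1)
DEFAULT_AF_DISTRIBUTED = AFParams(center=0.0, sd=5.0, gain=1.0, offset=0.1)

#: boundary between the focused and distributed task extents (deg radius)
TASK_BOUNDARY_DEG = 0.3
# decay chosen so the default beta difference crosses zero at the boundary
_TASK_PROFILE_DECAY = TASK_BOUNDARY_DEG / np.log(1.3 / 0.6)


def default_task_profile(ecc, condition: str):
    """Task-block baseline shift (percent signal) vs eccentricity and condition.

    Focused-task betas dominate for pRFs inside the focused stimulus extent
    (< 0.3 deg); distributed-task betas dominate beyond it, saturating in
    the periphery.  The magnitudes are order-of-magnitude choices — the
    qualitative sign structure, not the scale, is the modeled feature.
    """
    ecc = np.asarray(ecc, dtype=float)
    if condition == "focused":
        return 0.1 + 0.7 * np.exp(-ecc / _TASK_PROFILE_DECAY)
    if condition == "distributed":
        return 0.1 + 0.6 * (1.0 - np.exp(-ecc / _TASK_PROFILE_DECAY))
    raise InvalidParameterError(f"unknown condition {condition!r}")


@dataclass
class VoxelRecord:
    """Ground truth for one synthetic voxel."""

    voxel_id: int
    roi_label: str
    sdprf: PRF2D
    prf_focused: PRF2D | None = None
    prf_distributed: PRF2D | None = None
    task_beta_focused: float = 0.0
    task_beta_distributed: float = 0.0

    def prf(self, condition: str) -> PRF2D:
        if condition == "independent":
            return self.sdprf
        prf = getattr(self, f"prf_{condition}", None)
        if prf is None:
            raise InvalidParameterError(
                f"condition {condition!r} unavailable; run apply_attention first"
            )
        return prf


@dataclass
class BehavioralRun:
    """Trial-level outcome of the color-proportion detection task."""

    is_target: np.ndarray
    responded: np.ndarray
    condition: str = ""
    target_proportion: float = 1.0 / 12.0

    @property
    def n_trials(self) -> int:
        return int(self.is_target.size)


def sample_population(
    roi_relations: Mapping[str, SizeEccRelation] | None = None,
    n_voxels: int = 500,
    ecc_range: tuple[float, float] = (0.05, 5.0),
    seed: int | np.random.Generator | None = None,
    sd_jitter: float = 0.2,
    peak_response_psc: float = 3.0,
    task_profile: Callable = default_task_profile,
) -> list[VoxelRecord]:
    """Sample stimulus-driven pRFs for a population spanning the visual hierarchy.

    Voxels are split evenly across the configured areas.  Eccentricities
    are drawn with density proportional to eccentricity (uniform over the
    visual-field area), polar angles uniformly; sizes follow the area's
    size-eccentricity relation with multiplicative lognormal jitter.
    Amplitudes are normalized by the Gaussian's area so every voxel's peak
    stimulus response is about ``peak_response_psc`` percent signal.
    """
    if n_voxels <= 0:
        raise InvalidParameterError(f"n_voxels must be positive, got {n_voxels}")
    lo, hi = ecc_range
    if not (0 <= lo < hi <= 5.5):
        raise InvalidParameterError(f"ecc_range must lie within [0, 5.5], got {ecc_range}")
    relations = dict(roi_relations or DEFAULT_RELATIONS)
    rng = np.random.default_rng(seed)
    rois = list(relations)
    counts = np.full(len(rois), n_voxels // len(rois))
    counts[: n_voxels % len(rois)] += 1

    records: list[VoxelRecord] = []
    vid = 0
    for roi, count in zip(rois, counts):
        rel = relations[roi]
        u = rng.random(count)
        ecc = np.sqrt(u * (hi**2 - lo**2) + lo**2)
        theta = rng.uniform(0, 2 * np.pi, count)
        sd = rel.sd_at(ecc) * rng.lognormal(0.0, sd_jitter, count)
        amp = peak_response_psc / (2.0 * np.pi * sd**2)
        for i in range(count):
            records.append(
                VoxelRecord(
                    voxel_id=vid,
                    roi_label=roi,
                    sdprf=PRF2D(
                        x=float(ecc[i] * np.cos(theta[i])),
                        y=float(ecc[i] * np.sin(theta[i])),
                        sd=float(sd[i]),
                        amplitude=float(amp[i]),
                    ),
                    task_beta_focused=float(task_profile(ecc[i], "focused")),
                    task_beta_distributed=float(task_profile(ecc[i], "distributed")),
                )
            )
            vid += 1
    return records


def apply_attention(
    records: Sequence[VoxelRecord],
    af_focused: AFParams = DEFAULT_AF_FOCUSED,
    af_distributed: AFParams = DEFAULT_AF_DISTRIBUTED,
    grid_spec: GridSpec | None = None,
) -> list[VoxelRecord]:
    """Attach per-condition attention-driven pRFs to each voxel record.

    The AF interaction is applied along the radial axis through the voxel's
    stimulus-driven center: the center is rescaled to the interaction's
    eccentricity (polar angle preserved) and the size is set to the
    interaction sd.  Both attention fields must be centered at fixation.
    """
    for af in (af_focused, af_distributed):
        if af.center != 0:
            raise InvalidParameterError("attention fields must be centered at fixation (0)")
    ecc = np.array([r.sdprf.eccentricity for r in records])
    sd2 = np.array([r.sdprf.sd for r in records])
    new = {}
    for name, af in (("focused", af_focused), ("distributed", af_distributed)):
        if af.offset == 0:
            c3 = np.array(
                [af_interaction_analytic(af, GaussianProfile1D(e, s)).center
                 for e, s in zip(ecc, sd2)]
            )
            sd3 = np.array(
                [af_interaction_analytic(af, GaussianProfile1D(e, s)).sd
                 for e, s in zip(ecc, sd2)]
            )
        else:
            c3, sd3, _ = _offset_interaction_rows(af, ecc, sd2, grid_spec)
        new[name] = (c3, sd3)
    out = []
    for i, rec in enumerate(records):
        prfs = {}
        for name in ("focused", "distributed"):
            c3, sd3 = new[name]
            scale = c3[i] / ecc[i] if ecc[i] > 0 else 0.0
            prfs[name] = replace(
                rec.sdprf, x=rec.sdprf.x * scale, y=rec.sdprf.y * scale, sd=float(sd3[i])
            )
        out.append(replace(rec, prf_focused=prfs["focused"], prf_distributed=prfs["distributed"]))
    return out


def task_regressors(design: RunDesign, hrf: HRFKernel) -> dict[str, np.ndarray]:
    """HRF-convolved task boxcar and onset/offset impulse regressors."""
    n = design.n_trs
    boxcar = np.zeros(n)
    boxcar[design.task_start : design.task_end] = 1.0
    onset = np.zeros(n)
    onset[design.task_start] = 1.0
    offset = np.zeros(n)
    offset[design.task_end - 1] = 1.0
    return {
        "task": convolve_hrf(boxcar, hrf),
        "onset": convolve_hrf(onset, hrf),
        "offset": convolve_hrf(offset, hrf),
    }


def simulate_bold(
    records: Sequence[VoxelRecord],
    movie: ApertureMovie,
    condition: str,
    hrf: HRFKernel | None = None,
    noise_sd: float = 0.0,
    onset_beta: float = 0.5,
    offset_beta: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate per-voxel BOLD series (percent signal) for one condition.

    The series is the linear pRF prediction for the condition's
    attention-driven pRF, plus the task-block baseline shift (HRF-convolved
    boxcar scaled by the voxel's task beta), onset/offset impulse
    responses, and white Gaussian noise.  The ``"independent"`` condition
    uses the stimulus-driven pRF with no task component, emulating the
    passively-fixated independent mapper used for unbiased binning.
    Returns an array of shape (n_voxels, n_trs).
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if movie.design is None:
        raise InvalidParameterError("movie must carry its run design")
    hrf = hrf or canonical_hrf(movie.tr_s)
    rng = np.random.default_rng(seed)
    prfs = [rec.prf(condition) for rec in records]
    overlaps = overlap_timecourses(
        [p.x for p in prfs], [p.y for p in prfs], [p.sd for p in prfs], movie
    )
    series = convolve_hrf(overlaps, hrf)
    series *= np.array([p.amplitude for p in prfs])[:, None]
    series += np.array([p.baseline for p in prfs])[:, None]
    if condition != "independent":
        regs = task_regressors(movie.design, hrf)
        betas = np.array([getattr(rec, f"task_beta_{condition}") for rec in records])
        series += betas[:, None] * regs["task"][None, :]
        series += onset_beta * regs["onset"][None, :] + offset_beta * regs["offset"][None, :]
    if noise_sd > 0:
        series += rng.normal(0.0, noise_sd, series.shape)
    return series


def simulate_behavior(
    n_trials: int,
    target_rate: float = 1.0 / 12.0,
    true_dprime: float = 2.7,
    criterion: float = 0.0,
    seed: int | np.random.Generator | None = None,
    condition: str = "",
) -> BehavioralRun:
    """Simulate detection trials from an equal-variance signal-detection observer.

    Targets occur independently with probability ``target_rate``; the
    observer responds to targets with probability Phi(d'/2 - c) and to
    non-targets with probability Phi(-d'/2 - c).
    """
    if n_trials <= 0:
        raise InvalidParameterError(f"n_trials must be positive, got {n_trials}")
    if not 0 < target_rate < 1:
        raise InvalidParameterError(f"target_rate must be in (0, 1), got {target_rate}")
    rng = np.random.default_rng(seed)
    is_target = rng.random(n_trials) < target_rate
    p_hit = norm.cdf(true_dprime / 2.0 - criterion)
    p_fa = norm.cdf(-true_dprime / 2.0 - criterion)
    p_resp = np.where(is_target, p_hit, p_fa)
    responded = rng.random(n_trials) < p_resp
    return BehavioralRun(
        is_target=is_target,
        responded=responded,
        condition=condition,
        target_proportion=target_rate,
    )


def jittered_af_pairs(
    n_participants: int,
    af_focused: AFParams = DEFAULT_AF_FOCUSED,
    af_distributed: AFParams = DEFAULT_AF_DISTRIBUTED,
    between_subject_sd: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[AFParams, AFParams]]:
    """Per-participant AF pairs with lognormal between-subject sd jitter.

    ``between_subject_sd`` is the sd of the lognormal multiplier applied to
    each AF's width; 0 gives every participant the group parameters.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_participants):
        jf, jd = rng.lognormal(0.0, between_subject_sd, 2) if between_subject_sd > 0 else (1.0, 1.0)
        pairs.append(
            (
                replace(af_focused, sd=af_focused.sd * float(jf)),
                replace(af_distributed, sd=af_distributed.sd * float(jd)),
            )
        )
    return pairs


def population_frame(records: Sequence[VoxelRecord]) -> pd.DataFrame:
    """Ground-truth table: one row per voxel with pRF parameters and betas."""
    rows = []
    for r in records:
        row = {
            "voxel_id": r.voxel_id,
            "roi": r.roi_label,
            "sdprf_x": r.sdprf.x,
            "sdprf_y": r.sdprf.y,
            "sdprf_sd": r.sdprf.sd,
            "sdprf_ecc": r.sdprf.eccentricity,
            "task_beta_focused": r.task_beta_focused,
            "task_beta_distributed": r.task_beta_distributed,
        }
        for cond in CONDITIONS:
            prf = getattr(r, f"prf_{cond}")
            if prf is not None:
                row[f"{cond}_x"] = prf.x
                row[f"{cond}_y"] = prf.y
                row[f"{cond}_sd"] = prf.sd
                row[f"{cond}_ecc"] = prf.eccentricity
        rows.append(row)
    return pd.DataFrame(rows)
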