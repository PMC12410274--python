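"""Run timing and bar-sweep aperture movies for visual field mapping.

A mapping run embeds a bar-sweep retinotopy stimulus inside a block
design: a passive-fixation block, a long attention-task block during
which a checkerboard bar traverses the visual field, and a closing
fixation block.  The bar is reduced here to its binary aperture — per-TR
masks on a pixel grid in degrees of visual angle — which is all a linear
pRF forward model needs (the carrier pattern is irrelevant).

Canonical timing (TR = 1.5 s): 14 TRs fixation, 224 TRs task, 21 TRs
fixation.  The mapper starts 10 TRs after task onset; eight 16-TR bar
sweeps (four orientations, each traversed in both directions) cross a
circular aperture of 5 deg radius, with a 10-TR task-only gap after
every second sweep and the remaining task TRs padded at the end.  The
stated stimulus durations do not tile the task block exactly, so the
end-of-task pad absorbs the remainder; the TR-denominated block lengths
are treated as authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .exceptions import ConfigurationError, DesignError

__all__ = [
    "TimingConfig",
    "ScreenConfig",
    "SweepSpec",
    "RunDesign",
    "ApertureMovie",
    "make_run_design",
    "make_aperture_movie",
]


@dataclass(frozen=True)
class TimingConfig:
    """Block/sweep timing of one run, in TRs."""

    tr_s: float = 1.5
    fix_start_trs: int = 14
    task_trs: int = 224
    fix_end_trs: int = 21
    mapper_delay_trs: int = 10
    n_sweeps: int = 8
    sweep_trs: int = 16
    gap_trs: int = 10
    gaps_after: tuple[int, ...] = (2, 4, 6)


@dataclass(frozen=True)
class ScreenConfig:
    """Pixel grid and bar geometry, in degrees of visual angle."""

    width_deg: float = 11.2
    height_deg: float = 5.6
    px_per_deg: float = 10.0
    aperture_radius_deg: float = 5.0
    bar_width_deg: float = 1.25
    bar_step_deg: float = 0.625


@dataclass(frozen=True)
class SweepSpec:
    """One bar pass: start TR, bar orientation, and motion direction sign.

    ``orientation_deg`` is the angle of the bar's long axis; the bar moves
    perpendicular to it, in the direction ``orientation + 90`` degrees for
    ``direction == +1`` and the opposite for ``-1``.
    """

    start_tr: int
    orientation_deg: float
    direction: int


@dataclass(frozen=True)
class RunDesign:
    condition: str
    tr_s: float
    blocks: tuple[tuple[str, int], ...]
    sweeps: tuple[SweepSpec, ...]
    mapper_delay_trs: int
    sweep_trs: int

    @property
    def n_trs(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def task_start(self) -> int:
        return self.blocks[0][1]

    @property
    def task_end(self) -> int:
        return self.task_start + self.blocks[1][1]

    @property
    def task_trs(self) -> int:
        return self.blocks[1][1]


# orientation/direction order of the eight passes; a gap follows every
# second sweep, so passes are grouped in same-orientation pairs
_SWEEP_ORDER: tuple[tuple[float, int], ...] = (
    (90.0, +1),
    (90.0, -1),
    (0.0, +1),
    (0.0, -1),
    (45.0, +1),
    (45.0, -1),
    (135.0, +1),
    (135.0, -1),
)


def make_run_design(condition: str = "focused", timing: TimingConfig | None = None) -> RunDesign:
    """Build the canonical block/sweep design for one run."""
    t = timing or TimingConfig()
    start = t.fix_start_trs + t.mapper_delay_trs
    sweeps = []
    tr = start
    for i in range(t.n_sweeps):
        orientation, direction = _SWEEP_ORDER[i % len(_SWEEP_ORDER)]
        sweeps.append(SweepSpec(tr, orientation, direction))
        tr += t.sweep_trs
        if (i + 1) in t.gaps_after:
            tr += t.gap_trs
    task_end = t.fix_start_trs + t.task_trs
    if tr > task_end:
        raise DesignError(
            f"sweeps end at TR {tr} but the task block ends at TR {task_end}; "
            "reduce sweep count, length, or gaps"
        )
    blocks = (
        ("fixation", t.fix_start_trs),
        ("task", t.task_trs),
        ("fixation", t.fix_end_trs),
    )
    return RunDesign(
        condition=condition,
        tr_s=t.tr_s,
        blocks=blocks,
        sweeps=tuple(sweeps),
        mapper_delay_trs=t.mapper_delay_trs,
        sweep_trs=t.sweep_trs,
    )


@dataclass
class ApertureMovie:
    """Per-TR binary aperture frames on a visual-field pixel grid.

    ``frames`` has shape (n_trs, ny, nx); ``x``/``y`` hold pixel-center
    coordinates in degrees, origin at fixation, x rightward, y upward.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tr_s: float
    design: RunDesign | None = None

    @cached_property
    def active_mask(self) -> np.ndarray:
        """Pixels touched by the bar in any frame (used to prune computation)."""
        return self.frames.any(axis=0)

    @property
    def px_per_deg(self) -> float:
        return 1.0 / float(self.x[1] - self.x[0])

    def pixel_area_deg2(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))


def make_aperture_movie(design: RunDesign, screen: ScreenConfig | None = None) -> ApertureMovie:
    """Render the binary bar-aperture movie for a run design.

    Each sweep advances a bar of the configured width by ``bar_step_deg``
    per TR along its motion axis, clipped to the circular mapper aperture;
    fixation, gap, and pad TRs are all-zero frames.
    """
    s = screen or ScreenConfig()
    if s.px_per_deg < 8:
        raise ConfigurationError(
            f"pixel resolution {s.px_per_deg}/deg is too coarse to resolve a "
            f"{s.bar_width_deg} deg bar; use at least 8 px/deg"
        )
    nx = int(round(s.width_deg * s.px_per_deg))
    ny = int(round(s.height_deg * s.px_per_deg))
    x = (np.arange(nx) + 0.5) / s.px_per_deg - s.width_deg / 2.0
    y = (np.arange(ny) + 0.5) / s.px_per_deg - s.height_deg / 2.0
    xx, yy = np.meshgrid(x, y)
    in_aperture = xx**2 + yy**2 <= s.aperture_radius_deg**2

    frames = np.zeros((design.n_trs, ny, nx), dtype=bool)
    half_w = s.bar_width_deg / 2.0
    for sweep in design.sweeps:
        theta = np.deg2rad(sweep.orientation_deg + 90.0)
        ux, uy = np.cos(theta), np.sin(theta)
        proj = ux * xx + uy * yy
        for k in range(design.sweep_trs):
            # bar center starts edge-aligned at -radius and advances one step per TR
            pos = -s.aperture_radius_deg + k * s.bar_step_deg
            if sweep.direction < 0:
                pos = -pos
            frames[sweep.start_tr + k] = in_aperture & (np.abs(proj - pos) <= half_w)
    return ApertureMovie(frames=frames, x=x, y=y, tr_s=design.tr_s, design=design)
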