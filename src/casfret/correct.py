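"""Raw two-channel intensities -> corrected FRET trajectories and histograms.

FRET is computed as E = I_A / (I_D + I_A) from background- and
leakage-corrected intensities.  Photobleaching is detected as a sustained
collapse of the corrected total intensity; frames after the bleach are
excluded from all downstream statistics.  Histograms pool the first few
frames of each molecule and report the bound fraction as the share of points
with FRET above the high threshold (0.75 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import medfilt

from .simulate import IntensityTrace

__all__ = [
    "AnalysisConfig",
    "FretTrajectory",
    "HistogramSummary",
    "correct_trace",
    "detect_photobleach",
    "build_histogram",
]


@dataclass
class AnalysisConfig:
    """Thresholds and correction parameters for trace analysis.

    ``bound_threshold`` separates the unbound (zero-FRET) state from the
    bound (mid+high) states; ``high_threshold`` defines the stably bound
    population counted in the bound fraction.
    """

    bound_threshold: float = 0.2
    high_threshold: float = 0.75
    histogram_frames: int = 5
    leakage_fraction: float = 0.07
    background_donor: float = 50.0
    background_acceptor: float = 50.0
    frame_interval_s: float = 0.1
    fret_clamp: tuple[float, float] = (-0.2, 1.2)
    min_total_intensity: float = 50.0
    bleach_drop_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.bound_threshold < self.high_threshold < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < bound_threshold < high_threshold < 1"
            )
        if self.histogram_frames < 1:
            raise ValueError("histogram_frames must be >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @classmethod
    def from_manifest(cls, manifest: dict, **overrides) -> "AnalysisConfig":
        """Pull backgrounds/leakage/frame interval from a dataset manifest."""
        em = manifest.get("emission", {})
        kw = dict(
            leakage_fraction=em.get("leakage_fraction", cls.leakage_fraction),
            background_donor=em.get("background_donor", cls.background_donor),
            background_acceptor=em.get(
                "background_acceptor", cls.background_acceptor
            ),
            frame_interval_s=manifest.get("frame_interval_s", cls.frame_interval_s),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FretTrajectory:
    """Corrected FRET time trajectory of one molecule.

    ``fret`` is NaN on invalid frames (corrected total intensity at or below
    zero before the bleach); ``valid_through`` is the index of the last
    pre-bleach frame.  Frames beyond it carry no information about the
    molecule and are excluded downstream.
    """

    molecule_id: str
    time_s: np.ndarray
    fret: np.ndarray
    donor_corrected: np.ndarray
    acceptor_corrected: np.ndarray
    valid_through: int
    frame_interval: float

    @property
    def valid_fret(self) -> np.ndarray:
        """Finite pre-bleach FRET values."""
        f = self.fret[: self.valid_through + 1]
        return f[np.isfinite(f)]

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.fret[: self.valid_through + 1]).sum())


@dataclass
class HistogramSummary:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int
    frames_per_molecule: int
    bound_fraction: float
    n_points: int


def detect_photobleach(trace: IntensityTrace, config: AnalysisConfig) -> int:
    """Index of the last frame before the corrected total intensity collapses.

    The corrected total is median-filtered (width 5); the bleach point is the
    last frame at or above ``bleach_drop_fraction`` of the median pre-drop
    level.  Returns the final frame when no collapse occurs and 0 for a trace
    that is dark throughout.
    """
    if trace.n_frames < 10:
        raise ValueError("photobleach detection needs at least 10 frames")
    i_d = trace.donor - config.background_donor
    i_a = trace.acceptor - config.background_acceptor - config.leakage_fraction * i_d
    total = medfilt(i_d + i_a, kernel_size=5)
    bright = total[total >= config.min_total_intensity]
    # a trace whose bright level is indistinguishable from background noise
    # is dark throughout (bleached before acquisition)
    if bright.size == 0 or np.median(bright) < 2 * config.min_total_intensity:
        return 0
    thresh = max(
        config.bleach_drop_fraction * float(np.median(bright)),
        config.min_total_intensity,
    )
    above = np.flatnonzero(total >= thresh)
    return int(above[-1]) if above.size else 0


def correct_trace(trace: IntensityTrace, config: AnalysisConfig) -> FretTrajectory:
    """Background/leakage correction and FRET computation for one trace.

    ``I_D = raw_donor - bg_D``; ``I_A = raw_acceptor - bg_A - leakage * I_D``;
    ``E = I_A / (I_D + I_A)`` clamped to ``config.fret_clamp``.  Pre-bleach
    frames whose corrected total is not positive are flagged invalid (NaN)
    rather than raising.
    """
    i_d = trace.donor - config.background_donor
    i_a = trace.acceptor - config.background_acceptor - config.leakage_fraction * i_d
    total = i_d + i_a
    with np.errstate(divide="ignore", invalid="ignore"):
        fret = np.where(total > 0, i_a / np.where(total > 0, total, 1.0), np.nan)
    fret = np.clip(fret, *config.fret_clamp)
    valid_through = detect_photobleach(trace, config)
    return FretTrajectory(
        molecule_id=trace.molecule_id,
        time_s=trace.time_s,
        fret=fret,
        donor_corrected=i_d,
        acceptor_corrected=i_a,
        valid_through=valid_through,
        frame_interval=trace.frame_interval,
    )


def build_histogram(
    trajectories: list[FretTrajectory], config: AnalysisConfig
) -> HistogramSummary:
    """Pool the first ``histogram_frames`` valid frames of every molecule.

    The bound fraction is the share of pooled points with FRET above
    ``high_threshold``.  Post-bleach frames never enter the pool, so a
    molecule contributes fewer than ``histogram_frames`` points if it
    bleaches early.
    """
    points = []
    for traj in trajectories:
        f = traj.valid_fret[: config.histogram_frames]
        if f.size:
            points.append(f)
    if not points:
        raise ValueError("no valid frames in any trajectory")
    pooled = np.concatenate(points)
    lo, hi = config.fret_clamp
    edges = np.arange(lo, hi + 0.025, 0.05)
    counts, _ = np.histogram(pooled, bins=edges)
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        n_molecules=len(trajectories),
        frames_per_molecule=config.histogram_frames,
        bound_fraction=float(np.mean(pooled > config.high_threshold)),
        n_points=int(pooled.size),
    )
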