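"""Escape-response kinematics from chase-video click tracks.

A tail flip is delimited by two mouse clicks on the video — the
animal's position before and after the flip.  The per-event speed is
the Euclidean pixel distance divided by the frame gap, scaled by the
recording frame rate and the pixel-to-cm calibration:

    v = (d / delta_frames) * fps / px_per_cm        [cm s^-1]

Trial-level summaries report the total number of escapes, mean and
maximum speed, and size-normalised speed in carapace lengths per
second.  Zero-frame-gap events (both clicks on the same frame) have
undefined speed; they are counted but excluded from speed statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from lobsterresp.trace_io import ChaseTrack

__all__ = [
    "EscapeSummary",
    "CorrelationResult",
    "euclidean_distance",
    "escape_speed",
    "relative_speed",
    "summarize_track",
    "correlate_with_epoc",
]


def euclidean_distance(p1, p2) -> float:
    """Straight-line distance between two click positions (px)."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def escape_speed(
    distance_px: float, frame_gap: float, fps: float, px_per_cm: float
) -> float:
    """Calibrated speed of one tail flip (cm s^-1).

    Raises ``ValueError`` for a zero frame gap — the event should be
    flagged and excluded from speed statistics by the caller.
    """
    if fps <= 0 or px_per_cm <= 0:
        raise ValueError("fps and px_per_cm must be > 0")
    if frame_gap < 1:
        raise ValueError("frame gap must be >= 1 frame; speed undefined")
    return (distance_px / frame_gap) * fps / px_per_cm


def relative_speed(speed_cm_s: float, carapace_length_cm: float) -> float:
    """Size-normalised speed in carapace lengths per second."""
    if carapace_length_cm <= 0:
        raise ValueError("carapace_length_cm must be > 0")
    return speed_cm_s / carapace_length_cm


@dataclass
class EscapeSummary:
    """Per-trial escape metrics."""

    total_escapes: int
    speeds_cm_s: np.ndarray
    mean_speed_cm_s: float
    max_speed_cm_s: float
    n_zero_duration: int
    mean_relative_speed_cl_s: float | None = None
    max_relative_speed_cl_s: float | None = None

    def to_row(self) -> dict:
        return {
            "total_escapes": self.total_escapes,
            "mean_speed_cm_s": self.mean_speed_cm_s,
            "max_speed_cm_s": self.max_speed_cm_s,
            "n_zero_duration": self.n_zero_duration,
            "mean_relative_speed_cl_s": np.nan
            if self.mean_relative_speed_cl_s is None
            else self.mean_relative_speed_cl_s,
            "max_relative_speed_cl_s": np.nan
            if self.max_relative_speed_cl_s is None
            else self.max_relative_speed_cl_s,
        }


def summarize_track(
    track: ChaseTrack, carapace_length_cm: float | None = None
) -> EscapeSummary:
    """Per-event speeds and trial-level escape statistics.

    ``total_escapes`` counts every paired event including zero-duration
    ones; speed statistics use only events with a positive frame gap.
    The trial-level speed is the mean over events (the maximum is also
    reported).
    """
    ev = track.events
    d = np.sqrt(
        (ev["x_end"] - ev["x_start"]) ** 2 + (ev["y_end"] - ev["y_start"]) ** 2
    ).to_numpy(dtype=float)
    gaps = (ev["frame_end"] - ev["frame_start"]).to_numpy(dtype=float)
    valid = gaps >= 1
    speeds = (d[valid] / gaps[valid]) * track.fps / track.px_per_cm
    mean_v = float(np.mean(speeds)) if len(speeds) else 0.0
    max_v = float(np.max(speeds)) if len(speeds) else 0.0
    mean_rel = max_rel = None
    if carapace_length_cm is not None and len(speeds):
        mean_rel = relative_speed(mean_v, carapace_length_cm)
        max_rel = relative_speed(max_v, carapace_length_cm)
    return EscapeSummary(
        total_escapes=int(len(ev)),
        speeds_cm_s=speeds,
        mean_speed_cm_s=mean_v,
        max_speed_cm_s=max_v,
        n_zero_duration=int(np.sum(~valid)),
        mean_relative_speed_cl_s=mean_rel,
        max_relative_speed_cl_s=max_rel,
    )


@dataclass
class CorrelationResult:
    """Pearson correlation between an escape metric and EPOC."""

    r: float
    p_value: float
    n: int
    x_normal: bool
    y_normal: bool
    normality_flagged: bool
    shapiro_p_x: float = float("nan")
    shapiro_p_y: float = float("nan")


def correlate_with_epoc(
    escape_metric, epoc, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson r between a per-animal escape metric and EPOC.

    Each variable is gated through a Shapiro-Wilk normality test; on
    failure the correlation is still computed but flagged, so callers
    can fall back to a rank-based method if they prefer.
    """
    x = np.asarray(escape_metric, dtype=float)
    y = np.asarray(epoc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired observations required")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    px = float(stats.shapiro(x).pvalue)
    py = float(stats.shapiro(y).pvalue)
    x_normal, y_normal = px >= alpha, py >= alpha
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        x_normal=x_normal,
        y_normal=y_normal,
        normality_flagged=not (x_normal and y_normal),
        shapiro_p_x=px,
        shapiro_p_y=py,
    )
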