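"""Sliding-window end-velocity analysis and end-region probe intensity.

The velocity of a tracked microtubule end is measured by ordinary
least-squares line fits over consecutive, non-overlapping 2-min windows.
Leading windows with negative velocity (trajectories starting in shrinkage)
are eliminated so every trajectory starts with a positive-velocity segment;
later negative-velocity windows are kept, and windows below -2.5 nm/s are
classified as shrinking and excluded from growth statistics.  The probe
intensity at the end is measured per kymograph line as the mean over a
5-pixel lattice window ending at the tracked end minus the mean over a
5-pixel solution window 3 pixels beyond the end.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EndTrajectory, Kymograph

__all__ = [
    "VelocitySegment",
    "fit_segment_velocities",
    "classify_segments",
    "end_intensity",
    "attach_segment_intensity",
    "bin_medians",
]

ELIMINATED = "eliminated"
SHRINKING = "shrinking"
GROWTH_SEG = "growth"


@dataclass
class VelocitySegment:
    t_start: float
    t_end: float
    velocity: float
    classification: str = GROWTH_SEG
    mean_probe_intensity: float | None = None


def fit_segment_velocities(
    trajectory: EndTrajectory,
    window: float = 120.0,
    min_final_window: float = 60.0,
) -> list[VelocitySegment]:
    """OLS end velocity over consecutive non-overlapping windows.

    Windows are anchored at the trajectory's first sample; a trailing partial
    window shorter than ``min_final_window`` is dropped.  Leading windows with
    negative velocity are marked ``eliminated`` until the first
    positive-velocity window; subsequent negative windows are retained.
    Windows containing fewer than two samples are absent.
    """
    t, x = trajectory.times, trajectory.positions
    if t[-1] - t[0] < window:
        raise ValueError("trajectory shorter than one window")
    t0 = t[0]
    segments: list[VelocitySegment] = []
    start = t0
    while start < t[-1] - 1e-9:
        end = min(start + window, t[-1])
        if end - start < window and end - start < min_final_window:
            break
        mask = (t >= start - 1e-9) & (t <= end + 1e-9)
        if mask.sum() >= 2:
            # centered least-squares sums: exact on noiseless lines
            tw, xw = t[mask], x[mask]
            tc, xc = tw - tw.mean(), xw - xw.mean()
            slope = float(np.dot(tc, xc) / np.dot(tc, tc))
            segments.append(VelocitySegment(start, end, slope))
        start += window

    seen_positive = False
    for seg in segments:
        if not seen_positive:
            if seg.velocity > 0:
                seen_positive = True
            else:
                seg.classification = ELIMINATED
    return segments


def classify_segments(
    segments: list[VelocitySegment], shrink_threshold: float = -2.5
) -> list[VelocitySegment]:
    """Flag segments with velocity strictly below the threshold as shrinking.

    The comparison is strict (<), so a segment at exactly the threshold is
    retained in the growth statistics.  Eliminated segments stay eliminated.
    """
    for seg in segments:
        if seg.classification == ELIMINATED:
            continue
        seg.classification = SHRINKING if seg.velocity < shrink_threshold else GROWTH_SEG
    return segments


def end_intensity(
    kymograph: Kymograph,
    trajectory: EndTrajectory,
    lattice_len: int = 5,
    gap: int = 3,
    bg_len: int = 5,
    channel: str = "probe",
    seed_offset_nm: float = 0.0,
) -> pd.DataFrame:
    """Background-subtracted probe intensity at the tracked end, per frame.

    For each frame: mean intensity over ``lattice_len`` pixels ending at the
    tracked end position, minus the mean over ``bg_len`` solution pixels
    starting ``gap`` pixels beyond the end.  Frames with fewer than ``bg_len``
    background pixels inside the image are eliminated.  ``seed_offset_nm``
    maps trajectory coordinates (relative to the seed boundary) onto kymograph
    columns when the seed occupies the left of the image.

    Returns a DataFrame (time_s, frame, intensity) of retained frames.
    """
    if channel not in kymograph.channels:
        raise ValueError(f"channel {channel!r} not present")
    img = kymograph.channels[channel]
    n_frames, n_px = img.shape
    px = kymograph.pixel_size

    rows = []
    frame_idx = np.round(trajectory.times / kymograph.frame_interval).astype(int)
    for t, f, pos in zip(trajectory.times, frame_idx, trajectory.positions):
        if f < 0 or f >= n_frames:
            continue
        p = int(round((pos + seed_offset_nm) / px))
        if p < 0 or p >= n_px:
            continue
        bg_lo, bg_hi = p + gap + 1, p + gap + bg_len  # inclusive
        if bg_hi > n_px - 1:
            continue  # fewer than bg_len background pixels available
        lat_lo = max(0, p - lattice_len + 1)
        lattice_mean = float(np.mean(img[f, lat_lo : p + 1]))
        bg_mean = float(np.mean(img[f, bg_lo : bg_hi + 1]))
        rows.append((float(t), int(f), lattice_mean - bg_mean))
    if not rows:
        import warnings

        warnings.warn("tracked end outside the image for all frames")
    return pd.DataFrame(rows, columns=["time_s", "frame", "intensity"])


def attach_segment_intensity(
    segments: list[VelocitySegment], intensity: pd.DataFrame
) -> list[VelocitySegment]:
    """Average the per-frame end intensity over each velocity window."""
    for seg in segments:
        mask = (intensity["time_s"] >= seg.t_start - 1e-9) & (
            intensity["time_s"] < seg.t_end - 1e-9
        )
        if mask.any():
            seg.mean_probe_intensity = float(intensity.loc[mask, "intensity"].mean())
    return segments


def segments_table(segments: list[VelocitySegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t_start": s.t_start,
                "t_end": s.t_end,
                "velocity": s.velocity,
                "classification": s.classification,
                "mean_probe_intensity": s.mean_probe_intensity,
            }
            for s in segments
        ]
    )


def bin_medians(
    segments: list[VelocitySegment],
    by: str = "time",
    bin_width: float | None = None,
    value: str = "velocity",
    include_shrinking: bool = False,
) -> pd.DataFrame:
    """Per-bin medians of velocity or probe intensity across segments.

    ``by='time'`` bins align with the velocity windows (one bin per window
    start); ``by='velocity'`` uses ``bin_width`` (nm/s).  Eliminated segments
    are always excluded; shrinking segments are excluded from growth
    statistics unless requested.  Empty bins are omitted.
    """
    usable = [
        s
        for s in segments
        if s.classification != ELIMINATED
        and (include_shrinking or s.classification != SHRINKING)
    ]
    if not usable:
        raise ValueError("no non-excluded segments")
    df = segments_table(usable)
    if value not in ("velocity", "mean_probe_intensity"):
        raise ValueError("value must be 'velocity' or 'mean_probe_intensity'")
    if by == "time":
        keys = df["t_start"]
    elif by == "velocity":
        if not bin_width or bin_width <= 0:
            raise ValueError("velocity binning needs a positive bin_width")
        keys = np.floor(df["velocity"] / bin_width) * bin_width + bin_width / 2
    else:
        raise ValueError("by must be 'time' or 'velocity'")
    grouped = df.groupby(keys)[value].agg(["median", "count"]).reset_index()
    grouped.columns = ["bin", "median", "n"]
    return grouped.dropna(subset=["median"]).reset_index(drop=True)
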