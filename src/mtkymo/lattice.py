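"""Lattice-level intensity analyses.

Covers the field-level probe loading measurement (masked total intensity),
seed-versus-GDP-lattice comparison, stretch-direction profiles, damage-site
linescans, the severing-protection statistic, and rolling-ball background
subtraction.  Masks are built automatically (Otsu threshold on the
time-averaged lattice channel, dilated by one pixel) since manual masking is
not reproducible.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_dilation
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball

from .containers import Kymograph, Linescan, MicrotubuleRecord
from .dynamics import weighted_mean

__all__ = [
    "masked_field_intensity",
    "region_compare",
    "stretch_profile",
    "damage_linescans",
    "severing_timecourse",
    "rolling_ball_background",
    "mad_outliers",
]

log = logging.getLogger(__name__)


def rolling_ball_background(image: np.ndarray, radius: int = 5) -> np.ndarray:
    """Rolling-ball background subtraction; output clipped at zero.

    Structures narrower than the ball (e.g. a single-pixel microtubule ridge)
    are preserved; plateaus wider than ~2*radius are treated as background and
    removed.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    background = rolling_ball(image, radius=radius)
    return np.clip(image - background, 0.0, None)


def build_mask(lattice_stack: np.ndarray, dilate_px: int = 1) -> np.ndarray:
    """Binary microtubule mask: Otsu on the time-averaged lattice channel."""
    mean_img = np.asarray(lattice_stack, dtype=float).mean(axis=0)
    thr = threshold_otsu(mean_img)
    mask = mean_img > thr
    if dilate_px > 0:
        mask = binary_dilation(mask, iterations=dilate_px)
    if not mask.any():
        raise ValueError("empty microtubule mask")
    return mask


def masked_field_intensity(
    probe_stack: np.ndarray,
    lattice_stack: np.ndarray,
    dilate_px: int = 1,
) -> np.ndarray:
    """Per-frame total probe intensity restricted to the microtubule mask.

    Both stacks are (frames, ...) image series of matching shape; the solution
    background outside the mask is excluded from the sum.
    """
    probe = np.asarray(probe_stack, dtype=float)
    lattice = np.asarray(lattice_stack, dtype=float)
    if probe.shape != lattice.shape:
        raise ValueError("probe and lattice stacks must have matching shapes")
    mask = build_mask(lattice, dilate_px=dilate_px)
    return probe[:, mask].sum(axis=1)


def region_compare(
    seed_values,
    gdp_values,
) -> dict:
    """Compare per-microtubule probe means on seed vs pre-existing GDP regions.

    ``seed_values`` and ``gdp_values`` are per-microtubule region means
    (paired by microtubule is not assumed).  Returns means, SDs and Welch's
    unequal-variance t-test.  Identical degenerate samples return p = 1.
    """
    a = np.asarray(seed_values, dtype=float)
    b = np.asarray(gdp_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both regions must be non-empty")
    degenerate = a.max() == a.min() and b.max() == b.min()
    if degenerate and a[0] == b[0]:
        t_stat, p = 0.0, 1.0  # identical constant samples
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "seed_mean": float(np.mean(a)),
        "seed_sd": float(np.std(a, ddof=1)) if a.size > 1 else 0.0,
        "gdp_mean": float(np.mean(b)),
        "gdp_sd": float(np.std(b, ddof=1)) if b.size > 1 else 0.0,
        "t": float(t_stat),
        "p_value": float(p),
        "n_seed": int(a.size),
        "n_gdp": int(b.size),
    }


def region_means_from_kymo(
    kymograph: Kymograph,
    seed_cols: slice,
    gdp_cols: slice,
    channel: str = "probe",
) -> tuple[float, float]:
    """Mean probe intensity over the seed and GDP column ranges of one kymograph."""
    img = kymograph.channels[channel]
    return float(img[:, seed_cols].mean()), float(img[:, gdp_cols].mean())


def stretch_profile(
    kymograph: Kymograph,
    initiation_px: int,
    frame: int,
    linescan_px: int = 20,
    channel: str = "probe",
    growth_direction: int = +1,
) -> pd.DataFrame:
    """Probe linescan centered on a stretch initiation point, center-normalized.

    Measures ``linescan_px`` pixels centered on ``initiation_px`` at ``frame``
    and divides by the center value, so the center reads 1.0.  The returned
    offsets are oriented so positive offsets point toward the direction of
    microtubule growth.  Raises if the initiation point is closer than half
    the linescan to the image edge.
    """
    img = kymograph.channels[channel]
    half = linescan_px // 2
    if initiation_px - half < 0 or initiation_px + half - 1 >= img.shape[1]:
        raise ValueError("initiation point too close to the image edge")
    if not (0 <= frame < img.shape[0]):
        raise ValueError("frame outside the movie")
    profile = img[frame, initiation_px - half : initiation_px + half].astype(float)
    offsets = np.arange(-half, half)
    center = profile[half]
    if center == 0:
        raise ValueError("zero intensity at the initiation point")
    if growth_direction < 0:
        offsets = -offsets[::-1]
        profile = profile[::-1]
    return pd.DataFrame(
        {
            "offset_px": offsets,
            "offset_um": offsets * kymograph.pixel_size / 1000.0,
            "relative_intensity": profile / center,
        }
    )


def find_stretch_trigger_frame(
    kymograph: Kymograph,
    initiation_px: int,
    trigger_length_um: float = 2.0,
    channel: str = "probe",
    level: float | None = None,
) -> int | None:
    """First frame where the contiguous above-threshold run through the
    initiation point reaches ``trigger_length_um``; None if never."""
    img = kymograph.channels[channel]
    thr = level if level is not None else 0.5 * img.max()
    need_px = int(np.ceil(trigger_length_um * 1000.0 / kymograph.pixel_size))
    for f in range(img.shape[0]):
        row = img[f] > thr
        if not row[initiation_px]:
            continue
        lo = initiation_px
        while lo > 0 and row[lo - 1]:
            lo -= 1
        hi = initiation_px
        while hi < row.size - 1 and row[hi + 1]:
            hi += 1
        if hi - lo + 1 >= need_px:
            return f
    return None


def damage_linescans(
    kymograph: Kymograph,
    times: list[float],
    channels: tuple[str, ...] = ("lattice", "probe"),
    normalize: bool = False,
) -> list[Linescan]:
    """Per-channel linescans along the microtubule at the requested times.

    Times outside the movie are skipped with a log entry.  With
    ``normalize=True`` each channel is min-max scaled to [0, 1] per linescan.
    """
    out = []
    n_frames = kymograph.n_frames
    positions = np.arange(kymograph.n_pixels) * kymograph.pixel_size / 1000.0
    for t in times:
        f = int(round(t / kymograph.frame_interval))
        if f < 0 or f >= n_frames:
            log.info("requested time %s s outside movie; skipped", t)
            continue
        chans = {}
        for name in channels:
            vals = kymograph.channels[name][f].astype(float)
            if normalize:
                span = vals.max() - vals.min()
                vals = (vals - vals.min()) / span if span > 0 else np.zeros_like(vals)
            chans[name] = vals
        out.append(Linescan(positions_um=positions.copy(), channels=chans, time_s=float(t)))
    return out


def mad_outliers(values, threshold: float = 3.0) -> np.ndarray:
    """Boolean outlier flags by the 3-scaled-MAD-from-median rule."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = stats.median_abs_deviation(values, scale="normal")
    if mad == 0:
        return values != med
    return np.abs(values - med) > threshold * mad


def severing_timecourse(
    records: list[MicrotubuleRecord],
    threshold: float = 0.2,
    baseline: tuple[float, float] = (0.0, 60.0),
    consecutive: int = 2,
    mad_threshold: float = 3.0,
) -> pd.DataFrame:
    """Severing-protection statistic per field of view.

    For each field: normalize every record to its own baseline window, average
    the control (non-coated) records per frame, find the first time the
    control mean stays below ``threshold`` for ``consecutive`` frames, then
    sample every record's normalized intensity at that time.  Population
    values per field combine single microtubules by 1/SE^2 weights after
    removing 3-scaled-MAD outliers.  Fields whose control never crosses the
    threshold are excluded with a log entry.

    Returns one row per field: threshold_time_s, control/coated weighted
    means and SEs, counts, and outliers removed.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    fields = sorted({r.field_id for r in records})
    for field in fields:
        recs = [r.normalized(baseline) for r in records if r.field_id == field]
        controls = [r for r in recs if not r.coated]
        coated = [r for r in recs if r.coated]
        if not controls or not coated:
            log.info("field %s lacks a control or coated population; skipped", field)
            continue
        times = controls[0].times
        ctrl_mean = np.mean([r.intensity for r in controls], axis=0)
        below = ctrl_mean < threshold
        t_idx = None
        run = 0
        for i, flag in enumerate(below):
            run = run + 1 if flag else 0
            if run >= consecutive:
                t_idx = i - consecutive + 1
                break
        if t_idx is None:
            log.info("field %s: control never fell below %.0f%%; excluded", field, 100 * threshold)
            continue
        t_star = float(times[t_idx])

        def population(rs):
            vals = np.array([r.intensity[t_idx] for r in rs])
            ses = np.array([max(r.intensity_se[t_idx], 1e-12) for r in rs])
            keep = ~mad_outliers(vals, threshold=mad_threshold)
            if keep.sum() == 0:
                keep = np.ones_like(keep)
            mean, se = weighted_mean(vals[keep], ses[keep])
            return mean, se, int(keep.sum()), int((~keep).sum())

        c_mean, c_se, c_n, c_out = population(controls)
        s_mean, s_se, s_n, s_out = population(coated)
        rows.append(
            {
                "field_id": field,
                "threshold_time_s": t_star,
                "control_mean": c_mean,
                "control_se": c_se,
                "n_control": c_n,
                "control_outliers": c_out,
                "coated_mean": s_mean,
                "coated_se": s_se,
                "n_coated": s_n,
                "coated_outliers": s_out,
            }
        )
    if not rows:
        raise ValueError("no field produced a threshold crossing")
    return pd.DataFrame(rows)
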