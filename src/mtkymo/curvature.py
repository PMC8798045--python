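"""Curvature along traced microtubules and the intensity-curvature regression.

Curvature magnitude is estimated at every interior trace point as the inverse
circumradius of the circle through three neighboring points of a boxcar
smoothed polyline; endpoints copy the nearest interior value.  Samples are
pooled across microtubules into 0.1 um^-1 curvature bins, intensity outliers
are rejected per bin with the 3-scaled-MAD rule, and an ordinary
least-squares line is fitted to the bin means to test for an
intensity-curvature dependence.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import median_abs_deviation

__all__ = [
    "polyline_curvature",
    "sample_intensity",
    "bin_and_filter",
    "fit_intensity_vs_curvature",
]


def _smooth(coords: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar; near the ends the window shrinks symmetrically so the
    smoothed point stays centered (an asymmetric window would drag endpoints
    inward and bias the curvature there)."""
    if window <= 1:
        return coords
    out = np.empty_like(coords)
    n = len(coords)
    half = window // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = coords[i - h : i + h + 1].mean(axis=0)
    return out


def _circumcurvature(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Unsigned curvature (1/R) of the circle through three points; 0 if collinear."""
    ab, ac, bc = b - a, c - a, c - b
    cross = abs(ab[0] * ac[1] - ab[1] * ac[0])
    denom = np.linalg.norm(ab) * np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        return 0.0
    return float(2.0 * cross / denom)


def polyline_curvature(
    coords,
    smoothing: int = 5,
    intensities=None,
) -> pd.DataFrame:
    """Per-point curvature samples for one traced filament.

    Parameters
    ----------
    coords : (n, 2) array of (x, y) in um, ordered along the filament with
        roughly uniform spacing.
    smoothing : boxcar window (points) applied to the coordinates before the
        three-point circumcircle estimate; 1 disables smoothing.
    intensities : optional per-point probe intensities to carry along.

    Returns a DataFrame with columns ``arclength_um``, ``curvature_per_um``
    and (if given) ``intensity``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 trace points")
    seglen = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(seglen == 0):
        raise ValueError("duplicated consecutive trace points")
    arclength = np.concatenate([[0.0], np.cumsum(seglen)])

    sm_coords = _smooth(coords, smoothing)
    kappa = np.empty(n)
    for i in range(1, n - 1):
        kappa[i] = _circumcurvature(sm_coords[i - 1], sm_coords[i], sm_coords[i + 1])
    kappa[0], kappa[-1] = kappa[1], kappa[-2]

    out = pd.DataFrame({"arclength_um": arclength, "curvature_per_um": kappa})
    if intensities is not None:
        intensities = np.asarray(intensities, dtype=float)
        if intensities.shape[0] != n:
            raise ValueError("intensities must match the number of trace points")
        out["intensity"] = intensities
    return out


def sample_intensity(image: np.ndarray, coords_um, pixel_size_nm: float = 160.0):
    """Nearest-pixel image intensity at each (x, y) um trace point."""
    image = np.asarray(image, dtype=float)
    coords = np.asarray(coords_um, dtype=float).reshape(-1, 2)
    px = pixel_size_nm / 1000.0
    cols = np.clip(np.round(coords[:, 0] / px).astype(int), 0, image.shape[1] - 1)
    rows = np.clip(np.round(coords[:, 1] / px).astype(int), 0, image.shape[0] - 1)
    return image[rows, cols]


def bin_and_filter(
    samples: pd.DataFrame,
    bin_width: float = 0.1,
    mad_threshold: float = 3.0,
) -> pd.DataFrame:
    """Bin curvature samples and reject per-bin intensity outliers.

    Samples fall into bins (k*w, (k+1)*w] with centers (k+0.5)*w (a sample on
    a boundary goes to the lower bin; curvature 0 goes to the first bin).
    Within each bin, intensities farther than ``mad_threshold`` scaled median
    absolute deviations from the bin median are flagged as outliers; the bin
    mean and SD are computed on the retained samples.  Empty bins are omitted.
    """
    if samples.empty:
        raise ValueError("no samples to bin")
    if "intensity" not in samples.columns:
        raise ValueError("samples must carry an 'intensity' column")
    kappa = samples["curvature_per_um"].to_numpy()
    idx = np.ceil(kappa / bin_width).astype(int) - 1
    idx[kappa <= 0] = 0
    idx = np.maximum(idx, 0)

    rows = []
    for k in np.unique(idx):
        vals = samples["intensity"].to_numpy()[idx == k]
        med = np.median(vals)
        mad = median_abs_deviation(vals, scale="normal")
        if mad > 0:
            keep = np.abs(vals - med) <= mad_threshold * mad
        else:
            keep = vals == med
        kept = vals[keep]
        if kept.size == 0:
            continue
        rows.append(
            {
                "bin_center": (k + 0.5) * bin_width,
                "mean_intensity": float(np.mean(kept)),
                "sd_intensity": float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0,
                "n": int(kept.size),
                "n_outliers": int(vals.size - kept.size),
            }
        )
    return pd.DataFrame(rows)


def fit_intensity_vs_curvature(binned: pd.DataFrame):
    """OLS of bin-mean intensity on bin-center curvature.

    Returns a dict with ``slope`` (a.u. x um), its 95% CI, the two-sided p
    for slope = 0, and the intercept.  Requires at least 3 bins.
    """
    if len(binned) < 3:
        raise ValueError("need at least 3 bins for the regression")
    X = sm.add_constant(binned["bin_center"].to_numpy())
    model = sm.OLS(binned["mean_intensity"].to_numpy(), X).fit()
    ci = model.conf_int(alpha=0.05)
    return {
        "slope": float(model.params[1]),
        "slope_ci95": (float(ci[1][0]), float(ci[1][1])),
        "p_value": float(model.pvalues[1]),
        "intercept": float(model.params[0]),
        "n_bins": int(len(binned)),
    }
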