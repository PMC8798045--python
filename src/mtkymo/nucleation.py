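"""Templated-nucleation counting and the sigmoid concentration fit.

A seed counts as nucleated if it grows at least one extension longer than
3 pixels (480 nm) within the 15-min observation.  The fraction of nucleated
seeds versus tubulin concentration x is fitted with a Hill-type sigmoid
y = x^s / (C^s + x^s), where C is the half-maximal concentration (uM) and s
the steepness.  Per-condition errors use the counting rule sqrt(N)/total,
with the special case 1/total when no seed nucleated; the literal N/total
reading is available as an option.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

from .containers import NucleationDataset, SigmoidFit
from .simgen import hill

__all__ = ["count_nucleated", "fraction_error", "fit_sigmoid"]


def count_nucleated(
    df,
    min_length: float = 480.0,
    window: float = 900.0,
) -> NucleationDataset:
    """Count nucleated seeds from per-seed extension-length measurements.

    ``df`` needs columns ``x_uM``, ``seed_id``, ``length_nm`` and optionally
    ``time_s`` (rows outside ``window`` are ignored).  A seed is nucleated iff
    any of its extensions is strictly longer than ``min_length`` within the
    window.
    """
    required = {"x_uM", "seed_id", "length_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("no seeds to count")
    # the seed universe is fixed before the time filter: a seed whose only
    # measurements fall outside the window still counts as observed
    universe = df[["x_uM", "seed_id"]].drop_duplicates()
    if "time_s" in df.columns:
        df = df[df["time_s"] <= window]
    per_seed = df.groupby(["x_uM", "seed_id"])["length_nm"].max()
    hit = (per_seed > min_length)  # strict: exactly min_length is not enough
    nucleated = hit.reindex(
        pd.MultiIndex.from_frame(universe), fill_value=False
    ).astype(bool)
    agg = nucleated.groupby("x_uM").agg(["sum", "count"])
    return NucleationDataset(
        x_uM=agg.index.to_numpy(dtype=float),
        seeds_total=agg["count"].to_numpy(),
        seeds_nucleated=agg["sum"].to_numpy().astype(int),
    )


def fraction_error(N: int, total: int, rule: str = "sqrt") -> float:
    """Error on the nucleated fraction N/total.

    ``rule='sqrt'`` (default) returns sqrt(N)/total for N>0 and 1/total for
    N=0; ``rule='literal'`` returns N/total (with the same N=0 special case),
    the published wording taken at face value.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if N < 0 or N > total:
        raise ValueError("N must lie in [0, total]")
    if N == 0:
        return 1.0 / total
    if rule == "sqrt":
        return float(np.sqrt(N)) / total
    if rule == "literal":
        return N / total
    raise ValueError("rule must be 'sqrt' or 'literal'")


def dataset_errors(dataset: NucleationDataset, rule: str = "sqrt") -> np.ndarray:
    return np.array(
        [
            fraction_error(int(n), int(tot), rule=rule)
            for n, tot in zip(dataset.seeds_nucleated, dataset.seeds_total)
        ]
    )


def _fit_core(x, y, sigma):
    pos = x > 0
    C0 = float(x[pos][np.argmin(np.abs(y[pos] - 0.5))]) if pos.any() else 1.0
    popt, pcov = curve_fit(
        hill,
        x,
        y,
        p0=[C0, 4.0],
        sigma=sigma,
        absolute_sigma=False,
        bounds=([1e-9, 1e-9], [10.0 * float(x.max()), 50.0]),
        maxfev=20000,
    )
    return popt, pcov


def fit_sigmoid(
    dataset: NucleationDataset,
    weighted: bool = False,
    error_rule: str = "sqrt",
    ci_method: str = "bootstrap",
    n_boot: int = 199,
) -> SigmoidFit:
    """Nonlinear least-squares fit of y = x^s / (C^s + x^s) to the fractions.

    Initialization takes C0 as the concentration whose fraction is nearest
    0.5 and s0 = 4, with bounds C in (0, 10*max x] and s in (0, 50] to avoid
    the flat-likelihood region at tiny steepness.  The fit is unweighted by
    default; ``weighted=True`` uses the per-condition counting errors as
    sigma.

    95% CIs use a parametric binomial bootstrap by default (counts resampled
    from the fitted curve at the observed seeds_total, refit, percentile
    interval; internally seeded, so deterministic): per-condition noise is
    binomial and strongly heteroscedastic, which the linearized covariance
    understates.  ``ci_method='linearized'`` selects the classic covariance
    CI (t quantile, n-2 dof).
    """
    x = dataset.x_uM
    y = dataset.fraction
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(y, y[0]):
        raise ValueError("fractions are all equal; sigmoid not identifiable")
    if np.all(y == 0):
        raise ValueError("all fractions are zero")

    sigma = None
    if weighted:
        sigma = dataset_errors(dataset, rule=error_rule)
        sigma = np.clip(sigma, 1e-6, None)
    try:
        popt, pcov = _fit_core(x, y, sigma)
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"sigmoid fit did not converge: {err}") from err
    C_hat, s_hat = float(popt[0]), float(popt[1])
    resid = y - hill(x, C_hat, s_hat)
    rss = float(np.sum(resid**2))

    if ci_method == "bootstrap":
        rng = np.random.default_rng(0)  # fixed stream keeps the fit deterministic
        p_fit = np.clip(hill(x, C_hat, s_hat), 0.0, 1.0)
        C_bs, s_bs = [], []
        for _ in range(n_boot):
            y_bs = rng.binomial(dataset.seeds_total, p_fit) / dataset.seeds_total
            try:
                pb, _ = _fit_core(x, y_bs, sigma)
            except RuntimeError:  # pragma: no cover - rare non-convergence
                continue
            C_bs.append(pb[0])
            s_bs.append(pb[1])
        C_ci = tuple(float(v) for v in np.percentile(C_bs, [2.5, 97.5]))
        s_ci = tuple(float(v) for v in np.percentile(s_bs, [2.5, 97.5]))
    elif ci_method == "linearized":
        dof = max(1, x.size - 2)
        tq = float(t_dist.ppf(0.975, dof))
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        C_ci = (C_hat - tq * float(se[0]), C_hat + tq * float(se[0]))
        s_ci = (s_hat - tq * float(se[1]), s_hat + tq * float(se[1]))
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'linearized'")
    return SigmoidFit(
        C=C_hat,
        C_ci95=C_ci,
        s=s_hat,
        s_ci95=s_ci,
        rss=rss,
        n_points=int(x.size),
    )
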