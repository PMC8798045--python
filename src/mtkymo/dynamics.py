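"""Dynamic-instability parameters from phase-annotated end trajectories.

Measurement conventions follow the standard kymograph workflow: catastrophe
frequency is the number of catastrophes per total time in growth; rescue is
counted per total shrinkage length; dynamicity is total length grown plus lost
divided by the observation time, with error pixel_size * N / T where N is the
number of marked points.  Catastrophe/rescue errors are counting errors
(sqrt(n) over the same denominator).  Rates are pooled across phases with
duration (growth) or length (shrink) weights, and replicates combine by
inverse-variance weighted means.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import median_abs_deviation

from .containers import (
    GROWTH,
    SHRINK,
    DynamicsSummary,
    EndTrajectory,
    PhaseAnnotation,
)

__all__ = [
    "segment_phases",
    "annotation_from_truth",
    "compute_dynamics",
    "weighted_mean",
]

#: a phase needs at least this many samples for a slope fit that excludes the
#: (phase-ambiguous) boundary samples; shorter phases get rate_ok=False
_MIN_SAMPLES_FOR_RATE = 4


def annotation_from_truth(trajectory: EndTrajectory) -> PhaseAnnotation:
    """Exact PhaseAnnotation from a simulated trajectory's ground truth."""
    if trajectory.truth_phases is None:
        raise ValueError("trajectory carries no truth phases")
    labels = [p[2] for p in trajectory.truth_phases]
    if trajectory.truth_vertices is not None:
        verts = trajectory.truth_vertices
    else:
        vt = np.array(
            [trajectory.truth_phases[0][0]] + [p[1] for p in trajectory.truth_phases]
        )
        verts = np.column_stack(
            [vt, np.interp(vt, trajectory.times, trajectory.positions)]
        )
    return PhaseAnnotation(
        vertices=verts,
        labels=labels,
        observation_time=trajectory.duration,
        n_marks=len(labels) + 1,
        rate_ok=[True] * len(labels),
    )


def _phase_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal equal-label interval runs as inclusive sample ranges (a, b)."""
    runs = []
    start = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            runs.append((start, i))
            start = i
    runs.append((start, len(labels)))
    return runs


def _merge_small(runs, labels, x, min_disp):
    """Merge phases with net displacement below min_disp into their neighbors."""
    runs = list(runs)
    labs = [labels[a] for a, _ in runs]
    while len(runs) > 1:
        disp = [abs(x[b] - x[a]) for a, b in runs]
        k = int(np.argmin(disp))
        if disp[k] >= min_disp:
            break
        if k == 0:
            runs[1] = (runs[0][0], runs[1][1])
            del runs[0], labs[0]
        elif k == len(runs) - 1:
            runs[-2] = (runs[-2][0], runs[-1][1])
            del runs[-1], labs[-1]
        else:
            # neighbors share a label (alternation), absorb all three
            runs[k - 1] = (runs[k - 1][0], runs[k + 1][1])
            del runs[k : k + 2]
            del labs[k : k + 2]
    return runs, labs


def _fit_line(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """OLS line (slope, intercept); exact for collinear input."""
    if t.size == 2:
        slope = (x[1] - x[0]) / (t[1] - t[0])
        return float(slope), float(x[0] - slope * t[0])
    slope, intercept = np.polyfit(t, x, 1)
    return float(slope), float(intercept)


def _run_line(t, x, a, b):
    """Fitted line of run samples a..b, excluding the (phase-ambiguous)
    boundary samples when enough remain."""
    ts, vals = t[a : b + 1], x[a : b + 1]
    if ts.size >= _MIN_SAMPLES_FOR_RATE:
        return _fit_line(ts[1:-1], vals[1:-1])
    return _fit_line(ts, vals)


def _line_dist(line, t, x) -> float:
    m, c = line
    return abs(x - (m * t + c))


def _split_hidden(t, x, a, b, label, tol):
    """Recursively split a run whose interior samples are not collinear.

    An excursion that starts and ends between two consecutive samples leaves
    no sign reversal, only an offset between the lines the samples before and
    after lie on.  Such jumps are located at the largest residual step and
    replaced by a short bridge segment of the opposite phase whose endpoints
    come from the two sub-run lines.  Bridges carry ``rate_ok=False``: the
    excursion's speed is not identifiable from the samples.

    Returns a list of items: ("run", a, b, label, line, rate_ok) and
    ("bridge", t0, x0, t1, x1, label).
    """
    n = b - a + 1
    line = _run_line(t, x, a, b)
    ok = n >= _MIN_SAMPLES_FOR_RATE
    if n < 5:
        if n == _MIN_SAMPLES_FOR_RATE:
            # two interior points are always collinear; require a boundary
            # sample on the same line as evidence the run is a single phase
            ok = (
                _line_dist(line, t[a], x[a]) <= tol
                or _line_dist(line, t[b], x[b]) <= tol
            )
        return [("run", a, b, label, line, ok)]
    ts, vals = t[a + 1 : b], x[a + 1 : b]
    m, c = _fit_line(ts, vals)
    resid = vals - (m * ts + c)
    if np.max(np.abs(resid)) <= tol:
        return [("run", a, b, label, line, ok)]
    j = a + 1 + int(np.argmax(np.abs(np.diff(resid))))
    if j <= a or j + 1 >= b:
        return [("run", a, b, label, line, False)]
    left = _split_hidden(t, x, a, j, label, tol)
    right = _split_hidden(t, x, j + 1, b, label, tol)
    m1, c1 = left[-1][4]
    m2, c2 = right[0][4]
    dt = t[j + 1] - t[j]
    if label == GROWTH:
        # hidden catastrophe (+ seed return or rescue) between samples j, j+1
        t0b = t[j + 1] - 0.01 * dt
        x0b, x1b = m1 * t0b + c1, m2 * t[j + 1] + c2
        if x1b >= x0b:  # not a downward offset; leave the run intact
            return [("run", a, b, label, line, False)]
        bridge = ("bridge", t0b, x0b, float(t[j + 1]), x1b, SHRINK)
    else:
        # hidden rescue + catastrophe: the later shrink line lies above
        tm = 0.5 * (t[j] + t[j + 1])
        t0b, t1b = tm - 0.01 * dt, tm + 0.01 * dt
        x0b, x1b = m1 * t0b + c1, m2 * t1b + c2
        if x1b <= x0b:
            return [("run", a, b, label, line, False)]
        bridge = ("bridge", t0b, x0b, t1b, x1b, GROWTH)
    return left + [bridge] + right


def _disjoint_runs(runs, labs):
    """Convert shared-boundary runs to disjoint sample ranges; runs emptied by
    the conversion (single-interval reversals) come back as None markers."""
    out = []
    for k, ((a, b), lab) in enumerate(zip(runs, labs)):
        s = a if k == 0 else a + 1
        out.append([s, b, lab] if b - s >= 1 else None)
    return out


def _peel_and_orphan(t, x, segs, tol):
    """Reassign or detach boundary samples that do not lie on their run's line.

    Peeling moves an edge sample to the neighboring run when it fits that
    run's line; orphaning detaches edge samples that fit neither line (they
    mark sub-frame excursions).  Returns (segs, lines, orphan pools), where
    pool i holds (t, x) points located between run i-1 and run i.
    """
    lines = [_run_line(t, x, s, e) for s, e, _ in segs]
    for _ in range(2):
        moved = False
        for i in range(len(segs) - 1):
            L, R = segs[i], segs[i + 1]
            while L[1] - L[0] >= 2:
                e = L[1]
                if (
                    _line_dist(lines[i], t[e], x[e]) > tol
                    and _line_dist(lines[i + 1], t[e], x[e]) <= tol
                ):
                    L[1] -= 1
                    R[0] = e
                    lines[i] = _run_line(t, x, L[0], L[1])
                    lines[i + 1] = _run_line(t, x, R[0], R[1])
                    moved = True
                else:
                    break
            while R[1] - R[0] >= 2:
                s = R[0]
                if (
                    _line_dist(lines[i + 1], t[s], x[s]) > tol
                    and _line_dist(lines[i], t[s], x[s]) <= tol
                ):
                    R[0] += 1
                    L[1] = s
                    lines[i] = _run_line(t, x, L[0], L[1])
                    lines[i + 1] = _run_line(t, x, R[0], R[1])
                    moved = True
                else:
                    break
        if not moved:
            break

    orphans = [[] for _ in range(len(segs) + 1)]
    for i, seg in enumerate(segs):
        if i < len(segs) - 1:
            for _ in range(2):
                e = seg[1]
                if seg[1] - seg[0] < 2:
                    break
                if (
                    _line_dist(lines[i], t[e], x[e]) > tol
                    and _line_dist(lines[i + 1], t[e], x[e]) > tol
                ):
                    orphans[i + 1].insert(0, (float(t[e]), float(x[e])))
                    seg[1] -= 1
                    lines[i] = _run_line(t, x, seg[0], seg[1])
                else:
                    break
        if i > 0:
            for _ in range(2):
                s = seg[0]
                if seg[1] - seg[0] < 2:
                    break
                if (
                    _line_dist(lines[i], t[s], x[s]) > tol
                    and _line_dist(lines[i - 1], t[s], x[s]) > tol
                ):
                    orphans[i].append((float(t[s]), float(x[s])))
                    seg[0] += 1
                    lines[i] = _run_line(t, x, seg[0], seg[1])
                else:
                    break
    return segs, lines, orphans


class _Assembler:
    """Accumulates vertices and per-segment labels/reliability flags."""

    def __init__(self, t0: float, x0: float):
        self.vt = [float(t0)]
        self.vx = [float(x0)]
        self.labels: list[str] = []
        self.ok: list[bool] = []

    def add(self, ti: float, xi: float, label: str, ok: bool) -> None:
        ti = max(float(ti), self.vt[-1] + 1e-9)
        self.vt.append(ti)
        self.vx.append(float(xi))
        self.labels.append(label)
        self.ok.append(ok)

    def connect(self, ti: float, xi: float, ok: bool = False) -> None:
        """Segment labeled by the sign of its displacement."""
        lab = GROWTH if xi >= self.vx[-1] else SHRINK
        self.add(ti, xi, lab, ok)


def _assemble(t, sequence, trace_t0, trace_t1):
    """Turn the element sequence (runs, bridges, orphans) into vertices."""
    first = next(el for el in sequence if el[0] == "run")
    m0, c0 = first[4]
    asm = _Assembler(trace_t0, m0 * trace_t0 + c0)
    for i, el in enumerate(sequence):
        if el[0] == "orphan":
            asm.connect(el[1], el[2])
            continue
        if el[0] == "bridge":
            _, t0b, x0b, t1b, x1b, lab = el
            asm.add(t1b, x1b, lab, False)
            continue
        _, a, b, lab, (m1, c1), ok = el
        if i > 0 and sequence[i - 1][0] == "orphan":
            # connector from the orphan point down/up to this run's line
            asm.connect(t[a], m1 * t[a] + c1)
        nxt = sequence[i + 1] if i + 1 < len(sequence) else None
        if nxt is None:
            asm.add(trace_t1, m1 * trace_t1 + c1, lab, ok)
        elif nxt[0] == "orphan":
            asm.add(t[b], m1 * t[b] + c1, lab, ok)
        elif nxt[0] == "bridge":
            asm.add(nxt[1], nxt[2], lab, ok)
        else:  # run
            m2, c2 = nxt[4]
            if lab != nxt[3] and abs(m1 - m2) > 1e-12:
                t_lo = max(t[b], trace_t0 + 1e-9)
                t_hi = min(t[nxt[1]], trace_t1 - 1e-9)
                ti = (c2 - c1) / (m1 - m2)
                eps = 1e-6 * max(1.0, abs(t_hi))  # float slack at window edges
                if t_lo - eps <= ti <= t_hi + eps:
                    ti = float(np.clip(ti, t_lo, t_hi))
                    asm.add(ti, m1 * ti + c1, lab, ok)
                else:
                    # lines do not cross between the runs (a sub-frame
                    # excursion separates them): explicit connector
                    asm.add(t[b], m1 * t[b] + c1, lab, ok)
                    asm.connect(t[nxt[1]], m2 * t[nxt[1]] + c2)
            else:
                # same-label or parallel lines: explicit connector
                asm.add(t[b], m1 * t[b] + c1, lab, ok)
                asm.connect(t[nxt[1]], m2 * t[nxt[1]] + c2)
    return asm


def _estimate_speeds(asm: _Assembler):
    """Duration/length-weighted speeds from the reliable segments."""
    vg_num = vg_den = vs_num = vs_den = 0.0
    for i, lab in enumerate(asm.labels):
        if not asm.ok[i]:
            continue
        dt = asm.vt[i + 1] - asm.vt[i]
        dx = asm.vx[i + 1] - asm.vx[i]
        if dt <= 0:
            continue
        if lab == GROWTH:
            vg_num += abs(dx)
            vg_den += dt
        else:
            vs_num += abs(dx)
            vs_den += dt
    v_g = vg_num / vg_den if vg_den > 0 else None
    v_s = vs_num / vs_den if vs_den > 0 else None
    return v_g, v_s


def _repair_slow_shrinks(
    asm: _Assembler,
    frame_interval: float,
    tol: float,
    slope_fraction: float = 0.9,
):
    """Reconstruct sub-frame excursions inside flagged descending segments.

    A descending segment much slower than the shrinkage speed cannot be a pure
    shrinkage phase; with the two speeds estimated from reliable segments the
    unique single-transition reconstruction is a peak (growth, then shrink)
    when the previous phase was growth, or a valley (shrink, then growth) when
    it was shrinkage.  The inserted vertex restores the transition the
    sampling hid.  Only segments flagged rate_ok=False are touched.
    """
    v_g, v_s = _estimate_speeds(asm)
    if not v_g or not v_s or v_g <= 0 or v_s <= 0:
        return asm
    vt, vx = list(asm.vt), list(asm.vx)
    labels, ok = list(asm.labels), list(asm.ok)
    i = 0
    while i < len(labels):
        dt = vt[i + 1] - vt[i]
        dx = vx[i + 1] - vx[i]
        if (
            labels[i] == SHRINK
            and not ok[i]
            and dt >= 0.5 * frame_interval
            and abs(dx) / dt < slope_fraction * v_s
        ):
            prev_growth = i > 0 and labels[i - 1] == GROWTH
            if prev_growth:
                # peak: growth for tau, then shrink
                tau = (dx + v_s * dt) / (v_g + v_s)
                if 0.05 * dt < tau < 0.95 * dt and v_g * tau > tol:
                    tp = vt[i] + tau
                    xp = vx[i] + v_g * tau
                    vt.insert(i + 1, tp)
                    vx.insert(i + 1, xp)
                    labels[i] = GROWTH
                    labels.insert(i + 1, SHRINK)
                    ok.insert(i + 1, False)
                    i += 2
                    continue
            elif i > 0 and labels[i - 1] == SHRINK:
                # valley: shrink for tau, then growth
                tau = (-dx + v_g * dt) / (v_g + v_s)
                xv = vx[i] - v_s * tau
                if 0.05 * dt < tau < 0.95 * dt and xv > -2 * tol:
                    tv = vt[i] + tau
                    vt.insert(i + 1, tv)
                    vx.insert(i + 1, max(xv, 0.0))
                    labels.insert(i + 1, GROWTH)
                    ok.insert(i + 1, False)
                    i += 2
                    continue
        i += 1
    out = _Assembler(vt[0], vx[0])
    out.vt, out.vx, out.labels, out.ok = vt, vx, labels, ok
    return out


def segment_phases(
    trajectory: EndTrajectory,
    min_event_displacement: float = 480.0,
    smooth_window: int = 1,
    use_truth: bool = False,
    split_tolerance_nm: float | None = None,
    repair: bool = True,
) -> PhaseAnnotation:
    """Automatic piecewise-linear phase segmentation of an end trajectory.

    The detection pipeline: (1) interval displacement signs define candidate
    growth/shrink runs; (2) reversals with net displacement below
    ``min_event_displacement`` (default 3 px = 480 nm) are merged into the
    surrounding phase; (3) boundary samples are reassigned to the neighboring
    run when they lie on its fitted line, or detached as orphan points when
    they lie on neither (sub-frame excursions); (4) runs whose interior
    samples are not collinear within ``split_tolerance_nm`` are split at the
    offset; (5) phase boundaries are refined to the intersections of the
    per-phase fitted lines; (6) with ``repair=True``, descending connector
    segments far slower than the estimated shrinkage speed are resolved into
    the peak or valley vertex the frame sampling hid.

    ``split_tolerance_nm=None`` estimates the tolerance from the trace's
    second differences, so it adapts to the noise level.  Set
    ``smooth_window`` > 1 (boxcar samples) for noisy traces.
    ``use_truth=True`` bypasses detection when ground-truth phases exist.
    """
    if trajectory.times.size < 3:
        raise ValueError("trajectory too short to segment (need >= 3 samples)")
    if use_truth and trajectory.truth_phases is not None:
        return annotation_from_truth(trajectory)

    t = trajectory.times
    x = trajectory.positions.astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        xs = np.convolve(x, kernel, mode="same")
        half = smooth_window // 2
        xs[:half] = x[:half]  # kernel truncated at the edges
        xs[-half:] = x[-half:]
    else:
        xs = x

    if split_tolerance_nm is None:
        d2 = np.diff(xs, 2)
        sigma = median_abs_deviation(d2, scale="normal") / np.sqrt(6.0)
        split_tolerance_nm = max(5.0 * float(sigma), 1.0)
    tol = split_tolerance_nm

    d = np.diff(xs)
    sign_labels = np.where(d >= 0, GROWTH, SHRINK)
    runs, labs = _merge_small(
        _phase_runs(sign_labels), sign_labels, xs, min_event_displacement
    )
    segs_or_none = _disjoint_runs(runs, labs)
    singles = [
        (float(t[s]), float(xs[s]))
        for sn, (a, b) in zip(segs_or_none, runs)
        for s in ([b] if sn is None else [])
    ]
    segs = [sg for sg in segs_or_none if sg is not None]
    if not segs:
        raise ValueError("no resolvable phases in trajectory")

    segs, lines, orphans = _peel_and_orphan(t, xs, segs, tol)
    # single-interval reversals emptied by the disjoint conversion behave
    # like orphans: re-insert them into the pools by time
    for pt in singles:
        for i, sg in enumerate(segs):
            if pt[0] < t[sg[0]]:
                orphans[i].append(pt)
                orphans[i].sort()
                break
        else:
            orphans[len(segs)].append(pt)

    sequence = []
    for i, sg in enumerate(segs):
        for pt in orphans[i]:
            sequence.append(("orphan", pt[0], pt[1]))
        sequence.extend(_split_hidden(t, xs, sg[0], sg[1], sg[2], tol))
    for pt in orphans[len(segs)]:
        sequence.append(("orphan", pt[0], pt[1]))

    asm = _assemble(t, sequence, float(t[0]), float(t[-1]))
    if repair:
        asm = _repair_slow_shrinks(asm, trajectory.frame_interval, tol)

    # on very noisy data refined displacements can slightly contradict their
    # labels; coerce instead of failing
    verts = np.column_stack([asm.vt, asm.vx])
    for i, lab in enumerate(asm.labels):
        dxi = verts[i + 1, 1] - verts[i, 1]
        if (lab == GROWTH and dxi < 0) or (lab == SHRINK and dxi > 0):
            verts[i + 1, 1] = verts[i, 1]
    return PhaseAnnotation(
        vertices=verts,
        labels=asm.labels,
        observation_time=trajectory.duration,
        n_marks=len(asm.vt),
        rate_ok=asm.ok,
    )


def _weighted_rate(rates: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    good = weights > 0
    rates, weights = rates[good], weights[good]
    if rates.size == 0:
        return float("nan"), float("nan")
    mean = float(np.sum(weights * rates) / np.sum(weights))
    n = rates.size
    if n == 1:
        return mean, float("nan")
    var = np.sum(weights * (rates - mean) ** 2) / np.sum(weights) * n / (n - 1)
    return mean, float(np.sqrt(var / n))


def compute_dynamics(
    annotations: list[PhaseAnnotation],
    seed_tolerance_nm: float = 40.0,
    pixel_size: float = 160.0,
) -> DynamicsSummary:
    """Pool dynamic-instability parameters over a set of phase annotations.

    A shrink phase followed by growth counts as a rescue unless it terminates
    at the seed (final position within ``seed_tolerance_nm`` of zero); a
    trailing shrink phase is censored (length counted, no event).  Segments
    with ``rate_ok=False`` contribute to totals and event counts but not to
    the pooled rates, because their slopes are not identifiable from the
    sampled trace.
    """
    if not annotations:
        raise ValueError("need at least one annotation")

    growth_time = growth_len = shrink_len = obs_time = 0.0
    n_cat = n_res = n_marks = n_growth = n_shrink = 0
    g_rates, g_w, s_rates, s_w = [], [], [], []

    for ann in annotations:
        obs_time += ann.observation_time
        n_marks += int(ann.n_marks)
        segs = list(ann.segments())
        ok = ann.rate_ok if ann.rate_ok is not None else [True] * len(segs)
        for i, (t0, t1, x0, x1, lab) in enumerate(segs):
            dt, dx = t1 - t0, x1 - x0
            if lab == GROWTH:
                n_growth += 1
                growth_time += dt
                growth_len += abs(dx)
                if dt > 0 and ok[i]:
                    g_rates.append(abs(dx) / dt)
                    g_w.append(dt)
                if i + 1 < len(segs) and segs[i + 1][4] == SHRINK:
                    n_cat += 1
            else:
                n_shrink += 1
                shrink_len += abs(dx)
                if dt > 0 and ok[i]:
                    s_rates.append(abs(dx) / dt)
                    s_w.append(abs(dx))
                if i + 1 < len(segs) and segs[i + 1][4] == GROWTH:
                    if x1 > seed_tolerance_nm:
                        n_res += 1

    if growth_time <= 0:
        if n_cat > 0:
            raise ValueError("catastrophes recorded with zero growth time")
        raise ValueError("no growth time in annotations")

    g_mean, g_se = _weighted_rate(np.array(g_rates), np.array(g_w))
    s_mean, s_se = _weighted_rate(np.array(s_rates), np.array(s_w))
    shrink_len_um = shrink_len / 1000.0

    cat_freq = n_cat / growth_time
    cat_err = float(np.sqrt(n_cat)) / growth_time
    if shrink_len_um > 0:
        res_rate = n_res / shrink_len_um
        res_err = float(np.sqrt(n_res)) / shrink_len_um
    else:
        res_rate, res_err = 0.0, float("nan")

    dynamicity = (growth_len + shrink_len) / obs_time
    dyn_err = pixel_size * n_marks / obs_time

    return DynamicsSummary(
        growth_rate=g_mean,
        growth_rate_se=g_se,
        shrink_rate=s_mean,
        shrink_rate_se=s_se,
        catastrophe_freq=cat_freq,
        catastrophe_freq_err=cat_err,
        rescue_per_length=res_rate,
        rescue_per_length_err=res_err,
        dynamicity=dynamicity,
        dynamicity_err=dyn_err,
        n_catastrophes=n_cat,
        n_rescues=n_res,
        n_growth_phases=n_growth,
        n_shrink_phases=n_shrink,
        total_growth_time_s=growth_time,
        total_growth_length_nm=growth_len,
        total_shrink_length_nm=shrink_len,
        total_observation_time_s=obs_time,
        n_marks=n_marks,
    )


def weighted_mean(values, errors) -> tuple[float, float]:
    """Inverse-variance weighted mean with combined SE = 1/sqrt(sum 1/SE^2)."""
    values = np.asarray(values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate")
    if np.any(errors <= 0):
        raise ValueError("all SEs must be > 0")
    w = 1.0 / errors**2
    return float(np.sum(w * values) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))
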