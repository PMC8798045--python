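"""Core in-memory containers shared across the analysis stages.

Tabular results (segment tables, curvature samples, binned summaries) are plain
:class:`pandas.DataFrame` objects with documented column schemas; the dataclasses
below hold the structured objects that carry calibration or ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: one tubulin dimer along a protofilament, nm; the binding-lattice site length
DIMER_NM = 8.0

GROWTH = "growth"
SHRINK = "shrink"


@dataclass
class EndTrajectory:
    """A microtubule end's position-vs-time trace.

    Positions are in nm relative to the seed boundary; times in seconds,
    strictly increasing.  ``truth_phases`` carries the noiseless generating
    phases ``(t_start, t_end, label)`` when the trace comes from the simulator.
    """

    times: np.ndarray
    positions: np.ndarray
    pixel_size: float = 160.0
    frame_interval: float = 5.0
    truth_phases: list[tuple[float, float, str]] | None = None
    truth_vertices: np.ndarray | None = None
    end_label: str = "plus"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.positions.shape:
            raise ValueError("times and positions must be equal-length 1-D arrays")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.truth_phases is not None:
            for (t0, t1, lab) in self.truth_phases:
                if not (t1 > t0):
                    raise ValueError("truth phase must have t_end > t_start")
                if lab not in (GROWTH, SHRINK):
                    raise ValueError(f"unknown phase label {lab!r}")
        if self.truth_vertices is not None:
            self.truth_vertices = np.asarray(self.truth_vertices, dtype=float).reshape(-1, 2)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class Kymograph:
    """A 2-channel (or more) space-time image: rows are frames, columns pixels.

    Channel roles follow the assay layout: ``seed`` (stabilized template),
    ``lattice`` (tubulin), ``probe`` (the MAP channel).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 160.0
    frame_interval: float = 5.0

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for k, v in self.channels.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {k!r} must be 2-D (frames x pixels)")
            self.channels[k] = arr

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_pixels(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class BindingEvent:
    """One single-molecule residence on the lattice."""

    position_um: float
    t_on: float
    t_off: float
    censored: bool = False
    condition: str = "control"

    def __post_init__(self) -> None:
        if not self.t_off > self.t_on:
            raise ValueError("t_off must exceed t_on")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class PhaseAnnotation:
    """Growth/shrink vertices marked on one kymograph.

    ``vertices`` is an (n, 2) array of (time s, position nm); ``labels`` has
    n-1 entries, one per segment between consecutive vertices.  ``n_marks`` is
    the number of marked points, which enters the dynamicity error formula.
    """

    vertices: np.ndarray
    labels: list[str]
    observation_time: float
    n_marks: int | None = None
    #: per-segment flag: False where the sampled trace cannot support a slope
    #: estimate (e.g. a one-interval reversal); lengths and counts still count
    rate_ok: list[bool] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.labels) != len(self.vertices) - 1:
            raise ValueError("need exactly one label per inter-vertex segment")
        t = self.vertices[:, 0]
        if not np.all(np.diff(t) > 0):
            raise ValueError("vertex times must be strictly increasing")
        dx = np.diff(self.vertices[:, 1])
        for i, lab in enumerate(self.labels):
            if lab == GROWTH and dx[i] < -1e-9:
                raise ValueError("growth segment with negative displacement")
            if lab == SHRINK and dx[i] > 1e-9:
                raise ValueError("shrink segment with positive displacement")
            if lab not in (GROWTH, SHRINK):
                raise ValueError(f"unknown phase label {lab!r}")
        if self.observation_time <= 0:
            raise ValueError("observation_time must be positive")
        if self.n_marks is None:
            self.n_marks = len(self.vertices)
        if self.rate_ok is not None and len(self.rate_ok) != len(self.labels):
            raise ValueError("rate_ok must have one entry per segment")

    def segments(self):
        """Yield (t0, t1, x0, x1, label) per phase segment."""
        v = self.vertices
        for i, lab in enumerate(self.labels):
            yield v[i, 0], v[i + 1, 0], v[i, 1], v[i + 1, 1], lab


@dataclass
class DynamicsSummary:
    """Dynamic-instability parameters pooled over a set of annotations.

    Rates in nm/s, catastrophe frequency in 1/s (per growth time), rescue in
    1/um (per shrinkage length), dynamicity in nm/s.  Errors follow the stated
    models: weighted SEs for rates, counting errors (sqrt(n)/denominator) for
    transition frequencies, and pixel_size * N / T for dynamicity.
    """

    growth_rate: float
    growth_rate_se: float
    shrink_rate: float
    shrink_rate_se: float
    catastrophe_freq: float
    catastrophe_freq_err: float
    rescue_per_length: float
    rescue_per_length_err: float
    dynamicity: float
    dynamicity_err: float
    n_catastrophes: int
    n_rescues: int
    n_growth_phases: int
    n_shrink_phases: int
    total_growth_time_s: float
    total_growth_length_nm: float
    total_shrink_length_nm: float
    total_observation_time_s: float
    n_marks: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NucleationDataset:
    """Per-condition templated-nucleation counts."""

    x_uM: np.ndarray
    seeds_total: np.ndarray
    seeds_nucleated: np.ndarray

    def __post_init__(self) -> None:
        self.x_uM = np.asarray(self.x_uM, dtype=float)
        self.seeds_total = np.asarray(self.seeds_total, dtype=int)
        self.seeds_nucleated = np.asarray(self.seeds_nucleated, dtype=int)
        if not (self.x_uM.shape == self.seeds_total.shape == self.seeds_nucleated.shape):
            raise ValueError("all columns must have equal length")
        if np.any(self.x_uM < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(self.seeds_total <= 0):
            raise ValueError("seeds_total must be positive")
        if np.any(self.seeds_nucleated < 0) or np.any(
            self.seeds_nucleated > self.seeds_total
        ):
            raise ValueError("seeds_nucleated must lie in [0, seeds_total]")

    @property
    def fraction(self) -> np.ndarray:
        return self.seeds_nucleated / self.seeds_total


@dataclass
class SigmoidFit:
    """Result of the Hill-type nucleation fit y = x^s / (C^s + x^s)."""

    C: float
    C_ci95: tuple[float, float]
    s: float
    s_ci95: tuple[float, float]
    rss: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore"):
            y = np.where(x > 0, x**self.s / (self.C**self.s + x**self.s), 0.0)
        return y


@dataclass
class Linescan:
    """Per-channel intensity sampled along a traced filament."""

    positions_um: np.ndarray
    channels: dict[str, np.ndarray]
    time_s: float | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.size >= 2 and not np.all(np.diff(self.positions_um) > 0):
            raise ValueError("positions must be monotone increasing")
        for k, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.positions_um.shape:
                raise ValueError(f"channel {k!r} length mismatch")
            self.channels[k] = v


@dataclass
class MicrotubuleRecord:
    """Per-microtubule intensity timecourse used by the severing analysis."""

    mt_id: str
    field_id: str
    coated: bool
    times: np.ndarray
    intensity: np.ndarray
    intensity_se: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.intensity_se = np.asarray(self.intensity_se, dtype=float)
        if not (self.times.shape == self.intensity.shape == self.intensity_se.shape):
            raise ValueError("times/intensity/SE must have equal length")
        if np.any(self.intensity_se < 0):
            raise ValueError("SE must be >= 0")

    def normalized(self, baseline: tuple[float, float] = (0.0, 60.0)) -> "MicrotubuleRecord":
        """Return a copy normalized to the mean intensity in the baseline window."""
        mask = (self.times >= baseline[0]) & (self.times <= baseline[1])
        if not np.any(mask):
            raise ValueError("no frames in baseline window")
        base = float(np.mean(self.intensity[mask]))
        if base == 0:
            raise ValueError("zero baseline intensity")
        return MicrotubuleRecord(
            self.mt_id,
            self.field_id,
            self.coated,
            self.times.copy(),
            self.intensity / base,
            self.intensity_se / abs(base),
        )
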