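"""Synthetic-data generators with known ground truth.

Four generators mirror the four experimental readouts the analysis stages
quantify:

* :func:`simulate_dynamic_instability` -- two-state (growth/shrink) end
  trajectories with exponential catastrophe/rescue waiting times and an
  absorbing-then-regrowing seed boundary at position 0;
* :func:`simulate_binding` -- a Gillespie simulation of (optionally
  cooperative) single-molecule binding on a 1-D lattice of 8 nm sites;
* :func:`render_kymograph` -- a two/three-channel kymograph renderer with
  Gaussian optics and additive noise;
* :func:`generate_nucleation_counts` -- binomial templated-nucleation counts
  from a Hill-type concentration dependence.

Helper generators produce stretch occupancy patterns, damage-site kymographs
and severing timecourses for the lattice-level analyses.  Everything is
reproducible bit-for-bit given ``SimConfig.rng_seed``.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import SimConfig
from .containers import (
    DIMER_NM,
    GROWTH,
    SHRINK,
    BindingEvent,
    EndTrajectory,
    Kymograph,
    MicrotubuleRecord,
    NucleationDataset,
)

__all__ = [
    "simulate_dynamic_instability",
    "simulate_binding",
    "render_kymograph",
    "generate_nucleation_counts",
    "simulate_stretch_occupancy",
    "simulate_damage_kymograph",
    "simulate_severing_records",
]


def _sample_phase_path(config: SimConfig, duration: float, rng: np.random.Generator):
    """One realization of the two-state model; returns (vertices, phases).

    vertices: list of (t, x) corner points starting at (0, 0);
    phases: list of (t_start, t_end, label) tiling [0, duration].
    """
    t, x = 0.0, 0.0
    phase = GROWTH
    verts = [(0.0, 0.0)]
    phases: list[tuple[float, float, str]] = []
    while t < duration:
        if phase == GROWTH:
            wait = rng.exponential(1.0 / config.f_c) if config.f_c > 0 else math.inf
            t_end = min(t + wait, duration)
            x_end = x + config.v_g * (t_end - t)
            phases.append((t, t_end, GROWTH))
            verts.append((t_end, x_end))
            t, x, phase = t_end, x_end, SHRINK
        else:
            wait = rng.exponential(1.0 / config.f_r) if config.f_r > 0 else math.inf
            t_seed = x / config.v_s  # time to reach the seed boundary
            t_end = min(t + wait, t + t_seed, duration)
            x_end = x - config.v_s * (t_end - t)
            if t_end == t + t_seed:
                x_end = 0.0  # exact seed return
            if t_end > t:
                phases.append((t, t_end, SHRINK))
                verts.append((t_end, x_end))
            t, x, phase = t_end, max(x_end, 0.0), GROWTH
    return verts, phases


def simulate_dynamic_instability(
    config: SimConfig, duration: float, n: int
) -> list[EndTrajectory]:
    """Simulate ``n`` end trajectories of length ``duration`` seconds.

    Positions are sampled on the frame grid (``config.frame_interval``); the
    exact phase boundaries are recorded in ``truth_phases``.  If
    ``config.pos_noise_sd`` > 0, additive Gaussian noise is applied to the
    rendered positions only (the recorded truth stays noiseless), so noisy
    traces may dip slightly below the seed boundary.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    times = np.arange(0.0, duration + 1e-9, config.frame_interval)
    out = []
    for _ in range(n):
        verts, phases = _sample_phase_path(config, duration, rng)
        vt = np.array([v[0] for v in verts])
        vx = np.array([v[1] for v in verts])
        pos = np.interp(times, vt, vx)
        if config.pos_noise_sd > 0:
            pos = pos + rng.normal(0.0, config.pos_noise_sd, size=pos.shape)
        out.append(
            EndTrajectory(
                times=times.copy(),
                positions=pos,
                pixel_size=config.pixel_size,
                frame_interval=config.frame_interval,
                truth_phases=phases,
                truth_vertices=np.array(verts),
            )
        )
    return out


def _binding_rates(occ: np.ndarray, config: SimConfig, site_um: float):
    """Per-site on/off rates for the current occupancy vector."""
    occf = occ.astype(float)
    # local density within +/-2 sites (neighbors only, self excluded)
    kernel5 = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
    rho = np.convolve(occf, kernel5, mode="same") / 4.0
    nn = np.convolve(occf, np.array([1.0, 0.0, 1.0]), mode="same")
    on = config.k_on * config.conc * site_um * (1.0 + config.coop_on * rho)
    on[occ] = 0.0
    off = np.where(occ, config.k_off / (1.0 + config.coop_off * nn), 0.0)
    return on, off


class _RateTable:
    """Combined on/off rate vector with block partial sums for O(block)
    sampling and O(1)-neighborhood updates (only sites within +/-2 of an
    event change their rates)."""

    def __init__(self, rates: np.ndarray, block: int = 256):
        self.block = block
        n_blocks = (rates.size + block - 1) // block
        self.rates = np.concatenate(
            [rates, np.zeros(n_blocks * block - rates.size)]
        )
        self.sums = self.rates.reshape(n_blocks, block).sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.sums.sum())

    def update(self, lo: int, hi: int, values: np.ndarray) -> None:
        """Replace rates[lo:hi] (a short contiguous span) and refresh sums."""
        self.rates[lo:hi] = values
        for b in range((lo // self.block), ((hi - 1) // self.block) + 1):
            self.sums[b] = self.rates[b * self.block : (b + 1) * self.block].sum()

    def sample(self, u: float) -> int:
        """Index with cumulative rate just above u (0 <= u < total)."""
        cs = np.cumsum(self.sums)
        b = int(np.searchsorted(cs, u, side="right"))
        b = min(b, len(self.sums) - 1)
        rem = u - (cs[b - 1] if b > 0 else 0.0)
        seg = np.cumsum(self.rates[b * self.block : (b + 1) * self.block])
        j = b * self.block + min(
            int(np.searchsorted(seg, rem, side="right")), self.block - 1
        )
        if self.rates[j] <= 0:  # float-edge fallback: nearest active entry
            nz = np.flatnonzero(self.rates > 0)
            if nz.size:
                j = int(nz[np.argmin(np.abs(nz - j))])
        return j


def _local_rates(occp, lo, hi, config, site_um):
    """Per-site on/off rates for sites lo..hi-1.

    ``occp`` is the occupancy as float with 2 zero-padded cells on each side,
    so neighborhood sums vectorize without bounds checks (missing neighbors
    count as empty, matching the global rate computation).
    """
    base = config.k_on * config.conc * site_um
    c = slice(lo + 2, hi + 2)  # center span in padded coordinates
    occ_c = occp[c]
    rho = (occp[lo : hi] + occp[lo + 1 : hi + 1]
           + occp[lo + 3 : hi + 3] + occp[lo + 4 : hi + 4]) / 4.0
    nn = occp[lo + 1 : hi + 1] + occp[lo + 3 : hi + 3]
    on = base * (1.0 + config.coop_on * rho) * (1.0 - occ_c)
    off = (config.k_off / (1.0 + config.coop_off * nn)) * occ_c
    return on, off


def simulate_binding(
    config: SimConfig,
    mt_length: float,
    duration: float,
    condition: str = "control",
    return_occupancy: bool = False,
):
    """Gillespie simulation of single-molecule binding on a 1-D 8 nm lattice.

    Arrivals are Poisson with per-site intensity
    ``k_on * conc * site_length * (1 + coop_on * rho_local)`` (``rho_local`` =
    occupied fraction within +/-2 sites); residences are exponential with rate
    ``k_off / (1 + coop_off * n_nearest_neighbors)``.  Molecules still bound at
    the end of the observation are emitted with ``censored=True``.  Only a
    ``labeled_fraction`` of molecules is reported, emulating spiking
    experiments where unlabeled molecules occupy the lattice invisibly.

    Parameters
    ----------
    mt_length : total microtubule length in um.
    duration : observation time in s.
    return_occupancy : also return a (n_frames, n_sites) boolean occupancy
        movie sampled on the frame grid.
    """
    if mt_length <= 0 or duration <= 0:
        raise ValueError("mt_length and duration must be > 0")
    rng = np.random.default_rng(config.rng_seed)
    site_um = DIMER_NM / 1000.0
    n_sites = max(1, int(round(mt_length / site_um)))
    occ = np.zeros(n_sites, dtype=bool)
    t_on = np.full(n_sites, np.nan)
    labeled = np.zeros(n_sites, dtype=bool)

    n_frames = int(np.floor(duration / config.frame_interval)) + 1
    occupancy = (
        np.zeros((n_frames, n_sites), dtype=bool) if return_occupancy else None
    )
    next_frame = 0

    on, off = _binding_rates(occ, config, site_um)
    table = _RateTable(np.concatenate([on, off]))
    occp = np.zeros(n_sites + 4)  # float occupancy, 2-padded for neighborhoods

    def refresh_neighborhood(site: int) -> None:
        lo, hi = max(0, site - 2), min(n_sites, site + 3)
        on_l, off_l = _local_rates(occp, lo, hi, config, site_um)
        table.update(lo, hi, on_l)
        table.update(n_sites + lo, n_sites + hi, off_l)

    events: list[BindingEvent] = []
    t = 0.0
    step = 0
    while True:
        total = table.total
        if total <= 0:
            t = duration
        else:
            t = t + rng.exponential(1.0 / total)
        if occupancy is not None:
            while next_frame < n_frames and next_frame * config.frame_interval <= min(t, duration):
                occupancy[next_frame] = occ
                next_frame += 1
        if t >= duration:
            break
        idx = table.sample(rng.uniform(0.0, total))
        site = idx % n_sites
        if idx < n_sites:  # arrival
            occ[site] = True
            occp[site + 2] = 1.0
            t_on[site] = t
            labeled[site] = rng.uniform() < config.labeled_fraction
        else:  # departure
            occ[site] = False
            occp[site + 2] = 0.0
            if labeled[site]:
                events.append(
                    BindingEvent(
                        position_um=site * site_um,
                        t_on=float(t_on[site]),
                        t_off=float(t),
                        censored=False,
                        condition=condition,
                    )
                )
            t_on[site] = np.nan
        refresh_neighborhood(site)
        step += 1
        if step % 8192 == 0:
            # guard against float drift in the incremental block sums
            on, off = _binding_rates(occ, config, site_um)
            table = _RateTable(np.concatenate([on, off]))
    # molecules still bound at the end of observation
    for site in np.flatnonzero(occ):
        if labeled[site]:
            events.append(
                BindingEvent(
                    position_um=site * site_um,
                    t_on=float(t_on[site]),
                    t_off=float(duration),
                    censored=True,
                    condition=condition,
                )
            )
    events.sort(key=lambda e: e.t_on)
    if return_occupancy:
        return events, occupancy
    return events


def simulate_binding_experiment(
    config: SimConfig,
    n_fields: int = 6,
    mt_length_per_field: float = 25.0,
    duration: float = 1200.0,
    condition: str = "control",
) -> list[BindingEvent]:
    """Pool binding events from several independent fields of view.

    Dwell-time experiments sample many microtubules across fields of view; a
    single 1-D lattice underrepresents that averaging (cluster formation is
    stochastic and a few large clusters dominate one lattice).  Each field is
    an independent lattice with a sub-seed derived from ``config.rng_seed``;
    event positions are offset by the field's position so they stay unique.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    events: list[BindingEvent] = []
    for k in range(n_fields):
        sub = config.replace(rng_seed=(config.rng_seed * 1009 + 7919 * k + 1) % (2**31))
        for e in simulate_binding(sub, mt_length_per_field, duration, condition=condition):
            e.position_um += k * mt_length_per_field
            events.append(e)
    events.sort(key=lambda e: e.t_on)
    return events


def _coverage_fraction(pos_nm: float, n_pixels: int, pixel_size: float) -> np.ndarray:
    """Per-pixel polymer coverage (0..1) for an end at ``pos_nm``."""
    edges = np.arange(n_pixels + 1) * pixel_size
    cov = np.clip((pos_nm - edges[:-1]) / pixel_size, 0.0, 1.0)
    return cov


def render_kymograph(
    trajectory: EndTrajectory,
    occupancy: np.ndarray | None,
    config: SimConfig,
    amplitude: float = 1000.0,
    baseline: float = 0.0,
    seed_length_nm: float = 2000.0,
    margin_px: int = 12,
) -> Kymograph:
    """Render seed/lattice/probe channels from a trajectory and an occupancy movie.

    The lattice channel is the polymer-coverage indicator blurred with a
    Gaussian PSF of ``config.psf_sigma`` px and scaled by ``amplitude``; the
    probe channel images ``occupancy`` (frames x 8 nm sites, values in [0, 1])
    under the same optics.  Occupancy site 0 sits at the seed boundary
    (trajectory position 0); the seed occupies the first ``seed_length_nm`` of
    the image, so image column ~= seed_length + site position.  Additive
    Gaussian noise of ``config.noise_sd`` is applied on top of ``baseline``
    and the result is clipped at zero.
    """
    if occupancy is not None and occupancy.shape[0] != trajectory.times.size:
        raise ValueError(
            "occupancy movie and trajectory must cover the same time span "
            f"({occupancy.shape[0]} frames vs {trajectory.times.size})"
        )
    rng = np.random.default_rng(config.rng_seed)
    px = config.pixel_size
    n_frames = trajectory.times.size
    max_pos = float(np.max(trajectory.positions)) + seed_length_nm
    n_px = int(np.ceil(max_pos / px)) + margin_px
    seed_px = seed_length_nm / px

    def optics(img: np.ndarray) -> np.ndarray:
        if config.psf_sigma > 0:
            img = gaussian_filter1d(img, config.psf_sigma, axis=1, mode="constant")
        img = amplitude * img + baseline
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)

    lattice = np.zeros((n_frames, n_px))
    for i, pos in enumerate(trajectory.positions):
        lattice[i] = _coverage_fraction(pos + seed_length_nm, n_px, px)
    seed = np.zeros((n_frames, n_px))
    seed[:, :] = _coverage_fraction(seed_length_nm, n_px, px)[None, :]

    channels = {"seed": optics(seed), "lattice": optics(lattice)}
    if occupancy is not None:
        sites_per_px = max(1, int(round(px / DIMER_NM)))
        n_sites = occupancy.shape[1]
        n_full = (n_sites // sites_per_px) * sites_per_px
        binned = occupancy[:, :n_full].astype(float)
        binned = binned.reshape(n_frames, -1, sites_per_px).mean(axis=2)
        probe = np.zeros((n_frames, n_px))
        offset = int(round(seed_px))
        width = min(binned.shape[1], n_px - offset)
        probe[:, offset : offset + width] = binned[:, :width]
        channels["probe"] = optics(probe)
    return Kymograph(
        channels=channels, pixel_size=px, frame_interval=config.frame_interval
    )


def hill(x, C: float, s: float):
    """Templated-nucleation concentration dependence y = x^s / (C^s + x^s)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(x > 0, x**s / (C**s + x**s), 0.0)
    return y


def generate_nucleation_counts(
    C: float,
    s: float,
    concentrations,
    seeds_per_condition: int,
    rng_seed: int,
) -> NucleationDataset:
    """Binomial nucleation counts: N_x ~ Binomial(total, x^s / (C^s + x^s))."""
    if C <= 0 or s <= 0:
        raise ValueError("C and s must be > 0")
    x = np.asarray(concentrations, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be >= 0")
    if seeds_per_condition < 1:
        raise ValueError("seeds_per_condition must be >= 1")
    rng = np.random.default_rng(rng_seed)
    p = hill(x, C, s)
    counts = rng.binomial(seeds_per_condition, p)
    return NucleationDataset(
        x_uM=x,
        seeds_total=np.full(x.shape, seeds_per_condition, dtype=int),
        seeds_nucleated=counts,
    )


def simulate_stretch_occupancy(
    n_frames: int,
    n_sites: int,
    initiation_site: int,
    start_frame: int = 0,
    expansion_sites_per_frame: float = 5.0,
    direction: int = +1,
    baseline: float = 0.1,
    stretch_level: float = 0.9,
) -> np.ndarray:
    """Occupancy movie with a high-occupancy stretch expanding from one point.

    The stretch starts at ``initiation_site`` at ``start_frame`` and expands at
    ``expansion_sites_per_frame`` exclusively in ``direction`` (+1 = toward the
    growing end / increasing site index), emulating probe stretches that expand
    only in the direction of growth.
    """
    occ = np.full((n_frames, n_sites), baseline)
    for f in range(start_frame, n_frames):
        ext = int((f - start_frame) * expansion_sites_per_frame)
        if direction >= 0:
            lo, hi = initiation_site, min(n_sites, initiation_site + ext + 1)
        else:
            lo, hi = max(0, initiation_site - ext), initiation_site + 1
        occ[f, lo:hi] = stretch_level
    return occ


def simulate_damage_kymograph(
    config: SimConfig,
    length_um: float,
    duration: float,
    n_damage_sites: int = 3,
    damage_depth: float = 0.5,
    damage_halfwidth_px: int = 2,
    probe_baseline: float = 0.1,
    probe_damage_level: float = 0.9,
    loading_time_s: float = 300.0,
) -> tuple[Kymograph, np.ndarray]:
    """Stabilized-microtubule kymograph with damage sites.

    Damage sites are low-occupancy lattice segments (tubulin dimmed by
    ``damage_depth``); the probe channel loads linearly in time (saturating at
    ``loading_time_s``) and is preferentially enriched at the damage sites.
    Returns the kymograph and the damage-site pixel positions.
    """
    rng = np.random.default_rng(config.rng_seed)
    px = config.pixel_size
    n_px = int(round(length_um * 1000.0 / px))
    n_frames = int(np.floor(duration / config.frame_interval)) + 1
    lo, hi = 4, n_px - 5
    if hi <= lo or n_damage_sites < 1:
        raise ValueError("geometry too small for requested damage sites")
    sites = np.sort(rng.choice(np.arange(lo, hi), size=n_damage_sites, replace=False))

    lattice = np.ones((n_frames, n_px))
    damage_mask = np.zeros(n_px, dtype=bool)
    for s in sites:
        damage_mask[max(0, s - damage_halfwidth_px) : s + damage_halfwidth_px + 1] = True
    lattice[:, damage_mask] *= 1.0 - damage_depth

    load = np.clip(
        np.arange(n_frames) * config.frame_interval / loading_time_s, 0.0, 1.0
    )
    probe = np.where(damage_mask[None, :], probe_damage_level, probe_baseline)
    probe = probe * load[:, None]

    def optics(img):
        if config.psf_sigma > 0:
            img = gaussian_filter1d(img, config.psf_sigma, axis=1, mode="nearest")
        img = 1000.0 * img
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)

    kymo = Kymograph(
        channels={"lattice": optics(lattice), "probe": optics(probe)},
        pixel_size=px,
        frame_interval=config.frame_interval,
    )
    return kymo, sites


def simulate_severing_records(
    rng_seed: int,
    n_fields: int = 3,
    n_control: int = 20,
    n_coated: int = 20,
    duration: float = 600.0,
    frame_interval: float = 15.0,
    sever_rate_control: float = 0.01,
    sever_rate_coated: float = 0.0,
    loss_fraction: tuple[float, float] = (0.2, 0.5),
    noise_sd: float = 0.03,
) -> list[MicrotubuleRecord]:
    """Severing assay timecourses for mixed coated/non-coated populations.

    Each microtubule loses a random fraction of its remaining polymer
    (``loss_fraction`` bounds, uniform) at Poisson severing times with the
    per-population rate; measured intensity adds Gaussian noise and carries a
    per-frame SE.  Coated microtubules with ``sever_rate_coated=0`` keep full
    intensity, mirroring full protection.
    """
    rng = np.random.default_rng(rng_seed)
    times = np.arange(0.0, duration + 1e-9, frame_interval)
    records = []
    for f in range(n_fields):
        for coated, n_mt, rate in (
            (False, n_control, sever_rate_control),
            (True, n_coated, sever_rate_coated),
        ):
            for i in range(n_mt):
                frac = np.ones_like(times)
                if rate > 0:
                    t = rng.exponential(1.0 / rate)
                    level = 1.0
                    while t < duration:
                        level *= 1.0 - rng.uniform(*loss_fraction)
                        frac[times >= t] = level
                        t += rng.exponential(1.0 / rate)
                meas = np.clip(frac + rng.normal(0, noise_sd, times.shape), 0, None)
                se = np.full(times.shape, noise_sd)
                records.append(
                    MicrotubuleRecord(
                        mt_id=f"f{f}_{'c' if coated else 'n'}{i}",
                        field_id=f"field{f}",
                        coated=coated,
                        times=times.copy(),
                        intensity=meas,
                        intensity_se=se,
                    )
                )
    return records
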