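"""Lattice-level intensity analyses: masks, region comparison, stretches,
damage linescans, the severing statistic, and rolling-ball background."""
import numpy as np
import pytest

from mtkymo.config import SimConfig
from mtkymo import simgen
from mtkymo.containers import EndTrajectory, Kymograph, MicrotubuleRecord
from mtkymo.lattice import (
    damage_linescans,
    find_stretch_trigger_frame,
    mad_outliers,
    masked_field_intensity,
    region_compare,
    rolling_ball_background,
    severing_timecourse,
    stretch_profile,
)


class TestRollingBall:
    def test_constant_image_becomes_zero(self):
        out = rolling_ball_background(np.full((30, 30), 7.0), radius=5)
        assert np.allclose(out, 0.0)

    def test_narrow_ridge_preserved(self):
        img = np.full((30, 30), 5.0)
        img[15, :] += 9.0
        out = rolling_ball_background(img, radius=5)
        assert np.allclose(out[15, 5:-5], 9.0, atol=0.2)

    def test_broad_plateau_removed(self):
        img = np.zeros((40, 40))
        img[5:35, 5:35] = 10.0  # plateau much wider than 2*radius
        out = rolling_ball_background(img, radius=5)
        assert out[20, 20] == pytest.approx(0.0, abs=0.2)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_background(np.zeros((5, 5)), radius=0)


class TestMaskedFieldIntensity:
    def _stack(self):
        lattice = np.zeros((10, 20, 20))
        lattice[:, 8:12, :] = 100.0
        return lattice

    def test_probe_off_mask_excluded(self):
        lattice = self._stack()
        probe = np.zeros_like(lattice)
        probe[:, 0:2, :] = 50.0  # far from the microtubule band
        series = masked_field_intensity(probe, lattice, dilate_px=0)
        assert np.allclose(series, 0.0)

    def test_constant_probe_on_mask_sums_exactly(self):
        lattice = self._stack()
        probe = np.zeros_like(lattice)
        probe[:, 8:12, :] = 3.0
        series = masked_field_intensity(probe, lattice, dilate_px=0)
        assert np.allclose(series, 3.0 * 4 * 20)

    def test_loading_series_tracks_truth_monotonically(self):
        cfg = SimConfig(rng_seed=0, noise_sd=5.0)
        kymo, _ = simgen.simulate_damage_kymograph(cfg, length_um=12.0, duration=600.0)
        probe = kymo.channels["probe"][:, None, :]
        lattice = kymo.channels["lattice"][:, None, :]
        series = masked_field_intensity(probe, lattice)
        load = np.clip(np.arange(series.size) * 5.0 / 300.0, 0, 1)
        # linear rise then saturation; shape matches the generating load curve
        r = np.corrcoef(series, load)[0, 1]
        assert r > 0.99
        assert series[10] < series[40] < series[80]


class TestRegionCompare:
    def test_identical_regions_p_one(self):
        out = region_compare([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert out["p_value"] == 1.0

    def test_separated_regions_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 17)
        b = rng.normal(10.0, 1.0, 17)  # 10 SD apart
        assert region_compare(a, b)["p_value"] < 1e-3

    def test_null_p_values_uniform(self):
        # equal occupancy on both regions at the experiment's n=17
        from scipy.stats import kstest

        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            a = rng.normal(1.0, 0.2, 17)
            b = rng.normal(1.0, 0.2, 17)
            ps.append(region_compare(a, b)["p_value"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_compare([], [1.0])


class TestStretchProfile:
    def _stretch_kymo(self, direction=+1):
        cfg = SimConfig(rng_seed=0, noise_sd=0.0, psf_sigma=0.0)
        occ = simgen.simulate_stretch_occupancy(
            n_frames=50,
            n_sites=1000,
            initiation_site=500,
            direction=direction,
            expansion_sites_per_frame=10,
        )
        traj = EndTrajectory(np.arange(50) * 5.0, np.full(50, 7800.0))
        kymo = simgen.render_kymograph(traj, occ, cfg)
        init_px = int(500 * 8 / 160) + int(2000 / 160)  # site -> px + seed offset
        return kymo, init_px

    def test_center_normalized_to_one(self):
        kymo, px = self._stretch_kymo()
        frame = find_stretch_trigger_frame(kymo, px, 2.0)
        prof = stretch_profile(kymo, px, frame)
        assert prof.loc[prof.offset_px == 0, "relative_intensity"].iloc[0] == 1.0

    def test_symmetric_stretch_symmetric_profile(self):
        cfg = SimConfig(rng_seed=0, noise_sd=0.0, psf_sigma=0.0)
        occ = np.full((20, 1000), 0.1)
        # block spanning 7 whole pixels (20 sites each), centered on px 37
        occ[:, 440:580] = 0.9
        traj = EndTrajectory(np.arange(20) * 5.0, np.full(20, 7800.0))
        kymo = simgen.render_kymograph(traj, occ, cfg)
        prof = stretch_profile(kymo, 37, 10)
        left = prof.set_index("offset_px")["relative_intensity"]
        for k in range(1, 9):
            assert left[k] == pytest.approx(left[-k], rel=1e-6)

    def test_growth_directed_expansion_asymmetric(self):
        kymo, px = self._stretch_kymo(direction=+1)
        frame = find_stretch_trigger_frame(kymo, px, 2.0)
        prof = stretch_profile(kymo, px, frame)
        toward = prof.loc[prof.offset_px > 0, "relative_intensity"].mean()
        away = prof.loc[prof.offset_px < 0, "relative_intensity"].mean()
        assert toward > away

    def test_initiation_near_edge_rejected(self):
        kymo, _ = self._stretch_kymo()
        with pytest.raises(ValueError):
            stretch_profile(kymo, 4, 10)


class TestDamageLinescans:
    def test_uniform_channel_flat(self):
        kymo = Kymograph({"lattice": np.full((10, 30), 5.0), "probe": np.full((10, 30), 2.0)})
        scans = damage_linescans(kymo, times=[25.0])
        assert np.allclose(scans[0].channels["lattice"], 5.0)

    def test_probe_peaks_at_lattice_dips(self):
        cfg = SimConfig(rng_seed=1, noise_sd=5.0)
        kymo, sites = simgen.simulate_damage_kymograph(cfg, length_um=12.0, duration=600.0)
        scan = damage_linescans(kymo, times=[600.0])[0]
        for s in sites:
            assert scan.channels["lattice"][s] < 0.8 * np.median(scan.channels["lattice"])
            assert scan.channels["probe"][s] > np.median(scan.channels["probe"])

    def test_normalization_bounds(self):
        cfg = SimConfig(rng_seed=1, noise_sd=5.0)
        kymo, _ = simgen.simulate_damage_kymograph(cfg, length_um=12.0, duration=600.0)
        scan = damage_linescans(kymo, times=[300.0], normalize=True)[0]
        for vals in scan.channels.values():
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_time_outside_movie_skipped(self):
        kymo = Kymograph({"lattice": np.ones((10, 30)), "probe": np.ones((10, 30))})
        assert damage_linescans(kymo, times=[1e6]) == []


class TestMadOutliers:
    def test_gross_outlier(self):
        flags = mad_outliers([10.0, 10.0, 10.0, 1000.0])
        assert list(flags) == [False, False, False, True]

    def test_all_equal_none_flagged(self):
        assert not mad_outliers([5.0] * 6).any()


class TestSeveringTimecourse:
    def _record(self, mt_id, coated, values, se=0.05, field="f0"):
        times = np.arange(len(values)) * 15.0
        return MicrotubuleRecord(
            mt_id, field, coated, times, np.asarray(values, float), np.full(len(values), se)
        )

    def test_constructed_threshold_crossing(self):
        # control decays below 20% at frame 40 for two consecutive frames
        n = 50
        control = np.ones(n)
        control[40:] = 0.15
        coated = np.ones(n)
        recs = [
            self._record("c1", False, control),
            self._record("s1", True, coated),
        ]
        out = severing_timecourse(recs, baseline=(0.0, 60.0))
        assert out.loc[0, "threshold_time_s"] == pytest.approx(40 * 15.0)
        assert out.loc[0, "coated_mean"] == pytest.approx(1.0)

    def test_equal_se_weighted_mean_is_arithmetic(self):
        n = 50
        control = np.ones(n)
        control[30:] = 0.1
        recs = [self._record("c1", False, control)]
        for i, level in enumerate((0.8, 1.0, 1.2)):
            recs.append(self._record(f"s{i}", True, np.full(n, level)))
        out = severing_timecourse(recs, baseline=(0.0, 60.0))
        assert out.loc[0, "coated_mean"] == pytest.approx(np.mean([0.8, 1.0, 1.2]))

    def test_control_never_crossing_excluded(self):
        recs = [
            self._record("c1", False, np.ones(30)),
            self._record("s1", True, np.ones(30)),
        ]
        with pytest.raises(ValueError):
            severing_timecourse(recs)

    def test_protected_population_exceeds_control_fourfold(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            recs = simgen.simulate_severing_records(rng_seed=seed)
            out = severing_timecourse(recs)
            ratio = (out["coated_mean"] / out["control_mean"]).mean()
            hits += ratio > 4.0
        assert hits >= 0.95 * n_seeds
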