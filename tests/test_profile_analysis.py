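"""Profile extraction, normalization, aligned averaging and the Welch test."""

import numpy as np
import pytest
from scipy import ndimage, stats

from mig import profile_analysis as pa
from mig import synthetic_assembly as syn


def synth_set(**kw):
    defaults = dict(n_filaments=20, enrichment=3.0, noise_sigma=0.3, seed=0)
    defaults.update(kw)
    return syn.make_fluorescence_profiles(syn.SyntheticProfileParams(**defaults))


class TestExtractProfiles:
    def _images(self, shape=(80, 120), value=10.0):
        return {ch: np.full(shape, value) for ch in pa.CHANNELS}

    def test_constant_image_minus_background_is_zero(self):
        images = self._images()
        polylines = {"mt1": np.array([[10.0, 40.0], [100.0, 40.0]])}
        pset = pa.extract_profiles(images, polylines, pixel_size_um=0.1)
        np.testing.assert_allclose(pset.profiles[0].probe, 0.0, atol=1e-9)
        assert pset.profiles[0].background["probe"] == pytest.approx(10.0)

    def test_sample_count_follows_arc_length(self):
        images = self._images()
        # 1.3 um straight line at 0.1 um/px -> 13 px long
        polylines = {"mt1": np.array([[20.0, 40.0], [33.0, 40.0]])}
        pset = pa.extract_profiles(images, polylines, pixel_size_um=0.1, step_um=0.13)
        assert len(pset.profiles[0].positions_um) == 11

    def test_three_pixel_averaging_matches_direct_bilinear_sampling(self, rng):
        img = rng.normal(size=(60, 90))
        images = {ch: img for ch in pa.CHANNELS}
        x0, x1, y = 10.0, 70.0, 30.0
        polylines = {"mt1": np.array([[x0, y], [x1, y]])}
        pset = pa.extract_profiles(images, polylines, pixel_size_um=0.1, step_um=0.2,
                                   background_offset_px=12.0)
        p = pset.profiles[0]
        xs = x0 + np.arange(len(p.positions_um)) * 2.0       # 0.2 um / 0.1 um/px
        expected = np.mean(
            [ndimage.map_coordinates(img, [np.full_like(xs, y + off), xs], order=1)
             for off in (-1.0, 0.0, 1.0)],
            axis=0,
        )
        bg = p.background["mt"]
        np.testing.assert_allclose(p.mt + bg, expected, atol=1e-9)

    def test_polyline_exiting_image_raises(self):
        images = self._images(shape=(40, 40))
        polylines = {"mt1": np.array([[5.0, 20.0], [200.0, 20.0]])}
        with pytest.raises(pa.BoundsError):
            pa.extract_profiles(images, polylines, pixel_size_um=0.1)


class TestNormalizeProfiles:
    def test_per_mt_lattice_mean_is_one(self):
        pset = synth_set()
        normed = pa.normalize_profiles(pset, mode="per_mt")
        for p in normed:
            mask = np.abs(p.positions_um - p.anchor_um) > pset.end_window_um
            assert p.probe[mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_per_replicate_reduces_to_per_mt_for_single_mt(self):
        pset = synth_set(n_filaments=1, n_replicates=1)
        a = pa.normalize_profiles(pset, mode="per_mt").profiles[0].probe
        b = pa.normalize_profiles(pset, mode="per_replicate").profiles[0].probe
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_per_replicate_scale_invariance(self):
        pset = synth_set(n_filaments=6, noise_sigma=0.0)
        scaled_profiles = []
        for p in pset:
            factor = 5.0 if p.replicate == 2 else 1.0
            q = pa.Profile(p.filament_id, p.positions_um, p.mt, p.turc,
                           p.probe * factor, p.replicate, p.anchor_um)
            scaled_profiles.append(q)
        scaled = pa.ProfileSet(scaled_profiles, pset.step_um,
                               end_window_um=pset.end_window_um)
        a = pa.normalize_profiles(pset, mode="per_replicate")
        b = pa.normalize_profiles(scaled, mode="per_replicate")
        for pa_, pb_ in zip(a, b):
            np.testing.assert_allclose(pb_.probe, pa_.probe, atol=1e-12)

    def test_nonpositive_normalizer_rejected(self):
        pset = synth_set(n_filaments=1, noise_sigma=0.0)
        p = pset.profiles[0]
        bad = pa.ProfileSet(
            [pa.Profile(p.filament_id, p.positions_um, p.mt, p.turc,
                        p.probe * 0.0, p.replicate, p.anchor_um)],
            pset.step_um, end_window_um=pset.end_window_um,
        )
        with pytest.raises(pa.NormalizationError):
            pa.normalize_profiles(bad)


class TestFindAnchor:
    def test_peak_found_at_construction_anchor(self):
        pset = synth_set(noise_sigma=0.05)
        for p in pset:
            assert pa.find_anchor(p) == pytest.approx(0.5, abs=2 * pset.step_um)


class TestAverageAligned:
    def test_identical_profiles_average_to_themselves(self):
        pset = synth_set(n_filaments=3, noise_sigma=0.0)
        df = pa.average_aligned(pset, min_length_um=5.0)
        inner = df[(df["position_um"] > -0.3) & (df["position_um"] < 7.0)]
        assert (inner["probe_ci_hi"] - inner["probe_ci_lo"]).abs().max() < 1e-9

    def test_anchors_aligned_to_zero(self):
        pset = synth_set(n_filaments=8, noise_sigma=0.1)
        df = pa.average_aligned(pset, min_length_um=5.0)
        at0 = df.loc[df["position_um"].abs() < 1e-9]
        # the gamma-TuRC peak sits at the aligned origin
        assert at0["turc_mean"].iloc[0] == df["turc_mean"].max()

    def test_short_profiles_excluded(self):
        long_set = synth_set(n_filaments=4)
        short = synth_set(n_filaments=2, length_um=3.0)
        mixed = pa.ProfileSet(long_set.profiles + short.profiles, long_set.step_um,
                              end_window_um=0.6)
        df = pa.average_aligned(mixed, min_length_um=5.0)
        assert df["probe_n"].max() == 4

    def test_ci_matches_textbook_formula(self, rng):
        pset = synth_set(n_filaments=12, noise_sigma=0.4, seed=5)
        df = pa.average_aligned(pset, min_length_um=5.0)
        row = df.loc[np.isclose(df["position_um"], 2.6)].iloc[0]
        vals = []
        for p in pset:
            k = np.argmin(np.abs((p.positions_um - p.anchor_um) - 2.6))
            vals.append(p.probe[k])
        vals = np.asarray(vals)
        n = len(vals)
        half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        assert row["probe_mean"] == pytest.approx(vals.mean(), abs=1e-12)
        assert row["probe_ci_hi"] - row["probe_mean"] == pytest.approx(half, abs=1e-12)

    def test_fewer_than_two_profiles_rejected(self):
        pset = synth_set(n_filaments=1)
        with pytest.raises(pa.InsufficientDataError):
            pa.average_aligned(pset)


class TestEndEnrichmentTest:
    def test_welch_t_df_match_textbook_formulas(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 1.0, 2.0, 2.0])
        profiles = [
            pa.Profile("in", np.arange(4) * 0.13, np.ones(4), np.ones(4), a, 1, 0.2),
            pa.Profile("out", np.arange(4) * 0.13 + 0.0, np.ones(4), np.ones(4), b, 1, 0.2),
        ]
        # craft a set where the first profile's samples are all in-window and
        # the second's all out-of-window
        profiles[0].positions_um = np.array([0.1, 0.2, 0.3, 0.4])
        profiles[0].anchor_um = 0.25
        profiles[1].positions_um = np.array([2.0, 2.2, 2.4, 2.6])
        profiles[1].anchor_um = 0.0
        pset = pa.ProfileSet(profiles, 0.13, end_window_um=0.6)
        res = pa.end_enrichment_test(pset, window_um=0.6)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_expected = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.df == pytest.approx(df_expected, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(
            stats.t.sf(t_expected, df_expected), abs=1e-12
        )

    def test_identical_groups_give_t0_p_half(self):
        v = np.array([1.0, 2.0, 1.0, 2.0])
        profiles = [
            pa.Profile("in", np.array([0.1, 0.2, 0.3, 0.4]), np.ones(4), np.ones(4), v, 1, 0.25),
            pa.Profile("out", np.array([2.0, 2.2, 2.4, 2.6]), np.ones(4), np.ones(4), v, 1, 0.0),
        ]
        pset = pa.ProfileSet(profiles, 0.13, end_window_um=0.6)
        res = pa.end_enrichment_test(pset)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(0.5, abs=1e-12)

    def test_simulated_enrichment_detected(self):
        pset = synth_set(n_filaments=60, enrichment=3.0, noise_sigma=0.5, seed=0)
        normed = pa.normalize_profiles(pset)
        res = pa.end_enrichment_test(normed)
        assert 2.5 <= res.ratio <= 3.5
        assert res.p_one_tailed < 1e-3

    def test_group_counts_partition_samples(self):
        pset = synth_set(n_filaments=10)
        res = pa.end_enrichment_test(pset)
        total = sum(len(p.positions_um) for p in pset)
        assert res.n_in + res.n_out == total


class TestPipelineStatistics:
    @pytest.mark.parametrize("enrichment", [1.0, 2.0, 3.0])
    def test_enrichment_estimates_unbiased(self, enrichment):
        """Mean estimate over 100 seeds within 2 Monte-Carlo SEs of truth."""
        estimates = []
        for seed in range(100):
            pset = synth_set(n_filaments=20, enrichment=enrichment,
                             noise_sigma=0.3, seed=seed)
            res = pa.end_enrichment_test(pset)
            estimates.append(res.ratio)
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - enrichment) <= 2 * se + 1e-3

    def test_type_i_error_controlled_at_null(self):
        """At enrichment 1 the one-tailed test fires in at most 7% of 500 seeds."""
        rejections = 0
        for seed in range(500):
            pset = synth_set(n_filaments=12, enrichment=1.0, noise_sigma=0.3,
                             seed=10_000 + seed)
            res = pa.end_enrichment_test(pset)
            rejections += res.p_one_tailed < 0.05
        assert rejections / 500 <= 0.07

    def test_ci_coverage_of_true_ratio(self):
        """95% CI covers the true enrichment in at least 90 of 100 replicates."""
        hits = 0
        for seed in range(100):
            pset = synth_set(n_filaments=100, enrichment=3.0, noise_sigma=0.5,
                             seed=seed)
            res = pa.end_enrichment_test(pset)
            lo, hi = res.ratio_ci
            hits += lo <= 3.0 <= hi
        assert hits >= 90

    def test_csv_round_trip(self, tmp_path):
        pset = synth_set(n_filaments=3)
        path = tmp_path / "profiles.csv"
        pset.to_csv(path)
        back = pa.ProfileSet.from_csv(path)
        assert len(back) == 3
        np.testing.assert_allclose(back.profiles[0].probe, pset.profiles[0].probe,
                                   atol=1e-9)
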