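"""TFCE enhancement, permutation nulls, clusters, and the symmetry test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from valuectx import tfce
from valuectx.core import time_axis
from valuectx.encoding import DesignSpec, build_design
from tests.conftest import tfce_oracle_1d, tfce_oracle_2d


class TestTFCESigned:
    def test_zero_input_zero_output(self):
        out = tfce.tfce_signed(np.zeros(20))
        np.testing.assert_array_equal(out, 0.0)

    def test_two_point_plateau_hand_value(self):
        # both points: sum over h=0.1..1.0 of 2^2 * h^2 * 0.1 = 1.54
        params = tfce.TFCEParams(E=2, H=2, dh=0.1)
        out = tfce.tfce_signed(np.array([1.0, 1.0]), params)
        np.testing.assert_allclose(out, [1.54, 1.54], atol=1e-12)

    def test_plateau_closed_form(self):
        # constant run of height h0 and length L: every point scores
        # sum_{h<=h0} L^E h^H dh
        L, h0, dh = 5, 2.0, 0.05
        params = tfce.TFCEParams(E=2, H=2, dh=dh)
        z = np.concatenate([np.zeros(3), np.full(L, h0), np.zeros(2)])
        out = tfce.tfce_signed(z, params)
        levels = dh * np.arange(1, int(round(h0 / dh)) + 1)
        expected = (L**2 * levels**2 * dh).sum()
        np.testing.assert_allclose(out[3 : 3 + L], expected, atol=1e-9)

    def test_negative_part_is_mirror(self, rng):
        z = rng.standard_normal(40)
        params = tfce.TFCEParams()
        np.testing.assert_allclose(
            tfce.tfce_signed(-z, params), -tfce.tfce_signed(z, params), atol=1e-9
        )

    def test_matches_brute_force_oracle(self, rng):
        params = tfce.TFCEParams(E=2, H=2)
        for _ in range(10):
            z = rng.standard_normal(rng.integers(5, 25))
            out = tfce.tfce_signed(z, params)
            oracle = tfce_oracle_1d(z, E=2, H=2, n_levels=100)
            np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_2d_matches_flood_fill_oracle(self, rng):
        params = tfce.TFCEParams(E=1, H=2, n_levels=40)
        z = rng.standard_normal((6, 9))
        out = tfce.tfce_signed(z, params)
        oracle = tfce_oracle_2d(z, E=1, H=2, n_levels=40)
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_batch_equals_per_row(self, rng):
        Z = rng.standard_normal((7, 23))
        params = tfce.TFCEParams()
        batch = tfce._tfce_signed_batch_1d(Z, params)
        rows = np.array([tfce.tfce_signed(z, params) for z in Z])
        np.testing.assert_allclose(batch, rows, atol=1e-9)

    @given(scale=st.floats(1.1, 4.0), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_amplification_never_decreases_magnitude(self, scale, seed):
        z = np.random.default_rng(seed).standard_normal(15)
        params = tfce.TFCEParams()
        base = tfce.tfce_signed(z, params)
        amp = tfce.tfce_signed(scale * z, params)
        assert np.all(np.abs(amp) >= np.abs(base) - 1e-9)

    def test_level_count_insensitivity_of_extreme_statistics(self, rng):
        # the inference consumes the max/min TFCE; across 50-200 levels
        # the discretization moves them by under 2% of the statistic's
        # scale (the dominant extreme magnitude)
        z = rng.standard_normal(60)
        ref = tfce.tfce_signed(z, tfce.TFCEParams(n_levels=100))
        scale = np.abs(ref).max()
        for n_levels in (50, 200):
            alt = tfce.tfce_signed(z, tfce.TFCEParams(n_levels=n_levels))
            assert abs(alt.max() - ref.max()) / scale < 0.02
            assert abs(alt.min() - ref.min()) / scale < 0.02

    def test_level_count_does_not_change_significance_decisions(self, rng):
        # the FWE mask of the group test is the same whether the height
        # grid has 50, 100, or 200 levels
        betas = rng.standard_normal((16, 20))
        betas[:, 5:11] += 1.0
        masks = []
        for n_levels in (50, 100, 200):
            res = tfce.group_permutation(
                betas, tfce.TFCEParams(n_levels=n_levels), n_perm=200, seed=8
            )
            masks.append(res.mask)
        np.testing.assert_array_equal(masks[0], masks[1])
        np.testing.assert_array_equal(masks[1], masks[2])

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            tfce.tfce_signed(np.full(5, np.nan))


class TestGroupPermutation:
    def test_large_common_offset_all_significant(self, rng):
        betas = 5.0 + 0.1 * rng.standard_normal((20, 15))
        res = tfce.group_permutation(betas, n_perm=200, seed=0)
        assert res.mask.all()
        assert (res.tfce > 0).all()

    def test_strong_negative_effect_flagged_negative(self, rng):
        betas = -5.0 + 0.1 * rng.standard_normal((20, 15))
        res = tfce.group_permutation(betas, n_perm=200, seed=0)
        assert res.mask.all() and (res.tfce < 0).all()

    def test_null_extreme_pvalues_approximately_uniform(self):
        # the familywise-adjusted p of the most extreme positive TFCE is
        # uniform over independent null datasets (pointwise adjusted p's
        # are intentionally super-uniform)
        root = np.random.SeedSequence(3)
        data_rng = np.random.default_rng(root.spawn(1)[0])
        seeds = np.random.SeedSequence(4).generate_state(300)
        pvals = []
        for i in range(300):
            betas = data_rng.standard_normal((12, 8))
            res = tfce.group_permutation(betas, n_perm=150, seed=int(seeds[i]))
            pvals.append(res.p[int(np.argmax(res.tfce))])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_direction_fwer_controlled(self):
        # positive-tail familywise rate on null data stays near alpha
        root = np.random.SeedSequence(11)
        data_rng = np.random.default_rng(root.spawn(1)[0])
        seeds = np.random.SeedSequence(12).generate_state(200)
        hits = 0
        for i in range(200):
            betas = data_rng.standard_normal((16, 20))
            res = tfce.group_permutation(betas, n_perm=200, seed=int(seeds[i]))
            hits += bool((res.tfce > res.upper).any())
        # alpha=0.05, n=200 -> 3 binomial SEs above is ~0.096
        assert hits / 200 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_odd_contact_count_handled(self, rng):
        betas = rng.standard_normal((9, 10))
        res = tfce.group_permutation(betas, n_perm=100, seed=1)
        assert res.max_stats.size == 100

    def test_too_few_contacts_rejected(self, rng):
        with pytest.raises(ValueError):
            tfce.group_permutation(rng.standard_normal((3, 10)), n_perm=10)


@pytest.fixture(scope="module")
def contact_data():
    cfg_rng = np.random.default_rng(21)
    n = 60
    sv = cfg_rng.choice(np.arange(10, 210, 10), size=n).astype(float)
    sv_prev = cfg_rng.choice(np.arange(10, 210, 10), size=n).astype(float)
    X = np.column_stack([np.ones(n), sv, sv_prev])
    names = ["const", "sv_current", "sv_previous"]
    return X, names, sv


class TestIndividualPermutation:
    def test_noiseless_effect_detected_only_for_its_regressor(self, contact_data):
        X, names, sv = contact_data
        t = np.linspace(-1, 1.5, 40)
        w = ((t > 0.2) & (t < 1.0)).astype(float)
        Y = 0.01 * np.outer(sv, w) + 1e-6 * np.random.default_rng(5).standard_normal(
            (60, 40)
        )
        res = tfce.individual_permutation(Y, X, names, n_perm=150, seed=3)
        assert res.significant[0]
        assert not res.significant[1]

    def test_extreme_timepoint_inside_effect_window(self, contact_data):
        X, names, sv = contact_data
        t = np.linspace(-1, 1.5, 40)
        w = ((t > 0.2) & (t < 1.0)).astype(float)
        Y = 0.01 * np.outer(sv, w) + 0.1 * np.random.default_rng(6).standard_normal(
            (60, 40)
        )
        res = tfce.individual_permutation(Y, X, names, n_perm=150, seed=3)
        assert w[res.extreme_time_idx[0]] == 1.0
        assert res.extreme_t[0] > 0

    def test_null_contacts_rate_bounded_by_directional_alphas(self):
        # a pure-noise contact triggers each one-tailed family at ~5%,
        # so the per-regressor rate is bounded by the two-direction
        # union (~2*alpha) plus Monte-Carlo error
        rng_data = np.random.default_rng(31)
        n, T = 40, 25
        sv = rng_data.choice(np.arange(10, 210, 10), size=n).astype(float)
        sv_prev = rng_data.choice(np.arange(10, 210, 10), size=n).astype(float)
        X = np.column_stack([np.ones(n), sv, sv_prev])
        names = ["const", "sv_current", "sv_previous"]
        seeds = np.random.SeedSequence(32).generate_state(100)
        hits = 0
        for i in range(100):
            Y = rng_data.standard_normal((n, T))
            res = tfce.individual_permutation(Y, X, names, n_perm=150, seed=int(seeds[i]))
            hits += bool(res.significant[0])
        assert 0.0 < hits / 100 <= 0.10 + 3 * np.sqrt(0.10 * 0.90 / 100)

    def test_too_few_trials_rejected(self, rng):
        X = np.column_stack([np.ones(4), rng.standard_normal(4), rng.standard_normal(4)])
        with pytest.raises(ValueError):
            tfce.individual_permutation(rng.standard_normal((4, 10)), X,
                                        ["const", "a", "b"], n_perm=10)


class TestClassification:
    def test_all_quiet_is_all_neither(self):
        table, props = tfce.classify_contacts(np.zeros(10, bool), np.zeros(10, bool))
        assert (table["category"] == "neither").all()
        assert props["frac_significant"] == 0.0

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        cur = rng.random(50) < 0.4
        prev = rng.random(50) < 0.4
        table, props = tfce.classify_contacts(cur, prev)
        counts = table["category"].value_counts()
        assert counts.sum() == 50
        total = sum(
            props[f"frac_{c}_all"]
            for c in ("current_only", "previous_only", "both", "neither")
        )
        assert total == pytest.approx(1.0)

    def test_proportions_among_significant(self):
        cur = np.array([True, True, False, False, False])
        prev = np.array([True, False, True, False, False])
        _, props = tfce.classify_contacts(cur, prev)
        assert props["n_significant"] == 3
        assert props["frac_both_significant"] == pytest.approx(1 / 3)


class TestClusterSummary:
    def test_single_point_cluster(self):
        t = time_axis()
        mask = np.zeros(t.size, bool)
        idx = int(np.argmin(np.abs(t - 0.7)))
        mask[idx] = True
        tf = np.zeros(t.size)
        tf[idx] = 12.0
        out = tfce.summarize_clusters(mask, tf, np.arange(100.0), -np.arange(100.0), t)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.cluster_size == 1
        assert row.start_ms == row.end_ms == row.peak_ms == pytest.approx(700.0)

    def test_cluster_size_from_span(self):
        # a run from 340 ms to 1500 ms on the 10-ms grid has 117 points
        t = time_axis()
        mask = (t >= 0.34 - 1e-9) & (t <= 1.5 + 1e-9)
        tf = np.where(mask, 5.0, 0.0)
        tf[np.argmin(np.abs(t - 0.71))] = 9.0
        out = tfce.summarize_clusters(mask, tf, np.arange(100.0), -np.arange(100.0), t)
        row = out.iloc[0]
        assert row.cluster_size == 117
        assert row.start_ms == pytest.approx(340.0)
        assert row.end_ms == pytest.approx(1500.0)
        assert row.peak_ms == pytest.approx(710.0)
        assert row.cluster_size == (row.end_ms - row.start_ms) / 10 + 1

    def test_empty_mask_empty_table(self):
        t = time_axis()
        out = tfce.summarize_clusters(
            np.zeros(t.size, bool), np.zeros(t.size), np.arange(10.0),
            -np.arange(10.0), t
        )
        assert len(out) == 0


class TestTimeFrequency:
    def test_strong_block_detected(self, rng):
        n_contacts, n_freq, n_time = 16, 10, 20
        betas = 0.3 * rng.standard_normal((n_contacts, n_freq, n_time))
        betas[:, 3:6, 8:14] += 4.0
        res = tfce.tf_group_permutation(betas, n_perm=150, seed=2)
        assert res.mask[3:6, 8:14].all()
        assert res.mask.mean() < 0.5

    def test_null_maps_rarely_significant(self, rng):
        seeds = np.random.SeedSequence(41).generate_state(60)
        hits = 0
        for i in range(60):
            betas = rng.standard_normal((12, 6, 10))
            res = tfce.tf_group_permutation(
                betas, tfce.TFCEParams(E=1, H=2, n_levels=40),
                n_perm=100, seed=int(seeds[i]),
            )
            hits += bool(res.mask.any())
        assert hits / 60 <= 0.25  # two one-tailed tests at 5% plus MC noise


class TestSymmetryBootstrap:
    def test_mirror_sample_has_zero_skewness(self):
        betas = np.array([[1.0], [-1.0], [2.0], [-2.0], [0.5], [-0.5]])
        res = tfce.skewness_symmetry_test(betas, n_boot=500, seed=0)
        assert res.skewness[0] == pytest.approx(0.0)
        assert res.symmetric[0]

    def test_hand_computed_skewness(self):
        # {0,0,0,10}: mean 2.5, median 0, sd 5 -> skewness 1.5
        val = tfce.pearson_median_skewness(np.array([0.0, 0.0, 0.0, 10.0]))
        assert val == pytest.approx(1.5)

    def test_skewed_distribution_flagged(self, rng):
        betas = rng.exponential(1.0, size=(200, 3))
        res = tfce.skewness_symmetry_test(betas, n_boot=2000, seed=1)
        assert not res.symmetric.any()
        assert (res.ci_low > 0).all()

    def test_gaussian_data_mostly_symmetric(self, rng):
        betas = rng.standard_normal((150, 10))
        res = tfce.skewness_symmetry_test(betas, n_boot=2000, seed=2)
        assert res.symmetric.mean() >= 0.8

    def test_resample_shared_across_timepoints(self):
        # duplicated columns must produce identical bootstrap CIs
        rng = np.random.default_rng(9)
        col = rng.standard_normal(50)
        betas = np.column_stack([col, col])
        res = tfce.skewness_symmetry_test(betas, n_boot=300, seed=5)
        assert res.ci_low[0] == res.ci_low[1]
        assert res.ci_high[0] == res.ci_high[1]
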