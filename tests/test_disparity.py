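import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pmdisparity as pm
from pmdisparity.disparity import (
    absolute_disparity,
    band_shares,
    count_burdened_districts,
    disparity_change,
    ks_compare,
    scale_ratio,
    weighted_quantile,
    z_score,
)

positive_vectors = st.lists(st.floats(1.0, 200.0), min_size=3, max_size=40).map(np.array)


class TestWeightedQuantile:
    def test_equal_weights_reduce_to_linear_interpolation(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 100, rng.integers(2, 40))
            q = rng.uniform(0, 1, 5)
            got = weighted_quantile(x, q, np.full(x.size, 3.7))
            assert np.allclose(got, np.quantile(x, q, method="linear"), atol=1e-9)

    def test_monotone_in_q(self, rng):
        x = rng.uniform(0, 10, 30)
        w = rng.lognormal(0, 1, 30)
        qs = np.linspace(0, 1, 21)
        vals = weighted_quantile(x, qs, w)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_quantile([1, 2, 3], [0.5], [1, -1, 1])
        with pytest.raises(ValueError):
            weighted_quantile([1, 2], [1.5])


class TestAbsoluteDisparity:
    def test_constant_vector_gives_zero(self):
        assert absolute_disparity(np.full(10, 42.0)).value == 0.0

    def test_closed_form_on_1_to_1000(self):
        # type-7: p01 at 0-based position 9.99 -> 10.99; p99 at 989.01 -> 990.01
        ad = absolute_disparity(np.arange(1.0, 1001.0))
        assert ad.p01 == pytest.approx(10.99, abs=1e-9)
        assert ad.p99 == pytest.approx(990.01, abs=1e-9)
        assert ad.value == pytest.approx(979.02, abs=1e-9)

    def test_matches_sort_based_quantile_oracle(self, rng):
        for _ in range(100):
            x = rng.uniform(10, 90, rng.integers(5, 200))
            ad = absolute_disparity(x)
            lo, hi = np.quantile(np.sort(x), [0.01, 0.99], method="linear")
            assert ad.value == pytest.approx(hi - lo, abs=1e-9)

    def test_shift_invariance(self, rng):
        x = rng.uniform(20, 80, 50)
        assert absolute_disparity(x + 13.5).value == pytest.approx(
            absolute_disparity(x).value, abs=1e-9)

    def test_requires_two_finite_values(self):
        with pytest.raises(ValueError):
            absolute_disparity([5.0])
        with pytest.raises(ValueError):
            absolute_disparity([5.0, np.nan])


class TestZScore:
    def test_identical_groups_give_zero_with_p_one(self, rng):
        x = rng.uniform(30, 70, 20)
        res = z_score(x, x.copy())
        assert res.z == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_groups_one_pooled_sd_apart_give_unit_z(self, rng):
        logs = rng.normal(np.log(50), 0.3, 40)
        shift = logs.std(ddof=1)  # equal-n equal-sd: pooled sd == each sd
        res = z_score(np.exp(logs + shift), np.exp(logs))
        assert res.z == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.lognormal(4, 0.3, 15)
        b = rng.lognormal(4.1, 0.25, 22)
        assert z_score(a, b).z == pytest.approx(-z_score(b, a).z, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=positive_vectors, b=positive_vectors, scale=st.floats(0.1, 50.0))
    def test_multiplicative_scale_invariance(self, a, b, scale):
        base = z_score(a, b)
        if base.degenerate:
            return
        scaled = z_score(scale * a, scale * b)
        assert scaled.z == pytest.approx(base.z, abs=1e-9)

    def test_log_base_invariance_via_power_transform(self, rng):
        # raising all PWCs to power k multiplies log means and sds by k
        a = rng.lognormal(4, 0.3, 18)
        b = rng.lognormal(4.05, 0.35, 18)
        assert z_score(a**2.5, b**2.5).z == pytest.approx(z_score(a, b).z, rel=1e-10)

    def test_ci_contains_z_and_sign_matches_means(self, rng):
        a = rng.lognormal(4.2, 0.3, 25)
        b = rng.lognormal(4.0, 0.3, 30)
        res = z_score(a, b)
        assert res.ci95[0] <= res.z <= res.ci95[1]
        assert np.sign(res.z) == np.sign(res.m1 - res.m2)
        assert res.s_pooled > 0

    def test_degenerate_and_error_cases(self):
        res = z_score([5.0, 5.0], [7.0, 7.0])
        assert res.z == 0.0 and res.degenerate and res.negligible
        with pytest.raises(ValueError):
            z_score([5.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            z_score([5.0, -1.0], [1.0, 2.0])


class TestKSCompare:
    def test_identical_weighted_samples_give_zero_d(self, rng):
        x = rng.normal(size=30)
        w = rng.lognormal(0, 0.5, 30)
        res = ks_compare(x, x.copy(), w, w.copy())
        assert res.d == 0.0

    def test_disjoint_supports_give_unit_d(self):
        res = ks_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.d == 1.0

    def test_unweighted_matches_scipy_reference(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(5, 80))
            n2 = int(rng.integers(5, 80))
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), 1, n2)
            ref = stats.ks_2samp(a, b, method="asymp")
            res = ks_compare(a, b)
            assert res.d == pytest.approx(ref.statistic, abs=1e-14)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_handles_ties_across_samples(self):
        res = ks_compare([1.0, 2.0, 2.0, 3.0], [2.0, 2.0, 4.0])
        ref = stats.ks_2samp([1.0, 2.0, 2.0, 3.0], [2.0, 2.0, 4.0], method="asymp")
        assert res.d == pytest.approx(ref.statistic, abs=1e-14)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([1.0, 2.0], [3.0], [0.0, 0.0], [1.0])
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


@pytest.fixture(scope="module")
def district_data():
    rng = np.random.default_rng(12)
    rows = []
    for d in range(30):
        base = rng.uniform(40, 70)
        for c in range(10):
            rows.append({
                "cluster_id": f"D{d}C{c}", "district_id": f"D{d}",
                "concentration": base + rng.normal(0, 8),
                "sample_weight": rng.lognormal(13, 0.5),
                "male": 0.5, "female": 0.5,
            })
    df = pd.DataFrame(rows)
    exposures = df[["cluster_id", "concentration"]].copy()
    clusters = df.drop(columns="concentration")
    return exposures, clusters


class TestCountBurdenedDistricts:
    def test_identical_compositions_never_significant(self, district_data):
        exposures, clusters = district_data
        out = count_burdened_districts(exposures, clusters, "gender", "male",
                                       scheme={"gender": ["male", "female"]})
        row = out.iloc[0]
        assert row.n_higher_significant == 0
        assert row.n_evaluable == 30

    def test_alpha_zero_never_significant(self, district_data):
        exposures, clusters = district_data
        clusters = clusters.copy()
        # give females a strong high-concentration tilt, then forbid rejections
        clusters["female"] = np.linspace(0.05, 0.95, len(clusters))
        clusters["male"] = 1.0 - clusters["female"]
        out = count_burdened_districts(exposures, clusters, "gender", "male",
                                       alpha=0.0,
                                       scheme={"gender": ["male", "female"]})
        assert out.iloc[0].n_higher_significant == 0

    def test_small_districts_not_evaluable(self, district_data):
        exposures, clusters = district_data
        single = clusters["cluster_id"] != "D0C0"
        out = count_burdened_districts(
            exposures[exposures["cluster_id"].isin(clusters[~single]["cluster_id"])],
            clusters[~single], "gender", "male",
            scheme={"gender": ["male", "female"]})
        assert out.iloc[0].n_evaluable == 0

    def test_strong_per_district_tilt_recovered(self):
        """Tilt +4 toward 'poorest' inside every district: counted
        higher-significant in >= 80% of 200 simulated districts."""
        cfg = pm.SimulationConfig(n_states=10, districts_per_state=20,
                                  clusters_per_district=30,
                                  grid_shape=(300, 300), seed=5)
        conc = pm.generate_concentration_field(cfg)
        clusters = pm.generate_clusters(cfg, conc)
        tilted = pd.concat([
            pm.inject_disparity(d, conc, "wealth", "poorest", 4.0)
            for _, d in clusters.groupby("district_id", sort=False)
        ], ignore_index=True)
        exposures = pm.assign_cluster_exposure(tilted, conc, pm.BufferPolicy())
        out = count_burdened_districts(exposures, tilted, "wealth", "richest",
                                       alpha=0.1)
        row = out[out["subgroup"] == "poorest"].iloc[0]
        assert row.n_evaluable == 200
        assert row.n_higher_significant >= 0.8 * row.n_evaluable


class TestBandShares:
    def test_shares_sum_to_100_within_each_partition_band(self, small_world, small_exposures):
        _, _, _, clusters = small_world
        table, _ = band_shares(small_exposures, clusters)
        sums = table.groupby(["band", "partition"])["share"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_identically_distributed_subgroups_split_evenly(self):
        rng = np.random.default_rng(3)
        n = 60
        exposures = pd.DataFrame({
            "cluster_id": [f"C{i}" for i in range(n)],
            "concentration": rng.uniform(30, 90, n),
        })
        clusters = pd.DataFrame({
            "cluster_id": exposures["cluster_id"],
            "sample_weight": rng.lognormal(13, 0.4, n),
            "male": 0.5, "female": 0.5,
        })
        table, _ = band_shares(exposures, clusters, scheme={"gender": ["male", "female"]})
        assert np.allclose(table["share"], 50.0, atol=1e-9)

    def test_subgroup_alone_in_top_cluster_owns_top_band(self):
        # weights push the p66 threshold above 3, so the gt_p66 band holds
        # exactly the top cluster, where only females live; the middle band
        # is empty and its rows are dropped (logged) rather than fabricated
        exposures = pd.DataFrame({
            "cluster_id": ["C0", "C1", "C2", "C3"],
            "concentration": [1.0, 2.0, 3.0, 100.0],
        })
        clusters = pd.DataFrame({
            "cluster_id": ["C0", "C1", "C2", "C3"],
            "sample_weight": [1.0, 1.0, 6.0, 2.0],
            "female": [0.0, 0.0, 0.0, 1.0],
            "male": [1.0, 1.0, 1.0, 0.0],
        })
        table, (lo, hi) = band_shares(exposures, clusters,
                                      scheme={"gender": ["male", "female"]})
        assert 3.0 < lo and hi < 100.0
        top = table[(table["band"] == "gt_p66") & (table["subgroup"] == "female")]
        assert top["share"].iloc[0] == pytest.approx(100.0)
        assert "p34_p66" not in set(table["band"])  # empty band omitted

    def test_band_thresholds_are_weighted_quantiles(self, small_world, small_exposures):
        _, _, _, clusters = small_world
        _, (lo, hi) = band_shares(small_exposures, clusters)
        df = small_exposures.merge(clusters, on="cluster_id")
        exp_lo, exp_hi = weighted_quantile(df["concentration"].to_numpy(),
                                           [0.34, 0.66],
                                           df["sample_weight"].to_numpy())
        assert (lo, hi) == (pytest.approx(exp_lo), pytest.approx(exp_hi))


class TestChangeAndScaleRatio:
    def test_equal_magnitudes_give_zero_change(self):
        assert disparity_change(0.05, -0.05).percent == 0.0

    def test_doubling_gives_plus_100_percent(self):
        assert disparity_change(0.05, 0.10).percent == pytest.approx(100.0)

    def test_sign_flip_flagged_with_zero_magnitude_change(self):
        ch = disparity_change(0.05, -0.05)
        assert ch.sign_flip and ch.percent == 0.0 and not ch.undefined

    def test_negligible_baseline_is_undefined(self):
        ch = disparity_change(0.009, 0.5)
        assert ch.undefined and np.isnan(ch.percent)

    def test_scale_ratio_closed_forms(self):
        assert scale_ratio(0.04, 0.04) == 1.0
        assert scale_ratio(0.04, 0.02) == 2.0
        assert scale_ratio(-0.04, 0.02) == -2.0  # direction reversal
        with pytest.raises(ValueError):
            scale_ratio(0.5, 0.005)
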