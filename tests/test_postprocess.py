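"""Record filtering, track repair, smoothing, correlations, enrichment, shafts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from filostoch.postprocess import (
    background_correct,
    cohort_ecdf,
    cross_correlate,
    effective_diameter,
    enrichment_length_change,
    filter_snapshots,
    repair_tracks,
    shaft_profile_fit,
    smooth_velocity,
    spearman_matrix,
    two_plus_enrichment_effect,
)
from filostoch.synthetic import gen_intensity_table


def area_for_diameter(d):
    return np.pi * (d / 2.0) ** 2


class TestFilterSnapshots:
    def test_diameter_boundary_strict_below(self):
        rec = pd.DataFrame(
            {
                "base_area_um2": [area_for_diameter(0.49), area_for_diameter(0.50)],
                "length_um": [10.0, 10.0],
            }
        )
        out = filter_snapshots(rec)
        assert len(out) == 1
        assert effective_diameter(out["base_area_um2"])[0] == pytest.approx(0.50)

    def test_counting_with_both_filters(self):
        diam = [0.3, 0.4, 0.45] + [1.0] * 7  # 3 below the diameter cut
        length = [10.0] * 3 + [3.0, 25.0] + [10.0] * 5  # 2 outside [5, 20]
        rec = pd.DataFrame(
            {"base_area_um2": [area_for_diameter(d) for d in diam], "length_um": length}
        )
        out = filter_snapshots(rec, length_bounds=(5.0, 20.0))
        assert len(out) == 5

    def test_empty_input(self):
        rec = pd.DataFrame({"base_area_um2": [], "length_um": []})
        assert len(filter_snapshots(rec)) == 0

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError):
            filter_snapshots(pd.DataFrame({"length_um": [1.0]}))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "base_area_um2": rng.exponential(1.0, 100),
                "length_um": rng.exponential(8.0, 100),
            }
        )
        once = filter_snapshots(rec, length_bounds=(5.0, 20.0))
        twice = filter_snapshots(once, length_bounds=(5.0, 20.0))
        pd.testing.assert_frame_equal(once, twice)


class TestBackgroundCorrect:
    def test_equal_means_zero(self):
        assert background_correct(100.0, 100.0) == 0.0

    def test_simple_difference(self):
        assert background_correct(150.0, 100.0) == 50.0

    def test_negative_preserved(self):
        assert background_correct(90.0, 100.0) == -10.0


def make_track(tid, frames, x, y):
    return pd.DataFrame(
        {"track_id": tid, "frame": frames, "x_um": x, "y_um": y, "length_um": 1.0}
    )


class TestRepairTracks:
    def test_merge_inside_all_gates(self):
        df = pd.concat(
            [
                make_track(0, range(0, 5), 0.0, 0.0),
                make_track(1, range(8, 12), 0.5, 0.0),  # 0.5 µm, 3 missing frames
            ]
        )
        out, mapping = repair_tracks(df)
        assert mapping[1] == 0
        assert out["track_id"].nunique() == 1

    def test_distance_gate_blocks(self):
        df = pd.concat(
            [make_track(0, range(0, 5), 0.0, 0.0), make_track(1, range(8, 12), 1.2, 0.0)]
        )
        _, mapping = repair_tracks(df)
        assert mapping[1] == 1

    def test_gap_gate_blocks(self):
        df = pd.concat(
            [make_track(0, range(0, 5), 0.0, 0.0), make_track(1, range(12, 15), 0.2, 0.0)]
        )
        _, mapping = repair_tracks(df)  # 7 missing frames
        assert mapping[1] == 1

    def test_overlap_blocks(self):
        df = pd.concat(
            [make_track(0, range(0, 6), 0.0, 0.0), make_track(1, range(5, 9), 0.2, 0.0)]
        )
        _, mapping = repair_tracks(df)
        assert mapping[1] == 1

    def test_chain_merges_to_one_regardless_of_order(self):
        frags = [
            make_track(0, range(0, 3), 0.0, 0.0),
            make_track(1, range(5, 8), 0.4, 0.0),
            make_track(2, range(10, 13), 0.8, 0.0),
        ]
        for perm in itertools.permutations(frags):
            df = pd.concat(perm)
            out, mapping = repair_tracks(df)
            assert out["track_id"].nunique() == 1
            assert set(mapping.values()) == {0}

    def test_never_creates_overlap(self):
        # A and C both near B but A/C overlap each other in time
        df = pd.concat(
            [
                make_track(0, range(0, 4), 0.0, 0.0),
                make_track(1, range(6, 9), 0.3, 0.0),
                make_track(2, range(2, 5), 0.35, 0.0),
            ]
        )
        out, _ = repair_tracks(df)
        for _, g in out.groupby("track_id"):
            assert g["frame"].is_unique


class TestSmoothVelocity:
    def test_cubic_reproduced_in_interior(self):
        t = np.arange(50, dtype=float)
        x = 0.01 * t**3 - 0.3 * t**2 + t + 5
        res = smooth_velocity(x, frame_interval_min=1.0)
        assert np.allclose(res["smoothed"][5:-5], x[5:-5], atol=1e-8)

    def test_linear_ramp_velocity(self):
        x = 2.0 * np.arange(40, dtype=float)
        res = smooth_velocity(x, frame_interval_min=1.0)
        assert np.allclose(res["velocity"][5:-5], 2.0, atol=1e-9)

    def test_short_series_flagged(self):
        res = smooth_velocity(np.arange(5, dtype=float))
        assert res["flagged"]

    def test_noise_variance_reduced_to_filter_gain(self):
        # the SG derivative is a linear filter; on white noise its variance
        # equals sigma^2 * sum(c^2) with c the derivative kernel
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200_000)
        res = smooth_velocity(x, frame_interval_min=1.0)
        kernel = signal.savgol_coeffs(11, 3, deriv=1, delta=1.0)
        expected = np.sum(kernel**2)
        got = res["velocity"][11:-11].var()
        assert got == pytest.approx(expected, rel=0.02)
        assert got < np.diff(x).var()  # beats finite differences


class TestSpearmanMatrix:
    def test_two_fov_average(self):
        # fov A: perfect agreement; fov B: perfect reversal -> mean 0
        a = pd.DataFrame({"fov": 0, "u": [1, 2, 3, 4], "v": [1, 2, 3, 4]})
        b = pd.DataFrame({"fov": 1, "u": [1, 2, 3, 4], "v": [4, 3, 2, 1]})
        m = spearman_matrix(pd.concat([a, b]), ["u", "v"])
        assert m.mean.loc["u", "v"] == pytest.approx(0.0)
        assert m.n_fov.loc["u", "v"] == 2

    def test_diagonal_is_one(self):
        df = pd.DataFrame({"fov": 0, "u": [1.0, 5.0, 2.0, 9.0]})
        m = spearman_matrix(df, ["u"])
        assert m.mean.loc["u", "u"] == 1.0

    def test_constant_variable_excluded(self):
        a = pd.DataFrame({"fov": 0, "u": [1, 2, 3], "v": [1, 1, 1]})
        b = pd.DataFrame({"fov": 1, "u": [1, 2, 3], "v": [3, 2, 1]})
        m = spearman_matrix(pd.concat([a, b]), ["u", "v"])
        assert m.n_fov.loc["u", "v"] == 1
        assert m.mean.loc["u", "v"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "fov": np.repeat(np.arange(3), 50),
                "u": rng.standard_normal(150),
                "v": rng.standard_normal(150),
            }
        )
        m1 = spearman_matrix(df, ["u", "v"]).mean.loc["u", "v"]
        df2 = df.assign(u=np.exp(df["u"]), v=df["v"] ** 3)
        m2 = spearman_matrix(df2, ["u", "v"]).mean.loc["u", "v"]
        assert m1 == pytest.approx(m2)

    def test_planted_rank_structure_recovered(self):
        r = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.2], [0.0, 0.2, 1.0]])
        scene = gen_intensity_table(6, 500, r, seed=3)
        cols = [f"intensity_{c}" for c in scene.ground_truth["channels"]]
        m = spearman_matrix(scene.data["records"], cols)
        got = m.mean.to_numpy()
        assert np.all(np.abs(got - r) < 0.05)


class TestEnrichment:
    def test_hand_assigned_single_fov(self):
        # 4 records, 2 channels; medians split intensities into halves
        df = pd.DataFrame(
            {
                "fov": 0,
                "length_um": [10.0, 12.0, 8.0, 10.0],
                "intensity_a": [1.0, 4.0, 2.0, 3.0],
                "intensity_b": [1.0, 4.0, 3.0, 2.0],
            }
        )
        res = enrichment_length_change(df, ["intensity_a", "intensity_b"])
        fov_mean = 10.0
        # top halves: a -> records 1,3; b -> records 1,2
        # counts: rec0 -> 0, rec1 -> 2, rec2 -> 1, rec3 -> 1
        assert res.loc[0, "rel_change"] == pytest.approx(10.0 / fov_mean - 1)
        assert res.loc[1, "rel_change"] == pytest.approx(9.0 / fov_mean - 1)
        assert res.loc[2, "rel_change"] == pytest.approx(12.0 / fov_mean - 1)

    def test_null_association_near_zero(self):
        r = np.eye(3)
        scene = gen_intensity_table(8, 400, r, effect_two_plus=0.0, seed=4)
        cols = [f"intensity_{c}" for c in scene.ground_truth["channels"]]
        res = enrichment_length_change(scene.data["records"], cols)
        for k in range(4):
            assert res.loc[k, "ci_low"] < 0.0 < res.loc[k, "ci_high"]

    def test_planted_effect_recovered(self):
        scene = gen_intensity_table(8, 1000, np.eye(3), effect_two_plus=0.10, seed=5)
        cols = [f"intensity_{c}" for c in scene.ground_truth["channels"]]
        eff = two_plus_enrichment_effect(scene.data["records"], cols)
        assert eff == pytest.approx(0.10, abs=0.03)

    def test_permuted_lengths_null(self):
        rng = np.random.default_rng(6)
        scene = gen_intensity_table(8, 400, np.eye(3), effect_two_plus=0.10, seed=7)
        df = scene.data["records"].copy()
        df["length_um"] = rng.permutation(df["length_um"].to_numpy())
        cols = [f"intensity_{c}" for c in scene.ground_truth["channels"]]
        eff = two_plus_enrichment_effect(df, cols)
        assert abs(eff) < 0.03

    def test_requires_two_channels(self):
        with pytest.raises(ValueError):
            enrichment_length_change(pd.DataFrame({"fov": [0]}), ["intensity_a"])


class TestCohortECDF:
    def test_median_thresholds_partition(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "fov": 0,
                "length_um": rng.exponential(7.6, 200),
                "intensity_a": rng.lognormal(size=200),
                "intensity_b": rng.lognormal(size=200),
            }
        )
        res = cohort_ecdf(df, "intensity_a", "intensity_b", hi_pct=50, lo_pct=50)
        # complementary halves per channel: each cohort is ~a quarter
        assert res["both_high"]["n"] + res["both_low"]["n"] <= res["all"]["n"]
        assert res["both_high"]["n"] > 0 and res["both_low"]["n"] > 0

    def test_independent_intensities_matched_ecdfs(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "fov": np.repeat(np.arange(4), 500),
                "length_um": rng.exponential(7.6, 2000),
                "intensity_a": rng.lognormal(size=2000),
                "intensity_b": rng.lognormal(size=2000),
            }
        )
        res = cohort_ecdf(df, "intensity_a", "intensity_b")
        from filostoch.inference import ks_two_sample

        ks = ks_two_sample(res["both_high"]["x"], res["both_low"]["x"])
        n1, n2 = res["both_high"]["n"], res["both_low"]["n"]
        crit = 1.63 * np.sqrt((n1 + n2) / (n1 * n2))  # ~alpha 0.01
        assert ks < crit

    def test_planted_effect_shifts_high_cohort(self):
        rng = np.random.default_rng(10)
        n = 2000
        ia = rng.lognormal(size=n)
        ib = rng.lognormal(size=n)
        lengths = rng.exponential(7.6, n)
        hi = (ia > np.quantile(ia, 0.7)) & (ib > np.quantile(ib, 0.7))
        lengths[hi] *= 1.5
        df = pd.DataFrame(
            {"fov": 0, "length_um": lengths, "intensity_a": ia, "intensity_b": ib}
        )
        res = cohort_ecdf(df, "intensity_a", "intensity_b")
        assert np.median(res["both_high"]["x"]) > np.median(res["both_low"]["x"])

    def test_low_n_flagged(self):
        df = pd.DataFrame(
            {
                "fov": 0,
                "length_um": np.arange(12.0),
                "intensity_a": np.arange(12.0),
                "intensity_b": np.arange(12.0),
            }
        )
        res = cohort_ecdf(df, "intensity_a", "intensity_b")
        assert res["both_high"]["low_n"]


class TestCrossCorrelate:
    def test_identity_peak_at_zero(self):
        rng = np.random.default_rng(11)
        v = rng.standard_normal(200)
        res = cross_correlate([v], [np.abs(v)], max_shift=5)
        assert res.loc[0, "correlation"] == pytest.approx(1.0)

    def test_lagged_intensity_peaks_negative(self):
        # I(t) = |v(t + k)|: intensity anticipates velocity -> peak at -k
        rng = np.random.default_rng(12)
        k = 3
        v = rng.standard_normal(300)
        intensity = np.abs(np.roll(v, -k))
        res = cross_correlate([v[: 300 - k]], [intensity[: 300 - k]], max_shift=6)
        assert res["correlation"].idxmax() == -k

    def test_independent_noise_null(self):
        rng = np.random.default_rng(13)
        vs = [rng.standard_normal(150) for _ in range(40)]
        js = [rng.standard_normal(150) for _ in range(40)]
        res = cross_correlate(vs, js, max_shift=4)
        se = 1.0 / np.sqrt(150)
        assert np.all(np.abs(res["correlation"]) < 3 * se)

    def test_short_series_skipped(self):
        res = cross_correlate([np.arange(5.0)], [np.arange(5.0)], max_shift=5)
        assert res["n"].sum() == 0


class TestShaftProfileFit:
    def test_exact_exponential(self):
        z = np.linspace(0, 10, 30)
        res = shaft_profile_fit(z, np.exp(-z / 3.0))
        assert res["param"] == pytest.approx(3.0, abs=1e-9)

    def test_exact_line(self):
        z = np.linspace(0, 10, 20)
        res = shaft_profile_fit(z, 5.0 - 0.2 * z, kind="linear")
        assert res["param"] == pytest.approx(-0.2, abs=1e-12)

    def test_nonpositive_values_excluded(self):
        z = np.arange(8.0)
        y = np.exp(-z / 2.0)
        y[3] = -0.1
        res = shaft_profile_fit(z, y)
        assert res["n_excluded"] == 1
        assert res["param"] == pytest.approx(2.0, abs=0.1)

    def test_bootstrap_ci_coverage(self):
        # 66% residual-bootstrap interval covers the true decay length in
        # at least ~60% of repeated noisy fits
        rng = np.random.default_rng(14)
        z = np.linspace(0, 6, 25)
        truth = 3.0
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            y = np.exp(-z / truth) * np.exp(rng.normal(0, 0.1, z.size))
            res = shaft_profile_fit(z, y, n_bootstrap=200, seed=rep)
            lo, hi = res["ci"]
            hits += lo <= truth <= hi
        assert hits / n_rep >= 0.55
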