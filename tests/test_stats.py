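"""Summary metrics, similarity, Mann-Whitney comparisons."""

import itertools

import numpy as np
import pytest

from adcfmri import stats
from adcfmri.errors import DataError, ParameterError
from adcfmri.stats import (
    MapRecord,
    ZMap,
    average_subject_maps,
    breathhold_zthresh,
    map_similarity,
    mean_variance_explained,
    pairwise_tests,
    percent_significant,
    similarity_suite,
)


class TestThresholdConstant:
    def test_p_001_rounds_to_3_09(self):
        assert round(breathhold_zthresh(0.001), 2) == 3.09

    def test_inverse_of_survival(self):
        from scipy.stats import norm

        assert norm.sf(breathhold_zthresh(0.001)) == pytest.approx(0.001, rel=1e-9)


class TestPercentSignificant:
    def test_all_zero_map(self):
        zm = ZMap(np.zeros((5, 5, 2)), np.ones((5, 5, 2), bool))
        assert percent_significant(zm, np.ones((5, 5, 2), bool), 3.09) == 0.0

    def test_direct_count(self):
        values = np.zeros(100)
        values[:10] = 5.0
        zm = ZMap(values.reshape(10, 10, 1), np.ones((10, 10, 1), bool))
        assert percent_significant(zm, np.ones((10, 10, 1), bool), 3.09) == 10.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        zm = ZMap(rng.normal(2.5, 1.0, (10, 10, 4)), np.ones((10, 10, 4), bool))
        mask = np.ones((10, 10, 4), bool)
        sweep = [percent_significant(zm, mask, t) for t in np.arange(2.0, 3.51, 0.1)]
        assert all(a >= b for a, b in zip(sweep, sweep[1:]))

    def test_empty_mask(self):
        zm = ZMap(np.zeros((2, 2, 1)), np.ones((2, 2, 1), bool))
        with pytest.raises(ParameterError):
            percent_significant(zm, np.zeros((2, 2, 1), bool), 3.09)

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(3.0, 1.0, 60)
        zm1 = ZMap(values.reshape(5, 4, 3), np.ones((5, 4, 3), bool))
        perm = rng.permutation(60)
        zm2 = ZMap(values[perm].reshape(5, 4, 3), np.ones((5, 4, 3), bool))
        m = np.ones((5, 4, 3), bool)
        assert percent_significant(zm1, m, 3.09) == percent_significant(zm2, m, 3.09)


class TestVarianceExplained:
    def _xmap(self, rmax_values):
        from adcfmri.lagmap import XCorrMap

        rmax = np.asarray(rmax_values, float).reshape(-1, 1, 1)
        shape = rmax.shape
        return XCorrMap(
            rmax=rmax,
            latency_s=np.full(shape, -10.0),
            n_overlap=np.full(shape, 100.0),
            zmax=np.zeros(shape),
            valid=np.ones(shape, bool),
            mask=np.ones(shape, bool),
            lags_s=np.arange(-30.0, 0.1, 0.5),
        )

    def test_uniform_half(self):
        assert mean_variance_explained(self._xmap([0.5] * 4)) == pytest.approx(25.0)

    def test_zero(self):
        assert mean_variance_explained(self._xmap([0.0] * 4)) == 0.0

    def test_mixed_arithmetic(self):
        assert mean_variance_explained(self._xmap([0.2, 0.4, 0.6])) == pytest.approx(
            18.666666, abs=1e-4
        )

    def test_no_valid_voxels(self):
        xm = self._xmap([0.5])
        xm.valid[:] = False
        with pytest.raises(DataError):
            mean_variance_explained(xm)


class TestAveraging:
    def test_identical_runs(self):
        rng = np.random.default_rng(0)
        zm = ZMap(rng.normal(size=(4, 4, 2)), np.ones((4, 4, 2), bool))
        avg = average_subject_maps([zm, zm])
        assert np.allclose(avg.values, zm.values)

    def test_elementwise_mean(self):
        a = ZMap(np.full((2, 2, 1), 2.0), np.ones((2, 2, 1), bool))
        b = ZMap(np.full((2, 2, 1), 4.0), np.ones((2, 2, 1), bool))
        assert np.allclose(average_subject_maps([a, b]).values, 3.0)

    def test_validity_propagates(self):
        valid_a = np.ones((2, 2, 1), bool)
        valid_b = valid_a.copy()
        valid_b[0, 0, 0] = False
        avg = average_subject_maps(
            [ZMap(np.ones((2, 2, 1)), valid_a), ZMap(np.ones((2, 2, 1)), valid_b)]
        )
        assert not avg.valid[0, 0, 0] and avg.valid.sum() == 3


class TestSimilarity:
    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(0)
        shape = (25, 20, 20)  # 10^4 voxels
        a = ZMap(rng.normal(size=shape), np.ones(shape, bool))
        b = ZMap(rng.normal(size=shape), np.ones(shape, bool))
        assert abs(map_similarity(a, b)) < 0.1

    def test_constructed_half_correlation(self):
        rng = np.random.default_rng(1)
        n = 40_000
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        shape = (40, 40, 25)
        z = map_similarity(
            ZMap(x.reshape(shape), np.ones(shape, bool)),
            ZMap(y.reshape(shape), np.ones(shape, bool)),
        )
        assert z == pytest.approx(np.arctanh(0.5), abs=0.05)

    def test_duplicated_map_flagged_degenerate_high(self):
        rng = np.random.default_rng(2)
        zm = ZMap(rng.normal(size=(5, 5, 4)), np.ones((5, 5, 4), bool))
        with pytest.warns(UserWarning, match="degenerate"):
            z = map_similarity(zm, zm)
        assert np.isfinite(z) and z > 10

    def test_constant_map_errors(self):
        zm = ZMap(np.ones((5, 5, 4)), np.ones((5, 5, 4), bool))
        other = ZMap(np.random.default_rng(0).normal(size=(5, 5, 4)), np.ones((5, 5, 4), bool))
        with pytest.raises(DataError):
            map_similarity(zm, other)


class TestSimilaritySuite:
    def _records(self):
        rng = np.random.default_rng(3)
        shape = (6, 6, 4)
        shared = rng.normal(size=shape)
        recs = []
        for subj in ("s1", "s2"):
            for run in ("r1", "r2"):
                noisy = shared + 0.5 * rng.normal(size=shape)
                recs.append(
                    MapRecord(subj, "breathhold", run, ZMap(noisy, np.ones(shape, bool)))
                )
            recs.append(
                MapRecord(subj, "resting", "r1",
                          ZMap(shared + rng.normal(size=shape), np.ones(shape, bool)))
            )
        # a third subject carrying pure noise
        recs.append(
            MapRecord("s3", "breathhold", "r1",
                      ZMap(rng.normal(size=shape), np.ones(shape, bool)))
        )
        recs.append(
            MapRecord("s3", "breathhold", "r2",
                      ZMap(rng.normal(size=shape), np.ones(shape, bool)))
        )
        return recs

    def test_shared_structure_beats_noise_subject(self):
        out = similarity_suite(self._records())
        inter = out["inter_subject"]
        bh = inter[inter.condition == "breathhold"].set_index("subject").similarity_z
        assert bh["s1"] > bh["s3"] and bh["s2"] > bh["s3"]

    def test_intra_and_cross_tables_populated(self):
        out = similarity_suite(self._records())
        assert set(out["intra_subject"].subject) == {"s1", "s2", "s3"}
        assert set(out["cross_condition"].subject) == {"s1", "s2"}

    def test_single_run_subject_skipped_with_warning(self):
        recs = self._records()[:1]
        with pytest.warns(UserWarning, match="only one breath-hold run"):
            out = similarity_suite(recs)
        assert out["intra_subject"].empty


class TestMannWhitney:
    def test_exact_enumeration_case(self):
        """{1,2,3} vs {4,5,6}: U = 0 and the exact two-tailed p is 2/20."""
        df = pairwise_tests({"a": [1, 2, 3], "b": [4, 5, 6]})
        row = df.iloc[0]
        assert row.U == 0.0
        assert row.p_raw == pytest.approx(0.1, rel=1e-12)
        assert row.p_bonferroni == pytest.approx(0.1, rel=1e-12)  # one pair tested

    def test_bonferroni_times_six_for_four_groups(self):
        groups = {
            "a": [1, 2, 3],
            "b": [4, 5, 6],
            "c": [7, 8, 9],
            "d": [10, 11, 12],
        }
        df = pairwise_tests(groups)
        assert len(df) == 6
        ab = df[(df.group_a == "a") & (df.group_b == "b")].iloc[0]
        assert ab.p_bonferroni == pytest.approx(min(1.0, 0.1 * 6), rel=1e-12)

    def test_identical_groups_capped_at_one(self):
        df = pairwise_tests({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert df.iloc[0].p_bonferroni == 1.0

    def test_label_swap_symmetry(self):
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        p1 = pairwise_tests({"a": x, "b": y}).iloc[0].p_raw
        p2 = pairwise_tests({"a": y, "b": x}).iloc[0].p_raw
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than"):
            df = pairwise_tests({"a": [1, 2], "b": [3, 4, 5], "c": [6, 7, 8]})
        assert set(df.group_a) | set(df.group_b) == {"b", "c"}

    def test_exact_p_matches_enumeration_oracle(self):
        """Brute-force enumeration of all C(6,3) label arrangements."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = x + y
        u_obs = sum(1 for xi in x for yj in y if xi > yj)

        def u_stat(xs, ys):
            return sum(1 for xi in xs for yj in ys if xi > yj)

        us = []
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            us.append(u_stat(xs, ys))
        us = np.asarray(us)
        n = len(x) * len(y)
        # two-tailed: as extreme in either direction
        p_exact = np.mean(np.minimum(us, n - us) <= min(u_obs, n - u_obs))
        df = pairwise_tests({"a": x, "b": y})
        assert df.iloc[0].p_raw == pytest.approx(p_exact, rel=1e-12)
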