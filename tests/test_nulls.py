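"""Time-shuffled surrogates, correlation nulls, KS and lesion permutation."""

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import topochron as tc
from conftest import make_avalanche

LABELS4 = ("A", "B", "C", "D")


def delay_matrix(values, labels=LABELS4):
    m = np.asarray(values, dtype=float)
    return tc.DelayMatrix(m, (~np.isnan(m)).astype(int), labels)


def length_matrix(values, labels=LABELS4):
    return tc.TractLengthMatrix(np.asarray(values, dtype=float), labels)


# ----------------------------------------------------------------- shuffling
class TestShuffle:
    def test_single_frame_unchanged(self):
        a = make_avalanche([{0, 1}], n_regions=3)
        assert tc.shuffle_avalanche(a, 0).frames == a.frames

    def test_frame_multiset_conserved(self, rng):
        a = make_avalanche([{0}, {1, 2}, set(), {3}], n_regions=4)
        for seed in range(20):
            s = tc.shuffle_avalanche(a, seed)
            assert sorted(map(sorted, s.frames)) == sorted(map(sorted, a.frames))
            assert s.n_bins == a.n_bins
            assert s.start_bin == a.start_bin

    def test_two_frame_orderings_equiprobable(self):
        a = make_avalanche([{0}, {1}], n_regions=2)
        swapped = sum(
            tc.shuffle_avalanche(a, seed).frames[0] == frozenset({1})
            for seed in range(1000)
        )
        # chi-squared against the exact two-outcome distribution
        chi2 = (swapped - 500) ** 2 / 500 + (1000 - swapped - 500) ** 2 / 500
        assert chi2 < stats.chi2.ppf(0.999, df=1)


# ------------------------------------------------------------------ ensemble
class TestSurrogateEnsemble:
    def _avalanches(self):
        return [
            make_avalanche([{0}, {1}, {2}], n_regions=4),
            make_avalanche([{1}, {3}, set(), {0}], n_regions=4),
            make_avalanche([{2}, {0, 3}], n_regions=4),
        ]

    def test_matches_reference_implementation(self):
        """Duplicate-route check: shuffle each avalanche with the same spawned
        streams and rebuild the subject matrix independently."""
        avs = self._avalanches()
        ens = tc.surrogate_delay_ensemble(
            avs, LABELS4, n_perm=10, seed=99, bin_width=2, fs=512.0, directed=True
        )
        streams = [np.random.default_rng(s)
                   for s in np.random.SeedSequence(99).spawn(10)]
        for p, rng in enumerate(streams):
            shuffled = [tc.shuffle_avalanche(a, rng) for a in avs]
            ref = tc.subject_delay_matrix(shuffled, LABELS4, 2, 512.0)
            got = ens.delays[p]
            np.testing.assert_array_equal(np.isnan(got), ~ref.present)
            np.testing.assert_allclose(got[ref.present], ref.mean_delay[ref.present])

    def test_bit_reproducible_from_seed(self):
        avs = self._avalanches()
        e1 = tc.surrogate_delay_ensemble(avs, LABELS4, 5, 7, 1, 512.0)
        e2 = tc.surrogate_delay_ensemble(avs, LABELS4, 5, 7, 1, 512.0)
        np.testing.assert_array_equal(e1.delays, e2.delays)

    def test_single_frame_avalanches_give_empty_surrogates(self):
        avs = [make_avalanche([{0, 1, 2}], n_regions=4)]
        ens = tc.surrogate_delay_ensemble(avs, LABELS4, 5, 0, 1, 512.0)
        assert np.isnan(ens.delays).all()

    def test_single_region_frames_give_no_pairs(self):
        avs = [make_avalanche([{0}, {0}, {0}], n_regions=4)]
        ens = tc.surrogate_delay_ensemble(avs, LABELS4, 5, 0, 1, 512.0)
        assert np.isnan(ens.delays).all()


# -------------------------------------------------------------- correlations
class TestLengthDelayCorrelation:
    def _pair(self, lengths, delays):
        n = len(lengths) + 1
        labels = tuple(f"R{i}" for i in range(n))
        L = np.full((n, n), np.nan); d = np.full((n, n), np.nan)
        for k, (l, v) in enumerate(zip(lengths, delays)):
            L[0, k + 1] = L[k + 1, 0] = l
            d[0, k + 1] = d[k + 1, 0] = v
        return (
            tc.DelayMatrix(d, (~np.isnan(d)).astype(int), labels),
            tc.TractLengthMatrix(L, labels),
        )

    def test_proportional_delays_give_spearman_one(self):
        d, L = self._pair([10, 20, 30, 40], [0.001, 0.002, 0.003, 0.004])
        r, p = tc.length_delay_correlation(d, L, "spearman")
        assert r == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        lengths = rng.uniform(10, 300, 100)
        delays = rng.uniform(0.001, 0.05, 100)
        d, L = self._pair(lengths, delays)
        r, _ = tc.length_delay_correlation(d, L, "spearman")
        oracle = stats.pearsonr(
            stats.rankdata(lengths), stats.rankdata(delays)
        )[0]
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_too_few_edges_rejected(self):
        d, L = self._pair([10, 20], [0.001, 0.002])
        with pytest.raises(ValueError, match="at least 3"):
            tc.length_delay_correlation(d, L)


class TestCorrelationNull:
    def _ensemble(self, rs_delays, labels):
        """Ensemble with prescribed per-permutation delay matrices."""
        return tc.SurrogateEnsemble(
            np.asarray(rs_delays), len(rs_delays), 0, labels
        )

    def test_add_one_rule(self, rng):
        n = 6
        labels = tuple(f"R{i}" for i in range(n))
        Lr = np.triu(rng.uniform(10, 200, (n, n)), 1); Lr = Lr + Lr.T
        Lr[Lr == 0] = np.nan
        L = tc.TractLengthMatrix(Lr, labels)
        # surrogates anti-correlated with length; observed perfectly correlated
        perms = []
        for _ in range(99):
            d = 1.0 / Lr + rng.uniform(0, 1e-4, Lr.shape)
            d = np.triu(d, 1); d = d + d.T; d[np.isnan(Lr)] = np.nan
            perms.append(d)
        ens = self._ensemble(perms, labels)
        p, rs = tc.correlation_null_test(0.999, ens, L, side="greater")
        assert p == pytest.approx(1 / 100)
        assert (rs < 0).all()

    def test_observed_equal_to_all_surrogates_gives_one(self, rng):
        n = 5
        labels = tuple(f"R{i}" for i in range(n))
        Lr = np.triu(rng.uniform(10, 200, (n, n)), 1); Lr = Lr + Lr.T
        Lr[Lr == 0] = np.nan
        L = tc.TractLengthMatrix(Lr, labels)
        d = Lr / 1000.0
        r_obs, _ = tc.length_delay_correlation(
            tc.DelayMatrix(d, (~np.isnan(d)).astype(int), labels), L
        )
        ens = self._ensemble([d] * 10, labels)
        p, rs = tc.correlation_null_test(r_obs, ens, L, side="greater")
        assert p == pytest.approx(1.0)

    def test_null_world_p_values_are_uniform(self, rng):
        """Calibration: with delays independent of length, the empirical p of
        the observed correlation is uniform over repeated experiments."""
        n = 8
        labels = tuple(f"R{i}" for i in range(n))
        Lr = np.triu(rng.uniform(10, 200, (n, n)), 1); Lr = Lr + Lr.T
        Lr[Lr == 0] = np.nan
        L = tc.TractLengthMatrix(Lr, labels)
        pvals = []
        for run in range(40):
            avs = []
            for _ in range(30):
                order = rng.permutation(n)[: rng.integers(2, 5)]
                avs.append(make_avalanche([{int(r)} for r in order], n_regions=n))
            dm = tc.subject_delay_matrix(avs, labels, 1, 512.0)
            r_obs, _ = tc.length_delay_correlation(dm, L)
            ens = tc.surrogate_delay_ensemble(avs, labels, 49, 1000 + run, 1, 512.0)
            p, _ = tc.correlation_null_test(r_obs, ens, L, side="greater")
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ------------------------------------------------------------------------ KS
class TestKS:
    def test_identical_samples_give_zero(self):
        res = tc.ks_compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_disjoint_supports_give_one(self):
        res = tc.ks_compare_groups([1.0, 2.0], [10.0, 11.0])
        assert res.statistic == 1.0

    def test_matches_brute_force_ecdf_scan(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1.2, 20)
        res = tc.ks_compare_groups(a, b)
        grid = np.concatenate([a, b])
        d = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert res.statistic == pytest.approx(d)

    def test_cdf_tables_are_monotone(self, rng):
        res = tc.ks_compare_groups(rng.normal(size=10), rng.normal(size=15))
        assert (np.diff(res.cdf_control["cdf"]) >= 0).all()
        assert res.cdf_patient["cdf"].iloc[-1] == pytest.approx(1.0)


# -------------------------------------------------------- edgewise differences
class TestEdgewise:
    def _setup(self):
        cm = np.full((4, 4), np.nan)
        cm[0, 1] = cm[1, 0] = 0.010
        cm[0, 2] = cm[2, 0] = 0.020
        controls_mean = delay_matrix(cm)
        pm = np.full((4, 4), np.nan)
        pm[0, 1] = pm[1, 0] = 0.012
        patient = delay_matrix(pm)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        return controls_mean, patient, mask

    def test_difference_and_flag(self):
        cm, patient, mask = self._setup()
        df = tc.edgewise_differences([patient], cm, [(0, 1), (0, 2)], [mask])
        assert len(df) == 1  # patient missing (0, 2)
        rec = df.iloc[0]
        assert rec["difference"] == pytest.approx(0.002)
        assert bool(rec["lesioned"])

    def test_record_count_equals_presence_oracle(self, rng):
        n = 6
        labels = tuple(f"R{i}" for i in range(n))
        cm = np.triu(rng.uniform(0.005, 0.02, (n, n)), 1); cm = cm + cm.T
        np.fill_diagonal(cm, np.nan)
        controls_mean = tc.DelayMatrix(cm, (~np.isnan(cm)).astype(int), labels)
        coverage = [(i, j) for i in range(n) for j in range(i + 1, n)]
        patients, masks, expected = [], [], 0
        for _ in range(5):
            pm = np.full((n, n), np.nan)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.6:
                        pm[i, j] = pm[j, i] = rng.uniform(0.005, 0.03)
            patients.append(tc.DelayMatrix(pm, (~np.isnan(pm)).astype(int), labels))
            masks.append(np.zeros((n, n), dtype=bool))
            expected += sum(1 for (i, j) in coverage if not np.isnan(pm[i, j]))
        df = tc.edgewise_differences(patients, controls_mean, coverage, masks)
        assert len(df) == expected


# ------------------------------------------------------------ lesion testing
class TestLesionPermutation:
    def _diffs(self, values, flags):
        return pd.DataFrame(
            {"patient": "P0", "i": 0, "j": np.arange(1, len(values) + 1),
             "difference": values, "lesioned": flags}
        )

    def test_all_equal_gives_p_near_one(self):
        df = self._diffs([0.002] * 6, [True, True, False, False, False, False])
        res = tc.lesion_permutation_test(df, n_perm=200, seed=0)
        assert res.pvalue == pytest.approx(1.0)

    def test_strong_shift_gives_minimal_p(self, rng):
        vals = np.concatenate([[0.010, 0.011], rng.uniform(0, 0.001, 50)])
        flags = np.concatenate([[True, True], np.zeros(50, dtype=bool)])
        res = tc.lesion_permutation_test(self._diffs(vals, flags), n_perm=1000, seed=1)
        assert res.pvalue == pytest.approx(1 / 1001)

    def test_null_matches_exhaustive_subset_enumeration(self):
        """5 records, 2 lesioned: the null support is exactly the C(5,2)=10
        subset means, hit approximately uniformly."""
        vals = [0.001, 0.002, 0.004, 0.008, 0.016]
        flags = [True, True, False, False, False]
        res = tc.lesion_permutation_test(
            self._diffs(vals, flags), n_perm=4000, seed=3, null_pool="all"
        )
        expected = sorted(np.mean(c) for c in combinations(vals, 2))
        got = Counter(np.round(res.null_distribution, 12))
        assert sorted(got) == pytest.approx(expected)
        counts = np.array([got[k] for k in sorted(got)])
        chi2 = ((counts - 400) ** 2 / 400).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_nonlesioned_pool_option(self):
        vals = [0.01, 0.01, 0.001, 0.002, 0.003]
        flags = [True, True, False, False, False]
        res = tc.lesion_permutation_test(
            self._diffs(vals, flags), n_perm=100, seed=0, null_pool="nonlesioned"
        )
        assert res.null_distribution.max() <= 0.003

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            tc.lesion_permutation_test(self._diffs([0.01] * 3, [True] * 3))

    def test_random_flags_give_uniform_p(self, rng):
        """Calibration: with lesion flags assigned at random the test's p is
        uniform (checked at 200 repetitions)."""
        vals = rng.normal(0.002, 0.001, 60)
        pvals = []
        for rep in range(200):
            flags = np.zeros(60, dtype=bool)
            flags[rng.choice(60, 12, replace=False)] = True
            res = tc.lesion_permutation_test(
                self._diffs(vals, flags), n_perm=99, seed=int(rng.integers(2**31))
            )
            pvals.append(res.pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------- convergence
class TestConvergence:
    def test_identical_subjects_give_zero_curve(self):
        m = np.full((4, 4), np.nan)
        m[0, 1] = m[1, 0] = 0.01; m[1, 2] = m[2, 1] = 0.02
        s = delay_matrix(m)
        res = tc.convergence_curve([s, s, s, s], n_orders=3, seed=0)
        np.testing.assert_allclose(res.curves, 0.0)

    def test_two_subject_single_point(self):
        a = np.full((4, 4), np.nan); b = np.full((4, 4), np.nan)
        for (i, j) in [(0, 1), (1, 2)]:
            a[i, j] = a[j, i] = 0.010
            b[i, j] = b[j, i] = 0.020
        res = tc.convergence_curve([delay_matrix(a), delay_matrix(b)],
                                   n_orders=1, seed=0)
        assert res.curves.shape == (1, 1)
        # |mean(A,B) - first| = 0.005 regardless of ordering
        assert res.curves[0, 0] == pytest.approx(0.005)

    def test_iid_subjects_curve_decreases(self, rng):
        labels = tuple(f"R{i}" for i in range(5))
        base = np.triu(rng.uniform(0.005, 0.02, (5, 5)), 1)
        base = base + base.T; np.fill_diagonal(base, np.nan)
        subs = []
        for _ in range(15):
            m = base * rng.uniform(0.8, 1.2, base.shape)
            m = np.triu(m, 1); m = m + m.T; np.fill_diagonal(m, np.nan)
            subs.append(tc.DelayMatrix(m, (~np.isnan(m)).astype(int), labels))
        res = tc.convergence_curve(subs, n_orders=8, seed=2)
        assert res.median_curve[-1] < res.median_curve[0]
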