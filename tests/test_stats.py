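"""Nonparametric battery: exact enumeration oracles, Monte-Carlo
calibration, correction rules, and the full study report."""

import itertools

import numpy as np
import pandas as pd
import pytest

import meniscus_strain as ms
from meniscus_strain.stats import StatsConfig


# --- independent enumeration oracles (brute force, no scipy) ---------------

def mw_exact_p_two_sided(a, b):
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = sorted(a) + sorted(b)
    n_a = len(a)

    def u_stat(group_a):
        group_b = [v for v in pooled if v not in group_a or group_a.count(v) < pooled.count(v)]
        # tie-free data assumed: simple count
        return sum(1 for x in group_a for y in group_b if x > y)

    observed = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2
    count = total = 0
    for comb in itertools.combinations(range(n), n_a):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n) if i not in comb]
        u = sum(1 for x in ga for y in gb if x > y)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p_two_sided(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus = ranks[d > 0].sum()
    n = len(d)
    total_rank = n * (n + 1) / 2
    observed_dev = abs(w_plus - total_rank / 2)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total_rank / 2) >= observed_dev - 1e-12:
            count += 1
    return count / 2 ** n


def friedman_stat_by_formula(M):
    """Textbook Friedman statistic (no ties): 12/(n k (k+1)) sum Rj^2 - 3n(k+1)."""
    from scipy.stats import rankdata
    n, k = M.shape
    R = rankdata(M, axis=1).sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3 * n * (k + 1)


def kruskal_stat_by_formula(groups):
    from scipy.stats import rankdata
    all_v = np.concatenate(groups)
    ranks = rankdata(all_v)
    n = len(all_v)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


# --- unit tests ------------------------------------------------------------

class TestMannWhitney:
    def test_separated_groups_exact(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.100."""
        U, p = ms.mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.100)
        assert p == pytest.approx(mw_exact_p_two_sided([1, 2, 3], [4, 5, 6]))

    def test_symmetric_null(self):
        _, p = ms.mann_whitney([1, 2], [1.5, 2.5])
        assert p == pytest.approx(mw_exact_p_two_sided([1, 2], [1.5, 2.5]))

    @pytest.mark.parametrize("seed", range(5))
    def test_enumeration_oracle_random_small(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.permutation(20)[:4].astype(float))
        b = list(rng.permutation(40)[:5] + 0.5)
        _, p = ms.mann_whitney(a, b)
        assert p == pytest.approx(mw_exact_p_two_sided(a, b), abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 within (0.03, 0.07) for two
        samples of 50 from the same distribution."""
        rng = np.random.default_rng(100)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            _, p = ms.mann_whitney(a, b)
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_empty_group(self):
        with pytest.raises(ValueError):
            ms.mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_positive_exact(self):
        """Six positive differences: exact two-sided p = 2/64 = 0.03125."""
        _, p = ms.wilcoxon_signed([1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(0.03125)
        assert p == pytest.approx(wilcoxon_exact_p_two_sided([1, 2, 3, 4, 5, 6]))

    def test_antisymmetric_pair(self):
        _, p = ms.wilcoxon_signed([-1.0, 1.5])
        assert p == pytest.approx(wilcoxon_exact_p_two_sided([-1.0, 1.5]))

    @pytest.mark.parametrize("seed", range(5))
    def test_enumeration_oracle_random_small(self, seed):
        rng = np.random.default_rng(seed + 50)
        d = rng.permutation(30)[:7] + 1.0
        d *= rng.choice([-1, 1], size=7)
        _, p = ms.wilcoxon_signed(list(d))
        assert p == pytest.approx(wilcoxon_exact_p_two_sided(d), abs=1e-12)

    def test_zero_differences_dropped_then_error(self):
        with pytest.raises(ValueError, match="zero"):
            ms.wilcoxon_signed([0.0, 0.0, 0.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(101)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            d = rng.normal(size=30)
            _, p = ms.wilcoxon_signed(d)
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestFriedman:
    def test_identically_ordered_blocks(self):
        """Six blocks each ranked (1, 2, 3): chi2_F = 12, confirmed by the
        rank-sum formula and a within-block permutation oracle."""
        M = np.tile([1.0, 2.0, 3.0], (6, 1)) + np.arange(6)[:, None] * 10
        chi2, p = ms.friedman(M)
        assert chi2 == pytest.approx(12.0)
        assert chi2 == pytest.approx(friedman_stat_by_formula(M))
        chi2_perm, p_perm = ms.friedman(M, n_permutations=2000, seed=0)
        assert chi2_perm == pytest.approx(12.0)
        # 6 identically ordered blocks: true permutation p = (1/6)^6 * ...
        assert p_perm < 0.01

    def test_identical_columns_null(self):
        M = np.tile([2.0, 2.0, 2.0], (5, 1))
        chi2, p = ms.friedman(M)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_formula_random(self):
        rng = np.random.default_rng(102)
        M = rng.normal(size=(10, 4))
        chi2, _ = ms.friedman(M)
        assert chi2 == pytest.approx(friedman_stat_by_formula(M), abs=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(103)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            M = rng.normal(size=(12, 3))
            _, p = ms.friedman(M)
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_degenerate_dimensions(self):
        with pytest.raises(ValueError):
            ms.friedman(np.zeros((1, 3)))


class TestKruskalWallis:
    def test_three_separated_pairs(self):
        """{1,2}, {3,4}, {5,6}: H = 4.571 by the rank formula."""
        groups = [[1, 2], [3, 4], [5, 6]]
        H, _ = ms.kruskal_wallis(groups)
        assert H == pytest.approx(4.571, abs=5e-4)
        assert H == pytest.approx(kruskal_stat_by_formula([np.asarray(g, float) for g in groups]))

    def test_identical_groups_null(self):
        H, p = ms.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert H == 0.0
        assert p == 1.0

    def test_two_group_equivalence_with_mann_whitney(self):
        """With two groups, H equals the squared standardized Mann-Whitney
        normal deviate (chi-square with 1 df)."""
        rng = np.random.default_rng(104)
        a = rng.normal(size=15)
        b = rng.normal(loc=0.5, size=17)
        H, _ = ms.kruskal_wallis([a, b])
        U, _ = ms.mann_whitney(a, b, exact_threshold=0)  # force asymptotic
        n1, n2 = len(a), len(b)
        mu = n1 * n2 / 2
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (U - mu) / sigma
        assert H == pytest.approx(z * z, abs=1e-9)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(105)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(size=12) for _ in range(3)]
            _, p = ms.kruskal_wallis(groups)
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestShapiroWilk:
    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            ms.shapiro_wilk([1.0, 2.0])

    def test_normal_draws_usually_pass(self):
        rng = np.random.default_rng(106)
        passes = sum(ms.shapiro_wilk(rng.normal(size=500))[1] > 0.05 for _ in range(200))
        assert passes >= 0.90 * 200

    def test_bimodal_mixture_usually_fails(self):
        rng = np.random.default_rng(107)
        fails = 0
        for _ in range(200):
            v = np.concatenate([rng.normal(-4, 1, 250), rng.normal(4, 1, 250)])
            fails += ms.shapiro_wilk(v)[1] < 0.05
        assert fails >= 0.95 * 200


class TestAdjustment:
    def test_holm_step_down(self):
        """{0.01, 0.02, 0.04} at alpha 0.05: Holm rejects all three
        (thresholds 0.05/3, 0.05/2, 0.05)."""
        adj, reject = ms.adjust_pvalues([0.01, 0.02, 0.04], "holm", 0.05)
        assert reject.all()
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])

    def test_bonferroni(self):
        adj, reject = ms.adjust_pvalues([0.01, 0.02, 0.04], "bonferroni", 0.05)
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.12])
        assert list(reject) == [True, False, False]

    def test_single_p_unchanged(self):
        for scheme in ("holm", "bonferroni"):
            adj, _ = ms.adjust_pvalues([0.03], scheme)
            assert adj[0] == pytest.approx(0.03)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(108)
        p = rng.uniform(size=10)
        adj, _ = ms.adjust_pvalues(p, "holm")
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ms.adjust_pvalues([0.5, 1.2])


class TestRankInvariance:
    def test_monotone_transform_leaves_tests_unchanged(self):
        """Rank-based tests are invariant under strictly increasing
        transformations of the data."""
        rng = np.random.default_rng(109)
        a = rng.normal(size=10)
        b = rng.normal(size=12)
        f = lambda x: np.exp(3 * x) + 5
        assert ms.mann_whitney(a, b) == pytest.approx(ms.mann_whitney(f(a), f(b)))
        M = rng.normal(size=(8, 3))
        assert ms.friedman(M)[0] == pytest.approx(ms.friedman(f(M))[0])
        groups = [rng.normal(size=7) for _ in range(3)]
        assert ms.kruskal_wallis(groups)[0] == pytest.approx(
            ms.kruskal_wallis([f(g) for g in groups])[0])


class TestStudyBattery:
    def test_degenerate_null_cohort_no_rejections(self):
        """Equal group means at sd = 0 (every specimen equals its group
        mean): no family rejects anywhere."""
        spec = ms.CohortSpec(
            n_per_group=6, load_levels=(1.0,),
            group_means={"axial": (-3.0, -3.0), "circumferential": (0.4, 0.4),
                         "radial": (0.4, 0.4)},
            group_sds={"axial": 0.0, "circumferential": 0.0, "radial": 0.0},
            seed=5)
        tab = ms.synthesize_cohort(spec)
        report = ms.run_study_stats(tab)
        # the normality screen legitimately flags the two-point (medial/
        # lateral scaled) distribution; no hypothesis contrast may reject
        contrasts = report[report.family != "normality"]
        assert len(contrasts) > 0
        assert not contrasts.significant.any()

    def test_report_schema_and_families(self):
        tab = ms.synthesize_cohort(ms.CohortSpec(n_per_group=5, seed=6))
        report = ms.run_study_stats(tab)
        assert {"family", "contrast", "test", "statistic", "p_raw", "p_adj",
                "significant"} <= set(report.columns)
        assert {"normality", "group", "location_omnibus", "attachments",
                "load_omnibus"} <= set(report.family)
        assert (report.p_adj >= report.p_raw - 1e-12).all()

    def test_shuffled_labels_near_nominal(self):
        """Permuting group labels makes the group family reject at roughly
        the nominal rate across replicates."""
        rng = np.random.default_rng(110)
        rates = []
        for rep in range(40):
            tab = ms.synthesize_cohort(ms.CohortSpec(n_per_group=8, load_levels=(1.0,), seed=200 + rep))
            ids = tab.specimen.unique()
            new_group = dict(zip(ids, rng.permutation(
                tab.groupby("specimen")["group"].first().values)))
            tab["group"] = tab.specimen.map(new_group)
            report = ms.run_study_stats(tab)
            grp = report[report.family == "group"]
            rates.append(grp.significant.mean())
        assert 0.01 <= np.mean(rates) <= 0.10

    def test_config_validation(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=1.5)
        with pytest.raises(ValueError):
            StatsConfig(correction="fdr")
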