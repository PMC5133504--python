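"""MB-MDR Steps 1-3: cell statistics, labeling, pooling, permutation maxT."""

import numpy as np
import pytest
from scipy import stats

from epistakit.datamodel import Trait
from epistakit.mbmdr import (PermutationPlan, all_pairs, build_risk_grid,
                             cell_statistic, codominant_adjust, compare_scans,
                             label_cells, maxt_scan, scan_gxe,
                             scan_main_effects, scan_pairs, speedmaxt_scan,
                             step2_statistic)
from epistakit.simulate import (PenetranceModel, SimConfig, simulate_genotypes,
                                simulate_trait, xor_table)

from conftest import make_genotypes


class TestCellStatistic:
    def test_binary_null_cell_zero(self):
        cell = np.r_[np.ones(5), np.zeros(5)]
        rest = np.r_[np.ones(50), np.zeros(50)]
        stat, p = cell_statistic(cell, rest, "binary")
        assert stat == 0.0 and p == 1.0

    def test_binary_matches_hand_chi2(self):
        # cell: 10 cases/10 controls; rest: 50 cases/950 controls
        cell = np.r_[np.ones(10), np.zeros(10)]
        rest = np.r_[np.ones(50), np.zeros(950)]
        stat, p = cell_statistic(cell, rest, "binary")
        tbl = np.array([[10, 10], [50, 950]])
        chi2, p_sp = stats.chi2_contingency(tbl, correction=False)[:2]
        assert abs(stat) == pytest.approx(chi2, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-12)
        assert stat > 0  # cell is case-enriched

    def test_continuous_equal_means_zero(self):
        cell = np.array([1.0, 2.0, 3.0])
        rest = np.array([0.0, 2.0, 4.0])
        stat, _ = cell_statistic(cell, rest, "continuous")
        assert stat == pytest.approx(0.0)

    def test_continuous_matches_welch(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 15))
            b = rng.normal(0.5, 2, rng.integers(3, 25))
            stat, p = cell_statistic(a, b, "continuous")
            t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
            assert stat == pytest.approx(t_sp, abs=1e-10)
            assert p == pytest.approx(p_sp, abs=1e-10)


class TestLabels:
    def test_null_grid_all_O(self):
        labels = label_cells(np.full(9, 50), np.zeros(9), np.ones(9))
        assert set(labels) == {"O"}

    def test_rule(self):
        counts = np.array([50, 50, 5])
        statistics = np.array([4.0, -4.0, 9.0])
        pvalues = np.array([0.04, 0.04, 0.002])
        labels = label_cells(counts, statistics, pvalues, alpha1=0.1, min_cell_count=10)
        assert list(labels) == ["H", "L", "O"]  # last cell undersized

    def test_trait_negation_swaps_H_and_L(self, rng):
        cells = rng.integers(0, 9, 200)
        y = rng.normal(0, 1, 200) + (cells == 4) * 1.5
        g1 = build_risk_grid(y, "continuous", cells, (3, 3), 0.1, 5)
        g2 = build_risk_grid(-y, "continuous", cells, (3, 3), 0.1, 5)
        swap = {"H": "L", "L": "H", "O": "O"}
        assert np.array_equal(np.vectorize(swap.get)(g1.labels), g2.labels)
        t1 = step2_statistic(g1, "continuous")
        t2 = step2_statistic(g2, "continuous")
        assert t1[2] == pytest.approx(t2[2])


class TestStep2:
    def test_all_O_grid_tmax_zero(self, rng):
        cells = rng.integers(0, 9, 100)
        y = rng.normal(0, 1, 100)
        grid = build_risk_grid(y, "continuous", cells, (3, 3), alpha1=1e-6)
        th, tl, tmax = step2_statistic(grid, "continuous")
        assert tmax == 0.0

    def test_single_H_cell_matches_pooling_oracle(self):
        # one cell holds all the cases
        cells = np.r_[np.zeros(20, int), np.ones(80, int)]
        y = np.r_[np.ones(20), np.zeros(80)]
        grid = build_risk_grid(y, "binary", cells, (3, 3), 0.1, 5)
        assert grid.labels.ravel()[0] == "H"
        th, _, _ = step2_statistic(grid, "binary")
        chi2 = stats.chi2_contingency(np.array([[20, 0], [0, 80]]),
                                      correction=False)[0]
        assert th == pytest.approx(chi2, abs=1e-10)

    def test_tmax_invariant_under_level_relabel(self, rng):
        cells = rng.integers(0, 9, 300)
        y = (rng.random(300) < 0.2 + 0.3 * (cells == 2)).astype(float)
        grid = build_risk_grid(y, "binary", cells, (3, 3), 0.1, 5)
        perm = rng.permutation(9)
        cells_p = perm[cells]
        grid_p = build_risk_grid(y, "binary", cells_p, (3, 3), 0.1, 5)
        assert step2_statistic(grid, "binary")[2] == \
            pytest.approx(step2_statistic(grid_p, "binary")[2])


class TestCodominantAdjust:
    def test_null_trait_residual_mean_zero(self, rng):
        y = rng.normal(5, 2, 300)
        fa = rng.integers(0, 3, 300)
        res = codominant_adjust(y, fa)
        assert abs(np.nanmean(res)) < 1e-10
        # adjustment on a null trait only recentres within genotype classes
        for lev in range(3):
            assert abs(res[fa == lev].mean()) < 1e-10

    def test_removes_pure_main_effect(self, rng):
        fa = rng.integers(0, 3, 500)
        fb = rng.integers(0, 3, 500)
        y = 2.0 * (fa == 1) + rng.normal(0, 1, 500)
        res = codominant_adjust(y, fa, fb)
        for lev in range(3):
            assert abs(res[fa == lev].mean()) < 0.2

    def test_empty_level_dropped(self, rng):
        fa = rng.integers(0, 2, 100)  # level 2 absent
        y = rng.normal(0, 1, 100)
        res = codominant_adjust(y, fa)
        assert np.isfinite(res).all()

    def test_missing_factor_gives_nan(self):
        y = np.arange(10, dtype=float)
        fa = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, -1])
        res = codominant_adjust(y, fa)
        assert np.isnan(res[-1]) and np.isfinite(res[:-1]).all()


def _small_scan_inputs(seed=0, n=200, p=8):
    g = simulate_genotypes(SimConfig(n_samples=n, n_snps=p, seed=seed,
                                     maf_range=(0.2, 0.5)))
    t = simulate_trait(g, [], "binary", seed=seed + 1, base=0.3)
    return g, t


class TestMaxtScan:
    def test_single_pair_adjusted_equals_raw(self):
        g, t = _small_scan_inputs()
        res = maxt_scan(g, t, [(0, 1)], PermutationPlan(B=200, seed=2))
        r = res.results[0]
        assert r.p_adjusted == r.p_raw

    def test_adjusted_monotone_in_tmax_and_geq_raw(self):
        g, t = _small_scan_inputs(seed=5)
        res = maxt_scan(g, t, all_pairs(8), PermutationPlan(B=300, seed=3))
        rs = sorted(res.results, key=lambda r: -r.t_max)
        assert all(a.p_adjusted <= b.p_adjusted for a, b in zip(rs, rs[1:]))
        assert all(r.p_adjusted >= r.p_raw for r in res.results)
        assert all(1 / 301 <= r.p_adjusted <= 1 for r in res.results)

    def test_main_scan_consistent_with_pair_machinery(self):
        # a 1-SNP grid must equal a pair grid whose second factor is constant
        g, t = _small_scan_inputs(seed=7)
        plan = PermutationPlan(B=150, seed=4)
        main = scan_main_effects(g, t, plan, snps=[2])
        env = Trait("const", "categorical", np.zeros(g.n_samples))
        via_pair = scan_gxe(g, t, env, plan, snps=[2])
        assert main.results[0].t_max == pytest.approx(via_pair.results[0].t_max)
        assert main.results[0].p_adjusted == via_pair.results[0].p_adjusted

    def test_planted_main_effect_ranks_first(self):
        g = simulate_genotypes(SimConfig(n_samples=600, n_snps=10, seed=8,
                                         maf_range=(0.3, 0.5)))
        t = simulate_trait(g, [PenetranceModel((3,), np.array([0.1, 0.25, 0.5]))],
                           "binary", seed=9)
        res = scan_main_effects(g, t, PermutationPlan(B=100, seed=10))
        assert res.top().factor_a == "snp00003"

    def test_deterministic_given_seed(self):
        g, t = _small_scan_inputs(seed=11)
        plan = PermutationPlan(B=100, seed=12)
        a = maxt_scan(g, t, all_pairs(6), plan).to_dataframe()
        b = maxt_scan(g, t, all_pairs(6), plan).to_dataframe()
        assert a.equals(b)


class TestSpeedMaxt:
    def test_check_interval_equal_B_identical_to_maxt(self):
        g, t = _small_scan_inputs(seed=13)
        pairs = all_pairs(8)
        pm = PermutationPlan(B=300, seed=14, mode="maxt")
        ps = PermutationPlan(B=300, seed=14, mode="speedmaxt", check_interval=300)
        a = maxt_scan(g, t, pairs, pm).to_dataframe()
        b = speedmaxt_scan(g, t, pairs, ps).to_dataframe()
        assert a.drop(columns="dropped_early").equals(b.drop(columns="dropped_early"))
        assert not b.dropped_early.any()

    def test_null_pair_dropped_at_first_checkpoint(self):
        # a pair with adjusted p near 1 must be dropped as soon as checked
        g = simulate_genotypes(SimConfig(n_samples=300, n_snps=6, seed=15,
                                         maf_range=(0.3, 0.5)))
        t = simulate_trait(g, [PenetranceModel((0, 1), xor_table(0.5))],
                           "binary", seed=16, base=0.05)
        plan = PermutationPlan(B=400, seed=17, mode="speedmaxt", check_interval=100)
        res = speedmaxt_scan(g, t, all_pairs(6), plan)
        df = res.to_dataframe()
        worst = df.sort_values("p_adjusted").iloc[-1]
        assert worst.dropped_early and worst.n_perm_used == 100
        # the planted pair is never dropped
        top = df.sort_values("T_max").iloc[-1]
        assert not top.dropped_early and top.n_perm_used == 400

    def test_fewer_evaluations_than_maxt(self):
        g, t = _small_scan_inputs(seed=18, n=300)
        pairs = all_pairs(8)
        pm = PermutationPlan(B=400, seed=19, mode="maxt")
        ps = PermutationPlan(B=400, seed=19, mode="speedmaxt", check_interval=100)
        a = maxt_scan(g, t, pairs, pm)
        b = speedmaxt_scan(g, t, pairs, ps)
        assert b.n_pair_perm_evals < a.n_pair_perm_evals
        assert a.n_pair_perm_evals == len(pairs) * 400


class TestGxE:
    def test_sex_grid_bookkeeping(self):
        g = simulate_genotypes(SimConfig(n_samples=240, n_snps=3, seed=20))
        rng = np.random.default_rng(21)
        sex = Trait("sex", "categorical", rng.integers(0, 2, 240).astype(float))
        t = simulate_trait(g, [], "binary", seed=22, base=0.3)
        res = scan_gxe(g, t, sex, PermutationPlan(B=50, seed=23))
        assert len(res) == 3
        grid = build_risk_grid(t.values, "binary",
                               g.codes[:, 0] * 2 + sex.values.astype(int), (3, 2))
        assert grid.counts.sum() == 240 and grid.counts.shape == (3, 2)

    def test_planted_gxe_recovered_with_adjustment(self):
        g = simulate_genotypes(SimConfig(n_samples=1000, n_snps=6, seed=24,
                                         maf_range=(0.3, 0.5)))
        rng = np.random.default_rng(25)
        env_vals = rng.integers(0, 3, 1000)
        env = Trait("age3", "categorical", env_vals.astype(float))
        # risk genotype differs by age band: a non-additive 3x3 pattern
        table = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        t = simulate_trait(g, [PenetranceModel((0, "env"), table)], "continuous",
                           seed=26, env=env_vals)
        res = scan_gxe(g, t, env, PermutationPlan(B=300, seed=27), adjust=True)
        df = res.to_dataframe()
        hit = df[df.factor_a == "snp00000"].iloc[0]
        assert hit.p_adjusted < 0.05
        assert df[df.factor_a != "snp00000"].p_adjusted.min() > 0.05


class TestCompareScans:
    def test_overlap_reporting(self):
        g, t = _small_scan_inputs(seed=28)
        plan = PermutationPlan(B=100, seed=29)
        main = scan_main_effects(g, t, plan)
        inter = scan_pairs(g, t, plan, pairs=all_pairs(5))
        df = compare_scans(main, inter, alpha=1.1)  # everything "significant"
        assert len(df) == len(inter)
        main_ids = {r.factor_a for r in main.results}
        for _, row in df.iterrows():
            assert row.a_is_main_hit == (row.factor_a in main_ids)

    def test_disjoint_sets_empty(self):
        g, t = _small_scan_inputs(seed=30)
        plan = PermutationPlan(B=100, seed=31)
        main = scan_main_effects(g, t, plan)
        inter = scan_pairs(g, t, plan, pairs=all_pairs(5))
        df = compare_scans(main, inter, alpha=1e-9)
        assert len(df) == 0
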