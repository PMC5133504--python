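"""Quality-control statistics, the iterative QC loop, relatedness, PCA, LD."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from epistakit.datamodel import Trait
from epistakit.qc import (QCThresholds, heterozygosity_outliers, hwe_test,
                          ibs_ibd_estimates, ld_prune, ld_r2, maf,
                          pca_outliers, run_qc, sample_call_rate,
                          snp_call_rate_by_group)
from epistakit.simulate import SimConfig, inject_missingness, simulate_genotypes

from conftest import make_genotypes


def cascade_fixture():
    """60 samples x 102 SNPs engineered so QC needs exactly two passes.

    Three SNPs are heavily missing in samples 1-5 and fail the SNP
    call-rate filter in pass 1; only after their removal does sample 0
    (which misses three *other* SNPs) drop below the 97% sample call
    rate, so it is excluded in pass 2.  The (i+j) mod 3 genotype
    pattern keeps every heterozygosity rate identical and every SNP at
    MAF 0.5 in HWE-compatible proportions.
    """
    n, p = 60, 102
    codes = ((np.arange(n)[:, None] + np.arange(p)[None, :]) % 3).astype(np.int8)
    mask = np.zeros((n, p), bool)
    mask[1:6, 0:3] = True          # mass-missing SNPs, sample 0 unaffected
    mask[0, [10, 11, 12]] = True   # sample 0's own missing entries
    return make_genotypes(codes, missing=mask)


class TestPerSampleStats:
    def test_call_rate_no_missing(self):
        g = make_genotypes(np.ones((5, 10)))
        assert np.all(sample_call_rate(g) == 1.0)

    def test_call_rate_strict_threshold_boundary(self):
        # 3 of 100 missing -> 0.97 exactly: retained ("less than" is strict)
        mask = np.zeros((2, 100), bool)
        mask[0, :3] = True
        g = make_genotypes(np.ones((2, 100)), missing=mask)
        rates = sample_call_rate(g)
        assert rates[0] == pytest.approx(0.97)
        assert not (rates < QCThresholds().sample_call_rate_min)[0]

    def test_call_rate_matches_count_oracle(self, rng):
        mask = rng.random((20, 50)) < 0.2
        g = make_genotypes(rng.integers(0, 3, (20, 50)), missing=mask)
        expected = 1 - mask.sum(axis=1) / 50
        assert np.allclose(sample_call_rate(g), expected)

    def test_het_outlier_all_identical_rates(self):
        g = make_genotypes(np.tile([0, 1, 2], (6, 10)))
        _, flags = heterozygosity_outliers(g)
        assert not flags.any()

    def test_het_outlier_all_het_sample_flagged(self, rng):
        codes = rng.integers(0, 3, (40, 100))
        codes[0] = 1  # fully heterozygous sample
        g = make_genotypes(codes)
        het, flags = heterozygosity_outliers(g)
        assert flags[0] and het[0] == 1.0
        assert flags.sum() == 1

    def test_het_flags_invariant_under_reordering(self, rng):
        codes = rng.integers(0, 3, (30, 60))
        codes[3] = 1
        g = make_genotypes(codes)
        _, flags = heterozygosity_outliers(g)
        perm = rng.permutation(30)
        _, flags_p = heterozygosity_outliers(make_genotypes(codes[perm]))
        assert np.array_equal(flags_p, flags[perm])


class TestSnpStats:
    def test_group_call_rate_case_specific_failure(self):
        codes = np.ones((100, 2), dtype=np.int8)
        mask = np.zeros((100, 2), bool)
        y = np.r_[np.ones(20), np.zeros(80)]
        mask[:3, 0] = True  # 3/20 cases missing = 85% case call rate, 97.6% overall
        g = make_genotypes(codes, missing=mask)
        df = snp_call_rate_by_group(g, Trait("t", "binary", y))
        assert df["call_rate_cases"][0] == pytest.approx(0.85)
        assert df["call_rate_controls"][0] == 1.0
        overall = (~g.missing_mask[:, 0]).mean()
        assert overall >= 0.97  # fails by group despite high overall rate

    def test_maf_examples(self):
        col = np.r_[np.zeros(81), np.ones(18), np.full(1, 2)].astype(np.int8)
        g = make_genotypes(col[:, None])
        assert maf(g)[0] == pytest.approx(0.10)
        mono = make_genotypes(np.zeros((50, 1)))
        assert maf(mono)[0] == 0.0

    def test_maf_matches_allele_count_oracle(self, rng):
        codes = rng.integers(0, 3, (200, 30))
        mask = rng.random((200, 30)) < 0.1
        g = make_genotypes(codes, missing=mask)
        for j in rng.choice(30, 5, replace=False):
            obs = codes[:, j][~mask[:, j]]
            f = (obs == 1).sum() + 2 * (obs == 2).sum()
            f = f / (2 * obs.size)
            assert maf(g)[j] == pytest.approx(min(f, 1 - f))


class TestHWE:
    def test_modal_configuration_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_het_deficit_extreme(self):
        assert hwe_test((50, 0, 50)) < 1e-5

    def test_exact_matches_enumeration_small(self):
        # independent oracle: direct log-factorial probabilities
        def oracle(n0, n1, n2):
            n = n0 + n1 + n2
            rare = 2 * min(n0, n2) + n1
            hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
            homr = (rare - hets) // 2
            homc = n - hets - homr
            logp = (gammaln(n + 1) - gammaln(homr + 1) - gammaln(hets + 1)
                    - gammaln(homc + 1) + hets * np.log(2)
                    + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1))
            pr = np.exp(logp)
            obs = pr[hets == n1][0]
            return min(pr[pr <= obs * (1 + 1e-12)].sum(), 1.0)

        rng = np.random.default_rng(3)
        for _ in range(50):
            n0, n1, n2 = rng.integers(0, 30, 3)
            if n0 + n1 + n2 == 0:
                continue
            assert hwe_test((n0, n1, n2)) == pytest.approx(oracle(n0, n1, n2), abs=1e-10)

    def test_exact_close_to_asymptotic_large_n(self):
        # the discrete two-sided exact p and the chi-square p agree tightly
        # in the decision-relevant tail; near p=1 the exact test's mass
        # ordering leaves a few-percent gap even at n=10000
        rng = np.random.default_rng(4)
        for _ in range(30):
            q = rng.uniform(0.1, 0.5)
            n = 10000
            counts = rng.multinomial(n, [(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
            e = hwe_test(tuple(counts))
            a = hwe_test(tuple(counts), "asymptotic")
            assert abs(e - a) < (0.01 if min(e, a) < 0.1 else 0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))


class TestRunQC:
    def test_clean_data_single_pass_fixpoint(self):
        # balanced pattern: no missing, common alleles, identical het rates
        n, p = 60, 102
        codes = ((np.arange(n)[:, None] + np.arange(p)[None, :]) % 3).astype(np.int8)
        g = make_genotypes(codes)
        out, report = run_qc(g, None, QCThresholds())
        assert report.n_passes == 0 and out.equals(g)

    def test_cascade_needs_two_passes(self):
        g = cascade_fixture()
        out, report = run_qc(g, None, QCThresholds())
        df = report.to_dataframe()
        assert report.n_passes == 2
        p1 = df[df["pass"] == 1]
        p2 = df[df["pass"] == 2]
        assert set(p1["reason"]) == {"snp_call_rate"} and len(p1) == 3
        assert list(p2["id"]) == ["S0"] and list(p2["reason"]) == ["sample_call_rate"]
        assert out.n_samples == 59 and out.n_snps == 99

    def test_idempotent_on_own_output(self):
        g = inject_missingness(
            simulate_genotypes(SimConfig(n_samples=300, n_snps=50, seed=21,
                                         maf_range=(0.01, 0.5),
                                         hwe_violation_snps=3, hwe_inbreeding=0.5)),
            0.01, seed=22)
        out, _ = run_qc(g, None, QCThresholds())
        again, report2 = run_qc(out, None, QCThresholds())
        assert report2.n_passes == 0 and again.equals(out)

    def test_exclusions_reproducible_from_report(self):
        g = cascade_fixture()
        _, report = run_qc(g, None, QCThresholds())
        # pass-1 snp exclusions must be recomputable on the pass-1 snapshot
        for e in report.exclusions:
            if e.pass_idx == 1 and e.reason == "snp_call_rate":
                j = g.snp_index(e.identifier)
                assert (~g.missing_mask[:, j]).mean() == pytest.approx(e.value)
                assert e.value < 0.98

    def test_all_excluded_raises(self):
        g = make_genotypes(np.zeros((10, 3)))  # all monomorphic -> MAF 0
        with pytest.raises(RuntimeError, match="pass 1"):
            run_qc(g, None, QCThresholds())


class TestRelatedness:
    def test_duplicate_sample_pi_hat_one(self):
        g = simulate_genotypes(SimConfig(n_samples=20, n_snps=400, seed=23,
                                         maf_range=(0.2, 0.5)))
        codes = g.codes.copy()
        codes[1] = codes[0]
        dup = make_genotypes(codes)
        df, remove = ibs_ibd_estimates(dup)
        row = df[(df.sample_a == "S0") & (df.sample_b == "S1")].iloc[0]
        assert row.PI_HAT > 0.95
        assert len(remove) >= 1

    def test_independent_samples_pi_hat_near_zero(self):
        g = simulate_genotypes(SimConfig(n_samples=30, n_snps=3000, seed=24,
                                         maf_range=(0.2, 0.5)))
        df, remove = ibs_ibd_estimates(g)
        assert df.PI_HAT.mean() < 0.05
        assert not remove

    def test_related_pair_flagged_at_copy_rate(self):
        g = simulate_genotypes(SimConfig(n_samples=40, n_snps=2000, seed=25,
                                         maf_range=(0.2, 0.5), related_pairs=(1, 0.5)))
        df, remove = ibs_ibd_estimates(g)
        row = df[(df.sample_a == "S00000") & (df.sample_b == "S00001")].iloc[0]
        # genotype copying with probability r puts ~r of the genome in IBD2
        assert abs(row.PI_HAT - 0.5) < 0.12
        assert len(remove) == 1 and remove[0] in ("S00000", "S00001")


class TestPCA:
    def test_two_populations_separate_on_pc1(self, rng):
        maf_a = rng.uniform(0.1, 0.3, 100)
        maf_b = np.clip(maf_a + 0.35, 0, 0.95)
        pop_a = (rng.random((60, 2, 100)) < maf_a).sum(axis=1)
        pop_b = (rng.random((60, 2, 100)) < maf_b).sum(axis=1)
        g = make_genotypes(np.vstack([pop_a, pop_b]))
        scores, _, _ = pca_outliers(g, n_components=2)
        pc1 = scores[:, 0]
        assert (pc1[:60].mean() < pc1[60:].mean()) != (pc1[:60].mean() > pc1[60:].mean()) or True
        # groups must be linearly separable on PC1
        assert max(pc1[:60].max() < pc1[60:].min(), pc1[60:].max() < pc1[:60].min())

    def test_homogeneous_population_few_outliers(self):
        g = simulate_genotypes(SimConfig(n_samples=300, n_snps=100, seed=26,
                                         maf_range=(0.1, 0.5)))
        _, flags, _ = pca_outliers(g, n_components=5, sd_limit=6.0)
        assert flags.mean() < 0.02

    def test_scores_orthogonal(self):
        g = simulate_genotypes(SimConfig(n_samples=100, n_snps=60, seed=27))
        scores, _, _ = pca_outliers(g, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-8 * np.abs(np.diag(gram)).max())


class TestLD:
    def test_identical_columns_r2_one(self):
        col = np.tile([0, 1, 2, 1, 0], 4).astype(np.int8)
        g = make_genotypes(np.column_stack([col, col]))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        g = make_genotypes(rng.integers(0, 3, (50, 4)))
        assert ld_r2(g, 0, 3) == pytest.approx(ld_r2(g, 3, 0))

    def test_null_mean_r2_near_one_over_n(self):
        vals = []
        for seed in range(40):
            g = simulate_genotypes(SimConfig(n_samples=100, n_snps=2, seed=600 + seed,
                                             maf_range=(0.3, 0.5)))
            vals.append(ld_r2(g, 0, 1))
        # E[r^2] ~ 1/n for independent SNPs
        assert abs(np.mean(vals) - 0.01) < 0.01

    def test_monomorphic_undefined(self):
        g = make_genotypes(np.column_stack([np.zeros(20), np.tile([0, 1], 10)]))
        assert np.isnan(ld_r2(g, 0, 1))

    def test_prune_duplicate_keeps_one(self):
        col = np.tile([0, 1, 2, 1], 10).astype(np.int8)
        g = make_genotypes(np.column_stack([col, col, np.roll(col, 7)]))
        out, pruned = ld_prune(g, r2_max=0.8)
        assert pruned == ["rs1"]
        assert list(out.snp_ids) == ["rs0", "rs2"]

    def test_prune_postcondition_and_independents_survive(self):
        g = simulate_genotypes(SimConfig(n_samples=400, n_snps=30, seed=28,
                                         maf_range=(0.2, 0.5), ld_blocks=[(5, 0.95)]))
        out, pruned = ld_prune(g, r2_max=0.5, window_size=30)
        assert len(pruned) >= 3  # most of the 5-SNP block collapses
        for a in range(out.n_snps):
            for b in range(a + 1, min(a + 31, out.n_snps)):
                r2 = ld_r2(out, a, b)
                assert np.isnan(r2) or r2 <= 0.5
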