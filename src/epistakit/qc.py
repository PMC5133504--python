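"""Iterative genotype quality control, relatedness, PCA outliers, and LD.

The central routine, :func:`run_qc`, repeats sample filters (call
rate, heterozygosity outliers) and SNP filters (call rate — separately
for cases and controls when a binary trait is supplied — minor allele
frequency, and Hardy-Weinberg equilibrium in controls) until a pass
excludes nothing.  Statistics are recomputed on the surviving data at
every pass, so cascading exclusions are handled naturally.

Default thresholds: sample call rate >= 97%, SNP call rate >= 98% per
phenotype group, heterozygosity within 3 SD of the mean, MAF >= 1%,
HWE exact-test p >= 1e-5 in controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix, Trait

__all__ = [
    "QCThresholds",
    "QCReport",
    "sample_call_rate",
    "snp_call_rate",
    "snp_call_rate_by_group",
    "heterozygosity_outliers",
    "maf",
    "hwe_test",
    "run_qc",
    "ibs_ibd_estimates",
    "pca_outliers",
    "ld_r2",
    "ld_prune",
]


@dataclass
class QCThresholds:
    sample_call_rate_min: float = 0.97
    snp_call_rate_min: float = 0.98
    het_sd_limit: float = 3.0
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    hwe_method: str = "exact"  # or "asymptotic"


@dataclass
class QCExclusion:
    pass_idx: int
    kind: str      # "sample" | "snp"
    identifier: str
    reason: str    # e.g. "sample_call_rate", "maf", "hwe"
    value: float


@dataclass
class QCReport:
    exclusions: list = field(default_factory=list)
    n_passes: int = 0           # passes that excluded something
    total_passes: int = 0       # passes executed (incl. the final empty one)
    initial_shape: tuple = (0, 0)
    final_shape: tuple = (0, 0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pass_idx, e.kind, e.identifier, e.reason, e.value) for e in self.exclusions],
            columns=["pass", "type", "id", "reason", "value"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [f"QC: {self.initial_shape[0]}x{self.initial_shape[1]} -> "
                 f"{self.final_shape[0]}x{self.final_shape[1]} in {self.n_passes} "
                 f"excluding pass(es)"]
        if len(df):
            for (p, reason), grp in df.groupby(["pass", "reason"]):
                lines.append(f"  pass {p}: {len(grp)} excluded ({reason})")
        return "\n".join(lines)


# --------------------------------------------------------------- per-op stats

def sample_call_rate(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotypes per sample."""
    if g.n_snps == 0:
        raise ValueError("call rate undefined with zero SNPs")
    return (~g.missing_mask).mean(axis=1)


def snp_call_rate(g: GenotypeMatrix) -> np.ndarray:
    if g.n_samples == 0:
        raise ValueError("call rate undefined with zero samples")
    return (~g.missing_mask).mean(axis=0)


def snp_call_rate_by_group(g: GenotypeMatrix, trait: Trait) -> pd.DataFrame:
    """Per-SNP call rate within cases and controls of a binary trait.

    A SNP fails the call-rate filter iff its rate drops below threshold
    in either group.
    """
    if trait.kind != "binary":
        raise ValueError("group call rate needs a binary trait")
    y = trait.values
    cases = y == 1
    controls = y == 0
    if not cases.any() or not controls.any():
        raise ValueError("one phenotype group is empty")
    rate_cases = (~g.missing_mask[cases]).mean(axis=0)
    rate_controls = (~g.missing_mask[controls]).mean(axis=0)
    return pd.DataFrame({"snp_id": g.snp_ids, "call_rate_cases": rate_cases,
                         "call_rate_controls": rate_controls})


def heterozygosity_outliers(g: GenotypeMatrix, sd_limit: float = 3.0):
    """Per-sample heterozygosity rate and |rate - mean| > sd_limit*SD flags."""
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    obs = ~g.missing_mask
    n_obs = obs.sum(axis=1)
    het = np.where(obs, g.codes == 1, False).sum(axis=1) / np.maximum(n_obs, 1)
    het[n_obs == 0] = np.nan
    mean = np.nanmean(het)
    sd = np.nanstd(het)
    if sd == 0 or np.isnan(sd):
        flags = np.zeros(g.n_samples, dtype=bool)
    else:
        flags = np.abs(het - mean) > sd_limit * sd
        flags &= ~np.isnan(het)
    return het, flags


def maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency among non-missing calls (<= 0.5).

    All-missing SNPs get NaN (they fail QC by construction).
    """
    obs = ~g.missing_mask
    n_alleles = 2 * obs.sum(axis=0)
    counted = np.where(obs, g.codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counted / n_alleles
    f = np.where(n_alleles == 0, np.nan, f)
    return np.minimum(f, 1 - f)


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test by enumeration over heterozygote counts at fixed
    allele counts (mid-probability convention: sum probabilities not
    exceeding the observed configuration's)."""
    n = n0 + n1 + n2
    rare = 2 * min(n0, n2) + n1
    # distribution over het counts with same parity as rare
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # multiplicative recurrence from the modal configuration
    logp = np.zeros(hets.size)
    for k in range(1, hets.size):
        h = hets[k]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h)/P(h-2) = 4*hom_r(prev)*hom_c(prev) / (h*(h-1))
        logp[k] = logp[k - 1] + np.log(4.0 * (hom_r + 1) * (hom_c + 1)) - np.log(h * (h - 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs_idx = int(np.flatnonzero(hets == n1)[0])
    return float(np.minimum(p[p <= p[obs_idx] * (1 + 1e-12)].sum(), 1.0))


def _hwe_asymptotic(n0: int, n1: int, n2: int) -> float:
    n = n0 + n1 + n2
    q = (2 * n2 + n1) / (2 * n)
    exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
    obs = np.array([n0, n1, n2], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(genotype_counts, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p value for genotype counts (n0, n1, n2).

    ``exact`` enumerates all heterozygote counts compatible with the
    observed allele counts (two-sided, summing configurations no more
    probable than the observed one); ``asymptotic`` is the 1-df chi^2.
    """
    n0, n1, n2 = (int(x) for x in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype counts")
    if n0 + n1 + n2 < 1:
        raise ValueError("empty genotype counts")
    if method == "exact":
        return _hwe_exact(n0, n1, n2)
    if method == "asymptotic":
        return _hwe_asymptotic(n0, n1, n2)
    raise ValueError(f"unknown HWE method {method!r}")


def _genotype_counts(g: GenotypeMatrix, sample_mask: np.ndarray | None = None) -> np.ndarray:
    codes = g.codes if sample_mask is None else g.codes[sample_mask]
    miss = g.missing_mask if sample_mask is None else g.missing_mask[sample_mask]
    out = np.zeros((g.n_snps, 3), dtype=int)
    for c in range(3):
        out[:, c] = ((codes == c) & ~miss).sum(axis=0)
    return out


# ------------------------------------------------------------------- run_qc

def run_qc(g: GenotypeMatrix, trait: Trait | None = None,
           thresholds: QCThresholds | None = None,
           max_passes: int = 50):
    """Iterate sample and SNP filters until a pass excludes nothing.

    Within a pass: sample call rate, then heterozygosity outliers (on
    the survivors), then SNP call rate (per case/control group when a
    binary ``trait`` is given), MAF, and HWE (controls only for binary
    traits, all samples otherwise).  Returns the filtered matrix and a
    :class:`QCReport`; raises if every sample or every SNP is excluded.
    """
    th = thresholds or QCThresholds()
    report = QCReport(initial_shape=(g.n_samples, g.n_snps))
    trait_vals = trait.values.copy() if trait is not None else None
    cur = g
    for pass_idx in range(1, max_passes + 1):
        report.total_passes = pass_idx
        excluded_any = False
        keep_samples = np.ones(cur.n_samples, dtype=bool)

        rates = sample_call_rate(cur)
        fail = rates < th.sample_call_rate_min
        for i in np.flatnonzero(fail):
            report.exclusions.append(QCExclusion(pass_idx, "sample", cur.sample_ids[i],
                                                 "sample_call_rate", float(rates[i])))
        keep_samples &= ~fail

        sub = cur.subset(samples=keep_samples)
        sub_traits = trait_vals[keep_samples] if trait_vals is not None else None
        if sub.n_samples >= 2:
            het, flags = heterozygosity_outliers(sub, sd_limit=th.het_sd_limit)
            for i in np.flatnonzero(flags):
                report.exclusions.append(QCExclusion(pass_idx, "sample", sub.sample_ids[i],
                                                     "heterozygosity", float(het[i])))
            if flags.any():
                sub = sub.subset(samples=~flags)
                if sub_traits is not None:
                    sub_traits = sub_traits[~flags]
        if sub.n_samples == 0:
            raise RuntimeError(f"QC pass {pass_idx} excluded all samples")
        excluded_any |= sub.n_samples < cur.n_samples

        keep_snps = np.ones(sub.n_snps, dtype=bool)
        # call rate
        if trait is not None and trait.kind == "binary" and sub_traits is not None \
                and (sub_traits == 1).any() and (sub_traits == 0).any():
            grp = snp_call_rate_by_group(sub, Trait("t", "binary", sub_traits))
            rate_fail = (grp["call_rate_cases"].to_numpy() < th.snp_call_rate_min) | \
                        (grp["call_rate_controls"].to_numpy() < th.snp_call_rate_min)
            rate_val = np.minimum(grp["call_rate_cases"], grp["call_rate_controls"]).to_numpy()
        else:
            rate_val = snp_call_rate(sub)
            rate_fail = rate_val < th.snp_call_rate_min
        for j in np.flatnonzero(rate_fail):
            report.exclusions.append(QCExclusion(pass_idx, "snp", sub.snp_ids[j],
                                                 "snp_call_rate", float(rate_val[j])))
        keep_snps &= ~rate_fail

        freqs = maf(sub)
        maf_fail = ~(freqs >= th.maf_min)  # NaN (all-missing) fails too
        maf_fail &= keep_snps
        for j in np.flatnonzero(maf_fail):
            report.exclusions.append(QCExclusion(pass_idx, "snp", sub.snp_ids[j],
                                                 "maf", float(freqs[j])))
        keep_snps &= ~maf_fail

        if trait is not None and trait.kind == "binary" and sub_traits is not None:
            hwe_mask = sub_traits == 0  # controls only
        else:
            hwe_mask = None
        counts = _genotype_counts(sub, hwe_mask)
        for j in np.flatnonzero(keep_snps):
            if counts[j].sum() == 0:
                continue
            pval = hwe_test(counts[j], method=th.hwe_method)
            if pval < th.hwe_p_min:
                report.exclusions.append(QCExclusion(pass_idx, "snp", sub.snp_ids[j],
                                                     "hwe", float(pval)))
                keep_snps[j] = False

        if not keep_snps.any():
            raise RuntimeError(f"QC pass {pass_idx} excluded all SNPs")
        excluded_any |= not keep_snps.all()
        nxt = sub.subset(snps=keep_snps)
        trait_vals = sub_traits
        if not excluded_any:
            report.final_shape = (cur.n_samples, cur.n_snps)
            return cur, report
        report.n_passes = pass_idx
        cur = nxt
        if trait is not None:
            trait = Trait(trait.name, trait.kind, trait_vals)
    report.final_shape = (cur.n_samples, cur.n_snps)
    return cur, report


# --------------------------------------------------------- relatedness / PCA

def ibs_ibd_estimates(g: GenotypeMatrix, pi_hat_threshold: float = 0.1875):
    """PLINK-style method-of-moments IBD estimates for every sample pair.

    Returns a DataFrame with per-pair IBS distance (1 - mean IBS/2),
    Z0/Z1/Z2 and PI_HAT = Z2 + Z1/2, plus a removal list: for each pair
    with PI_HAT above the threshold, the member with the lower call
    rate.  Expectations use overall allele frequencies without
    small-sample correction factors; monomorphic SNPs are ignored.
    """
    freqs = maf(g)
    poly = (freqs > 0) & ~np.isnan(freqs)
    if not poly.any():
        raise ValueError("IBD undefined: all SNPs monomorphic")
    sub = g.subset(snps=poly)
    q = maf(sub)
    p_ = 1 - q
    e_ibs0_ibd0 = float(np.sum(2 * p_ ** 2 * q ** 2))
    e_ibs1_ibd0 = float(np.sum(4 * p_ ** 3 * q + 4 * p_ * q ** 3))
    e_ibs2_ibd0 = float(np.sum(p_ ** 4 + q ** 4 + 4 * p_ ** 2 * q ** 2))
    e_ibs1_ibd1 = float(np.sum(2 * p_ * q))
    e_ibs2_ibd1 = float(np.sum(p_ ** 2 + q ** 2))
    m_total = sub.n_snps

    codes = np.where(sub.missing_mask, -9, sub.codes).astype(np.int16)
    n = sub.n_samples
    rows = []
    call = sample_call_rate(g)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(valid.sum())
            if m == 0:
                continue
            diff = np.abs(codes[i, valid] - codes[j, valid])
            n0 = int((diff == 2).sum())
            n1 = int((diff == 1).sum())
            n2 = m - n0 - n1
            scale = m / m_total  # expectations computed over all polymorphic SNPs
            z0 = n0 / (e_ibs0_ibd0 * scale) if e_ibs0_ibd0 > 0 else 0.0
            z1 = (n1 - z0 * e_ibs1_ibd0 * scale) / (e_ibs1_ibd1 * scale)
            z2 = (n2 - z0 * e_ibs2_ibd0 * scale - z1 * e_ibs2_ibd1 * scale) / m
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            if z.sum() > 0:
                z = z / z.sum()
            pi_hat = z[2] + 0.5 * z[1]
            rows.append((sub.sample_ids[i], sub.sample_ids[j],
                         1.0 - (2 * n2 + n1) / (2 * m), z[0], z[1], z[2], pi_hat))
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "ibs_distance",
                                     "Z0", "Z1", "Z2", "PI_HAT"])
    remove = []
    call_by_id = dict(zip(g.sample_ids, call))
    for _, r in df[df["PI_HAT"] > pi_hat_threshold].iterrows():
        a, b = r["sample_a"], r["sample_b"]
        drop = a if call_by_id[a] < call_by_id[b] else b
        if drop not in remove:
            remove.append(drop)
    return df, remove


def pca_outliers(g: GenotypeMatrix, n_components: int = 10, sd_limit: float = 6.0):
    """Scores on the leading genotype principal components plus outlier flags.

    Columns are standardized (observed mean/SD, missing set to the
    mean); samples beyond ``sd_limit`` SD on any retained component are
    flagged.  Degenerate directions are dropped by rank truncation.
    """
    if g.n_samples < n_components:
        raise ValueError("need at least n_components samples")
    X = g.codes.astype(float)
    X[g.missing_mask] = np.nan
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    keep = sd > 0
    X = (X[:, keep] - mu[keep]) / sd[keep]
    X[np.isnan(X)] = 0.0
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if s.size else 0
    k = min(n_components, rank)
    scores = u[:, :k] * s[:k]
    score_sd = scores.std(axis=0, ddof=1)
    flags = (np.abs(scores) > sd_limit * score_sd).any(axis=1)
    explained = (s[:k] ** 2) / (s ** 2).sum() if s.size else np.array([])
    return scores, flags, explained


# ------------------------------------------------------------------------ LD

def ld_r2(g: GenotypeMatrix, snp_a, snp_b) -> float:
    """Squared genotype-count correlation (composite LD, no phasing).

    SNPs may be given by id or column index.  Returns NaN when either
    SNP is monomorphic among jointly non-missing samples.
    """
    a = g.snp_index(snp_a) if isinstance(snp_a, str) else int(snp_a)
    b = g.snp_index(snp_b) if isinstance(snp_b, str) else int(snp_b)
    valid = ~(g.missing_mask[:, a] | g.missing_mask[:, b])
    x, y = g.codes[valid, a].astype(float), g.codes[valid, b].astype(float)
    if valid.sum() < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.5, window_size: int = 50):
    """Greedy left-to-right windowed LD pruning.

    Scanning SNPs in column order, a SNP is dropped if its r^2 with any
    *kept* SNP within the preceding ``window_size`` columns exceeds
    ``r2_max``; the earlier SNP of a correlated pair is always the one
    retained.  Returns (pruned GenotypeMatrix, list of pruned SNP ids).
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    kept: list[int] = []
    pruned: list[str] = []
    for j in range(g.n_snps):
        drop = False
        for k in reversed(kept):
            if j - k > window_size:
                break
            r2 = ld_r2(g, k, j)
            if not np.isnan(r2) and r2 > r2_max:
                drop = True
                break
        if drop:
            pruned.append(g.snp_ids[j])
        else:
            kept.append(j)
    return g.subset(snps=np.asarray(kept, dtype=int)), pruned
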