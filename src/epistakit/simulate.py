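"""Synthetic genotype/phenotype cohorts with planted interaction effects.

The generator emulates the statistical structure a blood-pressure
association cohort presents to the analysis chain: a MAF spectrum with
rare variants, Hardy-Weinberg-violating SNPs (excess homozygosity via
an inbreeding-style parameter), LD blocks generated from a shared
latent Gaussian haplotype factor (a Gaussian copula, which gives
tunable within-block r^2 without a coalescent dependency), related
sample pairs by genotype copying, genotype missingness, and traits
driven by penetrance/mean-shift tables over one or two loci or a
locus x environment combination.

Everything is driven by an explicit seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypeMatrix, PhenotypeTable, Trait

__all__ = [
    "PenetranceModel",
    "SimConfig",
    "simulate_genotypes",
    "simulate_trait",
    "inject_missingness",
    "simulate_blood_pressure_cohort",
    "xor_table",
]


@dataclass
class PenetranceModel:
    """Effect of one or two factors on a trait.

    ``loci`` holds 1 or 2 SNP column indices; the string "env" in the
    second slot refers to the environmental factor passed to
    :func:`simulate_trait`.  ``table`` holds additive contributions to
    the penetrance (binary trait) or trait mean (continuous trait) for
    each genotype/level combination: shape (3,), (3,3) or (3,L).
    """

    loci: tuple
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        arity = len(self.loci)
        if arity not in (1, 2):
            raise ValueError("PenetranceModel takes 1 or 2 loci")
        if self.table.ndim != arity:
            raise ValueError("table dimensionality must match loci arity")
        if arity >= 1 and self.table.shape[0] != 3:
            raise ValueError("first table axis must have 3 genotype levels")


def xor_table(effect: float) -> np.ndarray:
    """3x3 table placing ``effect`` where exactly one locus is heterozygous.

    At MAF 0.5 this interaction has no marginal single-locus effect.
    """
    t = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            if (a == 1) != (b == 1):
                t[a, b] = effect
    return t


@dataclass
class SimConfig:
    """Configuration of a simulated genotype panel."""

    n_samples: int = 1000
    n_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    ld_blocks: list = field(default_factory=list)  # [(block_size, latent_corr), ...]
    missing_rate: float = 0.0
    hwe_violation_snps: int = 0
    hwe_inbreeding: float = 0.3
    related_pairs: tuple = (0, 0.0)  # (count, genotype-copy probability)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(b for b, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("LD blocks exceed n_snps")
        count, kin = self.related_pairs
        if not 0 <= kin <= 1:
            raise ValueError("relatedness must be in [0, 1]")
        if 2 * count > self.n_samples:
            raise ValueError("too many related pairs for n_samples")


def _genotypes_from_latent(z: np.ndarray, maf: float) -> np.ndarray:
    """Two latent standard-normal haplotypes -> allele counts."""
    from scipy.stats import norm

    thresh = norm.ppf(maf)
    return (z < thresh).sum(axis=-1).astype(np.int8)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a genotype panel under the configured structure.

    SNPs outside LD blocks are drawn under HWE at their MAF; block SNPs
    share a latent haplotype factor so within-block genotype r^2 tracks
    the configured latent correlation; the first ``hwe_violation_snps``
    non-block SNPs get excess homozygosity P(AA)=q^2+Fpq etc.; related
    pairs copy whole genotypes with the configured probability.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_snps
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    codes = np.zeros((n, p), dtype=np.int8)

    j = 0
    for block_size, rho in cfg.ld_blocks:
        if not 0 <= rho <= 1:
            raise ValueError("latent correlation must be in [0, 1]")
        shared = rng.standard_normal((n, 2))
        for _ in range(block_size):
            noise = rng.standard_normal((n, 2))
            z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            codes[:, j] = _genotypes_from_latent(z, maf[j])
            j += 1
    block_end = j

    n_hwe = cfg.hwe_violation_snps
    if block_end + n_hwe > p:
        raise ValueError("not enough non-block SNPs for HWE violations")
    F = cfg.hwe_inbreeding
    for k in range(n_hwe):
        q = maf[j]
        probs = np.array([(1 - q) ** 2 + F * q * (1 - q),
                          2 * q * (1 - q) * (1 - F),
                          q ** 2 + F * q * (1 - q)])
        codes[:, j] = rng.choice(3, size=n, p=probs / probs.sum())
        j += 1
    if j < p:
        u = rng.random((n, 2, p - j))
        codes[:, j:] = (u < maf[j:]).sum(axis=1).astype(np.int8)

    count, kin = cfg.related_pairs
    for k in range(count):
        a, b = 2 * k, 2 * k + 1
        copy = rng.random(p) < kin
        codes[b, copy] = codes[a, copy]

    return GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        snp_ids=[f"snp{j:05d}" for j in range(p)],
        chrom=["1"] * p,
        pos=np.arange(1, p + 1) * 1000,
        codes=codes,
        missing_mask=np.zeros((n, p), dtype=bool),
    )


def _combined_effect(g: GenotypeMatrix, env: np.ndarray | None,
                     models: list[PenetranceModel]) -> np.ndarray:
    effect = np.zeros(g.n_samples)
    for m in models:
        idx = [l for l in m.loci]
        a = idx[0]
        if not 0 <= a < g.n_snps:
            raise ValueError(f"model locus {a} not in genotype matrix")
        ca = g.codes[:, a].astype(int)
        ca = np.where(g.missing_mask[:, a], 0, ca)  # missing treated as baseline
        if len(idx) == 1:
            effect += m.table[ca]
        else:
            b = idx[1]
            if b == "env":
                if env is None:
                    raise ValueError("model uses an environmental factor but none given")
                cb = env.astype(int)
            else:
                cb = g.codes[:, b].astype(int)
                cb = np.where(g.missing_mask[:, b], 0, cb)
            if m.table.shape[1] <= cb.max():
                raise ValueError("penetrance table missing a level combination")
            effect += m.table[ca, cb]
    return effect


def simulate_trait(g: GenotypeMatrix, models: list[PenetranceModel],
                   kind: str, seed: int, env: np.ndarray | None = None,
                   base: float = 0.0, noise_sd: float = 1.0,
                   name: str = "sim_trait") -> Trait:
    """Draw a trait from planted penetrance/mean-shift models.

    Binary: affection ~ Bernoulli(clip(base + sum of table entries)).
    Continuous: base + sum of table entries + N(0, noise_sd).  With an
    empty model list the trait is pure noise (a global null).
    """
    rng = np.random.default_rng(seed)
    effect = base + _combined_effect(g, env, models)
    if kind == "binary":
        pen = np.clip(effect, 0.0, 1.0)
        values = (rng.random(g.n_samples) < pen).astype(float)
    elif kind == "continuous":
        values = effect + rng.normal(0.0, noise_sd, size=g.n_samples)
    else:
        raise ValueError(f"unknown trait kind {kind!r}")
    return Trait(name=name, kind=kind, values=values)


def inject_missingness(g: GenotypeMatrix, rate: float, pattern: str = "uniform",
                       seed: int = 0, snps: list | None = None) -> GenotypeMatrix:
    """Set entries missing at the given rate.

    ``uniform`` masks every entry independently; ``per_snp`` masks only
    the designated SNP columns (by index), concentrating missingness to
    force call-rate failures downstream.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = g.missing_mask.copy()
    if rate > 0:
        if pattern == "uniform":
            mask |= rng.random(g.codes.shape) < rate
        elif pattern == "per_snp":
            if not snps:
                raise ValueError("per_snp pattern needs a list of SNP indices")
            for j in snps:
                mask[:, j] |= rng.random(g.n_samples) < rate
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
    codes = g.codes.copy()
    codes[mask] = 0
    return GenotypeMatrix(g.sample_ids, g.snp_ids, g.chrom, g.pos, codes, mask,
                          allele_minor=g.allele_minor, allele_major=g.allele_major)


def simulate_blood_pressure_cohort(cfg: SimConfig | None = None, seed: int = 0,
                                   models_sbp: list[PenetranceModel] | None = None):
    """A full cohort: genotypes plus an age/sex/SBP/DBP/BPMEDS table.

    Returns (GenotypeMatrix, PhenotypeTable).  SBP and DBP carry an age
    trend plus noise plus any planted models; BPMEDS is more likely for
    high measured pressure, and hypertension prevalence lands near the
    ~12% of a typical adult cohort.
    """
    import pandas as pd

    if cfg is None:
        cfg = SimConfig(seed=seed)
    g = simulate_genotypes(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_samples
    age = rng.uniform(20, 80, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    sbp = 108.0 + 0.45 * age + rng.normal(0, 14, size=n)
    dbp = 62.0 + 0.25 * age + rng.normal(0, 9, size=n)
    if models_sbp:
        env3 = np.digitize(age, np.quantile(age, [1 / 3, 2 / 3]))
        sbp = sbp + _combined_effect(g, env3, models_sbp)
    # medication odds rise with measured SBP; the midpoint is set so the
    # derived hypertension prevalence lands near 12% of the cohort
    bpmeds = (rng.random(n) < 1 / (1 + np.exp(-(sbp - 158) / 8.0))).astype(float)
    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": g.sample_ids, "sex": sex, "age": age,
        "sbp": sbp, "dbp": dbp, "bpmeds": bpmeds,
    }))
    return g, pheno
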