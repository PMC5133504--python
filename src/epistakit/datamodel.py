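"""Core containers for genotype and phenotype data.

Genotypes are biallelic SNP hard calls coded as minor-allele counts
(0/1/2) with an explicit missingness mask.  Phenotypes carry the blood
pressure traits and covariates used throughout the pipeline, plus the
derived traits: binary hypertension status and a balanced categorical
age factor for gene-environment scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "Trait",
    "derive_hypertension",
    "categorize_age",
]


def _as_str_array(x) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele-count matrix with SNP metadata.

    ``codes`` entries are 0, 1 or 2 where ``missing_mask`` is False and
    are undefined (conventionally 0) where it is True.  ``pos`` holds
    1-based physical positions.  ``allele_minor``/``allele_major`` are
    the counted and reference allele letters; they default to "B"/"A"
    when the source format carries no allele labels.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    codes: np.ndarray
    missing_mask: np.ndarray
    allele_minor: np.ndarray | None = None
    allele_major: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.allele_minor is None:
            self.allele_minor = np.asarray(["B"] * self.n_snps, dtype=object)
        else:
            self.allele_minor = _as_str_array(self.allele_minor)
        if self.allele_major is None:
            self.allele_major = np.asarray(["A"] * self.n_snps, dtype=object)
        else:
            self.allele_major = _as_str_array(self.allele_major)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        n, p = self.codes.shape if self.codes.size else (len(self.sample_ids), len(self.snp_ids))
        if self.codes.shape != (self.n_samples, self.n_snps):
            # allow (n, 0) / (0, p) degenerate shapes
            self.codes = self.codes.reshape(self.n_samples, self.n_snps)
        if self.missing_mask.shape != self.codes.shape:
            raise ValueError("missing_mask shape does not match codes")
        if len(set(self.snp_ids)) != self.n_snps:
            raise ValueError("snp_ids are not unique")
        if len(set(self.sample_ids)) != self.n_samples:
            raise ValueError("sample_ids are not unique")
        if self.pos.size and np.any(self.pos <= 0):
            raise ValueError("positions must be strictly positive (1-based)")
        observed = self.codes[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("genotype codes must be in {0,1,2} where non-missing")

    # -- convenience -------------------------------------------------

    def subset(self, samples: np.ndarray | Sequence[int] | None = None,
               snps: np.ndarray | Sequence[int] | None = None) -> "GenotypeMatrix":
        """Positional/boolean subset of samples and/or SNPs (copy)."""
        s_idx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        j_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if j_idx.dtype == bool:
            j_idx = np.flatnonzero(j_idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[s_idx],
            snp_ids=self.snp_ids[j_idx],
            chrom=self.chrom[j_idx],
            pos=self.pos[j_idx],
            codes=self.codes[np.ix_(s_idx, j_idx)] if s_idx.size and j_idx.size
            else np.zeros((s_idx.size, j_idx.size), dtype=np.int8),
            missing_mask=self.missing_mask[np.ix_(s_idx, j_idx)] if s_idx.size and j_idx.size
            else np.zeros((s_idx.size, j_idx.size), dtype=bool),
            allele_minor=self.allele_minor[j_idx],
            allele_major=self.allele_major[j_idx],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if not hits.size:
            raise KeyError(snp_id)
        return int(hits[0])

    def equals(self, other: "GenotypeMatrix", metadata: bool = True) -> bool:
        same = (
            list(self.sample_ids) == list(other.sample_ids)
            and list(self.snp_ids) == list(other.snp_ids)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                np.where(self.missing_mask, -1, self.codes),
                np.where(other.missing_mask, -1, other.codes),
            )
        )
        if metadata:
            same = same and list(self.chrom) == list(other.chrom) and np.array_equal(self.pos, other.pos)
        return bool(same)


@dataclass
class Trait:
    """A per-sample trait: binary, continuous, or categorical.

    Values are stored as floats with NaN marking samples that are
    missing or excluded for this trait.  Binary traits take values
    {0, 1}; categorical traits take integer level codes 0..L-1.
    """

    name: str
    kind: str  # "binary" | "continuous" | "categorical"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("binary", "continuous", "categorical"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        obs = self.values[~np.isnan(self.values)]
        if self.kind == "binary":
            levels = np.unique(obs)
            if obs.size and not np.all(np.isin(levels, [0.0, 1.0])):
                raise ValueError("binary trait must be coded 0/1")
        elif self.kind == "continuous":
            if obs.size and np.unique(obs).size < 2:
                raise ValueError("continuous trait needs >= 2 distinct values")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_levels(self) -> int:
        obs = self.values[self.observed]
        return int(obs.max()) + 1 if obs.size else 0


@dataclass
class PhenotypeTable:
    """Per-sample phenotype and covariate table.

    Mandatory columns: sample id, sex (0/1), age (years), sbp and dbp
    (mmHg), bpmeds (0/1 antihypertensive-medication flag).  Missing
    entries are NaN; samples are never silently dropped here — trait
    derivation flags or excludes them explicitly.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample_id", "sex", "age", "sbp", "dbp", "bpmeds")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in phenotype table")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def aligned_to(self, g: GenotypeMatrix) -> "PhenotypeTable":
        """Explicit join: reorder/subset rows to match ``g.sample_ids``.

        Raises if any genotyped sample lacks a phenotype row.
        """
        idx = self.data.set_index("sample_id")
        missing = [s for s in g.sample_ids if s not in idx.index]
        if missing:
            raise KeyError(f"samples without phenotype rows: {missing[:5]}...")
        out = idx.loc[list(g.sample_ids)].reset_index()
        return PhenotypeTable(out)


def derive_hypertension(p: PhenotypeTable, sbp_threshold: float = 140.0,
                        dbp_threshold: float = 90.0) -> Trait:
    """Binary hypertension status from blood pressure and medication.

    A sample is a case iff (SBP > sbp_threshold AND DBP > dbp_threshold)
    OR it is on antihypertensive medication; inequalities are strict.
    Samples missing any of the three inputs get NaN (excluded for this
    trait) rather than being dropped from the table.
    """
    sbp, dbp, meds = p.column("sbp"), p.column("dbp"), p.column("bpmeds")
    incomplete = np.isnan(sbp) | np.isnan(dbp) | np.isnan(meds)
    hs = (((sbp > sbp_threshold) & (dbp > dbp_threshold)) | (meds == 1)).astype(float)
    hs[incomplete] = np.nan
    if np.all(incomplete):
        raise ValueError("no sample has complete SBP/DBP/BPMEDS data")
    return Trait(name="hs", kind="binary", values=hs)


def categorize_age(p: PhenotypeTable, n_groups: int = 3) -> Trait:
    """Categorize age into balanced ordered groups at empirical quantiles.

    Group boundaries sit at ranks i*n/n_groups; samples tied on an age
    value spanning a boundary are all assigned to the lower group, which
    makes assignment deterministic and order-preserving in age.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    age = p.column("age")
    obs = ~np.isnan(age)
    vals = age[obs]
    if np.unique(vals).size < n_groups:
        raise ValueError("fewer distinct ages than requested groups")
    order = np.argsort(vals, kind="stable")
    n = vals.size
    group_sorted = (np.arange(n) * n_groups) // n
    # tie rule: every copy of a value takes the lowest group seen for it
    sorted_vals = vals[order]
    run_starts = np.flatnonzero(np.r_[True, np.diff(sorted_vals) != 0])
    run_ends = np.r_[run_starts[1:], n]
    for start, end in zip(run_starts, run_ends):
        group_sorted[start:end] = group_sorted[start]
    groups = np.empty(n, dtype=float)
    groups[order] = group_sorted
    out = np.full(age.shape, np.nan)
    out[obs] = groups
    return Trait(name=f"age_{n_groups}groups", kind="categorical", values=out)
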