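"""Readers and writers for genotype and phenotype files.

Supported genotype formats:

* ``vcf`` — VCF 4.x, GT field only, biallelic records (read via cyvcf2;
  written as plain text).  The minor allele is determined per record
  from observed allele frequencies, so codes always count the rarer
  allele regardless of REF/ALT orientation.
* ``plink_text`` — the .ped/.map pair (path names the .ped file, the
  .map sits beside it) and the .raw additive-coding dialect.
* ``matrix_tsv`` — an internal TSV: samples as rows, a header row of
  SNP ids, missing token "NA", with chrom/pos/allele metadata in
  leading ``#`` lines.  Round-trips exactly.

Phenotype tables are plain TSV with a mandatory header containing
sample_id, sex, age, sbp, dbp, bpmeds.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, PhenotypeTable

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "recode_minor",
]

MISSING_TOKEN = "NA"


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------- matrix_tsv

def _write_matrix_tsv(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\t" + ",".join(map(str, g.chrom)) + "\n")
        fh.write("#pos\t" + ",".join(map(str, g.pos)) + "\n")
        fh.write("#minor\t" + ",".join(map(str, g.allele_minor)) + "\n")
        fh.write("#major\t" + ",".join(map(str, g.allele_major)) + "\n")
        fh.write("\t".join(["sample_id", *map(str, g.snp_ids)]) + "\n")
        codes = g.codes.astype(object)
        codes[g.missing_mask] = MISSING_TOKEN
        for i, sid in enumerate(g.sample_ids):
            fh.write("\t".join([str(sid), *map(str, codes[i])]) + "\n")


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition("\t")
            meta[key] = val.split(",") if val else []
            body_start = i + 1
        else:
            break
    if body_start >= len(lines):
        raise ParseError(f"{path}: missing header row")
    header = lines[body_start].split("\t")
    if header[0] != "sample_id":
        raise ParseError(f"{path}: line {body_start + 1}: expected 'sample_id' header")
    snp_ids = header[1:]
    p = len(snp_ids)
    sample_ids, rows, mask_rows = [], [], []
    for ln, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != p + 1:
            raise ParseError(f"{path}: line {ln}: expected {p + 1} fields, got {len(parts)}")
        sample_ids.append(parts[0])
        miss = [t == MISSING_TOKEN for t in parts[1:]]
        try:
            rows.append([0 if m else int(t) for t, m in zip(parts[1:], miss)])
        except ValueError as e:
            raise ParseError(f"{path}: line {ln}: {e}") from None
        mask_rows.append(miss)
    n = len(sample_ids)
    chrom = meta.get("chrom", ["0"] * p)
    pos = [int(x) for x in meta.get("pos", [])] or list(range(1, p + 1))
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chrom=chrom if len(chrom) == p else ["0"] * p,
        pos=pos if len(pos) == p else list(range(1, p + 1)),
        codes=np.asarray(rows, dtype=np.int8).reshape(n, p),
        missing_mask=np.asarray(mask_rows, dtype=bool).reshape(n, p),
        allele_minor=meta.get("minor") if len(meta.get("minor", [])) == p else None,
        allele_major=meta.get("major") if len(meta.get("major", [])) == p else None,
    )


# ----------------------------------------------------------------- plink text

def _write_ped_map(g: GenotypeMatrix, ped_path: Path) -> None:
    map_path = ped_path.with_suffix(".map")
    with open(map_path, "w") as fh:
        for j in range(g.n_snps):
            fh.write(f"{g.chrom[j]}\t{g.snp_ids[j]}\t0\t{g.pos[j]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                if g.missing_mask[i, j]:
                    fields += ["0", "0"]
                else:
                    c = g.codes[i, j]
                    mi, ma = g.allele_minor[j], g.allele_major[j]
                    fields += {0: [ma, ma], 1: [ma, mi], 2: [mi, mi]}[int(c)]
            fh.write("\t".join(fields) + "\n")


def _read_ped_map(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise ParseError(f"missing .map companion for {ped_path}")
    chrom, snp_ids, pos = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ParseError(f"{map_path}: line {ln}: expected 3-4 fields")
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            pos.append(int(parts[-1]))
    p = len(snp_ids)
    sample_ids, allele_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * p:
                raise ParseError(f"{ped_path}: line {ln}: expected {6 + 2 * p} fields, got {len(parts)}")
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    n = len(sample_ids)
    codes = np.zeros((n, p), dtype=np.int8)
    mask = np.zeros((n, p), dtype=bool)
    minor = np.empty(p, dtype=object)
    major = np.empty(p, dtype=object)
    alleles = np.asarray(allele_rows, dtype=object).reshape(n, p, 2) if n else np.empty((0, p, 2), dtype=object)
    for j in range(p):
        a = alleles[:, j, :].ravel() if n else np.array([], dtype=object)
        observed = a[a != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise ParseError(f"{ped_path}: SNP {snp_ids[j]} has >2 alleles")
        if uniq.size == 0:
            minor[j], major[j] = "B", "A"
            mask[:, j] = True
            continue
        if uniq.size == 1:
            major[j], minor[j] = uniq[0], "B" if uniq[0] != "B" else "C"
        else:
            # rarer allele is minor; tie broken toward the lexicographically
            # larger letter (the writer's default minor letter sorts last)
            if counts[0] != counts[1]:
                k = int(np.argmin(counts))
            else:
                k = int(np.argmax(uniq.astype(str)))
            minor[j], major[j] = uniq[k], uniq[1 - k]
        if n:
            pair = alleles[:, j, :]
            miss = np.any(pair == "0", axis=1)
            mask[:, j] = miss
            codes[:, j] = np.where(miss, 0, (pair == minor[j]).sum(axis=1))
    return GenotypeMatrix(sample_ids, snp_ids, chrom, pos, codes, mask,
                          allele_minor=minor, allele_major=major)


def _write_raw(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        header += [f"{sid}_{g.allele_minor[j]}" for j, sid in enumerate(g.snp_ids)]
        fh.write(" ".join(header) + "\n")
        codes = g.codes.astype(object)
        codes[g.missing_mask] = MISSING_TOKEN
        for i, sid in enumerate(g.sample_ids):
            fh.write(" ".join([str(sid), str(sid), "0", "0", "0", "-9"]
                              + [str(x) for x in codes[i]]) + "\n")


def _read_raw(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ParseError(f"{path}: line 1: not a .raw header")
        snp_cols = header[6:]
        snp_ids = [c.rsplit("_", 1)[0] for c in snp_cols]
        minor = [c.rsplit("_", 1)[1] if "_" in c else "B" for c in snp_cols]
        sample_ids, rows, mask_rows = [], [], []
        for ln, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + len(snp_ids):
                raise ParseError(f"{path}: line {ln}: wrong field count")
            sample_ids.append(parts[1])
            miss = [t in (MISSING_TOKEN, "NA") for t in parts[6:]]
            rows.append([0 if m else int(t) for t, m in zip(parts[6:], miss)])
            mask_rows.append(miss)
    n, p = len(sample_ids), len(snp_ids)
    return GenotypeMatrix(sample_ids, snp_ids, ["0"] * p, list(range(1, p + 1)),
                          np.asarray(rows, dtype=np.int8).reshape(n, p),
                          np.asarray(mask_rows, dtype=bool).reshape(n, p),
                          allele_minor=minor)


# ------------------------------------------------------------------------ vcf

def _read_vcf(path: Path, strict: bool = False) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    snp_ids, chrom, pos, minor, major = [], [], [], [], []
    cols, masks = [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1 or not var.ALT[0] or var.ALT[0] == ".":
            if strict:
                raise ParseError(f"{path}: record {var.CHROM}:{var.POS} is not biallelic")
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        miss = gt == 3
        alt_count = gt.copy()
        alt_count[miss] = 0
        n_obs = 2 * int((~miss).sum())
        alt_freq = alt_count.sum() / n_obs if n_obs else 0.0
        if alt_freq <= 0.5:
            codes, mi, ma = alt_count, var.ALT[0], var.REF
        else:
            codes, mi, ma = np.where(miss, 0, 2 - alt_count).astype(np.int8), var.REF, var.ALT[0]
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        minor.append(mi)
        major.append(ma)
        cols.append(codes)
        masks.append(miss)
    n = len(sample_ids)
    p = len(snp_ids)
    codes = np.column_stack(cols).astype(np.int8) if p else np.zeros((n, 0), dtype=np.int8)
    mask = np.column_stack(masks) if p else np.zeros((n, 0), dtype=bool)
    return GenotypeMatrix(sample_ids, snp_ids, chrom, pos, codes, mask,
                          allele_minor=minor, allele_major=major)


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.sample_ids)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(g.n_snps):
            gts = ["./." if g.missing_mask[i, j] else gt_map[int(g.codes[i, j])]
                   for i in range(g.n_samples)]
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\t{g.allele_major[j]}\t"
                     f"{g.allele_minor[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# -------------------------------------------------------------------- public

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".vcf", ".gz", ".bcf"):
        return "vcf"
    if suffix in (".ped", ".raw"):
        return "plink_text"
    return "matrix_tsv"


def read_genotypes(path, format: str | None = None, strict: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix; ``format`` in {vcf, plink_text, matrix_tsv}.

    With ``strict`` set, non-biallelic VCF records raise instead of
    being skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        return _read_vcf(path, strict=strict)
    if fmt == "plink_text":
        return _read_raw(path) if path.suffix == ".raw" else _read_ped_map(path)
    if fmt == "matrix_tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str | None = None) -> Path:
    """Write a genotype matrix; matrix_tsv and plink_text round-trip."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "plink_text":
        if path.suffix == ".raw":
            _write_raw(g, path)
        else:
            _write_ped_map(g, path)
    elif fmt == "matrix_tsv":
        _write_matrix_tsv(g, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    return path


def recode_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Recode columns so codes count the currently-minor allele.

    After sample exclusions the minor allele of a SNP can flip; this
    recomputes observed allele frequencies and flips codes (2 - code)
    and the allele labels for any SNP whose coded allele now has
    frequency > 0.5.
    """
    codes = g.codes.copy()
    minor = g.allele_minor.copy()
    major = g.allele_major.copy()
    obs = ~g.missing_mask
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, codes, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    flip = freq > 0.5
    codes[:, flip] = 2 - codes[:, flip]
    codes[g.missing_mask] = 0
    minor[flip], major[flip] = g.allele_major[flip], g.allele_minor[flip]
    return GenotypeMatrix(g.sample_ids, g.snp_ids, g.chrom, g.pos, codes,
                          g.missing_mask, allele_minor=minor, allele_major=major)


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV with a mandatory header."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=[MISSING_TOKEN])
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path) -> Path:
    p.data.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)
    return Path(path)
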