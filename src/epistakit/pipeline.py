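"""End-to-end orchestration: simulate/ingest -> QC -> filter -> scans -> report.

A single :class:`RunConfig` (YAML-serializable) drives the whole
analysis; every stage writes its outputs into the run directory, a
manifest records SHA-256 hashes of every artifact, and reruns with the
same config and seed are bit-identical.  Multiple-testing correction
is strictly within each scan, never across scans.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .datamodel import GenotypeMatrix, Trait, derive_hypertension, categorize_age
from .mbmdr import (PermutationPlan, scan_gxe, scan_main_effects, scan_pairs,
                    compare_scans)
from .qc import QCThresholds, run_qc
from .relief import compute_filter, select_top_k, filter_concordance
from .simulate import SimConfig, simulate_blood_pressure_cohort

__all__ = ["RunConfig", "ScanSpec", "run_pipeline", "make_report"]


@dataclass
class ScanSpec:
    trait: str = "hs"              # "hs" | "sbp" | "dbp"
    mode: str = "pairs"            # "main" | "pairs" | "gxe"
    env: str | None = None         # "age" | "sex" (gxe only)
    adjust: bool = False
    alpha1: float = 0.1
    min_cell_count: int = 10
    plan: PermutationPlan = field(default_factory=PermutationPlan)
    use_filter_subset: bool = False


@dataclass
class RunConfig:
    genotypes: str | None = None       # path; None -> simulate
    phenotypes: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    filter_method: str | None = None   # one of the seven filter names
    filter_top_k: int = 1000
    scans: list = field(default_factory=list)
    seed: int = 0

    # ---- (de)serialization ----
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig(**{**d["sim"],
                                    "maf_range": tuple(d["sim"].get("maf_range", (0.05, 0.5))),
                                    "related_pairs": tuple(d["sim"].get("related_pairs", (0, 0.0))),
                                    "ld_blocks": [tuple(b) for b in d["sim"].get("ld_blocks", [])]})
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCThresholds(**d["qc"])
        scans = []
        for s in d.get("scans", []):
            if isinstance(s, dict):
                s = dict(s)
                if isinstance(s.get("plan"), dict):
                    s["plan"] = PermutationPlan(**s["plan"])
                s = ScanSpec(**s)
            scans.append(s)
        d["scans"] = scans
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_top_grid(path, g, trait, res, spec, pheno) -> None:
    """Write the risk grid (counts, statistics, H/L/O labels) of the
    scan's top-ranked pair — the per-hit diagnostic view."""
    from .mbmdr import build_risk_grid

    top = res.top()
    a = g.snp_index(top.factor_a)
    ca = np.where(g.missing_mask[:, a], -1, g.codes[:, a]).astype(int)
    if top.factor_b is None:
        cells, shape = ca, (3,)
    elif spec.mode == "gxe":
        env = _resolve_env(spec.env or "age", pheno)
        cb = np.where(np.isnan(env.values), -1, env.values).astype(int)
        L = env.n_levels
        cells = np.where((ca >= 0) & (cb >= 0), ca * L + cb, -1)
        shape = (3, L)
    else:
        b = g.snp_index(top.factor_b)
        cb = np.where(g.missing_mask[:, b], -1, g.codes[:, b]).astype(int)
        cells = np.where((ca >= 0) & (cb >= 0), ca * 3 + cb, -1)
        shape = (3, 3)
    grid = build_risk_grid(trait.values, trait.kind if trait.kind != "categorical"
                           else "binary", cells, shape, spec.alpha1,
                           spec.min_cell_count, top.factor_a, top.factor_b)
    grid.to_dataframe().to_csv(path, sep="\t", index=False)


def _resolve_trait(name: str, pheno) -> Trait:
    if name == "hs":
        return derive_hypertension(pheno)
    if name in ("sbp", "dbp"):
        return Trait(name, "continuous", pheno.column(name))
    raise ValueError(f"unknown trait {name!r}")


def _resolve_env(name: str, pheno) -> Trait:
    if name == "age":
        return categorize_age(pheno, n_groups=3)
    if name == "sex":
        return Trait("sex", "categorical", pheno.column("sex"))
    raise ValueError(f"unknown environmental factor {name!r}")


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute all configured stages; returns the run directory.

    Stage order: data (simulate or load), trait derivation, iterative
    QC, optional nearest-neighbor filtering on hypertension status,
    the configured scans, and the summary report.  Each stage logs the
    sample/SNP counts crossing its boundary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    cfg.to_yaml(outdir / "config.yaml")

    # -- stage: data ------------------------------------------------
    if cfg.genotypes is None:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        g, pheno = simulate_blood_pressure_cohort(sim)
        log(f"simulate: {g.n_samples} samples x {g.n_snps} SNPs (seed {cfg.seed})")
    else:
        g = gio.read_genotypes(cfg.genotypes)
        pheno = gio.read_phenotypes(cfg.phenotypes).aligned_to(g)
        log(f"load: {g.n_samples} samples x {g.n_snps} SNPs from {cfg.genotypes}")
    gio.write_genotypes(g, outdir / "genotypes.tsv", format="matrix_tsv")
    gio.write_phenotypes(pheno, outdir / "phenotypes.tsv")

    hs = derive_hypertension(pheno)
    n_excl = int((~hs.observed).sum())
    log(f"traits: hypertension cases={int(np.nansum(hs.values))} "
        f"controls={int((hs.values == 0).sum())} phenotype-incomplete={n_excl}")

    # -- stage: QC --------------------------------------------------
    try:
        g_qc, report = run_qc(g, hs, cfg.qc)
    except Exception as e:  # outputs written so far remain for inspection
        raise RuntimeError(f"pipeline stage 'qc' failed: {e}") from e
    report.to_tsv(outdir / "qc_exclusions.tsv")
    (outdir / "qc_log.txt").write_text(report.summary() + "\n")
    log(f"qc: {report.initial_shape} -> {report.final_shape} "
        f"in {report.n_passes} excluding pass(es)")
    pheno_qc = pheno.aligned_to(g_qc)

    # -- stage: filter ----------------------------------------------
    subset = None
    if cfg.filter_method:
        hs_qc = derive_hypertension(pheno_qc)
        complete = hs_qc.observed
        hs_vals = hs_qc.values[complete]
        kw = {}
        if cfg.filter_method in ("relieff", "turf"):
            smaller = int(min((hs_vals == 1).sum(), (hs_vals == 0).sum()))
            kw["k"] = min(10, max(1, smaller - 1))
        if cfg.filter_method in ("turf", "surf_star_n_turf"):
            kw["stop_at"] = max(min(cfg.filter_top_k, g_qc.n_snps - 1), 1)
        fw = compute_filter(cfg.filter_method, g_qc.subset(samples=complete),
                            Trait("hs", "binary", hs_vals), **kw)
        fw.to_dataframe().to_csv(outdir / "filter_weights.tsv", sep="\t", index=False)
        k = min(cfg.filter_top_k, g_qc.n_snps)
        subset = select_top_k(fw, k)
        (outdir / "filter_subset.txt").write_text("\n".join(subset) + "\n")
        log(f"filter: {cfg.filter_method} top-{k} subset written")

    # -- stage: scans -----------------------------------------------
    scan_tables = {}
    for s_idx, spec in enumerate(cfg.scans):
        name = f"scan{s_idx}_{spec.mode}_{spec.trait}"
        try:
            trait = _resolve_trait(spec.trait, pheno_qc)
            plan = dataclasses.replace(spec.plan, seed=spec.plan.seed or cfg.seed + s_idx)
            g_scan = g_qc
            if spec.use_filter_subset and subset is not None:
                keep = np.isin(g_qc.snp_ids, list(subset))
                g_scan = g_qc.subset(snps=keep)
            kw = dict(alpha1=spec.alpha1, min_cell_count=spec.min_cell_count)
            if spec.mode == "main":
                res = scan_main_effects(g_scan, trait, plan, **kw)
            elif spec.mode == "pairs":
                res = scan_pairs(g_scan, trait, plan, **kw)
            elif spec.mode == "gxe":
                env = _resolve_env(spec.env or "age", pheno_qc)
                res = scan_gxe(g_scan, trait, env, plan, adjust=spec.adjust, **kw)
            else:
                raise ValueError(f"unknown scan mode {spec.mode!r}")
            res.to_dataframe().to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            scan_tables[name] = res
            log(f"{name}: {len(res)} hypotheses, "
                f"{len(res.significant(0.05))} significant at 0.05, "
                f"{res.n_pair_perm_evals} pair-permutation evaluations")
            _dump_top_grid(outdir / f"{name}_top_grid.tsv", g_scan, trait, res,
                           spec, pheno_qc)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    # -- stage: concordance -----------------------------------------
    if subset is not None:
        hits = [(r.factor_a, r.factor_b) for name, res in scan_tables.items()
                if "pairs" in name for r in res.significant(0.05)]
        conc = filter_concordance({cfg.filter_method: subset}, hits)
        (outdir / "filter_concordance.json").write_text(json.dumps(conc, indent=2) + "\n")
        log(f"concordance: {conc}")

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    manifest = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    make_report(outdir)
    return outdir


def make_report(run_dir) -> Path:
    """Regenerate the human-readable summary for a completed run."""
    import pandas as pd

    run_dir = Path(run_dir)
    if not (run_dir / "run_log.txt").exists():
        raise FileNotFoundError("incomplete run: missing run_log.txt")
    lines = ["# Run report", ""]
    lines += ["## Stage log", "", "```",
              (run_dir / "run_log.txt").read_text().rstrip(), "```", ""]
    if (run_dir / "qc_log.txt").exists():
        lines += ["## Quality control", "", "```",
                  (run_dir / "qc_log.txt").read_text().rstrip(), "```", ""]
    for scan_file in sorted(run_dir.glob("scan*_*.tsv")):
        if scan_file.stem.endswith("_top_grid"):
            continue
        df = pd.read_csv(scan_file, sep="\t")
        sig = df[df["p_adjusted"] <= 0.05]
        lines += [f"## {scan_file.stem}", ""]
        if len(sig):
            lines += [f"{len(sig)} significant hit(s) at adjusted p <= 0.05:", ""]
            top = sig.sort_values("p_adjusted").head(20)
            lines += [top.to_string(index=False), ""]
        else:
            lines += ["0 significant hits at adjusted p <= 0.05.", ""]
    if (run_dir / "filter_concordance.json").exists():
        lines += ["## Filter concordance", "",
                  (run_dir / "filter_concordance.json").read_text().rstrip(), ""]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
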