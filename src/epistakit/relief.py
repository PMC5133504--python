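"""Nearest-neighbor relevance filters for SNP preselection.

Implements the Relief family for a binary affection status: Relief,
ReliefF, TuRF, SURF, SURF*, multiSURF and SURF*nTuRF.  Each filter
assigns a per-SNP weight that increases when nearest neighbors of the
*other* class differ at the SNP and decreases when nearest neighbors
of the *same* class differ, so SNPs whose genotypes track the class
boundary — singly or jointly — float to the top.

Distances between samples default to the genotype mismatch fraction
(the metric of the Relief-for-SNPs literature); missing genotypes are
skipped pairwise with renormalization so high-missingness SNPs are not
favored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypeMatrix, Trait

__all__ = [
    "FilterWeights",
    "genotype_distance",
    "pairwise_distances",
    "relief_weights",
    "relieff_weights",
    "surf_weights",
    "turf",
    "select_top_k",
    "filter_concordance",
    "compute_filter",
    "FILTER_NAMES",
]

FILTER_NAMES = ("relief", "relieff", "turf", "surf", "surf_star", "multisurf",
                "surf_star_n_turf")


@dataclass
class FilterWeights:
    snp_ids: np.ndarray
    weights: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    removal_round: np.ndarray | None = None  # TuRF only; -1 = survived

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(list(self.snp_ids), dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")
        if self.snp_ids.size != self.weights.size:
            raise ValueError("one weight per SNP required")

    def ranking(self) -> np.ndarray:
        """Indices ordered best-first; ties broken by SNP id order.

        For TuRF results, SNPs removed in later rounds outrank SNPs
        removed earlier, and all survivors outrank all removed SNPs.
        """
        n = self.weights.size
        tiebreak = np.arange(n)  # input order == SNP id order of the matrix
        if self.removal_round is None:
            keys = (tiebreak, -self.weights)
        else:
            rr = self.removal_round
            survived = np.where(rr < 0, np.iinfo(np.int64).max, rr)
            keys = (tiebreak, -self.weights, -survived)
        return np.lexsort(keys)

    def to_dataframe(self):
        import pandas as pd

        order = self.ranking()
        rank = np.empty_like(order)
        rank[order] = np.arange(1, order.size + 1)
        return pd.DataFrame({"snp_id": self.snp_ids, "weight": self.weights,
                             "rank": rank, "method": self.method,
                             "params": [repr(self.params)] * self.snp_ids.size})


# ------------------------------------------------------------------ distances

def genotype_distance(a: np.ndarray, b: np.ndarray, metric: str = "mismatch",
                      a_missing: np.ndarray | None = None,
                      b_missing: np.ndarray | None = None) -> float:
    """Distance between two samples' genotype code vectors.

    mismatch: fraction of pairwise-comparable SNPs with unequal codes;
    manhattan: mean |a-b| over comparable SNPs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    valid = np.ones(a.shape, dtype=bool)
    if a_missing is not None:
        valid &= ~np.asarray(a_missing, dtype=bool)
    if b_missing is not None:
        valid &= ~np.asarray(b_missing, dtype=bool)
    m = valid.sum()
    if m == 0:
        raise ValueError("no comparable SNPs between samples")
    if metric == "mismatch":
        return float((a[valid] != b[valid]).sum() / m)
    if metric == "manhattan":
        return float(np.abs(a[valid] - b[valid]).sum() / m)
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_distances(g: GenotypeMatrix, metric: str = "mismatch",
                       chunk: int = 64) -> np.ndarray:
    """Full n x n distance matrix with pairwise missing-skip."""
    n, p = g.n_samples, g.n_snps
    codes = g.codes.astype(np.int16)
    obs = ~g.missing_mask
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for start in range(0, p, chunk):
        c = codes[:, start:start + chunk]
        o = obs[:, start:start + chunk]
        both = o[:, None, :] & o[None, :, :]
        if metric == "mismatch":
            d = (c[:, None, :] != c[None, :, :]) & both
            num += d.sum(axis=2)
        elif metric == "manhattan":
            d = np.abs(c[:, None, :] - c[None, :, :]) * both
            num += d.sum(axis=2)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        cnt += both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = num / cnt
    dist[cnt == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist


# ------------------------------------------------------------------- updates

def _accumulate(g: GenotypeMatrix, target: int, neighbors: np.ndarray,
                num: np.ndarray, cnt: np.ndarray) -> None:
    """Add per-SNP diff counts target-vs-neighbors into (num, cnt)."""
    if neighbors.size == 0:
        return
    ct = g.codes[target]
    ot = ~g.missing_mask[target]
    cn = g.codes[neighbors]
    on = ~g.missing_mask[neighbors]
    valid = ot[None, :] & on
    diff = (cn != ct[None, :]) & valid
    num += diff.sum(axis=0)
    cnt += valid.sum(axis=0)


def _finish_weights(pos_num, pos_cnt, neg_num, neg_cnt) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = np.where(pos_cnt > 0, pos_num / np.maximum(pos_cnt, 1), 0.0)
        neg = np.where(neg_cnt > 0, neg_num / np.maximum(neg_cnt, 1), 0.0)
    return pos - neg


def _classes(trait: Trait) -> np.ndarray:
    if trait.kind != "binary":
        raise ValueError("nearest-neighbor filters require a binary trait")
    y = trait.values
    if np.isnan(y).any():
        raise ValueError("trait has missing values; subset samples first")
    return y.astype(int)


def relieff_weights(g: GenotypeMatrix, trait: Trait, k: int = 10,
                    n_iterations: int | None = None, metric: str = "mismatch",
                    seed: int | None = None,
                    dist: np.ndarray | None = None) -> FilterWeights:
    """Classical ReliefF: k nearest hits and misses per target sample.

    With ``n_iterations`` None every sample is a target (deterministic);
    otherwise that many targets are sampled without replacement using
    ``seed``.  Weight of a SNP rises with genotype differences to the
    nearest misses and falls with differences to the nearest hits; a
    constant SNP gets weight exactly 0.
    """
    y = _classes(trait)
    n = g.n_samples
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be non-empty")
    if k >= counts.min():
        raise ValueError(f"k={k} must be smaller than the smaller class ({counts.min()})")
    if dist is None:
        dist = pairwise_distances(g, metric=metric)
    if n_iterations is None:
        targets = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        targets = rng.choice(n, size=min(n_iterations, n), replace=False)
    pos_num = np.zeros(g.n_snps)
    pos_cnt = np.zeros(g.n_snps)
    neg_num = np.zeros(g.n_snps)
    neg_cnt = np.zeros(g.n_snps)
    for t in targets:
        # stable neighbor order: distance, then sample index
        order = np.lexsort((np.arange(n), dist[t]))
        order = order[order != t]
        hits = order[y[order] == y[t]][:k]
        misses = order[y[order] != y[t]][:k]
        _accumulate(g, t, misses, pos_num, pos_cnt)
        _accumulate(g, t, hits, neg_num, neg_cnt)
    w = _finish_weights(pos_num, pos_cnt, neg_num, neg_cnt)
    return FilterWeights(g.snp_ids, w, "relieff",
                         {"k": k, "n_iterations": n_iterations, "metric": metric,
                          "seed": seed})


def relief_weights(g: GenotypeMatrix, trait: Trait, n_iterations: int = 100,
                   metric: str = "mismatch", seed: int = 0,
                   dist: np.ndarray | None = None) -> FilterWeights:
    """Original Relief: single nearest hit/miss, sampled targets."""
    fw = relieff_weights(g, trait, k=1, n_iterations=n_iterations, metric=metric,
                         seed=seed, dist=dist)
    return FilterWeights(fw.snp_ids, fw.weights, "relief", fw.params)


def surf_weights(g: GenotypeMatrix, trait: Trait, variant: str = "surf",
                 metric: str = "mismatch",
                 thresholds: list[float] | None = None,
                 dist: np.ndarray | None = None) -> FilterWeights:
    """SURF-family filters with distance-threshold neighborhoods.

    surf: every other sample closer than T = mean pairwise distance is
    a neighbor, contributing with ReliefF signs (misses up, hits down).
    surf_star: samples beyond T also contribute, with inverted signs.
    multisurf: per-target thresholds T_i = mean distance from target i
    (near neighbors only).  Passing explicit ``thresholds`` instead runs
    SURF once per global threshold and averages the weights — the
    alternative reading of "multiple runs of SURF".
    """
    if variant not in ("surf", "surf_star", "multisurf"):
        raise ValueError(f"unknown SURF variant {variant!r}")
    y = _classes(trait)
    if np.bincount(y, minlength=2).min() == 0:
        raise ValueError("both classes must be non-empty")
    n = g.n_samples
    if dist is None:
        dist = pairwise_distances(g, metric=metric)
    off_diag = dist[~np.eye(n, dtype=bool)]
    if np.allclose(off_diag, off_diag.flat[0]):
        raise ValueError("degenerate distances: all pairs equally distant")

    def one_run(thr_per_target: np.ndarray, star: bool) -> np.ndarray:
        pos_num = np.zeros(g.n_snps)
        pos_cnt = np.zeros(g.n_snps)
        neg_num = np.zeros(g.n_snps)
        neg_cnt = np.zeros(g.n_snps)
        for t in range(n):
            near = np.flatnonzero((dist[t] < thr_per_target[t]) & (np.arange(n) != t))
            hits = near[y[near] == y[t]]
            misses = near[y[near] != y[t]]
            _accumulate(g, t, misses, pos_num, pos_cnt)
            _accumulate(g, t, hits, neg_num, neg_cnt)
            if star:
                far = np.flatnonzero((dist[t] >= thr_per_target[t]) & (np.arange(n) != t))
                fhits = far[y[far] == y[t]]
                fmisses = far[y[far] != y[t]]
                _accumulate(g, t, fhits, pos_num, pos_cnt)
                _accumulate(g, t, fmisses, neg_num, neg_cnt)
        return _finish_weights(pos_num, pos_cnt, neg_num, neg_cnt)

    mean_dist = float(off_diag.mean())
    if variant == "multisurf":
        if thresholds is not None:
            w = np.mean([one_run(np.full(n, t), star=False) for t in thresholds], axis=0)
            params = {"metric": metric, "thresholds": list(thresholds)}
        else:
            per_target = (dist.sum(axis=1)) / (n - 1)
            w = one_run(per_target, star=False)
            params = {"metric": metric, "threshold": "per-target mean"}
    else:
        w = one_run(np.full(n, mean_dist), star=(variant == "surf_star"))
        params = {"metric": metric, "threshold": mean_dist}
    return FilterWeights(g.snp_ids, w, variant, params)


def turf(g: GenotypeMatrix, trait: Trait, base_filter: str = "relieff",
         drop_fraction: float = 0.1, n_rounds: int | None = None,
         stop_at: int | None = None, **base_kwargs) -> FilterWeights:
    """Tuned wrapper: recompute base weights, drop the worst fraction.

    Each round removes ``floor(drop_fraction * remaining)`` (at least 1)
    lowest-weighted SNPs and recomputes the base filter on the
    survivors.  ``n_rounds`` bounds the rounds; ``stop_at`` stops once
    at most that many SNPs remain.  Survivors keep their last-round
    weights; removed SNPs keep the weight they had when removed, with
    the removal round recorded so ranking respects rounds first.
    SURF*nTuRF is ``base_filter="surf_star"``.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    if n_rounds is None and stop_at is None:
        raise ValueError("give n_rounds and/or stop_at")
    p = g.n_snps
    weights = np.zeros(p)
    removal_round = np.full(p, -1, dtype=int)
    active = np.arange(p)
    rounds_done = 0

    def base(sub: GenotypeMatrix) -> np.ndarray:
        if base_filter == "relieff":
            return relieff_weights(sub, trait, **base_kwargs).weights
        if base_filter in ("surf", "surf_star", "multisurf"):
            return surf_weights(sub, trait, variant=base_filter, **base_kwargs).weights
        if base_filter == "relief":
            return relief_weights(sub, trait, **base_kwargs).weights
        raise ValueError(f"unknown base filter {base_filter!r}")

    while True:
        sub = g.subset(snps=active)
        w = base(sub)
        weights[active] = w
        done_rounds = n_rounds is not None and rounds_done >= n_rounds
        done_size = stop_at is not None and active.size <= stop_at
        if done_rounds or done_size:
            break
        n_drop = max(1, int(np.floor(drop_fraction * active.size)))
        if stop_at is not None:
            n_drop = min(n_drop, active.size - stop_at)
        if n_drop <= 0 or n_drop >= active.size:
            break
        # drop lowest weights; on ties the earlier SNP is kept
        order = np.lexsort((active, -w))  # descending weight, then SNP order
        drop_local = order[-n_drop:]
        rounds_done += 1
        removal_round[active[drop_local]] = rounds_done
        keep = np.ones(active.size, dtype=bool)
        keep[drop_local] = False
        active = active[keep]

    name = "surf_star_n_turf" if base_filter == "surf_star" else "turf"
    return FilterWeights(g.snp_ids, weights, name,
                         {"base_filter": base_filter, "drop_fraction": drop_fraction,
                          "n_rounds": n_rounds, "stop_at": stop_at, **base_kwargs},
                         removal_round=removal_round)


def compute_filter(name: str, g: GenotypeMatrix, trait: Trait, **kwargs) -> FilterWeights:
    """Dispatch one of the seven filters by name."""
    if name == "relief":
        return relief_weights(g, trait, **kwargs)
    if name == "relieff":
        return relieff_weights(g, trait, **kwargs)
    if name == "surf":
        return surf_weights(g, trait, variant="surf", **kwargs)
    if name == "surf_star":
        return surf_weights(g, trait, variant="surf_star", **kwargs)
    if name == "multisurf":
        return surf_weights(g, trait, variant="multisurf", **kwargs)
    if name == "turf":
        return turf(g, trait, base_filter="relieff", **kwargs)
    if name == "surf_star_n_turf":
        return turf(g, trait, base_filter="surf_star", **kwargs)
    raise ValueError(f"unknown filter {name!r}; choose from {FILTER_NAMES}")


def select_top_k(w: FilterWeights, k: int = 1000) -> list[str]:
    """The k top-ranked SNP ids (ties broken by SNP id order)."""
    if k > w.snp_ids.size:
        raise ValueError(f"k={k} exceeds {w.snp_ids.size} weighted SNPs")
    return list(w.snp_ids[w.ranking()[:k]])


def filter_concordance(subsets: dict[str, "set[str] | list[str]"],
                       scan_hits: list[tuple]) -> dict[str, int]:
    """Count significant pairs fully contained in each filter subset.

    ``scan_hits`` holds (snp_id_a, snp_id_b) pairs from an interaction
    scan; a pair counts for a subset when both members are present.
    """
    out = {}
    for name, subset in subsets.items():
        s = set(subset)
        out[name] = sum(1 for a, b in scan_hits if a in s and b in s)
    return out
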