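"""Model-based multifactor dimensionality reduction (MB-MDR).

For a pair of discrete factors (two SNPs, or a SNP and a categorical
environmental factor) the genotype/level combinations span a grid of
cells.  Step 1 tests each cell against all others (chi-square for a
binary trait, Welch t for a continuous trait) and labels it H(igh
risk), L(ow risk) or O (no evidence) from the test's sign and
significance at ``alpha1``; undersized cells are O.  Step 2 pools the
H cells and tests them against the rest (T_H), likewise for L (T_L),
and keeps T_max = max(T_H, T_L).  Step 3 assesses T_max over all
scanned pairs by permutation-based maxT multiple-testing correction:
the trait is permuted across samples (one shared permutation per
replicate), every pair's T_max is recomputed, and a pair's adjusted p
is the add-one fraction of permutation maxima reaching its observed
T_max.  The speedMAXT variant drops pairs whose running adjusted-p
estimate exceeds a confidence bound around 1.5/(permutations so far),
saving the bulk of the permutation work for clearly null pairs.

Lower-order (main) effects can be removed before scanning a continuous
trait with the co-dominant adjustment: the trait is residualized on
unordered-category indicators of each factor in the pair, so only
genuinely non-additive cell patterns survive into Steps 1-3.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeMatrix, Trait

__all__ = [
    "PermutationPlan",
    "RiskGrid",
    "ScanResult",
    "ScanResults",
    "cell_statistic",
    "label_cells",
    "build_risk_grid",
    "step2_statistic",
    "codominant_adjust",
    "maxt_scan",
    "speedmaxt_scan",
    "scan_main_effects",
    "scan_pairs",
    "scan_gxe",
    "compare_scans",
    "all_pairs",
]

DEFAULT_ALPHA1 = 0.1
DEFAULT_MIN_CELL = 10


@dataclass
class PermutationPlan:
    """Permutation budget and the speedMAXT early-dropping constants.

    In speedmaxt mode, every ``check_interval`` permutations a pair is
    retired when (a) its adjusted-p estimate exceeds the Wilson upper
    confidence bound around ``drop_bound_factor`` / (permutations so
    far), and (b) its exceedance count already rules out significance
    at ``alpha_guard`` even if no further permutation ever reached its
    statistic — so a retired pair is non-significant under plain maxT
    as well, by construction.
    """

    B: int = 10000
    seed: int = 0
    mode: str = "maxt"  # "maxt" | "speedmaxt"
    check_interval: int = 100000
    ci_level: float = 0.95
    drop_bound_factor: float = 1.5
    alpha_guard: float = 0.05
    exhaustive: bool = False

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1")
        if self.mode not in ("maxt", "speedmaxt"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ------------------------------------------------------------ cell statistics

def _chi2_2x2(a, b, c, d):
    """Signed Pearson chi-square (no continuity correction) of the 2x2
    table [[a, b], [c, d]]; sign follows the direction a/(a+b) vs
    c/(c+d).  Degenerate margins give 0."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    det = a * d - b * c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * det * det / denom, 0.0)
    return chi2, np.sign(det)


def _welch_t(n1, m1, v1, n2, m2, v2):
    """Welch t statistic and degrees of freedom from summary stats.

    Returns (t, df); t is 0 (df 1) when either group has < 2
    observations or both variances vanish with equal means.
    """
    n1, m1, v1, n2, m2, v2 = (np.asarray(x, dtype=float) for x in (n1, m1, v1, n2, m2, v2))
    q1 = v1 / np.maximum(n1, 1.0)
    q2 = v2 / np.maximum(n2, 1.0)
    se2 = q1 + q2
    df_denom = q1 * q1 / np.maximum(n1 - 1.0, 1.0) + q2 * q2 / np.maximum(n2 - 1.0, 1.0)
    ok = (se2 > 0) & (n1 >= 2) & (n2 >= 2)
    t = np.zeros(np.broadcast(se2, m1).shape)
    np.divide(m1 - m2, np.sqrt(se2, where=se2 > 0, out=np.ones_like(se2)), out=t, where=ok)
    df = np.ones_like(t)
    np.divide(se2 * se2, df_denom, out=df, where=ok & (df_denom > 0))
    return t, df


def cell_statistic(cell_samples, rest_samples, kind: str):
    """Signed association statistic and two-sided p for cell vs rest.

    Binary: chi-square of cell membership x affection, signed by the
    cell's case enrichment.  Continuous: Welch two-sample t signed by
    the mean difference.
    """
    cell = np.asarray(cell_samples, dtype=float)
    rest = np.asarray(rest_samples, dtype=float)
    if cell.size == 0 or rest.size == 0:
        raise ValueError("cell and rest must be non-empty")
    if kind == "binary":
        a, b = cell.sum(), cell.size - cell.sum()
        c, d = rest.sum(), rest.size - rest.sum()
        chi2, sign = _chi2_2x2(a, b, c, d)
        p = float(stats.chi2.sf(chi2, df=1))
        return float(sign * chi2), p
    if kind == "continuous":
        v1 = cell.var(ddof=1) if cell.size > 1 else 0.0
        v2 = rest.var(ddof=1) if rest.size > 1 else 0.0
        t, df = _welch_t(cell.size, cell.mean(), v1, rest.size, rest.mean(), v2)
        p = float(2 * stats.t.sf(abs(t), df)) if (cell.size > 1 and rest.size > 1) else 1.0
        return float(t), p
    raise ValueError(f"unknown trait kind {kind!r}")


def label_cells(counts: np.ndarray, statistics: np.ndarray, pvalues: np.ndarray,
                alpha1: float = DEFAULT_ALPHA1,
                min_cell_count: int = DEFAULT_MIN_CELL) -> np.ndarray:
    """H/L/O labels from per-cell signed statistics and p values.

    A cell is H when significant (p <= alpha1) with positive statistic,
    L when significant with negative statistic, O otherwise; cells with
    fewer than ``min_cell_count`` samples are O regardless.
    """
    counts = np.asarray(counts)
    statistics = np.asarray(statistics, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    labels = np.full(counts.shape, "O", dtype=object)
    sig = (pvalues <= alpha1) & (counts >= min_cell_count)
    labels[sig & (statistics > 0)] = "H"
    labels[sig & (statistics < 0)] = "L"
    return labels


@dataclass
class RiskGrid:
    """Step-1 output for one factor pair: per-cell counts, statistics
    and H/L/O labels, plus the cell assignment used to build it."""

    factor_a: str
    factor_b: str | None
    counts: np.ndarray        # (Ka,) or (Ka, Kb)
    statistics: np.ndarray
    pvalues: np.ndarray
    labels: np.ndarray
    cell_index: np.ndarray    # per analyzed sample, flat cell id
    trait_values: np.ndarray  # per analyzed sample

    def to_dataframe(self) -> pd.DataFrame:
        shape = self.counts.shape
        rows = []
        for flat, (cnt, st, pv, lab) in enumerate(zip(
                self.counts.ravel(), self.statistics.ravel(),
                self.pvalues.ravel(), self.labels.ravel())):
            idx = np.unravel_index(flat, shape)
            rows.append((*idx, cnt, st, pv, lab) if len(shape) == 2
                        else (idx[0], cnt, st, pv, lab))
        cols = (["level_a", "level_b"] if len(shape) == 2 else ["level_a"]) + \
               ["count", "statistic", "p", "label"]
        return pd.DataFrame(rows, columns=cols)


def build_risk_grid(y: np.ndarray, kind: str, cells: np.ndarray, shape: tuple,
                    alpha1: float = DEFAULT_ALPHA1,
                    min_cell_count: int = DEFAULT_MIN_CELL,
                    factor_a: str = "a", factor_b: str | None = "b") -> RiskGrid:
    """Reference (scalar) Step-1 construction for one pair.

    ``cells`` holds flat cell ids (-1 = missing factor data); samples
    with missing trait or factor are excluded from the grid.
    """
    y = np.asarray(y, dtype=float)
    keep = (cells >= 0) & ~np.isnan(y)
    yv, cv = y[keep], cells[keep]
    K = int(np.prod(shape))
    counts = np.bincount(cv, minlength=K).astype(int)
    statistics = np.zeros(K)
    pvalues = np.ones(K)
    for j in range(K):
        in_cell = cv == j
        if counts[j] == 0 or counts[j] == yv.size:
            continue
        statistics[j], pvalues[j] = cell_statistic(yv[in_cell], yv[~in_cell], kind)
    labels = label_cells(counts, statistics, pvalues, alpha1, min_cell_count)
    return RiskGrid(factor_a, factor_b,
                    counts.reshape(shape), statistics.reshape(shape),
                    pvalues.reshape(shape), labels.reshape(shape),
                    cell_index=cv, trait_values=yv)


def step2_statistic(grid: RiskGrid, kind: str):
    """(T_H, T_L, T_max) from pooling H cells vs the rest, and L vs rest.

    The test family matches Step 1; on the chi-square scale for binary
    traits and the squared-t scale for continuous traits, so the two
    sides are comparable.  A side with no cells contributes 0.
    """
    flat_labels = grid.labels.ravel()
    y, cv = grid.trait_values, grid.cell_index
    out = {}
    for side in ("H", "L"):
        member_cells = np.flatnonzero(flat_labels == side)
        in_side = np.isin(cv, member_cells)
        if not in_side.any() or in_side.all():
            out[side] = 0.0
            continue
        if kind == "binary":
            stat, _ = cell_statistic(y[in_side], y[~in_side], kind)
            out[side] = abs(stat)
        else:
            t, _ = cell_statistic(y[in_side], y[~in_side], kind)
            out[side] = t * t
    return out["H"], out["L"], max(out["H"], out["L"])


# -------------------------------------------------------- co-dominant adjust

def codominant_adjust(y: np.ndarray, factor_a: np.ndarray,
                      factor_b: np.ndarray | None = None,
                      covariates: np.ndarray | None = None) -> np.ndarray:
    """Residualize a continuous trait on unordered-category factor codes.

    Each factor enters as indicator contrasts over its observed levels
    (one dropped for the intercept; empty levels drop out naturally),
    plus optional covariate columns.  Returns residuals with NaN where
    the trait or a factor is missing.
    """
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(y) & (np.asarray(factor_a) >= 0)
    if factor_b is not None:
        valid &= np.asarray(factor_b) >= 0
    cols = [np.ones(valid.sum())]
    for fac in (factor_a, factor_b):
        if fac is None:
            continue
        f = np.asarray(fac)[valid].astype(int)
        levels = np.unique(f)
        for lev in levels[1:]:
            cols.append((f == lev).astype(float))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov[valid].T)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y[valid], rcond=None)
    out = np.full(y.shape, np.nan)
    out[valid] = y[valid] - X @ beta
    return out


# ----------------------------------------------------------- scan machinery

@dataclass
class ScanResult:
    factor_a: str
    factor_b: str | None
    t_h: float
    t_l: float
    t_max: float
    p_raw: float
    p_adjusted: float
    n_perm: int
    dropped_early: bool = False

    @property
    def pair(self) -> tuple:
        return (self.factor_a, self.factor_b)


@dataclass
class ScanResults:
    results: list
    plan: PermutationPlan
    kind: str
    alpha1: float = DEFAULT_ALPHA1
    min_cell_count: int = DEFAULT_MIN_CELL
    n_pair_perm_evals: int = 0

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.factor_a, r.factor_b, r.t_h, r.t_l, r.t_max, r.p_raw,
              r.p_adjusted, r.n_perm, r.dropped_early) for r in self.results],
            columns=["factor_a", "factor_b", "T_H", "T_L", "T_max", "p_raw",
                     "p_adjusted", "n_perm_used", "dropped_early"],
        )

    def significant(self, alpha: float = 0.05) -> list:
        return [r for r in self.results if r.p_adjusted <= alpha]

    def top(self) -> ScanResult:
        return max(self.results, key=lambda r: r.t_max)


def _kernel_tmax(cells: np.ndarray, K: int, Y: np.ndarray, kind: str,
                 alpha1: float, min_cell: int, details: bool = False):
    """T_max for every (permutation row of Y) x (pair row of cells).

    ``cells``: (P, n) flat cell ids with -1 for missing; ``Y``: (B, n)
    trait replicates (row 0 is usually the observed trait).  Returns a
    (B, P) array, plus per-pair Step-1/2 detail for row 0 on request.
    """
    P, n = cells.shape
    B = Y.shape[0]
    ind = np.zeros((n, P * K))
    for p in range(P):
        v = cells[p] >= 0
        ind[np.flatnonzero(v), p * K + cells[p, v]] = 1.0
    tot = ind.sum(axis=0).reshape(P, K)            # (P, K) cell sizes
    n_eff = tot.sum(axis=1)                        # (P,)
    S1 = (Y @ ind).reshape(B, P, K)

    if kind == "binary":
        cases = S1.sum(axis=2)                     # (B, P)
        a = S1
        # a*d - b*c simplifies to a*N - (row margin)*(column margin)
        det = a * n_eff[None, :, None] - tot[None] * cases[:, :, None]
        denom = tot[None] * (n_eff[None, :, None] - tot[None]) * \
            cases[:, :, None] * (n_eff[None, :, None] - cases[:, :, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(denom > 0, n_eff[None, :, None] * det * det / denom, 0.0)
        crit = stats.chi2.isf(alpha1, df=1)
        sig = (chi2 >= crit) & (tot[None] >= min_cell)
        H = sig & (det > 0)
        L = sig & (det < 0)

        def pooled(side):
            A = (a * side).sum(axis=2)
            Tcell = (tot[None] * side).sum(axis=2)
            stat, _ = _chi2_2x2(A, Tcell - A, cases - A,
                                (n_eff[None] - Tcell) - (cases - A))
            return np.where((Tcell > 0) & (Tcell < n_eff[None]), stat, 0.0)

        T_H, T_L = pooled(H), pooled(L)
    elif kind == "continuous":
        S2 = ((Y * Y) @ ind).reshape(B, P, K)
        tS1 = S1.sum(axis=2)
        tS2 = S2.sum(axis=2)
        n1 = np.broadcast_to(tot[None], S1.shape)
        n2 = n_eff[None, :, None] - n1
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = np.where(n1 > 0, S1 / np.maximum(n1, 1), 0.0)
            v1 = np.where(n1 > 1, (S2 - S1 ** 2 / np.maximum(n1, 1)) / np.maximum(n1 - 1, 1), 0.0)
            m2 = np.where(n2 > 0, (tS1[:, :, None] - S1) / np.maximum(n2, 1), 0.0)
            v2 = np.where(n2 > 1, ((tS2[:, :, None] - S2) - (tS1[:, :, None] - S1) ** 2
                                   / np.maximum(n2, 1)) / np.maximum(n2 - 1, 1), 0.0)
        t, df = _welch_t(n1, m1, v1, n2, m2, v2)
        # |t| below the normal quantile can never reach p <= alpha1 for any
        # df, so the expensive t-tail evaluation runs on candidates only
        abs_t = np.abs(t)
        cand = abs_t >= stats.norm.isf(alpha1 / 2)
        pv = np.ones_like(t)
        pv[cand] = 2 * stats.t.sf(abs_t[cand], df[cand])
        sig = (pv <= alpha1) & (n1 >= min_cell) & (n1 >= 2) & (n2 >= 2)
        H = sig & (t > 0)
        L = sig & (t < 0)

        def pooled(side):
            nH = (n1 * side).sum(axis=2)
            s1H = (S1 * side).sum(axis=2)
            s2H = (S2 * side).sum(axis=2)
            nR = n_eff[None] - nH
            with np.errstate(invalid="ignore", divide="ignore"):
                mH = np.where(nH > 0, s1H / np.maximum(nH, 1), 0.0)
                vH = np.where(nH > 1, (s2H - s1H ** 2 / np.maximum(nH, 1)) / np.maximum(nH - 1, 1), 0.0)
                mR = np.where(nR > 0, (tS1 - s1H) / np.maximum(nR, 1), 0.0)
                vR = np.where(nR > 1, ((tS2 - s2H) - (tS1 - s1H) ** 2 / np.maximum(nR, 1))
                              / np.maximum(nR - 1, 1), 0.0)
            tp, _ = _welch_t(nH, mH, vH, nR, mR, vR)
            return np.where((nH >= 2) & (nR >= 2), tp * tp, 0.0)

        T_H, T_L = pooled(H), pooled(L)
        t0, df0 = t, df  # kept for details
    else:
        raise ValueError(f"unknown trait kind {kind!r}")

    T_max = np.maximum(np.abs(T_H), np.abs(T_L))
    if not details:
        return T_max, None
    if kind == "binary":
        stat0 = np.sign(det[0]) * chi2[0]
        pv0_ = stats.chi2.sf(chi2[0], df=1)
    else:
        stat0 = t0[0]
        pv0_ = 2 * stats.t.sf(np.abs(t0[0]), df0[0])
    labels0 = np.full((P, K), "O", dtype=object)
    labels0[H[0]] = "H"
    labels0[L[0]] = "L"
    det0 = {"T_H": np.abs(T_H[0]), "T_L": np.abs(T_L[0]), "counts": tot.astype(int),
            "statistics": stat0, "pvalues": pv0_, "labels": labels0}
    return T_max, det0


def _factor(g: GenotypeMatrix, spec, env_codes: np.ndarray | None = None):
    """Resolve a factor spec into (name, codes, n_levels)."""
    if spec is None:
        return None
    if isinstance(spec, Trait):
        if spec.kind == "continuous":
            raise ValueError("environmental factors must be discrete")
        vals = spec.values
        codes = np.where(np.isnan(vals), -1, vals).astype(np.int64)
        levels = np.unique(codes[codes >= 0])
        if levels.size < 1:
            raise ValueError(f"factor {spec.name} has no observed levels")
        # drop empty levels (compact recode), warn if any vanished
        if levels.size != levels.max() + 1:
            warnings.warn(f"factor {spec.name}: empty levels dropped")
        remap = {int(l): i for i, l in enumerate(levels)}
        codes = np.array([remap.get(int(c), -1) if c >= 0 else -1 for c in codes])
        return (spec.name, codes, levels.size)
    j = g.snp_index(spec) if isinstance(spec, str) else int(spec)
    codes = np.where(g.missing_mask[:, j], -1, g.codes[:, j]).astype(np.int64)
    return (str(g.snp_ids[j]), codes, 3)


def _permutation_matrix(plan: PermutationPlan, n: int):
    """Rows of sample permutations; row 0 is identity.

    Sampled mode returns B+1 rows (identity + B draws); exhaustive mode
    returns all n! permutations (identity first).
    """
    if plan.exhaustive:
        if n > 8:
            raise ValueError("exhaustive permutation only supported for n <= 8")
        return np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    rng = np.random.default_rng(plan.seed)
    perms = np.argsort(rng.random((plan.B, n)), axis=1)
    return np.vstack([np.arange(n, dtype=np.int64)[None, :], perms])


def _wilson_upper(successes: float, trials: int, ci_level: float) -> float:
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    p0 = successes / trials
    denom = 1 + z * z / trials
    center = p0 + z * z / (2 * trials)
    half = z * np.sqrt(p0 * (1 - p0) / trials + z * z / (4 * trials ** 2))
    return float((center + half) / denom)


def _prepare(g: GenotypeMatrix, trait: Trait, pairs, env=None):
    """Subset to trait-observed samples and build the cell-index matrix."""
    keep = trait.observed
    y = trait.values[keep]
    factors = []
    for a, b in pairs:
        fa = _factor(g, a)
        fb = _factor(g, b)
        factors.append((fa, fb))
    K = None
    cell_rows = []
    names = []
    for fa, fb in factors:
        ca = fa[1][keep]
        if fb is None:
            cells = ca.copy()
            k = fa[2]
            names.append((fa[0], None))
        else:
            cb = fb[1][keep]
            cells = np.where((ca >= 0) & (cb >= 0), ca * fb[2] + cb, -1)
            k = fa[2] * fb[2]
            names.append((fa[0], fb[0]))
        if K is None:
            K = k
        elif K != k:
            raise ValueError("all pairs in one scan must share the grid shape")
        cell_rows.append(cells)
    cells = np.asarray(cell_rows, dtype=np.int64)
    return y, cells, K, names, factors, keep


def _adjusted_responses(y, factors, keep, covariates):
    """Per-pair co-dominant residual vectors (continuous traits)."""
    cov = None if covariates is None else np.asarray(covariates, dtype=float)[keep]
    out = []
    for fa, fb in factors:
        res = codominant_adjust(y, fa[1][keep], None if fb is None else fb[1][keep],
                                covariates=cov)
        out.append(res)
    return out


def _finalize(T_obs, det, raw_count, adj_count, n_perm_used, dropped, names, plan,
              kind, alpha1, min_cell, evals, add_one):
    results = []
    for i, (na, nb) in enumerate(names):
        B_i = int(n_perm_used[i])
        if add_one:
            p_raw = (1 + raw_count[i]) / (B_i + 1)
            p_adj = (1 + adj_count[i]) / (B_i + 1)
        else:  # exhaustive: counts include the identity row
            p_raw = raw_count[i] / B_i
            p_adj = adj_count[i] / B_i
        results.append(ScanResult(na, nb, float(det["T_H"][i]), float(det["T_L"][i]),
                                  float(T_obs[i]), float(p_raw), float(p_adj),
                                  B_i, bool(dropped[i])))
    return ScanResults(results, plan, kind, alpha1, min_cell, n_pair_perm_evals=int(evals))


def _run_scan(g, trait, pairs, plan, alpha1, min_cell, adjust, covariates, speed):
    plan.validate()
    if adjust and trait.kind != "continuous":
        raise ValueError("co-dominant adjustment is only supported for continuous traits")
    y, cells, K, names, factors, keep = _prepare(g, trait, pairs)
    n = y.size
    P = cells.shape[0]
    perms = _permutation_matrix(plan, n)
    n_rows = perms.shape[0]
    add_one = not plan.exhaustive
    B = n_rows - 1 if add_one else n_rows

    responses = None
    if adjust:
        responses = _adjusted_responses(y, factors, keep, covariates)
        kind = "continuous"
    else:
        kind = trait.kind
    if kind == "categorical":
        raise ValueError("scan traits must be binary or continuous")

    # observed statistics and details
    if adjust:
        T_obs = np.zeros(P)
        det = {"T_H": np.zeros(P), "T_L": np.zeros(P)}
        for i in range(P):
            Tm, d = _kernel_tmax(cells[i:i + 1], K, responses[i][None, :], kind,
                                 alpha1, min_cell, details=True)
            T_obs[i] = Tm[0, 0]
            det["T_H"][i] = d["T_H"][0]
            det["T_L"][i] = d["T_L"][0]
    else:
        _, det = _kernel_tmax(cells, K, y[None, :], kind, alpha1, min_cell, details=True)
        T_obs = np.maximum(np.abs(det["T_H"]), np.abs(det["T_L"]))

    raw_count = np.zeros(P)
    adj_count = np.zeros(P)
    n_perm_used = np.full(P, B)
    dropped = np.zeros(P, dtype=bool)
    evals = 0

    start = 0 if plan.exhaustive else 1  # sampled mode: row 0 is the observed trait
    perm_rows = perms[start:]
    total = perm_rows.shape[0]
    active = np.arange(P)
    block = plan.check_interval if speed else total
    done = 0
    chunk_rows = max(1, int(4_000_000 // max(P * K, 1)))

    def eval_rows(pair_idx, sub_rows):
        """T statistics for the given pairs on the given permutation rows."""
        if adjust:
            T = np.empty((sub_rows.shape[0], len(pair_idx)))
            for ii, i in enumerate(pair_idx):
                Yp = responses[i][sub_rows]
                Tm, _ = _kernel_tmax(cells[i:i + 1], K, Yp, kind, alpha1, min_cell)
                T[:, ii] = Tm[:, 0]
            return T
        Yp = y[sub_rows]
        T, _ = _kernel_tmax(cells[pair_idx], K, Yp, kind, alpha1, min_cell)
        return T

    # significance threshold on exceedance counts at the guard level: a pair
    # with count > thr can never reach p_adjusted <= alpha_guard
    thr = int(np.floor(plan.alpha_guard * (total + 1))) - 1
    # per post-drop row: global index, max over then-evaluated pairs, era
    tail_rows: list[tuple[int, float, int]] = []
    drop_era = np.zeros(P, dtype=int)  # 0 = never dropped
    era = 0

    while done < total and active.size:
        this_block = min(block, total - done)
        rows = perm_rows[done:done + this_block]
        block_max = np.full(this_block, -np.inf)
        raw_inc = np.zeros(active.size)
        for s in range(0, this_block, chunk_rows):
            sub_rows = rows[s:s + chunk_rows]
            T = eval_rows(active, sub_rows)
            block_max[s:s + sub_rows.shape[0]] = T.max(axis=1)
            raw_inc += (T >= T_obs[active][None, :]).sum(axis=0)
        raw_count[active] += raw_inc
        adj_count[active] += (block_max[:, None] >= T_obs[active][None, :]).sum(axis=0)
        evals += active.size * this_block
        if era > 0:
            tail_rows.extend((done + r, block_max[r], era) for r in range(this_block))
        done += this_block

        if speed and done < total:
            perms_so_far = done
            p_hat = (1 + adj_count[active]) / (perms_so_far + 1)
            bound = _wilson_upper(plan.drop_bound_factor, perms_so_far, plan.ci_level)
            # futility guard: only retire pairs whose exceedance count so far
            # already rules out significance at alpha_guard over the full
            # budget, so a retired pair is non-significant under plain maxT too
            futile = adj_count[active] > thr
            drop = (p_hat > bound) & futile
            if drop.any():
                era += 1
                idx = active[drop]
                dropped[idx] = True
                drop_era[idx] = era
                n_perm_used[idx] = perms_so_far
                active = active[~drop]

    # Lazy resolution: for rows after the first drop, adj_count of surviving
    # pairs misses exceedances that only a dropped pair would have supplied.
    # A survivor whose significance call could depend on those rows gets them
    # evaluated now (dropped pairs only, early exit), making every
    # significance call at alpha_guard identical to plain maxT's.
    if speed and era > 0 and active.size:
        undecided = [i for i in active
                     if adj_count[i] <= thr <
                     adj_count[i] + sum(m < T_obs[i] for _, m, _ in tail_rows)]
        for r, m, row_era in tail_rows if undecided else []:
            relevant = [i for i in undecided if T_obs[i] > m]
            if not relevant:
                continue
            cap = max(T_obs[i] for i in relevant)
            unevaluated = np.flatnonzero((drop_era > 0) & (drop_era <= row_era))
            running = m
            for s in range(0, unevaluated.size, 16):
                batch = unevaluated[s:s + 16]
                Tj = eval_rows(batch, perm_rows[r:r + 1])
                evals += batch.size
                running = max(running, float(Tj[0].max()))
                if running >= cap:
                    break
            for i in relevant:
                if running >= T_obs[i]:
                    adj_count[i] += 1

    return _finalize(T_obs, det, raw_count, adj_count, n_perm_used, dropped, names,
                     plan, kind, alpha1, min_cell, evals, add_one)


# ------------------------------------------------------------------- public

def all_pairs(n_snps: int) -> list:
    return [(i, j) for i, j in itertools.combinations(range(n_snps), 2)]


def maxt_scan(g: GenotypeMatrix, trait: Trait, pairs, plan: PermutationPlan,
              alpha1: float = DEFAULT_ALPHA1, min_cell_count: int = DEFAULT_MIN_CELL,
              adjust: bool = False, covariates=None) -> ScanResults:
    """Steps 1-3 over the given factor pairs with plain maxT correction.

    One shared trait permutation per replicate across all pairs; the
    adjusted p of a pair is the add-one fraction of per-permutation
    maxima (over pairs) reaching its observed T_max (single-step maxT).
    """
    if plan.mode != "maxt":
        raise ValueError("plan.mode must be 'maxt'")
    return _run_scan(g, trait, pairs, plan, alpha1, min_cell_count, adjust,
                     covariates, speed=False)


def speedmaxt_scan(g: GenotypeMatrix, trait: Trait, pairs, plan: PermutationPlan,
                   alpha1: float = DEFAULT_ALPHA1, min_cell_count: int = DEFAULT_MIN_CELL,
                   adjust: bool = False, covariates=None) -> ScanResults:
    """maxT with early dropping of clearly null pairs.

    Every ``check_interval`` permutations, a still-active pair whose
    adjusted-p estimate exceeds the Wilson upper confidence bound
    around ``drop_bound_factor``/(permutations so far) stops being
    recomputed; it keeps its current estimate, flagged dropped_early.
    Pairs surviving all permutations report like maxt_scan up to the
    removal of dropped pairs from the permutation-max pool.
    """
    if plan.mode != "speedmaxt":
        raise ValueError("plan.mode must be 'speedmaxt'")
    return _run_scan(g, trait, pairs, plan, alpha1, min_cell_count, adjust,
                     covariates, speed=True)


def _scan_dispatch(g, trait, pairs, plan, **kw):
    if plan.mode == "speedmaxt":
        return speedmaxt_scan(g, trait, pairs, plan, **kw)
    return maxt_scan(g, trait, pairs, plan, **kw)


def scan_main_effects(g: GenotypeMatrix, trait: Trait, plan: PermutationPlan,
                      snps=None, **kw) -> ScanResults:
    """Single-SNP scan: Steps 1-3 on 3-cell one-dimensional grids."""
    idx = range(g.n_snps) if snps is None else snps
    pairs = [(j, None) for j in idx]
    return _scan_dispatch(g, trait, pairs, plan, **kw)


def scan_pairs(g: GenotypeMatrix, trait: Trait, plan: PermutationPlan,
               pairs=None, **kw) -> ScanResults:
    """SNP x SNP interaction scan over the given (or all) pairs."""
    if pairs is None:
        pairs = all_pairs(g.n_snps)
    return _scan_dispatch(g, trait, pairs, plan, **kw)


def scan_gxe(g: GenotypeMatrix, trait: Trait, env: Trait, plan: PermutationPlan,
             adjust: bool = False, snps=None, covariates=None, **kw) -> ScanResults:
    """SNP x environment scan on 3 x L grids.

    ``env`` is a discrete Trait with 2-10 levels (one level degenerates
    to a main-effect scan of the SNP).  With ``adjust`` the co-dominant
    adjustment removes each pair's lower-order effects first
    (continuous traits).
    """
    n_levels = env.n_levels
    if n_levels > 10:
        raise ValueError("environmental factor must have at most 10 levels")
    idx = range(g.n_snps) if snps is None else snps
    pairs = [(j, env) for j in idx]
    return _scan_dispatch(g, trait, pairs, plan, adjust=adjust,
                          covariates=covariates, **kw)


def compare_scans(main: ScanResults, interaction: ScanResults,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Interaction hits whose member factors are also main-effect hits.

    Pure reporting: one row per significant interaction pair, flagging
    each member's presence among the significant main effects, to show
    whether main effects could be driving interaction results.
    """
    main_hits = {r.factor_a for r in main.significant(alpha)}
    rows = []
    for r in interaction.significant(alpha):
        rows.append((r.factor_a, r.factor_b, r.p_adjusted,
                     r.factor_a in main_hits,
                     r.factor_b in main_hits if r.factor_b is not None else False,
                     (r.factor_a in main_hits) or (r.factor_b in main_hits)))
    return pd.DataFrame(rows, columns=["factor_a", "factor_b", "p_adjusted",
                                       "a_is_main_hit", "b_is_main_hit",
                                       "driven_by_main"])
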