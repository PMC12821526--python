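"""Nonparametric statistics for ordered age groups.

The battery mirrors a standard workflow for K ordered groups of per-nucleus
measurements that deviate from normality:

* Shapiro-Wilk normality screen (per group);
* categorical group association by an exact r x c contingency test
  (Freeman-Halton generalisation of Fisher's exact test, computed by full
  enumeration over the fixed margins) with pairwise 2x2 follow-ups under
  Bonferroni correction;
* pairwise Mann-Whitney tests with Bonferroni correction;
* the Jonckheere-Terpstra (JT) ordered-trend test, run only when the
  pairwise pattern is trend-consistent (group medians monotone in the
  declared order), with a tie-corrected normal approximation and optional
  exact or permutation p-values;
* Kendall's tau-b between group rank and value, tie-corrected on both
  variables.

All p-values are two-sided.  The Mann-Whitney statistic U counts
first-sample wins (pairs with x > y, plus half the ties), so U + U' =
n1 * n2.  JT sums the "later group greater" pair counts over all ordered
group pairs; a decreasing trend therefore gives JT below its null mean and
a negative z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InputError

__all__ = [
    "TrendResult",
    "fisher_exact_rxc",
    "pairwise_fisher_bonferroni",
    "mann_whitney",
    "jt_statistic",
    "jonckheere_terpstra",
    "kendall_tau",
    "normality_screen",
    "cohort_report",
]


@dataclass(frozen=True)
class TrendResult:
    """Outcome of one statistical test.

    ``z_value`` and ``p_adjusted`` are ``None`` where not applicable.
    ``label`` records what was compared (metric and groups).
    """

    statistic_name: str  # "U", "JT", "W_shapiro", "tau", "p_FH"
    statistic: Optional[float]
    z_value: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    n_per_group: tuple[int, ...]
    sidedness: str = "two"
    label: str = ""

    def __post_init__(self):
        for p in (self.p_raw, self.p_adjusted):
            if p is not None and not 0 <= p <= 1 + 1e-12:
                raise InputError(f"p-value out of range: {p}")
        if self.p_adjusted is not None and self.p_raw is not None:
            if self.p_adjusted < self.p_raw - 1e-12:
                raise InputError("adjusted p cannot be below raw p")


# ---------------------------------------------------------------------------
# Exact contingency tests


def _table_log_prob(table: np.ndarray, lgam: np.ndarray) -> float:
    # log multivariate hypergeometric probability given both margins
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        lgam[rows].sum() + lgam[cols].sum() - lgam[n]
        - lgam[table.ravel()].sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    k = len(row_sums)
    if k == 1:
        yield [list(col_sums)]
        return
    ranges = [range(min(row_sums[0], c) + 1) for c in col_sums]

    def rec(j, left, row):
        if j == len(col_sums):
            if left == 0:
                rest_cols = [c - r for c, r in zip(col_sums, row)]
                for sub in _enumerate_tables(row_sums[1:], rest_cols):
                    yield [list(row)] + sub
            return
        for v in ranges[j]:
            if v > left or v > col_sums[j]:
                break
            row.append(v)
            yield from rec(j + 1, left - v, row)
            row.pop()

    yield from rec(0, row_sums[0], [])


def fisher_exact_rxc(table) -> TrendResult:
    """Two-sided exact test of association in an r x c table.

    The p-value is the total null probability of all tables with the
    observed margins whose hypergeometric probability does not exceed that
    of the observed table (with a 1e-12 relative tolerance on the
    comparison), computed by exhaustive enumeration.  For 2x2 tables this
    coincides with the classical two-sided Fisher exact test.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("need a table with at least 2 rows and 2 columns")
    if (table < 0).any():
        raise InputError("counts must be nonnegative")
    row_sums = table.sum(axis=1)
    if (row_sums == 0).any():
        raise InputError("every group (row) must contain observations")
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    lgam = np.array([math.lgamma(i + 1) for i in range(n + 1)])

    obs_lp = _table_log_prob(table, lgam)
    p = 0.0
    for t in _enumerate_tables(list(row_sums), list(col_sums)):
        lp = _table_log_prob(np.asarray(t, dtype=np.int64), lgam)
        if lp <= obs_lp + 1e-12:
            p += math.exp(lp)
    p = min(1.0, p)
    return TrendResult(
        statistic_name="p_FH",
        statistic=p,
        z_value=None,
        p_raw=p,
        p_adjusted=None,
        n_per_group=tuple(int(r) for r in row_sums),
        label=f"exact {table.shape[0]}x{table.shape[1]} association",
    )


def pairwise_fisher_bonferroni(table, group_names: Optional[Sequence[str]] = None
                               ) -> list[TrendResult]:
    """Pairwise 2x2 exact tests between the rows of a K x 2 table, each
    two-sided p multiplied by K(K-1)/2 and capped at 1."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] < 3:
        raise InputError("pairwise follow-up needs at least 3 groups")
    k = table.shape[0]
    if group_names is None:
        group_names = [f"g{i + 1}" for i in range(k)]
    m = k * (k - 1) // 2
    results = []
    for i, j in combinations(range(k), 2):
        sub = table[[i, j]]
        res = fisher_exact_rxc(sub)
        results.append(
            TrendResult(
                statistic_name="p_FH",
                statistic=res.p_raw,
                z_value=None,
                p_raw=res.p_raw,
                p_adjusted=min(1.0, m * res.p_raw),
                n_per_group=(int(table[i].sum()), int(table[j].sum())),
                label=f"{group_names[i]}_vs_{group_names[j]}",
            )
        )
    return results


# ---------------------------------------------------------------------------
# Mann-Whitney


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_u_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact permutation p via the shift algorithm on doubled midranks.

    Counts, for every subset of size n1 of the pooled sample, the rank-sum
    value; ties are handled exactly because midranks are permutation
    functions of the pooled multiset.  Feasible whenever n1*n2 is modest.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.asarray(np.rint(2 * sps.rankdata(pooled)), dtype=np.int64)
    total = int(ranks2.sum())
    # dp[k, s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    counts = dp[n1]
    n_subsets = counts.sum()
    # doubled U = doubled rank sum - n1(n1+1)
    s_vals = np.arange(total + 1)
    u2_vals = s_vals - n1 * (n1 + 1)
    center = n1 * n2  # doubled U under H0 symmetry centre n1 n2 / 2
    dev = abs(2 * u_obs - center) - 1e-9
    return float(counts[np.abs(u2_vals - center) >= dev].sum() / n_subsets)


def mann_whitney(x, y, adjust_m: int = 1, exact_limit: int = 400) -> TrendResult:
    """Two-sided Mann-Whitney test; U counts first-sample wins.

    Uses exact enumeration of the permutation distribution when
    ``n1 * n2 <= exact_limit``, otherwise a tie-corrected normal
    approximation (no continuity correction).  ``adjust_m`` applies a
    Bonferroni factor to the reported adjusted p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)

    if var <= 0:  # all observations identical
        z, p = 0.0, 1.0
    elif n1 * n2 <= exact_limit:
        z = (u - mu) / math.sqrt(var)
        p = _exact_u_pvalue(x, y, u)
    else:
        z = (u - mu) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    p = min(1.0, p)
    return TrendResult(
        statistic_name="U",
        statistic=u,
        z_value=z,
        p_raw=p,
        p_adjusted=min(1.0, adjust_m * p),
        n_per_group=(n1, n2),
    )


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra


def jt_statistic(groups: Sequence) -> float:
    """JT = sum over ordered group pairs i < j of #(b > a) + #(b == a)/2
    for a in group i, b in group j."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    s = 0.0
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a = arrays[i][:, None]
            b = arrays[j][None, :]
            s += float((b > a).sum()) + 0.5 * float((b == a).sum())
    return s


def _jt_moments(pooled: np.ndarray, ns: np.ndarray) -> tuple[float, float]:
    """Tie-corrected null mean and variance of JT."""
    n = int(ns.sum())
    _, cnt = np.unique(pooled, return_counts=True)
    t = cnt.astype(float)
    nsf = ns.astype(float)
    mu = (n ** 2 - (nsf ** 2).sum()) / 4.0
    var = (
        (n * (n - 1) * (2 * n + 5)
         - (nsf * (nsf - 1) * (2 * nsf + 5)).sum()
         - (t * (t - 1) * (2 * t + 5)).sum()) / 72.0
        + ((nsf * (nsf - 1) * (nsf - 2)).sum() * (t * (t - 1) * (t - 2)).sum())
        / (36.0 * n * (n - 1) * (n - 2))
        + ((nsf * (nsf - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
    )
    return mu, var


def _jt_exact_pvalue(pooled: np.ndarray, ns: Sequence[int], jt_obs: float,
                     mu: float, limit: int = 300_000) -> float:
    """Exact two-sided p by enumeration of all distinct group assignments."""
    n = len(pooled)
    n_arr = math.factorial(n)
    for k in ns:
        n_arr //= math.factorial(k)
    if n_arr > limit:
        raise InputError(
            f"{n_arr} arrangements exceed the exact-enumeration limit {limit}"
        )
    dev = abs(jt_obs - mu) - 1e-9
    hits = 0
    total = 0

    idx_all = tuple(range(n))

    def rec(remaining: tuple, gi: int, chosen: list):
        nonlocal hits, total
        if gi == len(ns) - 1:
            groups = chosen + [np.asarray(remaining)]
            stat = jt_statistic([pooled[np.asarray(g, dtype=int)] for g in groups])
            total += 1
            if abs(stat - mu) >= dev:
                hits += 1
            return
        for comb in combinations(remaining, ns[gi]):
            rest = tuple(i for i in remaining if i not in comb)
            rec(rest, gi + 1, chosen + [np.asarray(comb)])

    rec(idx_all, 0, [])
    return hits / total


def jonckheere_terpstra(
    groups: Sequence,
    mode: str = "normal_approx",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TrendResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    ``mode`` selects the p-value computation: ``"normal_approx"`` uses the
    tie-corrected normal null; ``"permutation"`` shuffles values across
    groups (preserving sizes) ``n_perm`` times with the given seed;
    ``"exact"`` enumerates every distinct assignment (small samples only).
    All are two-sided around the exact null mean.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise InputError("the JT test needs at least 3 ordered groups")
    if any(a.size == 0 for a in arrays):
        raise InputError("every group must be nonempty")
    if mode not in ("normal_approx", "permutation", "exact"):
        raise InputError(f"unknown mode {mode!r}")

    ns = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    jt = jt_statistic(arrays)
    mu, var = _jt_moments(pooled, ns)
    z = 0.0 if var <= 0 else (jt - mu) / math.sqrt(var)

    if var <= 0:
        p = 1.0
    elif mode == "normal_approx":
        p = 2.0 * sps.norm.sf(abs(z))
    elif mode == "exact":
        p = _jt_exact_pvalue(pooled, [int(k) for k in ns], jt, mu)
    else:
        rng = np.random.default_rng(seed)
        dev = abs(jt - mu) - 1e-9
        hits = 0
        work = pooled.copy()
        splits = np.cumsum(ns)[:-1]
        for _ in range(n_perm):
            rng.shuffle(work)
            stat = jt_statistic(np.split(work, splits))
            if abs(stat - mu) >= dev:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    p = min(1.0, p)
    return TrendResult(
        statistic_name="JT",
        statistic=jt,
        z_value=z,
        p_raw=p,
        p_adjusted=None,
        n_per_group=tuple(int(k) for k in ns),
    )


# ---------------------------------------------------------------------------
# Kendall's tau-b


def kendall_tau(group_ranks, values) -> TrendResult:
    """Kendall's tau-b between an ordinal group rank and a value, with tie
    corrections on both variables and a tie-corrected normal two-sided p.

    Returns an absent statistic (with a warning label) when either variable
    is constant, where tau is undefined.
    """
    gr = np.asarray(group_ranks, dtype=float)
    vals = np.asarray(values, dtype=float)
    if gr.shape != vals.shape or gr.ndim != 1:
        raise InputError("group_ranks and values must be equal-length 1D")
    if np.unique(gr).size < 2:
        raise InputError("need at least 2 distinct group ranks")
    n = gr.size
    if np.unique(vals).size < 2:
        return TrendResult(
            statistic_name="tau", statistic=None, z_value=None,
            p_raw=None, p_adjusted=None, n_per_group=(n,),
            label="tau undefined: constant values",
        )

    dg = np.sign(gr[:, None] - gr[None, :])
    dv = np.sign(vals[:, None] - vals[None, :])
    iu = np.triu_indices(n, k=1)
    conc = int(((dg[iu] * dv[iu]) > 0).sum())
    disc = int(((dg[iu] * dv[iu]) < 0).sum())
    s = conc - disc

    n0 = n * (n - 1) / 2.0
    _, tg = np.unique(gr, return_counts=True)
    _, tv = np.unique(vals, return_counts=True)
    n1 = (tg * (tg - 1) / 2.0).sum()
    n2 = (tv * (tv - 1) / 2.0).sum()
    tau = s / math.sqrt((n0 - n1) * (n0 - n2))

    v0 = n * (n - 1) * (2 * n + 5)
    vt = (tg * (tg - 1) * (2 * tg + 5)).sum()
    vu = (tv * (tv - 1) * (2 * tv + 5)).sum()
    v1 = (tg * (tg - 1)).sum() * (tv * (tv - 1)).sum() / (2.0 * n * (n - 1))
    v2 = ((tg * (tg - 1) * (tg - 2)).sum() * (tv * (tv - 1) * (tv - 2)).sum()
          / (9.0 * n * (n - 1) * (n - 2)))
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        z, p = 0.0, 1.0
    else:
        z = s / math.sqrt(var_s)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TrendResult(
        statistic_name="tau", statistic=tau, z_value=z,
        p_raw=p, p_adjusted=None, n_per_group=(n,),
    )


# ---------------------------------------------------------------------------
# Normality


def normality_screen(sample) -> TrendResult:
    """Shapiro-Wilk test of normality (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InputError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        return TrendResult(
            statistic_name="W_shapiro", statistic=None, z_value=None,
            p_raw=None, p_adjusted=None, n_per_group=(x.size,),
            label="W undefined: constant sample",
        )
    w, p = sps.shapiro(x)
    return TrendResult(
        statistic_name="W_shapiro", statistic=float(w), z_value=None,
        p_raw=float(p), p_adjusted=None, n_per_group=(x.size,),
    )


# ---------------------------------------------------------------------------
# Full battery


def _medians_monotone(medians: Sequence[float]) -> bool:
    diffs = np.diff(medians)
    return bool((diffs <= 0).all() or (diffs >= 0).all())


def cohort_report(
    table: pd.DataFrame,
    group_order: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    value_columns: Sequence[str] = ("n_bodies", "mean_diameter_um", "mean_max_intensity"),
    always_run_jt: bool = False,
) -> dict:
    """Descriptive summaries plus the full test battery for a cohort table.

    Only non-excluded rows are analysed.  Per metric and group the report
    gives n, median, IQR and maximum; between-group testing runs
    Shapiro-Wilk, pairwise Mann-Whitney with Bonferroni, JT (gated on a
    monotone pattern of group medians unless ``always_run_jt``) and
    Kendall's tau-b.  The cytoplasmic flag is tested with the exact r x c
    association test and pairwise follow-ups.
    """
    if len(table) == 0:
        raise InputError("empty cohort table")
    data = table.loc[~table["excluded"]].copy() if "excluded" in table else table.copy()
    if len(data) == 0:
        raise InputError("no analysis rows after exclusions")

    if group_order is None:
        group_order = list(pd.unique(data["group"]))
    groups_present = [g for g in group_order if (data["group"] == g).any()]
    report: dict = {
        "group_order": list(groups_present),
        "n_per_group": {g: int((data["group"] == g).sum()) for g in groups_present},
        "summaries": {},
        "tests": {},
        "warnings": [],
    }

    for col in value_columns:
        if col not in data.columns:
            continue
        per_group = {}
        for g in groups_present:
            v = data.loc[data["group"] == g, col].dropna().to_numpy(dtype=float)
            per_group[g] = {
                "n": int(v.size),
                "median": float(np.median(v)) if v.size else None,
                "iqr": float(np.subtract(*np.percentile(v, [75, 25]))) if v.size else None,
                "max": float(v.max()) if v.size else None,
            }
        report["summaries"][col] = per_group

    if "cytoplasmic_flag" in data.columns:
        flags = data.dropna(subset=["cytoplasmic_flag"])
        report["cytoplasmic_counts"] = {
            g: {
                "positive": int(((flags["group"] == g) & flags["cytoplasmic_flag"].astype(bool)).sum()),
                "negative": int(((flags["group"] == g) & ~flags["cytoplasmic_flag"].astype(bool)).sum()),
            }
            for g in groups_present
        }

    if len(groups_present) < 2:
        report["warnings"].append("fewer than 2 nonempty groups; no between-group tests run")
        return report

    rank_of = {g: i for i, g in enumerate(groups_present)}
    for col in value_columns:
        if col not in data.columns:
            continue
        sub = data.dropna(subset=[col])
        samples = [sub.loc[sub["group"] == g, col].to_numpy(dtype=float)
                   for g in groups_present]
        if any(s.size == 0 for s in samples):
            report["warnings"].append(f"{col}: some groups empty after dropping missing values")
            continue
        tests: dict = {"shapiro": {}, "pairwise_mw": [], "jt": None, "kendall": None}
        for g, s in zip(groups_present, samples):
            if 3 <= s.size <= 5000:
                res = normality_screen(s)
                tests["shapiro"][g] = res
        m = len(groups_present) * (len(groups_present) - 1) // 2
        for (i, gi), (j, gj) in combinations(enumerate(groups_present), 2):
            res = mann_whitney(samples[i], samples[j], adjust_m=m)
            tests["pairwise_mw"].append(
                TrendResult(
                    statistic_name="U", statistic=res.statistic, z_value=res.z_value,
                    p_raw=res.p_raw, p_adjusted=res.p_adjusted,
                    n_per_group=res.n_per_group, label=f"{col} {gi}_vs_{gj}",
                )
            )
        if len(groups_present) >= 3:
            medians = [float(np.median(s)) for s in samples]
            if always_run_jt or _medians_monotone(medians):
                tests["jt"] = jonckheere_terpstra(samples)
            else:
                report["warnings"].append(
                    f"{col}: group medians not monotone in declared order; JT skipped"
                )
        ranks = sub["group"].map(rank_of).to_numpy(dtype=float)
        vals = sub[col].to_numpy(dtype=float)
        try:
            tests["kendall"] = kendall_tau(ranks, vals)
        except InputError as exc:
            report["warnings"].append(f"{col}: {exc}")
        report["tests"][col] = tests

    if "cytoplasmic_counts" in report:
        counts = report["cytoplasmic_counts"]
        ctab = np.array([[counts[g]["positive"], counts[g]["negative"]]
                         for g in groups_present])
        if (ctab.sum(axis=1) > 0).all():
            fh = fisher_exact_rxc(ctab)
            cat: dict = {"fisher_rxc": fh}
            if len(groups_present) >= 3:
                cat["pairwise"] = pairwise_fisher_bonferroni(ctab, groups_present)
            report["tests"]["cytoplasmic_flag"] = cat
    report["alpha"] = alpha
    return report
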