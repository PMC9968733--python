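"""Population statistics for morphometry and ddPCR tables.

The battery mirrors common practice in cell-biology statistics software:

* two-group comparisons gated on normality (Lilliefors-corrected
  Kolmogorov–Smirnov; a plain KS test with estimated mean/SD would be
  anti-conservative): Student's t-test when both groups pass, otherwise the
  Mann–Whitney rank-sum test with tie-corrected normal approximation;
* Kruskal–Wallis ANOVA on ranks with Dunn's mean-rank post-hoc z tests,
  which accommodate unequal group sizes;
* per-donor fold changes for paired expression data (each control set to 1;
  genes whose controls are essentially unexpressed are reported in raw
  copies/µL instead of as ratios);
* percent-change comparison matrices across named conditions;
* correlograms with method dispatch — Spearman when either variable is
  categorical/ordinal (treatment class coded 0/1, donor, grade), Pearson
  when both are numerical.

No multiple-testing correction is applied by default (single-comparison
α = 0.05 convention); Holm adjustment is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult", "DunnResult", "FoldChangeResult",
    "PercentChangeResult", "CorrelogramResult",
    "compare_two_groups", "multi_group_ranks", "dunn_all_pairs",
    "fold_change", "percent_change_matrix", "correlogram",
    "broadcast_condition_to_cells",
]

#: Variables treated as categorical/ordinal in correlograms by default.
DEFAULT_CATEGORICAL = ("condition", "donor_id", "grade")


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_means: tuple[float, ...]
    group_medians: tuple[float, ...]
    alpha: float
    significant: bool
    normality: tuple[bool, ...] = ()

    def as_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic,
            "p_value": self.p_value, "alpha": self.alpha,
            "significant": self.significant,
            "group_means": list(self.group_means),
            "group_medians": list(self.group_medians),
            "normality": list(self.normality),
        }


@dataclass(frozen=True)
class DunnResult:
    group_a: int
    group_b: int
    z: float
    p_value: float
    significant: bool


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Normality gate.  Groups too small for the Lilliefors table (n < 4)
    or with zero variance are routed to the rank test."""
    if len(x) < 4 or np.ptp(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return bool(p >= alpha)


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney U with tie-corrected normal approximation and
    continuity correction.  Degenerate (zero-variance) pooled samples
    return p = 1."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    x, y, alpha: float = 0.05
) -> TestResult:
    """Normality-gated two-group comparison.

    Student's t-test (pooled variance) when both groups pass the Lilliefors
    normality gate at ``alpha``; otherwise the Mann–Whitney rank-sum test.
    A zero-variance group under the t-test path falls back to the rank test
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    normal = (_is_normal(x, alpha), _is_normal(y, alpha))
    means = (float(x.mean()), float(y.mean()))
    medians = (float(np.median(x)), float(np.median(y)))
    if all(normal):
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            warnings.warn("zero-variance groups; falling back to rank test")
            stat, p = _mann_whitney(x, y)
            name = "mann-whitney"
        else:
            stat, p = sps.ttest_ind(x, y, equal_var=True)
            stat, p, name = float(stat), float(p), "t-test"
    else:
        stat, p = _mann_whitney(x, y)
        name = "mann-whitney"
    return TestResult(test=name, statistic=stat, p_value=p,
                      group_means=means, group_medians=medians,
                      alpha=alpha, significant=bool(p < alpha),
                      normality=normal)


def multi_group_ranks(
    groups: list, alpha: float = 0.05
) -> tuple[TestResult, list[DunnResult]]:
    """Kruskal–Wallis omnibus (tie-corrected) plus Dunn's all-pairs post-hoc.

    Pairwise Dunn decisions are only reported as significant when the
    omnibus test is significant, following the gatekeeping convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        omnibus = TestResult(test="kruskal-wallis", statistic=0.0,
                             p_value=1.0,
                             group_means=tuple(float(g.mean()) for g in groups),
                             group_medians=tuple(float(np.median(g))
                                                 for g in groups),
                             alpha=alpha, significant=False)
        pairs = dunn_all_pairs(groups, alpha, gate=False)
        return omnibus, pairs
    h, p = sps.kruskal(*groups)
    omnibus = TestResult(
        test="kruskal-wallis", statistic=float(h), p_value=float(p),
        group_means=tuple(float(g.mean()) for g in groups),
        group_medians=tuple(float(np.median(g)) for g in groups),
        alpha=alpha, significant=bool(p < alpha),
    )
    pairs = dunn_all_pairs(groups, alpha, gate=omnibus.significant)
    return omnibus, pairs


def dunn_all_pairs(groups: list, alpha: float = 0.05, gate: bool = True
                   ) -> list[DunnResult]:
    """Dunn z statistics on mean ranks for all group pairs (tie-corrected)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    # tie correction: sum over tie groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            results.append(DunnResult(
                group_a=i, group_b=j, z=float(z), p_value=float(p),
                significant=bool(gate and p < alpha)))
    return results


# --------------------------------------------------------------------------
# Fold changes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldChangeResult:
    """Per-donor paired fold changes for one gene (controls set to 1),
    or raw copies/µL when the gene is essentially unexpressed in controls."""

    gene: str
    mode: str                       # "fold" or "copies"
    per_donor: pd.DataFrame         # donor_id, control, treated, fold (or NaN)
    mean: float                     # mean fold (or mean treated copies/µL)
    sem: float
    control_mean: float

    @property
    def low_control_flagged(self) -> bool:
        return self.mode == "copies"


def fold_change(
    table: pd.DataFrame, gene: str, near_zero: float = 0.5
) -> FoldChangeResult:
    """Donor-paired fold change of one gene (treated / matched control).

    Each control is set to 1; the group summary is the mean ± SEM of the
    per-donor folds.  When the gene is essentially unexpressed in controls
    (median control below ``near_zero`` copies/µL, or any control exactly
    zero), division is unstable and the result switches to raw copies/µL.
    """
    need = {"donor_id", "condition", gene}
    if not need <= set(table.columns):
        raise ValueError(f"table lacks columns {need - set(table.columns)}")
    ctrl = table[table["condition"] == 0].set_index("donor_id")[gene]
    trt = table[table["condition"] == 1].set_index("donor_id")[gene]
    donors = ctrl.index.intersection(trt.index)
    if len(donors) == 0:
        raise ValueError("no donor-matched control/treated pairs")
    ctrl, trt = ctrl.loc[donors], trt.loc[donors]
    per = pd.DataFrame({"donor_id": donors, "control": ctrl.values,
                        "treated": trt.values})
    if float(ctrl.median()) < near_zero or (ctrl == 0).any():
        per["fold"] = np.nan
        mean = float(trt.mean())
        sem = float(trt.std(ddof=1) / np.sqrt(len(trt)))
        mode = "copies"
    else:
        per["fold"] = per["treated"] / per["control"]
        mean = float(per["fold"].mean())
        sem = float(per["fold"].std(ddof=1) / np.sqrt(len(per)))
        mode = "fold"
    return FoldChangeResult(gene=gene, mode=mode, per_donor=per,
                            mean=mean, sem=sem,
                            control_mean=float(ctrl.mean()))


# --------------------------------------------------------------------------
# Percent-change comparison matrix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentChangeResult:
    """Descriptor × comparison matrices of percent change and significance."""

    percent: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame


def percent_change_matrix(
    conditions: dict[str, pd.DataFrame],
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
    variables: list[str] | None = None,
) -> PercentChangeResult:
    """Percent change of group means between named conditions.

    ``conditions`` maps a condition name to a per-cell (or per-sample) table
    of numeric descriptor columns.  For each ordered pair ``(a, b)`` the
    matrix entry is ``100·(mean_b − mean_a)/mean_a`` with significance from
    the normality-gated two-group comparison.
    """
    if not comparisons:
        raise ValueError("no comparisons requested")
    for name in {c for pair in comparisons for c in pair}:
        if name not in conditions:
            raise ValueError(f"unknown condition {name!r}")
        if len(conditions[name]) == 0:
            raise ValueError(f"condition {name!r} is empty")
    first = conditions[comparisons[0][0]]
    if variables is None:
        variables = [c for c in first.columns
                     if pd.api.types.is_numeric_dtype(first[c])]
    cols = [f"{a} -> {b}" for a, b in comparisons]
    pct = pd.DataFrame(index=variables, columns=cols, dtype=float)
    pvals = pd.DataFrame(index=variables, columns=cols, dtype=float)
    sig = pd.DataFrame(index=variables, columns=cols, dtype=bool)
    for (a, b), col in zip(comparisons, cols):
        for v in variables:
            xa = conditions[a][v].to_numpy(dtype=float)
            xb = conditions[b][v].to_numpy(dtype=float)
            ma = xa.mean()
            if ma == 0:
                raise ValueError(f"mean of {v!r} in condition {a!r} is zero")
            res = compare_two_groups(xa, xb, alpha)
            pct.loc[v, col] = 100.0 * (xb.mean() - ma) / ma
            pvals.loc[v, col] = res.p_value
            sig.loc[v, col] = res.significant
    return PercentChangeResult(percent=pct, p_values=pvals, significant=sig)


# --------------------------------------------------------------------------
# Correlograms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelogramResult:
    """Pairwise correlations with per-pair method dispatch."""

    r: pd.DataFrame
    p_values: pd.DataFrame
    method: pd.DataFrame        # "pearson" / "spearman" per pair
    significant: pd.DataFrame   # non-significant cells are rendered blank
    alpha: float


def correlogram(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
    alpha: float = 0.05,
    holm: bool = False,
) -> CorrelogramResult:
    """Class-coded correlogram of a sample- or cell-level table.

    Spearman rank-order correlation is used whenever one of the two
    variables is categorical/ordinal (treatment condition coded 0/1, donor,
    macroscopic grade); Pearson product-moment otherwise.  Constant
    variables yield missing entries.  p-values are two-sided; Holm
    adjustment is optional and off by default.
    """
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])
                     or c in categorical]
    if len(table) < 4:
        raise ValueError("need at least 4 rows")
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    meth = pd.DataFrame("", index=variables, columns=variables, dtype=object)

    def numeric(col: str) -> np.ndarray:
        vals = table[col]
        if not pd.api.types.is_numeric_dtype(vals):
            # ordinal coding of non-numeric categoricals (e.g. donor ids)
            vals = pd.Categorical(vals).codes
        return np.asarray(vals, dtype=float)

    flat_p, flat_idx = [], []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variables[i], variables[j]
            x, y = numeric(vi), numeric(vj)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij, mname = np.nan, np.nan, "undefined"
            elif vi in categorical or vj in categorical:
                rij, pij = sps.spearmanr(x, y)
                mname = "spearman"
            else:
                rij, pij = sps.pearsonr(x, y)
                mname = "pearson"
            r.loc[vi, vj] = r.loc[vj, vi] = rij
            p.loc[vi, vj] = p.loc[vj, vi] = pij
            meth.loc[vi, vj] = meth.loc[vj, vi] = mname
            if np.isfinite(pij):
                flat_p.append(pij)
                flat_idx.append((vi, vj))
    if holm and flat_p:
        adj = multipletests(flat_p, alpha=alpha, method="holm")[1]
        for (vi, vj), pa in zip(flat_idx, adj):
            p.loc[vi, vj] = p.loc[vj, vi] = pa
    sig = (p < alpha) & r.notna()
    np.fill_diagonal(sig.values, True)
    return CorrelogramResult(r=r, p_values=p, method=meth,
                             significant=sig, alpha=alpha)


def broadcast_condition_to_cells(
    cells: pd.DataFrame, samples: pd.DataFrame,
    columns: tuple[str, ...] = ("condition",),
) -> pd.DataFrame:
    """Attach sample-level class labels to a per-cell table.

    Single-cell correlograms need the treatment class on every cell; the
    sample's class is broadcast to all of its cells.
    """
    meta = samples[["sample_id", *columns]]
    return cells.merge(meta, on="sample_id", how="left")
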