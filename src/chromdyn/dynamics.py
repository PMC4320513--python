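"""Statistics of chromatin-state enrichment and temporal dynamics.

All operations consume the module x state x time-point gene-ratio
tensor. Four families of results:

* temporal-change tests — per module, state and adjacent time-point
  transition, a one-sample t-test asking whether the change in that
  state's gene ratio stands out against the changes of the other states
  in the same module (Bonferroni-corrected within a configurable
  family);
* pairwise enrichment — Wilcoxon rank-sum comparisons of pooled gene
  ratios between modules (is one cohort globally more state-laden than
  another);
* dynamics scores — per module or state, ``-log10`` of the summed raw
  temporal-change P-values (higher = more chromatin remodelling), with
  one-sided Wilcoxon comparisons between groups;
* the expression/complexity regression — Pearson correlation of
  log(FPKM + 1) with the number of distinct states in the gene region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import GeneRatioTensor

__all__ = [
    "temporal_change_test",
    "temporal_change_table",
    "TemporalChangeTable",
    "count_significant_changes",
    "cluster_enrichment_matrix",
    "PairwiseMatrix",
    "dynamics_score",
    "dynamics_comparison_matrix",
    "expression_state_regression",
    "RegressionResult",
    "wilcoxon_rank_sum",
]

EXACT_WILCOXON_MAX_N = 25


# ----------------------------------------------------------------------
# Wilcoxon helper
# ----------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> float:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) P-value.

    Uses the exact null distribution when both groups have at most
    25 observations and there are no ties; otherwise the normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size <= EXACT_WILCOXON_MAX_N and y.size <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    if np.ptp(pooled) == 0:
        return 1.0  # identical constant samples carry no evidence
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def _bonferroni(p: np.ndarray, family_size: int) -> np.ndarray:
    return np.minimum(1.0, np.asarray(p, dtype=float) * family_size)


# ----------------------------------------------------------------------
# Temporal-change tests
# ----------------------------------------------------------------------

def temporal_change_test(
    ratios: GeneRatioTensor,
    module: int,
    state: int,
    transition: tuple[str, str],
    blank_states: set[int] | None = None,
    include_self: bool = True,
) -> float:
    """Raw P-value for a change in one state's gene ratio within a module.

    Let ``delta_s = rho[c, s, t2] - rho[c, s, t1]``. The sample is the
    set of deltas over the module's non-blank states (including state
    ``s`` itself by default) and the null mean is ``delta_s``: the test
    asks whether this state's change is an outlier against the overall
    change in ratios in the module. ``include_self=False`` drops the
    state's own delta from the sample (the alternative reading).

    Degenerate contract: a zero-variance sample yields P = 1 when
    ``delta_s`` equals the common value and P = 0 otherwise.
    """
    blank = blank_states or set()
    t1, t2 = transition
    mi = ratios.modules.index(module)
    i1 = ratios.time_points.index(t1)
    i2 = ratios.time_points.index(t2)
    deltas = ratios.values[mi, :, i2] - ratios.values[mi, :, i1]
    target = deltas[state - 1]
    keep = [
        s - 1
        for s in range(1, ratios.n_states + 1)
        if s not in blank and (include_self or s != state)
    ]
    sample = deltas[keep]
    if sample.size < 3:
        raise ValueError(
            f"need >= 3 non-blank states for the temporal test, have {sample.size}"
        )
    if np.ptp(sample) == 0:
        return 1.0 if np.isclose(sample[0], target) else 0.0
    return float(stats.ttest_1samp(sample, popmean=target).pvalue)


@dataclass
class TemporalChangeTable:
    """Per (module, state, transition) temporal-change test results.

    ``table`` columns: module, state, transition, p_raw, p_adj,
    significant. ``family`` records the Bonferroni family definition
    and ``family_sizes`` the per-family test counts.
    """

    table: pd.DataFrame
    alpha: float
    family: str
    family_sizes: dict[str, int] = field(default_factory=dict)
    blank_states: set[int] = field(default_factory=set)

    def raw_pvalues(self, group_by: str) -> dict[int, np.ndarray]:
        if group_by not in {"module", "state"}:
            raise ValueError("group_by must be 'module' or 'state'")
        return {
            int(g): grp["p_raw"].to_numpy() for g, grp in self.table.groupby(group_by)
        }


def temporal_change_table(
    ratios: GeneRatioTensor,
    alpha: float = 0.05,
    blank_states: set[int] | None = None,
    family: str = "per_module",
    include_self: bool = True,
) -> TemporalChangeTable:
    """All temporal-change tests with Bonferroni correction.

    ``family="per_module"`` corrects each module's state x transition
    tests together; ``family="global"`` corrects all tests at once.
    Blank states are excluded both from the test samples and from the
    tested rows.
    """
    if family not in {"per_module", "global"}:
        raise ValueError("family must be 'per_module' or 'global'")
    blank = blank_states or set()
    tps = ratios.time_points
    transitions = list(zip(tps[:-1], tps[1:]))
    states = [s for s in range(1, ratios.n_states + 1) if s not in blank]
    rows = []
    for module in ratios.modules:
        for state in states:
            for t1, t2 in transitions:
                p = temporal_change_test(
                    ratios, module, state, (t1, t2), blank_states=blank, include_self=include_self
                )
                rows.append((module, state, f"{t1}/{t2}", p))
    df = pd.DataFrame(rows, columns=["module", "state", "transition", "p_raw"])
    sizes: dict[str, int] = {}
    if family == "per_module":
        adj = np.empty(len(df))
        for module, grp in df.groupby("module"):
            sizes[str(module)] = len(grp)
            adj[grp.index] = _bonferroni(grp["p_raw"].to_numpy(), len(grp))
        df["p_adj"] = adj
    else:
        sizes["global"] = len(df)
        df["p_adj"] = _bonferroni(df["p_raw"].to_numpy(), len(df))
    df["significant"] = df["p_adj"] < alpha
    return TemporalChangeTable(df, alpha, family, sizes, blank)


def count_significant_changes(table: TemporalChangeTable, transition: str) -> int:
    """Significant state changes across all modules at one transition."""
    df = table.table
    if transition not in set(df["transition"]):
        raise KeyError(f"unknown transition {transition!r}")
    return int(df.loc[df["transition"] == transition, "significant"].sum())


# ----------------------------------------------------------------------
# Pairwise matrices
# ----------------------------------------------------------------------

@dataclass
class PairwiseMatrix:
    """Pairwise comparison P-values between groups (modules or states).

    ``p_adj`` is Bonferroni-adjusted over the number of unordered pairs.
    For two-sided comparisons ``direction[a, b]`` is +1 when group a's
    mean exceeds b's; for one-sided dynamics comparisons the entry
    (a, b) tests "a more dynamic than b".
    """

    labels: tuple[int, ...]
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    direction: pd.DataFrame
    family_size: int
    alternative: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p_adj < alpha


def cluster_enrichment_matrix(
    ratios: GeneRatioTensor, exclude_states: set[int] | None = None
) -> PairwiseMatrix:
    """Which modules are globally more state-enriched than which others.

    Each module's sample pools its gene ratios over all non-excluded
    states and all time points; module pairs are compared by two-sample
    two-sided Wilcoxon rank-sum with Bonferroni correction over pairs.
    The blank state is excluded by default logic at the call site
    (pass ``exclude_states={blank_id}``).
    """
    excl = exclude_states or set()
    keep = [s - 1 for s in range(1, ratios.n_states + 1) if s not in excl]
    if len(ratios.modules) < 2:
        raise ValueError("need at least 2 modules")
    samples = {
        m: ratios.values[mi][keep, :].ravel() for mi, m in enumerate(ratios.modules)
    }
    return _pairwise(samples, alternative="two-sided")


def _pairwise(samples: dict[int, np.ndarray], alternative: str) -> PairwiseMatrix:
    labels = tuple(samples)
    n = len(labels)
    p_raw = np.ones((n, n))
    direction = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = samples[labels[i]], samples[labels[j]]
        if alternative == "two-sided":
            p = wilcoxon_rank_sum(a, b, "two-sided")
            p_raw[i, j] = p_raw[j, i] = p
            sign = np.sign(a.mean() - b.mean())
            direction[i, j] = sign
            direction[j, i] = -sign
        else:  # one-sided, both orientations
            p_raw[i, j] = wilcoxon_rank_sum(a, b, alternative)
            p_raw[j, i] = wilcoxon_rank_sum(b, a, alternative)
            direction[i, j] = 1.0
            direction[j, i] = 1.0
    family = n * (n - 1) // 2
    p_adj = np.minimum(1.0, p_raw * family)
    np.fill_diagonal(p_raw, 1.0)
    np.fill_diagonal(p_adj, 1.0)
    idx = pd.Index(labels)
    return PairwiseMatrix(
        labels,
        pd.DataFrame(p_raw, index=idx, columns=idx),
        pd.DataFrame(p_adj, index=idx, columns=idx),
        pd.DataFrame(direction, index=idx, columns=idx),
        family,
        alternative,
    )


# ----------------------------------------------------------------------
# Dynamics scores
# ----------------------------------------------------------------------

def dynamics_score(table: TemporalChangeTable, group_by: str = "module") -> pd.Series:
    """Per module (or state), ``-log10`` of the summed raw P-values.

    Raw (unadjusted) P-values are summed; smaller P-values (stronger
    temporal changes) give a higher score. Scores may be negative when
    the P-values sum above 1; no clamping is applied.
    """
    groups = table.raw_pvalues(group_by)
    out = {}
    for g, ps in groups.items():
        total = ps.sum()
        if total <= 0:
            raise ValueError(
                f"{group_by} {g}: P-values sum to 0 (underflow); configure a minimum-P floor"
            )
        out[g] = -np.log10(total)
    return pd.Series(out, name="dynamics_score").sort_index()


def dynamics_comparison_matrix(
    table: TemporalChangeTable, group_by: str = "module"
) -> PairwiseMatrix:
    """One-sided Wilcoxon comparisons of raw P-value sets between groups.

    Entry (a, b) tests the alternative that group a's temporal-change
    P-values are stochastically smaller than group b's, i.e. a shows
    greater chromatin-state dynamics. One-sided testing is used because
    P-value distributions are strongly right-skewed. Bonferroni over
    unordered pairs.
    """
    groups = table.raw_pvalues(group_by)
    for g, ps in groups.items():
        if ps.size < 2:
            raise ValueError(f"{group_by} {g} has fewer than 2 P-values")
    return _pairwise(groups, alternative="less")


# ----------------------------------------------------------------------
# Expression vs chromatin complexity
# ----------------------------------------------------------------------

@dataclass
class RegressionResult:
    r: float
    slope: float
    intercept: float
    pvalue: float
    n: int

    def summary(self) -> str:
        return (
            f"Pearson r = {self.r:.3f} (P = {self.pvalue:.3g}, n = {self.n}); "
            f"states = {self.slope:.3f} x log(FPKM+1) + {self.intercept:.3f}"
        )


def expression_state_regression(
    expr: pd.DataFrame, state_counts: pd.DataFrame
) -> RegressionResult:
    """Pearson regression of chromatin complexity on expression level.

    Pairs every (gene, time point) observation of log(FPKM + 1) with the
    number of distinct chromatin states in the gene's extended region at
    the matching time point and fits a least-squares line.
    """
    common_genes = state_counts.index.intersection(expr.index)
    common_tps = [tp for tp in expr.columns if tp in state_counts.columns]
    if len(common_genes) < 3:
        raise ValueError("need at least 3 genes with both expression and state counts")
    x = np.log1p(expr.loc[common_genes, common_tps].to_numpy(dtype=float)).ravel()
    y = state_counts.loc[common_genes, common_tps].to_numpy(dtype=float).ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in expression or state counts")
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.rvalue), float(fit.slope), float(fit.intercept), float(fit.pvalue), x.size)
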