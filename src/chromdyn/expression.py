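"""Transcriptome-side computations for the differentiation time course.

Operates on a gene x time-point FPKM table (pandas DataFrame, genes as
index, time points as ordered columns, e.g. D-2 < D0 < D3 < D9). Log
transforms use log(FPKM + 1) throughout so zero-FPKM genes stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

__all__ = [
    "filter_expressed",
    "call_differential",
    "DifferentialCalls",
    "cv2_profile",
    "pca_summary",
    "cluster_modules",
    "ModuleAssignment",
]


def filter_expressed(expr: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with FPKM > 0 at at least one time point."""
    return expr.loc[expr.max(axis=1) > 0]


@dataclass
class DifferentialCalls:
    """Up/down gene sets and per-gene fold changes for one transition."""

    transition: tuple[str, str]
    up: set[str]
    down: set[str]
    fold_change: pd.Series  # pseudocount-regularized ratio t2/t1

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")


def _resolve_transition(expr: pd.DataFrame, transition) -> tuple[str, str]:
    if isinstance(transition, str):
        parts = transition.split("/")
        if len(parts) != 2:
            raise KeyError(f"transition label {transition!r} is not 't1/t2'")
        transition = tuple(parts)
    t1, t2 = transition
    for t in (t1, t2):
        if t not in expr.columns:
            raise KeyError(f"unknown time point {t!r}; have {list(expr.columns)}")
    return t1, t2


def call_differential(
    expr: pd.DataFrame,
    transition,
    fc_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> DifferentialCalls:
    """Threshold-based differential-expression calls between two time points.

    A gene is up-regulated when ``(FPKM_t2 + c) / (FPKM_t1 + c) >
    fc_threshold`` and down-regulated when the ratio is below
    ``1 / fc_threshold``. The pseudocount ``c`` regularizes zero-FPKM
    genes. No significance test is applied by default: replicate-based
    testing is a separate concern and can be layered on the returned
    fold changes.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    t1, t2 = _resolve_transition(expr, transition)
    ratio = (expr[t2] + pseudocount) / (expr[t1] + pseudocount)
    up = set(ratio.index[ratio > fc_threshold])
    down = set(ratio.index[ratio < 1.0 / fc_threshold])
    return DifferentialCalls((t1, t2), up, down, ratio)


def cv2_profile(expr: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """CV^2 of FPKM as a function of expression level, per time point.

    Genes are binned by log10 FPKM (zero-FPKM genes are excluded from
    the binning since their log is undefined); within each bin,
    CV^2 = sample variance / squared mean of raw FPKM. Bins with fewer
    than two genes yield NaN.

    Returns a long-form frame with columns
    ``time_point, bin, log_fpkm_center, n_genes, cv2``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rows = []
    for tp in expr.columns:
        vals = expr[tp].to_numpy(dtype=float)
        vals = vals[vals > 0]
        if vals.size == 0:
            continue
        logv = np.log10(vals)
        edges = np.linspace(logv.min(), logv.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(logv, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = vals[which == b]
            center = 0.5 * (edges[b] + edges[b + 1])
            if sel.size < 2:
                rows.append((tp, b, center, sel.size, np.nan))
            else:
                cv2 = sel.var(ddof=1) / sel.mean() ** 2
                rows.append((tp, b, center, sel.size, cv2))
    return pd.DataFrame(rows, columns=["time_point", "bin", "log_fpkm_center", "n_genes", "cv2"])


def pca_summary(expr: pd.DataFrame) -> pd.DataFrame:
    """Coordinates of the time points on the first two principal components.

    PCA is computed on log(FPKM + 1) with time points as observations
    and genes as variables. Component signs are fixed by making the
    largest-magnitude gene loading positive, so output is deterministic.
    Returns a frame indexed by time point with columns PC1, PC2 plus an
    ``explained_variance_ratio`` attribute row stored in ``.attrs``.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes for PCA")
    X = np.log1p(expr.to_numpy(dtype=float)).T  # time points x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("no variance: expression matrix is constant across time points")
    # SVD of the centered matrix = eigendecomposition of the gene-gene covariance
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(2, S.size)
    coords = U[:, :n_comp] * S[:n_comp]
    for j in range(n_comp):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            coords[:, j] *= -1
    out = pd.DataFrame(
        np.column_stack([coords, np.zeros((X.shape[0], 2 - n_comp))]),
        index=expr.columns,
        columns=["PC1", "PC2"],
    )
    var = S**2 / max(X.shape[0] - 1, 1)
    total = var.sum()
    out.attrs["explained_variance_ratio"] = (var[:2] / total if total > 0 else var[:2]).tolist()
    return out


@dataclass
class ModuleAssignment:
    """Gene -> expression-module map with per-module mean profiles."""

    assignments: pd.Series  # gene_id -> module id, dense 1..k
    n_modules: int
    profiles: pd.DataFrame  # module x time point mean log1p(FPKM)
    silhouette_by_k: dict[int, float] | None = None

    def genes_in(self, module: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module])

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def _scale_profiles(expr: pd.DataFrame, scaling: str) -> np.ndarray:
    X = np.log1p(expr.to_numpy(dtype=float))
    if scaling == "raw":
        return expr.to_numpy(dtype=float)
    if scaling == "log":
        return X
    if scaling == "zscore":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        out = np.zeros_like(X)
        np.divide(X - mu, sd, out=out, where=sd > 0)
        return out
    raise ValueError(f"scaling must be 'zscore', 'log' or 'raw', got {scaling!r}")


def cluster_modules(
    expr: pd.DataFrame,
    k: int | None = None,
    linkage: str = "complete",
    metric: str = "euclidean",
    scaling: str = "zscore",
    auto_k: tuple[int, int] | None = None,
    random_state: int | None = None,
) -> ModuleAssignment:
    """Group genes into temporal expression modules by hierarchical clustering.

    Profiles are log(FPKM + 1), optionally z-scored per gene so that the
    shape of the time course (rather than its magnitude) drives the
    grouping; ``scaling="log"`` keeps magnitude information, which is
    needed when modules differ only in level (e.g. stable-low vs
    stable-high cohorts). The dendrogram (scipy ``linkage``) is cut into
    ``k`` flat clusters; alternatively ``auto_k=(lo, hi)`` selects k by
    silhouette maximization over that inclusive range (ties to the
    smallest k).

    Module ids are re-labelled deterministically (decreasing size, then
    smallest member gene id) so the output does not depend on gene
    input order.
    """
    if (k is None) == (auto_k is None):
        raise ValueError("exactly one of k and auto_k must be given")
    n = expr.shape[0]
    X = _scale_profiles(expr, scaling)
    # sort genes so the linkage sees an order-independent input
    order = np.argsort(expr.index.to_numpy())
    inv = np.empty_like(order)
    inv[order] = np.arange(n)
    Z = hierarchy.linkage(X[order], method=linkage, metric=metric)

    silhouettes: dict[int, float] | None = None
    if auto_k is not None:
        lo, hi = auto_k
        hi = min(hi, n - 1)
        if lo < 2 or lo > hi:
            raise ValueError(f"invalid auto_k range ({auto_k}) for {n} genes")
        silhouettes = {}
        D = pdist(X[order], metric=metric)
        from scipy.spatial.distance import squareform

        Dsq = squareform(D)
        for kk in range(lo, hi + 1):
            lab = hierarchy.fcluster(Z, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                silhouettes[kk] = -1.0
                continue
            silhouettes[kk] = float(silhouette_score(Dsq, lab, metric="precomputed"))
        k = min(silhouettes, key=lambda kk: (-silhouettes[kk], kk))
    assert k is not None
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes {n}")
    flat = hierarchy.fcluster(Z, k, criterion="maxclust")[inv]

    # dense, order-independent relabelling
    genes = expr.index.to_numpy()
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, flat):
        clusters.setdefault(int(c), []).append(g)
    ranked = sorted(clusters.values(), key=lambda members: (-len(members), min(members)))
    mapping = {}
    for new_id, members in enumerate(ranked, start=1):
        for g in members:
            mapping[g] = new_id
    assignments = pd.Series({g: mapping[g] for g in genes}, name="module").loc[genes]
    n_modules = len(ranked)

    logX = np.log1p(expr.to_numpy(dtype=float))
    prof = pd.DataFrame(
        [logX[assignments.to_numpy() == m].mean(axis=0) for m in range(1, n_modules + 1)],
        index=pd.RangeIndex(1, n_modules + 1, name="module"),
        columns=expr.columns,
    )
    return ModuleAssignment(assignments, n_modules, prof, silhouettes)
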