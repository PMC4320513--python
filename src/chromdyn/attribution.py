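"""Linking chromatin states to genes and expression modules.

A chromatin state is attributed to a gene when at least one bin carrying
that state overlaps the gene body extended symmetrically by W bases on
both sides (strand is ignored: regulatory regions flank genes on either
side). W itself is data-derived: half of the upper-quartile distance
from state-changing bins to their nearest gene, averaged over adjacent
time-point transitions.

Per expression module c, state s and time point t, the "gene ratio"
rho[c, s, t] is the fraction of the module's genes whose extended region
contains state s — the normalized enrichment unit all downstream
statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import StateSegmentation
from .expression import ModuleAssignment

__all__ = [
    "changed_bins",
    "derive_extension_window",
    "ExtensionWindow",
    "attribute_states",
    "StatePresenceTensor",
    "gene_ratios",
    "GeneRatioTensor",
    "state_count_per_gene",
]


def changed_bins(labels_t1: np.ndarray, labels_t2: np.ndarray) -> np.ndarray:
    """Global indices of bins whose state differs between two time points."""
    a = np.asarray(labels_t1)
    b = np.asarray(labels_t2)
    if a.shape != b.shape:
        raise ValueError(f"segmentations have different bin counts: {a.shape} vs {b.shape}")
    return np.flatnonzero(a != b)


@dataclass
class ExtensionWindow:
    """Derived symmetric gene-extension window.

    ``window`` is rounded to the nearest bin multiple; ``raw_window``
    keeps the unrounded value. ``per_transition_quantile`` maps
    "t1/t2" -> the upper-quantile change-to-gene distance (bases).
    """

    window: int
    raw_window: float
    per_transition_quantile: dict[str, float]
    quantile: float
    fraction: float

    @property
    def mean_quantile_distance(self) -> float:
        return float(np.mean(list(self.per_transition_quantile.values())))


def _nearest_gene_distance(
    chrom: str, positions: np.ndarray, annotation: pd.DataFrame
) -> np.ndarray:
    """Distance from each position to the nearest gene edge on ``chrom``.

    0 inside a gene; positions on chromosomes without genes get NaN.
    """
    genes = annotation[annotation["chrom"] == chrom]
    if genes.empty:
        return np.full(positions.shape, np.nan)
    starts = genes["start"].to_numpy(dtype=float)
    ends = genes["end"].to_numpy(dtype=float)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    # distance to interval [start, end): max(start - x, x - end, 0);
    # scan all genes per chromosome (gene counts are modest).
    d = np.maximum.reduce(
        [
            starts[None, :] - positions[:, None],
            positions[:, None] - ends[None, :],
            np.zeros((positions.size, starts.size)),
        ]
    )
    return d.min(axis=1)


def derive_extension_window(
    segmentation: StateSegmentation,
    annotation: pd.DataFrame,
    quantile: float = 0.75,
    fraction: float = 0.5,
) -> ExtensionWindow:
    """Derive W from the distances of state-changing bins to genes.

    For each adjacent time-point transition, every bin whose state
    changes contributes the distance from its midpoint to the nearest
    gene edge (0 inside a gene). The per-transition ``quantile``
    (default: upper quartile) of these distances is averaged across
    transitions and multiplied by ``fraction`` (default 0.5); the result
    is rounded to the nearest bin multiple.
    """
    tps = segmentation.time_points
    if len(tps) < 2:
        raise ValueError("need at least 2 time points to observe dynamics")
    bins = segmentation.bins
    bw = bins.bin_width
    per_transition: dict[str, float] = {}
    for t1, t2 in zip(tps[:-1], tps[1:]):
        idx = changed_bins(segmentation.labels[t1], segmentation.labels[t2])
        dists: list[np.ndarray] = []
        for chrom in bins.chrom_names:
            sl = bins.chrom_slice(chrom)
            local = idx[(idx >= sl.start) & (idx < sl.stop)] - sl.start
            if local.size == 0:
                continue
            midpoints = local * bw + bw / 2.0
            d = _nearest_gene_distance(chrom, midpoints, annotation)
            dists.append(d[~np.isnan(d)])
        if dists and (sample := np.concatenate(dists)).size > 0:
            per_transition[f"{t1}/{t2}"] = float(np.quantile(sample, quantile))
    if not per_transition:
        raise ValueError(
            "no changed bins between any adjacent time points: "
            "no dynamics to derive a window from; supply W explicitly"
        )
    raw = fraction * float(np.mean(list(per_transition.values())))
    window = int(round(raw / bw)) * bw
    return ExtensionWindow(window, raw, per_transition, quantile, fraction)


@dataclass
class StatePresenceTensor:
    """Boolean gene x state x time-point presence of states in gene +/- W."""

    genes: tuple[str, ...]
    n_states: int
    time_points: tuple[str, ...]
    values: np.ndarray  # (n_genes, n_states, n_time_points) bool
    window: int

    def __post_init__(self) -> None:
        expected = (len(self.genes), self.n_states, len(self.time_points))
        if self.values.shape != expected:
            raise ValueError(f"presence tensor shape {self.values.shape} != {expected}")

    def to_frame(self) -> pd.DataFrame:
        """Long-form (gene, state, time_point, present)."""
        g, s, t = np.meshgrid(
            np.arange(len(self.genes)),
            np.arange(1, self.n_states + 1),
            np.arange(len(self.time_points)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "gene_id": np.asarray(self.genes)[g.ravel()],
                "state": s.ravel(),
                "time_point": np.asarray(self.time_points)[t.ravel()],
                "present": self.values.ravel(),
            }
        )


def attribute_states(
    segmentation: StateSegmentation,
    annotation: pd.DataFrame,
    window: int,
) -> StatePresenceTensor:
    """Mark state s present for gene g at time t iff >= 1 bin with state s
    overlaps ``[start - W, end + W)`` (clipped to the chromosome).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    bins = segmentation.bins
    missing = sorted(set(annotation["chrom"]) - set(bins.chrom_names))
    if missing:
        bad = annotation.loc[annotation["chrom"].isin(missing), "gene_id"].tolist()
        raise ValueError(f"genes on chromosomes absent from segmentation: {bad}")
    genes = tuple(annotation["gene_id"])
    K = segmentation.n_states
    tps = segmentation.time_points
    values = np.zeros((len(genes), K, len(tps)), dtype=bool)
    for gi, row in enumerate(annotation.itertuples(index=False)):
        sl = bins.chrom_slice(row.chrom)
        lo = max(0, row.start - window)
        hi = min(bins.chrom_length(row.chrom), row.end + window)
        first, last = bins.overlapping_bins(row.chrom, lo, hi)
        if first >= last:
            continue
        for ti, tp in enumerate(tps):
            states = segmentation.labels[tp][sl.start + first : sl.start + last]
            present = np.bincount(states, minlength=K + 1)[1:] > 0
            values[gi, :, ti] = present
    return StatePresenceTensor(genes, K, tps, values, window)


@dataclass
class GeneRatioTensor:
    """Module x state x time-point gene ratios rho in [0, 1].

    ``rho[c, s, t] * module_size[c]`` is the integer count of module-c
    genes whose extended region carries state s at time t.
    """

    modules: tuple[int, ...]
    n_states: int
    time_points: tuple[str, ...]
    values: np.ndarray  # (n_modules, n_states, n_time_points) float
    module_sizes: dict[int, int]

    def ratio(self, module: int, state: int, time_point: str) -> float:
        return float(
            self.values[
                self.modules.index(module), state - 1, self.time_points.index(time_point)
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mi, m in enumerate(self.modules):
            for s in range(1, self.n_states + 1):
                for ti, tp in enumerate(self.time_points):
                    rows.append((m, s, tp, self.values[mi, s - 1, ti]))
        return pd.DataFrame(rows, columns=["module", "state", "time_point", "gene_ratio"])


def gene_ratios(
    presence: StatePresenceTensor, modules: ModuleAssignment | pd.Series
) -> GeneRatioTensor:
    """Fraction of each module's genes carrying each state at each time point.

    The denominator is the full module size, so genes lacking a state
    still count toward its normalization.
    """
    assignments = modules.assignments if isinstance(modules, ModuleAssignment) else modules
    missing = [g for g in presence.genes if g not in assignments.index]
    if missing:
        raise ValueError(f"genes without a module assignment: {missing[:10]}")
    labels = assignments.loc[list(presence.genes)].to_numpy()
    module_ids = tuple(sorted(set(int(m) for m in labels)))
    sizes = {}
    values = np.zeros((len(module_ids), presence.n_states, len(presence.time_points)))
    for mi, m in enumerate(module_ids):
        mask = labels == m
        size = int(mask.sum())
        if size == 0:
            raise ValueError(f"module {m} is empty")
        sizes[m] = size
        values[mi] = presence.values[mask].mean(axis=0)
    return GeneRatioTensor(module_ids, presence.n_states, presence.time_points, values, sizes)


def state_count_per_gene(
    presence: StatePresenceTensor, exclude: set[int] | None = None
) -> pd.DataFrame:
    """Number of distinct states in each gene's region per time point.

    ``exclude`` removes states (e.g. the blank state) from the count.
    """
    mask = np.ones(presence.n_states, dtype=bool)
    for s in exclude or ():
        mask[s - 1] = False
    counts = presence.values[:, mask, :].sum(axis=1)
    return pd.DataFrame(counts, index=list(presence.genes), columns=list(presence.time_points))
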