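"""Synthetic genomes, chromatin-mark tracks and expression tables.

The generator plants fully known ground truth emulating the statistical
structure the analysis assumes: K latent chromatin states with
product-Bernoulli mark emissions and sparse (diagonal-dominant)
transitions along the genome; per-bin state resampling between time
points with per-state "flip" probabilities so that one state can be
made hyper-dynamic and another near-frozen; genes whose FPKM
time-courses follow 19 named temporal archetypes; and an optional
coupling that makes chromatin-state complexity track expression level.

All randomness flows through ``numpy.random.default_rng`` (PCG64)
seeded from the config, so a fixed seed gives byte-identical output
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import json

import numpy as np
import pandas as pd
import yaml

from .bins import GenomeBins
from .hmm import BinarizedTracks, ChromatinStateModel, DEFAULT_MARKS
from . import io as gio

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "load_archetypes",
    "generate_genome",
    "generate_state_paths",
    "emit_mark_tracks",
    "generate_expression",
    "planted_model",
    "simulate",
]

DEFAULT_TIME_POINTS = ("D-2", "D0", "D3", "D9")


def load_archetypes() -> dict[str, dict]:
    """The 19 shipped temporal archetype templates (name -> shape, FPKM levels)."""
    text = resources.files("chromdyn.data").joinpath("archetypes.yaml").read_text()
    raw = yaml.safe_load(text)["archetypes"]
    return {
        name: {"shape": spec["shape"], "fpkm": np.asarray(spec["fpkm"], dtype=float)}
        for name, spec in raw.items()
    }


def default_module_spec(genes_per_module: int = 50, fpkm_scale: float = 1.0):
    """One module per shipped archetype with equal gene counts."""
    return [(name, genes_per_module, fpkm_scale) for name in load_archetypes()]


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator.

    ``module_spec`` is a list of (archetype id, gene count, FPKM scale);
    ``dynamics_coupling`` maps 1-based state ids to a per-transition
    flip probability (scalar, applied to every transition, or a
    sequence with one entry per adjacent time-point transition). States
    not listed default to ``default_flip``.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    bin_width: int = 200
    n_states: int = 8
    n_marks: int = 7
    mark_names: tuple[str, ...] = DEFAULT_MARKS
    n_time_points: int = 4
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_genes: int = 950  # 19 archetypes x 50 genes, the default module_spec
    module_spec: list[tuple[str, int, float]] = field(default_factory=default_module_spec)
    dynamics_coupling: dict[int, float | tuple[float, ...]] = field(default_factory=dict)
    default_flip: float = 0.1
    noise_sd: float = 0.1
    seed: int = 0
    expression_state_coupling: bool = False
    gene_length_log_mean: float = float(np.log(2000.0))
    gene_length_log_sd: float = 0.6
    lambda_low: float = 1.0
    lambda_high: float = 8.0
    self_transition: float = 0.95

    def __post_init__(self) -> None:
        if self.chromosome_length % self.bin_width != 0:
            raise ValueError("bin_width must divide chromosome_length")
        if self.n_time_points != len(self.time_points):
            raise ValueError("time_points length must equal n_time_points")
        if len(self.mark_names) != self.n_marks:
            raise ValueError("mark_names length must equal n_marks")
        total = sum(count for _, count, _ in self.module_spec)
        if total != self.n_genes:
            raise ValueError(
                f"module_spec gene counts sum to {total}, expected n_genes={self.n_genes}"
            )
        for state, flip in self.dynamics_coupling.items():
            flips = np.atleast_1d(np.asarray(flip, dtype=float))
            if ((flips < 0) | (flips > 1)).any():
                raise ValueError(f"flip probabilities for state {state} outside [0, 1]")
            if not 1 <= state <= self.n_states:
                raise ValueError(f"dynamics_coupling references unknown state {state}")

    @property
    def bins(self) -> GenomeBins:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))
        return GenomeBins(names, (self.chromosome_length,) * self.n_chromosomes, self.bin_width)

    def flip_matrix(self) -> np.ndarray:
        """(n_states, n_transitions) per-state, per-transition flip probabilities."""
        n_trans = self.n_time_points - 1
        out = np.full((self.n_states, n_trans), self.default_flip, dtype=float)
        for state, flip in self.dynamics_coupling.items():
            flips = np.atleast_1d(np.asarray(flip, dtype=float))
            if flips.size == 1:
                out[state - 1, :] = flips[0]
            elif flips.size == n_trans:
                out[state - 1, :] = flips
            else:
                raise ValueError(
                    f"state {state}: expected 1 or {n_trans} flip probabilities, got {flips.size}"
                )
        return out


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    true_model: ChromatinStateModel
    true_paths: dict[str, np.ndarray]  # time point -> per-bin state 1..K
    true_modules: pd.Series  # gene_id -> archetype id
    planted_dynamic_state: int | None
    planted_stable_state: int | None


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the truth that produced it."""

    config: SyntheticConfig
    bins: GenomeBins
    annotation: pd.DataFrame
    tracks: BinarizedTracks
    expression: pd.DataFrame
    truth: SyntheticTruth
    counts: dict[str, np.ndarray] | None = None

    def write(self, outdir: str | Path) -> None:
        """Write the dataset as plain-text files (BED6/GTF/TSV/JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_gene_annotation_bed(self.annotation, outdir / "genes.bed")
        gio.write_gene_annotation_gtf(self.annotation, outdir / "genes.gtf")
        gio.write_expression(self.expression, outdir / "expression.tsv")
        for tp in self.tracks.time_points:
            df = pd.DataFrame(self.tracks.data[tp], columns=list(self.tracks.mark_names))
            df.index.name = "bin"
            df.to_csv(outdir / f"marks_{tp}.tsv", sep="\t")
        truth = {
            "emission": self.truth.true_model.emission.tolist(),
            "transition": self.truth.true_model.transition.tolist(),
            "initial": self.truth.true_model.initial.tolist(),
            "true_paths": {tp: path.tolist() for tp, path in self.truth.true_paths.items()},
            "true_modules": self.truth.true_modules.to_dict(),
            "planted_dynamic_state": self.truth.planted_dynamic_state,
            "planted_stable_state": self.truth.planted_stable_state,
        }
        (outdir / "truth.json").write_text(json.dumps(truth))


# ----------------------------------------------------------------------
# Genome and genes
# ----------------------------------------------------------------------

def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Place non-overlapping genes with log-normal lengths.

    Genes are spread round-robin across chromosomes. Each start
    position is drawn uniformly from the set of positions that keep the
    gene inside its chromosome and off every previously placed gene
    (tracked as a shrinking list of free gaps), so placement succeeds
    whenever the gene fits anywhere at all. Gene lengths follow
    ``LogNormal(gene_length_log_mean, gene_length_log_sd)`` rounded to
    integer bases (minimum 1 bin).
    """
    rng = rng or np.random.default_rng(config.seed)
    bins = config.bins
    n = config.n_genes
    records: list[tuple[str, str, int, int, str]] = []
    if n == 0:
        return pd.DataFrame(records, columns=gio.ANNOTATION_COLUMNS)
    lengths = np.maximum(
        config.bin_width,
        np.round(rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, size=n)),
    ).astype(int)
    chrom_of = [bins.chrom_names[i % bins.n_chromosomes] for i in range(n)]
    # free gaps per chromosome as parallel start/end arrays
    gaps: dict[str, tuple[np.ndarray, np.ndarray]] = {
        c: (np.array([0], dtype=np.int64), np.array([bins.chrom_length(c)], dtype=np.int64))
        for c in bins.chrom_names
    }
    width = len(str(n))
    for i in range(n):
        chrom, length = chrom_of[i], int(lengths[i])
        gs, ge = gaps[chrom]
        slots = np.maximum(0, (ge - gs) - length + 1)
        total = int(slots.sum())
        if total == 0:
            raise ValueError(
                f"could not place gene {i + 1} of {n} ({length} bp) without overlap: "
                f"no free gap on {chrom} is large enough; reduce n_genes or gene "
                f"lengths, or enlarge chromosomes"
            )
        pick = int(rng.integers(0, total))
        g = int(np.searchsorted(np.cumsum(slots), pick, side="right"))
        start = int(gs[g]) + (pick - (int(np.cumsum(slots)[g - 1]) if g else 0))
        end = start + length
        # split the chosen gap around the new gene
        new_gs = np.concatenate([gs[:g], [gs[g], end], gs[g + 1 :]])
        new_ge = np.concatenate([ge[:g], [start, ge[g]], ge[g + 1 :]])
        keep = new_ge > new_gs
        gaps[chrom] = (new_gs[keep], new_ge[keep])
        strand = "+" if rng.random() < 0.5 else "-"
        records.append((f"g{i + 1:0{width}d}", chrom, start, end, strand))
    df = pd.DataFrame(records, columns=gio.ANNOTATION_COLUMNS)
    return df.sort_values(["chrom", "start", "gene_id"], kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# Chromatin states and marks
# ----------------------------------------------------------------------

def planted_model(config: SyntheticConfig, rng: np.random.Generator | None = None) -> ChromatinStateModel:
    """A well-separated ground-truth model for recovery experiments.

    Each state emits a distinct subset of marks at probability 0.9 and
    the rest at 0.1 (mirrored block patterns); transitions are
    diagonal-dominant with the configured self-transition probability.
    The last state is "blank": every mark at 0.02, mimicking the
    unmarked bulk of the genome.
    """
    K, M = config.n_states, config.n_marks
    emission = np.full((K, M), 0.1)
    for k in range(K - 1):
        # distinct mark subsets: mark k mod M plus its right neighbour
        emission[k, k % M] = 0.9
        emission[k, (k + 1) % M] = 0.9 if (k // M) % 2 == 0 else 0.5
    emission[K - 1, :] = 0.02  # blank-like state
    transition = np.full((K, K), (1.0 - config.self_transition) / (K - 1) if K > 1 else 0.0)
    np.fill_diagonal(transition, config.self_transition if K > 1 else 1.0)
    initial = np.full(K, 1.0 / K)
    return ChromatinStateModel(emission, transition, initial, config.mark_names)


def generate_state_paths(
    config: SyntheticConfig,
    model: ChromatinStateModel,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Sample per-time-point state paths (1..K) for every bin.

    The first time point is a Markov-chain sample per chromosome. Each
    later path is derived from the previous one by independent
    resampling of whole same-state segments: a segment in state s is
    relabelled with that state's flip probability for the transition,
    its destination drawn with probability proportional to the
    destination state's own flip probability (source excluded; uniform
    fallback when every other state is frozen).

    Two properties of this scheme matter downstream. Resampling whole
    segments preserves the segment-length structure of the genome, so
    later time points do not fragment into spurious single-bin states
    (fragmentation would inflate the presence of every state in gene
    regions over time and drown any planted coupling). Flip-weighted
    destinations balance each state's influx against its efflux, so
    every state's genome share is stationary while the *magnitude* of
    its gene-ratio changes scales with its flip probability: a planted
    high-flip state churns strongly and a near-frozen state neither
    loses nor accumulates territory. The expected fraction of changed
    bins per state still equals its configured flip probability.
    """
    rng = rng or np.random.default_rng(config.seed)
    if model.n_states != config.n_states:
        raise ValueError("model state count does not match config")
    if np.abs(model.transition.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("transition rows must sum to 1")
    bins = config.bins
    K = config.n_states
    flips = config.flip_matrix()

    first = np.empty(bins.total_bins, dtype=np.int64)
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transition, axis=1)
    for chrom in bins.chrom_names:
        sl = bins.chrom_slice(chrom)
        T = sl.stop - sl.start
        u = rng.random(T)
        path = np.empty(T, dtype=np.int64)
        path[0] = np.searchsorted(cum_init, u[0])
        for t in range(1, T):
            path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t])
        first[sl] = path + 1

    paths = {config.time_points[0]: first}
    prev = first
    for j in range(1, config.n_time_points):
        new = prev.copy()
        dest_weight = flips[:, j - 1]
        for chrom in bins.chrom_names:
            sl = bins.chrom_slice(chrom)
            arr = prev[sl]
            change_pts = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change_pts])
            ends = np.concatenate([change_pts, [arr.size]])
            seg_states = arr[starts]
            flip = rng.random(starts.size) < flips[seg_states - 1, j - 1]
            if K <= 1 or not flip.any():
                continue
            dest = np.zeros(starts.size, dtype=np.int64)
            for src in np.unique(seg_states[flip]):
                sel = flip & (seg_states == src)
                w = dest_weight.copy()
                w[src - 1] = 0.0
                if w.sum() <= 0:  # every other state frozen: uniform fallback
                    w = np.ones(K)
                    w[src - 1] = 0.0
                dest[sel] = rng.choice(K, size=int(sel.sum()), p=w / w.sum()) + 1
            seg_new = arr.copy()
            for s, e, d in zip(starts[flip], ends[flip], dest[flip]):
                seg_new[s:e] = d
            new[sl] = seg_new
        paths[config.time_points[j]] = new
        prev = new
    return paths


def emit_mark_tracks(
    paths: dict[str, np.ndarray],
    model: ChromatinStateModel,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    counts: bool = False,
) -> BinarizedTracks | tuple[BinarizedTracks, dict[str, np.ndarray]]:
    """Sample binary mark tracks (and optionally Poisson counts) from paths.

    In counts mode each mark additionally gets integer counts:
    Poisson(``lambda_high``) where the binary presence fired and
    Poisson(``lambda_low``) background elsewhere, for exercising the
    binarization step.
    """
    rng = rng or np.random.default_rng(config.seed)
    bins = config.bins
    data: dict[str, np.ndarray] = {}
    count_data: dict[str, np.ndarray] = {}
    for tp in config.time_points:
        states = paths[tp]
        if states.shape != (bins.total_bins,):
            raise ValueError(f"path for {tp} does not match the binning")
        p = model.emission[states - 1]  # (n_bins, M)
        binary = (rng.random(p.shape) < p).astype(np.uint8)
        data[tp] = binary
        if counts:
            lam = np.where(binary == 1, config.lambda_high, config.lambda_low)
            count_data[tp] = rng.poisson(lam)
    tracks = BinarizedTracks(bins, config.time_points, config.mark_names, data)
    return (tracks, count_data) if counts else tracks


# ----------------------------------------------------------------------
# Expression
# ----------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig,
    gene_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """FPKM table plus true archetype labels per gene.

    Each gene's profile is its archetype template (scaled by the
    module's FPKM scale) with multiplicative log-normal noise
    ``exp(N(0, noise_sd^2))`` per cell; template zeros therefore stay
    exactly zero, so "induced at D3" genes have FPKM 0 before D3.
    """
    rng = rng or np.random.default_rng(config.seed)
    templates = load_archetypes()
    if gene_ids is None:
        width = len(str(config.n_genes))
        gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    if len(gene_ids) != config.n_genes:
        raise ValueError("gene_ids length does not match n_genes")
    rows = []
    labels = []
    for archetype, count, scale in config.module_spec:
        if archetype not in templates:
            raise KeyError(
                f"unknown archetype {archetype!r}; known: {sorted(templates)}"
            )
        template = templates[archetype]["fpkm"][: config.n_time_points] * scale
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=(count, config.n_time_points)))
        rows.append(template[None, :] * noise)
        labels.extend([archetype] * count)
    values = np.vstack(rows) if rows else np.zeros((0, config.n_time_points))
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=list(config.time_points))
    modules = pd.Series(labels, index=expr.index, name="archetype")
    return expr, modules


# ----------------------------------------------------------------------
# Full simulation
# ----------------------------------------------------------------------

def _apply_expression_coupling(
    paths: dict[str, np.ndarray],
    annotation: pd.DataFrame,
    expr: pd.DataFrame,
    config: SyntheticConfig,
) -> None:
    """Overwrite gene-body states so state complexity tracks expression.

    For gene g at time t, the number of distinct states written into its
    body scales with log(FPKM + 1) relative to the dataset maximum; the
    body's bins then cycle deterministically through that many states.
    Used only to exercise the expression/complexity regression.
    """
    bins = config.bins
    K = config.n_states
    logx = np.log1p(expr.to_numpy(dtype=float))
    lmax = logx.max() or 1.0
    gene_rows = {g: i for i, g in enumerate(expr.index)}
    for row in annotation.itertuples(index=False):
        gi = gene_rows[row.gene_id]
        sl = bins.chrom_slice(row.chrom)
        first, last = bins.overlapping_bins(row.chrom, row.start, row.end)
        if first >= last:
            continue
        for ti, tp in enumerate(config.time_points):
            n_states = 1 + int(round((K - 1) * logx[gi, ti] / lmax))
            span = np.arange(last - first)
            paths[tp][sl.start + first : sl.start + last] = span % n_states + 1


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    annotation = generate_genome(config, rng)
    model = planted_model(config)
    paths = generate_state_paths(config, model, rng)
    expr, archetype_labels = generate_expression(
        config, gene_ids=list(annotation["gene_id"]) if len(annotation) else None, rng=rng
    )
    if config.expression_state_coupling:
        _apply_expression_coupling(paths, annotation, expr, config)
    tracks = emit_mark_tracks(paths, model, config, rng)

    flips = config.flip_matrix()
    if config.dynamics_coupling:
        mean_flip = flips.mean(axis=1)
        dynamic = int(np.argmax(mean_flip)) + 1
        stable = int(np.argmin(mean_flip)) + 1
    else:
        dynamic = stable = None
    truth = SyntheticTruth(model, paths, archetype_labels, dynamic, stable)
    return SyntheticDataset(config, config.bins, annotation, tracks, expr, truth)
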