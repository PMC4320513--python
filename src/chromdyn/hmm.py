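"""Chromatin-state segmentation with a multivariate Bernoulli HMM.

A hidden chromatin state is assigned to every fixed-width genomic bin
from the combination of binarized chromatin marks it carries. Emissions
are product-Bernoulli (one presence probability per mark per state),
transitions couple adjacent bins along each chromosome, and a single
parameter set is learned jointly from all time points: each
(time point, chromosome) pair contributes an independent observation
sequence, so the chain is reset at sequence boundaries but the states
themselves are shared across the time course.

The public surface follows the statsmodels convention: build a
:class:`ChromatinStateHMM` from binarized tracks, call :meth:`fit`, and
work with the returned :class:`ChromatinStateHMMResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bins import GenomeBins
from .io import write_segmentation_bed

__all__ = [
    "ChromatinStateModel",
    "BinarizedTracks",
    "StateSegmentation",
    "ChromatinStateHMM",
    "ChromatinStateHMMResults",
    "poisson_threshold",
    "binarize",
    "baum_welch_train",
    "decode",
    "state_coverage",
    "segment_length_stats",
    "transition_summary",
    "blank_states",
]

EMISSION_EPS = 1e-6
DEFAULT_MARKS = ("H3K27me3", "H3K27ac", "H3K4me1", "H3K4me2", "H3K4me3", "H3K36me3", "CTCF")


# ----------------------------------------------------------------------
# Containers
# ----------------------------------------------------------------------

@dataclass
class ChromatinStateModel:
    """Parameters of the chromatin-state HMM.

    Attributes
    ----------
    emission
        ``(K, M)`` Bernoulli presence probabilities, clamped to
        ``[1e-6, 1 - 1e-6]``.
    transition
        ``(K, K)`` row-stochastic matrix.
    initial
        Length-``K`` initial state distribution.
    mark_names
        Names of the ``M`` marks, in column order.
    state_labels
        Optional functional annotation per state (1-based ids), e.g.
        ``{9: "bivalent promoter"}``. Assigning such labels is a manual,
        interpretive step; :func:`blank_states` offers the one heuristic
        that is mechanical (near-zero emission of every mark).
    """

    emission: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    mark_names: tuple[str, ...] = DEFAULT_MARKS
    state_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def n_marks(self) -> int:
        return self.emission.shape[1]

    def validate(self, tol: float = 1e-9) -> None:
        K, M = self.emission.shape
        if self.transition.shape != (K, K):
            raise ValueError("transition matrix shape does not match state count")
        if self.initial.shape != (K,):
            raise ValueError("initial distribution shape does not match state count")
        if len(self.mark_names) != M:
            raise ValueError("mark_names length does not match emission columns")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > tol:
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > tol:
            raise ValueError("initial distribution must sum to 1")
        if (self.emission < 0).any() or (self.emission > 1).any():
            raise ValueError("emission probabilities outside [0, 1]")

    def clamped_emission(self) -> np.ndarray:
        return np.clip(self.emission, EMISSION_EPS, 1.0 - EMISSION_EPS)

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_states": self.n_states,
            "mark_names": list(self.mark_names),
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "state_labels": {str(k): v for k, v in (self.state_labels or {}).items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromatinStateModel":
        payload = json.loads(Path(path).read_text())
        labels = {int(k): v for k, v in payload.get("state_labels", {}).items()} or None
        return cls(
            emission=np.array(payload["emission"]),
            transition=np.array(payload["transition"]),
            initial=np.array(payload["initial"]),
            mark_names=tuple(payload["mark_names"]),
            state_labels=labels,
        )


@dataclass
class BinarizedTracks:
    """Binary mark presence per bin, per time point.

    ``data[tp]`` is a ``(total_bins, M)`` 0/1 array aligned to ``bins``.
    """

    bins: GenomeBins
    time_points: tuple[str, ...]
    mark_names: tuple[str, ...]
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        M = len(self.mark_names)
        for tp in self.time_points:
            arr = np.asarray(self.data[tp])
            if arr.shape != (self.bins.total_bins, M):
                raise ValueError(
                    f"track for {tp} has shape {arr.shape}, expected "
                    f"({self.bins.total_bins}, {M})"
                )
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"track for {tp} is not binary")
            self.data[tp] = arr.astype(np.uint8)

    def sequences(self) -> list[np.ndarray]:
        """Per-(time point, chromosome) observation sequences.

        Each is a ``(T, M)`` binary array; the HMM treats them as
        independent realizations of one parameter set.
        """
        out = []
        for tp in self.time_points:
            for chrom in self.bins.chrom_names:
                out.append(self.data[tp][self.bins.chrom_slice(chrom)])
        return out


@dataclass
class StateSegmentation:
    """Per-bin chromatin-state labels (1..K) for each time point."""

    bins: GenomeBins
    time_points: tuple[str, ...]
    labels: dict[str, np.ndarray]
    n_states: int

    def __post_init__(self) -> None:
        for tp in self.time_points:
            arr = np.asarray(self.labels[tp], dtype=np.int64)
            if arr.shape != (self.bins.total_bins,):
                raise ValueError(f"labels for {tp} do not match the binning")
            if arr.size and (arr.min() < 1 or arr.max() > self.n_states):
                raise ValueError(f"labels for {tp} outside 1..{self.n_states}")
            self.labels[tp] = arr

    def intervals(self, time_point: str) -> pd.DataFrame:
        """Merged maximal same-state runs as (chrom, start, end, state)."""
        rows = []
        lab = self.labels[time_point]
        for chrom in self.bins.chrom_names:
            sl = self.bins.chrom_slice(chrom)
            arr = lab[sl]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            bw = self.bins.bin_width
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s) * bw, int(e) * bw, int(arr[s])))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def to_bed(self, time_point: str, path: str | Path) -> None:
        write_segmentation_bed(self.bins, self.labels[time_point], path)


# ----------------------------------------------------------------------
# Binarization
# ----------------------------------------------------------------------

def poisson_threshold(background_rate: float, p_threshold: float = 1e-4) -> int:
    """Smallest count c with Poisson upper-tail P(X >= c) <= p_threshold.

    This is the conventional signal/background call for binned ChIP-seq
    counts: a bin is "marked" when its count is improbably large under a
    Poisson background with the genome-wide mean rate.
    """
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    if p_threshold == 1.0:
        return 0
    # P(X >= c) = sf(c - 1); isf gives the smallest integer x with sf(x) <= p,
    # hence c = x + 1.
    c = int(stats.poisson.isf(p_threshold, background_rate)) + 1
    while c > 0 and stats.poisson.sf(c - 2, background_rate) <= p_threshold:
        c -= 1
    return c


def binarize(
    counts: np.ndarray,
    background_rate: np.ndarray | float | None = None,
    p_threshold: float = 1e-4,
) -> np.ndarray:
    """Binarize a (bins x marks) count matrix with a Poisson-tail threshold.

    ``background_rate`` may be a scalar, a per-mark vector, or ``None``
    (estimated as the genome-wide mean count per mark).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (bins x marks)")
    n_marks = counts.shape[1]
    if background_rate is None:
        lam = counts.mean(axis=0)
    else:
        lam = np.broadcast_to(np.asarray(background_rate, dtype=float), (n_marks,)).copy()
    if (lam <= 0).any():
        raise ValueError("background rate must be positive for every mark")
    thresholds = np.array([poisson_threshold(l, p_threshold) for l in lam])
    return (counts >= thresholds[None, :]).astype(np.uint8)


# ----------------------------------------------------------------------
# Baum-Welch core
# ----------------------------------------------------------------------

def _log_emission(seq: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """(T, K) log p(observation_t | state) for binary observations."""
    p = np.clip(emission, EMISSION_EPS, 1 - EMISSION_EPS)
    return seq @ np.log(p).T + (1 - seq) @ np.log(1 - p).T


def _group_by_length(seqs: list[np.ndarray]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(s.shape[0], []).append(i)
    return groups


def _e_step(
    seqs: list[np.ndarray],
    emission: np.ndarray,
    transition: np.ndarray,
    initial: np.ndarray,
    want_xi: bool = True,
):
    """Scaled forward-backward over all sequences (batched by length).

    Returns (loglik, gamma_list, xi_sum, gamma0_sum, emission_numer,
    gamma_sum_per_state). ``gamma_list`` is aligned with ``seqs``.
    """
    K = emission.shape[0]
    M = emission.shape[1]
    loglik = 0.0
    xi_sum = np.zeros((K, K))
    gamma0 = np.zeros(K)
    em_numer = np.zeros((K, M))
    gamma_tot = np.zeros(K)
    gamma_list: list[np.ndarray | None] = [None] * len(seqs)

    for T, idxs in _group_by_length(seqs).items():
        batch = np.stack([seqs[i].astype(float) for i in idxs])  # (S,T,M)
        S = batch.shape[0]
        logB = np.einsum("stm,km->stk", batch, np.log(np.clip(emission, EMISSION_EPS, 1 - EMISSION_EPS)))
        logB += np.einsum("stm,km->stk", 1.0 - batch, np.log(np.clip(1 - emission, EMISSION_EPS, 1 - EMISSION_EPS)))
        bmax = logB.max(axis=2, keepdims=True)
        B = np.exp(logB - bmax)  # (S,T,K), scaled per position

        alpha = np.empty((S, T, K))
        c = np.empty((S, T))
        a = initial[None, :] * B[:, 0]
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0] = a / c[:, 0, None]
        for t in range(1, T):
            a = (alpha[:, t - 1] @ transition) * B[:, t]
            ct = a.sum(axis=1)
            c[:, t] = ct
            alpha[:, t] = a / ct[:, None]
        if not np.isfinite(c).all() or (c <= 0).any():
            raise FloatingPointError("non-finite forward pass; data/model mismatch")
        loglik += float(np.log(c).sum() + bmax.sum())

        gamma = np.empty((S, T, K))
        beta = np.ones((S, K))
        gamma[:, T - 1] = alpha[:, T - 1] * beta
        for t in range(T - 2, -1, -1):
            tmp = B[:, t + 1] * beta / c[:, t + 1, None]  # (S,K)
            if want_xi:
                xi_sum += np.einsum("sk,kl,sl->kl", alpha[:, t], transition, tmp)
            beta = tmp @ transition.T
            g = alpha[:, t] * beta
            gamma[:, t] = g / g.sum(axis=1, keepdims=True)
        if not np.isfinite(gamma).all():
            raise FloatingPointError("non-finite backward pass")

        gamma0 += gamma[:, 0].sum(axis=0)
        em_numer += np.einsum("stk,stm->km", gamma, batch)
        gamma_tot += gamma.sum(axis=(0, 1))
        for j, i in enumerate(idxs):
            gamma_list[i] = gamma[j]

    return loglik, gamma_list, xi_sum, gamma0, em_numer, gamma_tot


def _init_params(K: int, M: int, rng: np.random.Generator):
    """Random initialization: mid-range emissions, diagonal-dominant transitions.

    Diagonal dominance reflects the segmental structure of chromatin
    domains (states persist over many consecutive bins).
    """
    emission = rng.uniform(0.2, 0.8, size=(K, M))
    if K > 1:
        transition = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(transition, 0.9)
    else:
        transition = np.ones((1, 1))
    initial = np.full(K, 1.0 / K)
    return emission, transition, initial


def baum_welch_train(
    tracks: BinarizedTracks,
    n_states: int,
    n_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    n_restarts: int = 1,
    mark_names: tuple[str, ...] | None = None,
) -> tuple[ChromatinStateModel, list[float]]:
    """Learn HMM parameters by EM from all time points jointly.

    Every (time point, chromosome) pair is an independent observation
    sequence sharing one parameter set. The best of ``n_restarts``
    seeded random initializations is returned, with states re-ordered
    canonically (descending expected genome coverage, ties broken by
    lexicographic emission row) so state numbering is stable across runs.

    Returns the model and the log-likelihood trace of the winning
    restart. The trace is checked to be non-decreasing (within 1e-8);
    a violation raises ``ArithmeticError``.
    """
    seqs = tracks.sequences()
    total = sum(s.shape[0] for s in seqs)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states > total:
        raise ValueError(f"n_states={n_states} exceeds number of bins {total}")
    marks = tuple(mark_names or tracks.mark_names)
    M = len(marks)

    best: tuple[float, ChromatinStateModel, list[float]] | None = None
    seed_seq = np.random.SeedSequence(seed)
    for child in seed_seq.spawn(n_restarts):
        rng = np.random.default_rng(child)
        emission, transition, initial = _init_params(n_states, M, rng)
        trace: list[float] = []
        for iteration in range(n_iter):
            try:
                ll, _gam, xi, g0, em_num, g_tot = _e_step(seqs, emission, transition, initial)
            except FloatingPointError as exc:
                raise FloatingPointError(f"E-step failed at iteration {iteration}: {exc}") from exc
            if trace and ll < trace[-1] - 1e-8:
                raise ArithmeticError(
                    f"log-likelihood decreased at iteration {iteration}: "
                    f"{trace[-1]:.10g} -> {ll:.10g}"
                )
            converged = bool(trace) and (ll - trace[-1]) <= tol * abs(trace[-1])
            trace.append(ll)
            if converged:
                break
            # M-step
            initial = g0 / g0.sum()
            row = xi.sum(axis=1, keepdims=True)
            transition = np.where(row > 0, xi / np.where(row > 0, row, 1.0), 1.0 / n_states)
            transition /= transition.sum(axis=1, keepdims=True)
            emission = np.clip(em_num / np.maximum(g_tot[:, None], 1e-300), EMISSION_EPS, 1 - EMISSION_EPS)
        if best is None or trace[-1] > best[0]:
            model = ChromatinStateModel(emission, transition, initial, marks)
            best = (trace[-1], model, trace)

    assert best is not None
    _, model, trace = best
    model = _canonical_order(model, seqs)
    return model, trace


def _canonical_order(model: ChromatinStateModel, seqs: list[np.ndarray]) -> ChromatinStateModel:
    """Re-number states: descending expected coverage, then emission row."""
    _, _, _, _, _, g_tot = _e_step(seqs, model.emission, model.transition, model.initial, want_xi=False)
    K = model.n_states
    order = sorted(
        range(K),
        key=lambda k: (-g_tot[k], tuple(model.emission[k])),
    )
    perm = np.array(order)
    return ChromatinStateModel(
        emission=model.emission[perm],
        transition=model.transition[np.ix_(perm, perm)],
        initial=model.initial[perm],
        mark_names=model.mark_names,
        state_labels=model.state_labels,
    )


# ----------------------------------------------------------------------
# Decoding
# ----------------------------------------------------------------------

def posterior_marginals(model: ChromatinStateModel, seq: np.ndarray) -> np.ndarray:
    """(T, K) forward-backward posterior state probabilities for one sequence."""
    _, gamma_list, *_ = _e_step(
        [np.asarray(seq)], model.clamped_emission(), model.transition, model.initial, want_xi=False
    )
    return gamma_list[0]


def _viterbi(model: ChromatinStateModel, seq: np.ndarray) -> np.ndarray:
    logA = np.log(np.clip(model.transition, 1e-300, None))
    logB = _log_emission(np.asarray(seq, dtype=float), model.emission)
    T, K = logB.shape
    delta = np.log(np.clip(model.initial, 1e-300, None)) + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def decode(
    model: ChromatinStateModel,
    tracks: BinarizedTracks,
    method: str = "posterior",
) -> StateSegmentation:
    """Label every bin with its chromatin state (1..K).

    ``method="posterior"`` takes the per-bin argmax of the
    forward-backward marginals (ties resolved toward the lower state
    index); ``method="viterbi"`` returns the jointly most probable path.
    """
    if method not in {"posterior", "viterbi"}:
        raise ValueError(f"method must be 'posterior' or 'viterbi', got {method!r}")
    if tuple(tracks.mark_names) != tuple(model.mark_names):
        raise ValueError(
            f"mark sets differ: model {model.mark_names} vs tracks {tracks.mark_names}"
        )
    labels: dict[str, np.ndarray] = {}
    for tp in tracks.time_points:
        out = np.empty(tracks.bins.total_bins, dtype=np.int64)
        for chrom in tracks.bins.chrom_names:
            sl = tracks.bins.chrom_slice(chrom)
            seq = tracks.data[tp][sl]
            if method == "posterior":
                gamma = posterior_marginals(model, seq)
                # round-off guard so exact ties break to the lowest index
                out[sl] = np.argmax(np.round(gamma, 12), axis=1) + 1
            else:
                out[sl] = _viterbi(model, seq) + 1
        labels[tp] = out
    return StateSegmentation(tracks.bins, tracks.time_points, labels, model.n_states)


# ----------------------------------------------------------------------
# Genome-level summaries
# ----------------------------------------------------------------------

def state_coverage(segmentation: StateSegmentation) -> pd.DataFrame:
    """Fraction of the binned genome in each state, per time point.

    Rows are states 1..K, columns time points; each column sums to 1.
    """
    K = segmentation.n_states
    data = {}
    for tp in segmentation.time_points:
        counts = np.bincount(segmentation.labels[tp], minlength=K + 1)[1:]
        data[tp] = counts / counts.sum()
    return pd.DataFrame(data, index=pd.RangeIndex(1, K + 1, name="state"))


def blank_states(model: ChromatinStateModel, threshold: float = 0.1) -> set[int]:
    """States (1-based) whose every mark emission is below ``threshold``.

    Such states carry essentially no mark and correspond to the
    unmodified bulk of the genome.
    """
    return {k + 1 for k in range(model.n_states) if model.emission[k].max() < threshold}


def marked_genome_fraction(
    segmentation: StateSegmentation, blank: set[int]
) -> pd.Series:
    """Per time point, fraction of the binned genome in non-blank states."""
    cov = state_coverage(segmentation)
    keep = [s for s in cov.index if s not in blank]
    return cov.loc[keep].sum(axis=0)


def segment_length_stats(segmentation: StateSegmentation) -> pd.DataFrame:
    """Length distribution (bases) of merged same-state segments per state.

    Segments are pooled across time points and chromosomes. The minimum
    possible length is one bin.
    """
    lengths: dict[int, list[int]] = {s: [] for s in range(1, segmentation.n_states + 1)}
    for tp in segmentation.time_points:
        iv = segmentation.intervals(tp)
        for state, grp in iv.groupby("state"):
            lengths[int(state)].extend((grp["end"] - grp["start"]).tolist())
    rows = []
    for state in sorted(lengths):
        arr = np.array(lengths[state], dtype=float)
        if arr.size == 0:
            rows.append((state, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
        else:
            rows.append(
                (
                    state,
                    arr.size,
                    arr.min(),
                    np.quantile(arr, 0.25),
                    np.quantile(arr, 0.5),
                    np.quantile(arr, 0.75),
                    arr.max(),
                )
            )
    return pd.DataFrame(
        rows, columns=["state", "n_segments", "min", "q25", "median", "q75", "max"]
    ).set_index("state")


def transition_summary(model: ChromatinStateModel) -> pd.DataFrame:
    """Per state: modal off-diagonal successor and transition-row entropy.

    ``entropy_bits`` is the Shannon entropy of the full row (0 for a
    deterministic row, log2 K for a uniform one); ``sparsity`` is
    ``1 - entropy / log2(K)`` so that 1 means fully concentrated.
    The successor is NaN when the row has no off-diagonal mass.
    """
    K = model.n_states
    rows = []
    for k in range(K):
        row = model.transition[k]
        off = row.copy()
        off[k] = 0.0
        if off.sum() <= 0:
            succ, succ_p = np.nan, 0.0
        else:
            j = int(off.argmax())
            succ, succ_p = j + 1, float(off[j])
        nz = row[row > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        sparsity = 1.0 - entropy / np.log2(K) if K > 1 else 1.0
        rows.append((k + 1, succ, succ_p, entropy, sparsity))
    return pd.DataFrame(
        rows, columns=["state", "top_successor", "successor_prob", "entropy_bits", "sparsity"]
    ).set_index("state")


# ----------------------------------------------------------------------
# Model / Results objects
# ----------------------------------------------------------------------

class ChromatinStateHMM:
    """Multivariate Bernoulli HMM of chromatin states over binned marks.

    Parameters
    ----------
    tracks
        Binarized mark tracks for all time points.
    n_states
        Number of hidden chromatin states K.

    Examples
    --------
    >>> model = ChromatinStateHMM(tracks, n_states=15)   # doctest: +SKIP
    >>> res = model.fit(seed=0, n_restarts=3)            # doctest: +SKIP
    >>> seg = res.decode()                               # doctest: +SKIP
    """

    def __init__(self, tracks: BinarizedTracks, n_states: int):
        self.tracks = tracks
        self.n_states = int(n_states)

    def fit(
        self,
        n_iter: int = 100,
        tol: float = 1e-4,
        seed: int = 0,
        n_restarts: int = 1,
    ) -> "ChromatinStateHMMResults":
        model, trace = baum_welch_train(
            self.tracks,
            self.n_states,
            n_iter=n_iter,
            tol=tol,
            seed=seed,
            n_restarts=n_restarts,
        )
        return ChromatinStateHMMResults(self, model, trace)


class ChromatinStateHMMResults:
    """Fitted chromatin-state HMM: parameters, fit diagnostics, decoding."""

    def __init__(self, parent: ChromatinStateHMM, model: ChromatinStateModel, trace: list[float]):
        self.model_spec = parent
        self.model = model
        self.log_likelihoods = list(trace)

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihoods[-1]

    @property
    def emission(self) -> np.ndarray:
        return self.model.emission

    @property
    def transition(self) -> np.ndarray:
        return self.model.transition

    def decode(self, tracks: BinarizedTracks | None = None, method: str = "posterior") -> StateSegmentation:
        return decode(self.model, tracks or self.model_spec.tracks, method=method)

    def transition_summary(self) -> pd.DataFrame:
        return transition_summary(self.model)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Chromatin-state HMM results",
            "===========================",
            f"states:            {m.n_states}",
            f"marks:             {', '.join(m.mark_names)}",
            f"sequences:         {len(self.model_spec.tracks.sequences())}",
            f"bins per sequence: {[s.shape[0] for s in self.model_spec.tracks.sequences()][:8]}",
            f"EM iterations:     {len(self.log_likelihoods)}",
            f"log-likelihood:    {self.log_likelihood:.4f}",
            "",
            "Emission probabilities (rows: states, cols: marks)",
        ]
        em = pd.DataFrame(
            m.emission, index=[f"cs{i}" for i in range(1, m.n_states + 1)], columns=list(m.mark_names)
        )
        lines.append(em.round(3).to_string())
        lines.append("")
        lines.append("Self-transition probabilities")
        lines.append(
            "  " + "  ".join(f"cs{i + 1}:{m.transition[i, i]:.3f}" for i in range(m.n_states))
        )
        return "\n".join(lines)
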