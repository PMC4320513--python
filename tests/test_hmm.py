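"""Binarization, Baum-Welch training, decoding and genome summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn import (
    BinarizedTracks,
    ChromatinStateHMM,
    ChromatinStateModel,
    GenomeBins,
    StateSegmentation,
    binarize,
    blank_states,
    decode,
    marked_genome_fraction,
    poisson_threshold,
    posterior_marginals,
    segment_length_stats,
    state_coverage,
    transition_summary,
)
from chromdyn.hmm import _log_emission


def brute_force_threshold(lam: float, p: float) -> int:
    """Smallest c with the Poisson upper tail P(X >= c) <= p, by summation."""
    c = 0
    while 1.0 - sum(stats.poisson.pmf(k, lam) for k in range(c)) > p:
        c += 1
    return c


class TestBinarize:
    @pytest.mark.parametrize("lam,p", [(1.0, 1e-4), (0.5, 1e-4), (2.0, 1e-3), (8.0, 1e-4)])
    def test_threshold_matches_tail_enumeration(self, lam, p):
        assert poisson_threshold(lam, p) == brute_force_threshold(lam, p)

    def test_lambda1_p1e4_is_seven(self):
        # P(X>=7; 1) ~ 8.3e-5 <= 1e-4 < P(X>=6; 1) ~ 5.9e-4
        assert poisson_threshold(1.0, 1e-4) == 7

    def test_all_zero_counts(self):
        assert binarize(np.zeros((100, 3)), background_rate=1.0).sum() == 0

    def test_degenerate_threshold_one(self):
        counts = np.zeros((10, 2))
        assert (binarize(counts, background_rate=1.0, p_threshold=1.0) == 1).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            binarize(np.array([[-1.0, 2.0]]))

    def test_background_estimated_from_mean(self, rng):
        counts = rng.poisson(2.0, size=(5000, 1)).astype(float)
        expected = poisson_threshold(counts.mean(), 1e-4)
        binary = binarize(counts)
        np.testing.assert_array_equal(binary[:, 0], counts[:, 0] >= expected)


def _tracks_from_labels(bins, labels_by_tp, model, rng=None, noiseless=False):
    """Emit binary tracks from given state paths (optionally deterministic)."""
    data = {}
    for tp, lab in labels_by_tp.items():
        p = model.emission[np.asarray(lab) - 1]
        if noiseless:
            data[tp] = (p >= 0.5).astype(np.uint8)
        else:
            data[tp] = (rng.random(p.shape) < p).astype(np.uint8)
    return BinarizedTracks(bins, tuple(labels_by_tp), model.mark_names, data)


class TestBaumWelch:
    def test_k1_closed_form(self, rng):
        bins = GenomeBins(("c",), (20_000,), 200)
        data = {"t0": (rng.random((100, 3)) < [0.3, 0.6, 0.9]).astype(np.uint8)}
        tracks = BinarizedTracks(bins, ("t0",), ("a", "b", "c"), data)
        res = ChromatinStateHMM(tracks, 1).fit(n_iter=5, seed=0)
        np.testing.assert_allclose(res.emission[0], data["t0"].mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(res.transition, [[1.0]])

    def test_planted_two_state_recovery(self, two_state_model, rng):
        bins = GenomeBins(("c",), (20_000_000,), 200)  # 1e5 bins
        T = bins.total_bins
        # sample the true chain
        path = np.empty(T, dtype=int)
        path[0] = 0
        flips = rng.random(T) < 0.05
        for t in range(1, T):
            path[t] = 1 - path[t - 1] if flips[t] else path[t - 1]
        tracks = _tracks_from_labels(bins, {"t0": path + 1}, two_state_model, rng)
        res = ChromatinStateHMM(tracks, 2).fit(n_iter=100, tol=1e-5, seed=1, n_restarts=2)
        best = min(
            itertools.permutations(range(2)),
            key=lambda p: np.abs(res.emission[list(p)] - two_state_model.emission).mean(),
        )
        p = list(best)
        assert np.abs(res.emission[p] - two_state_model.emission).max() < 0.05
        assert np.abs(res.transition[np.ix_(p, p)] - two_state_model.transition).max() < 0.05

    def test_loglik_trace_nondecreasing(self, two_state_model, rng):
        bins = GenomeBins(("c",), (200_000,), 200)
        path = rng.integers(1, 3, size=bins.total_bins)
        tracks = _tracks_from_labels(bins, {"t0": path}, two_state_model, rng)
        res = ChromatinStateHMM(tracks, 2).fit(n_iter=40, tol=0.0, seed=3)
        trace = np.array(res.log_likelihoods)
        assert (np.diff(trace) >= -1e-8).all()

    def test_too_many_states_rejected(self, two_state_model, rng):
        bins = GenomeBins(("c",), (2_000,), 200)
        tracks = _tracks_from_labels(bins, {"t0": np.ones(10, dtype=int)}, two_state_model, rng)
        with pytest.raises(ValueError, match="exceeds"):
            ChromatinStateHMM(tracks, 100).fit()


def enumerate_posterior(model: ChromatinStateModel, seq: np.ndarray) -> np.ndarray:
    """Posterior marginals by exhaustive summation over all K^T paths."""
    T = seq.shape[0]
    K = model.n_states
    logB = _log_emission(seq.astype(float), model.emission)
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        logp = np.log(model.initial[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            logp += np.log(model.transition[path[t - 1], path[t]]) + logB[t, path[t]]
        w = np.exp(logp)
        total += w
        for t in range(T):
            post[t, path[t]] += w
    return post / total


class TestDecode:
    def test_noiseless_recovery_is_exact(self, rng):
        model = ChromatinStateModel(
            emission=np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
            transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
            initial=np.array([0.5, 0.5]),
            mark_names=("a", "b", "c"),
        )
        bins = GenomeBins(("c",), (200_000,), 200)
        path = rng.integers(1, 3, size=bins.total_bins)
        tracks = _tracks_from_labels(bins, {"t0": path}, model, noiseless=True)
        for method in ("posterior", "viterbi"):
            seg = decode(model, tracks, method=method)
            np.testing.assert_array_equal(seg.labels["t0"], path)

    def test_12bin_posterior_matches_exhaustive_enumeration(self, two_state_model, rng):
        seq = (rng.random((12, 3)) < 0.5).astype(np.uint8)
        gamma = posterior_marginals(two_state_model, seq)
        expected = enumerate_posterior(two_state_model, seq)
        np.testing.assert_allclose(gamma, expected, atol=1e-6)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_posterior_matches_hmmlearn_oracle(self, two_state_model, rng):
        """Independent cross-check: encode the 3-mark vectors as 8 categorical
        symbols and compare forward-backward posteriors."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        seq = (rng.random((200, 3)) < 0.5).astype(np.uint8)
        m = two_state_model
        symbols = seq @ np.array([4, 2, 1])
        emissionprob = np.zeros((2, 8))
        for s in range(8):
            bits = np.array([(s >> 2) & 1, (s >> 1) & 1, s & 1])
            emissionprob[:, s] = np.prod(
                np.where(bits == 1, m.emission, 1 - m.emission), axis=1
            )
        oracle = hmmlearn.CategoricalHMM(n_components=2)
        oracle.startprob_ = m.initial
        oracle.transmat_ = m.transition
        oracle.emissionprob_ = emissionprob
        expected = oracle.predict_proba(symbols.reshape(-1, 1))
        gamma = posterior_marginals(m, seq)
        np.testing.assert_allclose(gamma, expected, atol=1e-6)

    def test_uniform_model_ties_break_to_state_one(self):
        model = ChromatinStateModel(
            emission=np.full((3, 2), 0.5),
            transition=np.full((3, 3), 1 / 3),
            initial=np.full(3, 1 / 3),
            mark_names=("a", "b"),
        )
        bins = GenomeBins(("c",), (2_000,), 200)
        data = {"t0": np.zeros((10, 2), dtype=np.uint8)}
        tracks = BinarizedTracks(bins, ("t0",), ("a", "b"), data)
        seg = decode(model, tracks)
        assert (seg.labels["t0"] == 1).all()

    def test_mark_mismatch_rejected(self, two_state_model):
        bins = GenomeBins(("c",), (2_000,), 200)
        tracks = BinarizedTracks(bins, ("t0",), ("x", "y", "z"), {"t0": np.zeros((10, 3), dtype=np.uint8)})
        with pytest.raises(ValueError, match="mark sets differ"):
            decode(two_state_model, tracks)


class TestSummaries:
    def test_state_coverage_constant_and_split(self):
        bins = GenomeBins(("c",), (2_000,), 200)
        seg = StateSegmentation(bins, ("t0",), {"t0": np.full(10, 2)}, 3)
        cov = state_coverage(seg)
        assert cov.loc[2, "t0"] == 1.0 and cov.loc[1, "t0"] == 0.0
        half = np.array([1] * 5 + [2] * 5)
        seg = StateSegmentation(bins, ("t0",), {"t0": half}, 2)
        assert state_coverage(seg).loc[1, "t0"] == 0.5

    def test_state_coverage_counting_oracle(self, rng):
        bins = GenomeBins(("a", "b"), (100_000, 60_000), 200)
        labels = rng.integers(1, 6, size=bins.total_bins)
        seg = StateSegmentation(bins, ("t0",), {"t0": labels}, 5)
        cov = state_coverage(seg)
        for s in range(1, 6):
            assert cov.loc[s, "t0"] == pytest.approx((labels == s).sum() / bins.total_bins)
        assert cov["t0"].sum() == pytest.approx(1.0)

    def test_marked_fraction_excludes_blank(self, rng):
        bins = GenomeBins(("a",), (100_000,), 200)
        labels = rng.integers(1, 4, size=bins.total_bins)
        seg = StateSegmentation(bins, ("t0",), {"t0": labels}, 3)
        frac = marked_genome_fraction(seg, blank={3})
        assert frac["t0"] == pytest.approx((labels != 3).mean())

    def test_blank_state_flagging(self):
        model = ChromatinStateModel(
            emission=np.array([[0.9, 0.2], [0.02, 0.05]]),
            transition=np.eye(2) * 0.9 + 0.1 * (1 - np.eye(2)),
            initial=np.array([0.5, 0.5]),
            mark_names=("a", "b"),
        )
        assert blank_states(model) == {2}

    def test_segment_lengths_match_rle_oracle(self, rng):
        bins = GenomeBins(("a",), (200_000,), 200)
        labels = rng.integers(1, 4, size=bins.total_bins)
        seg = StateSegmentation(bins, ("t0",), {"t0": labels}, 3)
        stats_df = segment_length_stats(seg)
        # oracle: run-length encode by hand
        lengths = {1: [], 2: [], 3: []}
        run_start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[run_start]:
                lengths[labels[run_start]].append((i - run_start) * 200)
                run_start = i
        for s in (1, 2, 3):
            arr = np.array(lengths[s], dtype=float)
            assert stats_df.loc[s, "n_segments"] == arr.size
            assert stats_df.loc[s, "min"] == arr.min() >= 200
            assert stats_df.loc[s, "median"] == pytest.approx(np.median(arr))

    def test_constant_genome_single_segment(self):
        bins = GenomeBins(("a",), (2_000,), 200)
        seg = StateSegmentation(bins, ("t0",), {"t0": np.full(10, 1)}, 1)
        st_df = segment_length_stats(seg)
        assert st_df.loc[1, "n_segments"] == 1 and st_df.loc[1, "max"] == 2_000

    def test_transition_summary_identity_and_uniform(self):
        ident = ChromatinStateModel(
            emission=np.full((3, 2), 0.5),
            transition=np.eye(3),
            initial=np.full(3, 1 / 3),
            mark_names=("a", "b"),
        )
        ts = transition_summary(ident)
        assert np.isnan(ts.loc[1, "top_successor"])
        assert ts["entropy_bits"].eq(0).all() and ts["sparsity"].eq(1.0).all()
        unif = ChromatinStateModel(
            emission=np.full((4, 2), 0.5),
            transition=np.full((4, 4), 0.25),
            initial=np.full(4, 0.25),
            mark_names=("a", "b"),
        )
        assert transition_summary(unif)["entropy_bits"].iloc[0] == pytest.approx(2.0)

    def test_transition_entropy_matches_formula(self, rng):
        row = rng.dirichlet(np.ones(5), size=5)
        model = ChromatinStateModel(
            emission=np.full((5, 2), 0.5), transition=row, initial=np.full(5, 0.2), mark_names=("a", "b")
        )
        ts = transition_summary(model)
        for k in range(5):
            expected = -(row[k] * np.log2(row[k])).sum()
            assert ts.loc[k + 1, "entropy_bits"] == pytest.approx(expected)
            off = row[k].copy()
            off[k] = 0
            assert ts.loc[k + 1, "top_successor"] == off.argmax() + 1


def test_model_json_roundtrip(two_state_model, tmp_path):
    p = tmp_path / "model.json"
    two_state_model.state_labels = {1: "active enhancer"}
    two_state_model.to_json(p)
    back = ChromatinStateModel.from_json(p)
    np.testing.assert_allclose(back.emission, two_state_model.emission)
    np.testing.assert_allclose(back.transition, two_state_model.transition)
    assert back.mark_names == two_state_model.mark_names
    assert back.state_labels == {1: "active enhancer"}
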