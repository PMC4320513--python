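"""Ground-truth structure of the synthetic genome/track/expression generator."""

import numpy as np
import pandas as pd
import pytest

from chromdyn import (
    SyntheticConfig,
    emit_mark_tracks,
    generate_expression,
    generate_genome,
    generate_state_paths,
    load_archetypes,
    planted_model,
    simulate,
)

MARKS4 = ("H3K27me3", "H3K4me3", "H3K36me3", "CTCF")


def small_config(**kw):
    defaults = dict(
        n_chromosomes=1,
        chromosome_length=400_000,
        n_states=4,
        n_marks=4,
        mark_names=MARKS4,
        n_genes=19,
        module_spec=[(a, 1, 1.0) for a in sorted(load_archetypes())],
        seed=0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfig:
    def test_bin_width_must_divide(self):
        with pytest.raises(ValueError, match="divide"):
            small_config(chromosome_length=1001)

    def test_module_counts_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            small_config(n_genes=5)

    def test_flip_probabilities_validated(self):
        with pytest.raises(ValueError, match="outside"):
            small_config(dynamics_coupling={1: 1.5})
        with pytest.raises(ValueError, match="unknown state"):
            small_config(dynamics_coupling={99: 0.5})

    def test_per_transition_flips(self):
        cfg = small_config(dynamics_coupling={1: (0.1, 0.5, 0.2), 2: 0.3})
        fm = cfg.flip_matrix()
        np.testing.assert_allclose(fm[0], [0.1, 0.5, 0.2])
        np.testing.assert_allclose(fm[1], [0.3, 0.3, 0.3])
        np.testing.assert_allclose(fm[2], [0.1, 0.1, 0.1])  # default flip


class TestGenerateGenome:
    def test_zero_genes_empty_annotation(self):
        cfg = small_config(n_genes=0, module_spec=[])
        assert generate_genome(cfg).empty

    def test_fixed_seed_byte_identical(self):
        cfg = small_config(seed=7)
        a = generate_genome(cfg)
        b = generate_genome(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_500_genes_non_overlapping_within_bounds(self):
        cfg = SyntheticConfig(
            n_chromosomes=2,
            chromosome_length=5_000_000,
            n_genes=500,
            module_spec=[("stable_low_1", 500, 1.0)],
            seed=3,
        )
        genes = generate_genome(cfg)
        assert len(genes) == 500
        for chrom, grp in genes.groupby("chrom"):
            assert (grp["start"] >= 0).all()
            assert (grp["end"] <= 5_000_000).all()
            rows = sorted(zip(grp["start"], grp["end"]))
            # exhaustive pairwise interval scan
            for (s1, e1), (s2, e2) in zip(rows[:-1], rows[1:]):
                assert e1 <= s2

    def test_impossible_placement_raises(self):
        cfg = small_config(
            chromosome_length=10_000,
            n_genes=19,
            gene_length_log_mean=float(np.log(5_000)),
            gene_length_log_sd=0.1,
        )
        with pytest.raises(ValueError, match="without overlap"):
            generate_genome(cfg)


class TestStatePaths:
    def test_zero_flip_freezes_all_paths(self):
        cfg = small_config(default_flip=0.0)
        paths = generate_state_paths(cfg, planted_model(cfg))
        first = paths["D-2"]
        for tp in ("D0", "D3", "D9"):
            np.testing.assert_array_equal(paths[tp], first)

    def test_flip_one_never_retains_state(self):
        cfg = small_config(dynamics_coupling={2: 1.0}, default_flip=0.0)
        paths = generate_state_paths(cfg, planted_model(cfg))
        tps = cfg.time_points
        for t1, t2 in zip(tps[:-1], tps[1:]):
            was_two = paths[t1] == 2
            assert not (paths[t2][was_two] == 2).any()

    def test_change_fraction_matches_flip_probability(self):
        # 1e5 bins, flip 0.3; segments are the resampling unit, so the
        # binomial oracle for the tolerance counts segments, not bins
        cfg = SyntheticConfig(
            n_chromosomes=1,
            chromosome_length=20_000_000,
            n_states=4,
            n_marks=4,
            mark_names=MARKS4,
            n_genes=0,
            module_spec=[],
            dynamics_coupling={1: 0.3},
            default_flip=0.1,
            seed=5,
        )
        model = planted_model(cfg)
        paths = generate_state_paths(cfg, model)
        prev, cur = paths["D-2"], paths["D0"]
        in_state = prev == 1
        changed = (cur != prev)[in_state].mean()
        runs = np.flatnonzero(np.diff(prev)) + 1
        seg_starts = np.concatenate([[0], runs])
        n_state_segments = (prev[seg_starts] == 1).sum()
        se = np.sqrt(0.3 * 0.7 / n_state_segments)
        assert changed == pytest.approx(0.3, abs=3 * se)

    def test_bad_transition_matrix_rejected(self):
        cfg = small_config()
        model = planted_model(cfg)
        model.transition = model.transition * 0.5  # rows no longer sum to 1
        with pytest.raises(ValueError, match="sum to 1"):
            generate_state_paths(cfg, model)


class TestEmitTracks:
    def test_deterministic_emissions(self):
        cfg = small_config(n_genes=0, module_spec=[])
        model = planted_model(cfg)
        model.emission = np.zeros((4, 4))
        model.emission[0, 0] = 1.0  # state 1 always emits mark 1, nothing else
        paths = generate_state_paths(cfg, model)
        tracks = emit_mark_tracks(paths, model, cfg)
        for tp in cfg.time_points:
            in1 = paths[tp] == 1
            assert (tracks.data[tp][in1, 0] == 1).all()
            assert tracks.data[tp][~in1, 0].sum() == 0
            assert tracks.data[tp][:, 1:].sum() == 0

    def test_emission_frequency_binomial_oracle(self):
        cfg = SyntheticConfig(
            n_chromosomes=1,
            chromosome_length=8_000_000,  # 4e4 bins
            n_states=2,
            n_marks=2,
            mark_names=("a", "b"),
            n_genes=0,
            module_spec=[],
            seed=9,
        )
        model = planted_model(cfg)
        model.emission = np.array([[0.8, 0.1], [0.1, 0.8]])
        paths = generate_state_paths(cfg, model)
        tracks = emit_mark_tracks(paths, model, cfg)
        in1 = paths["D-2"] == 1
        n = int(in1.sum())
        freq = tracks.data["D-2"][in1, 0].mean()
        se = np.sqrt(0.8 * 0.2 / n)
        assert freq == pytest.approx(0.8, abs=3 * se)

    def test_counts_mode_separable_under_binarization(self):
        from chromdyn import binarize

        cfg = small_config(n_genes=0, module_spec=[], seed=2)
        model = planted_model(cfg)
        paths = generate_state_paths(cfg, model)
        tracks, counts = emit_mark_tracks(paths, model, cfg, counts=True)
        binary = binarize(counts["D-2"], background_rate=cfg.lambda_low, p_threshold=1e-4)
        agreement = (binary == tracks.data["D-2"]).mean()
        # oracle: at threshold c* = 7, a present mark (Poisson 8) is missed
        # with P(X < 7) and an absent one (Poisson 1) misfires with P(X >= 7)
        from scipy import stats as ss

        present = tracks.data["D-2"].mean()
        miss = ss.poisson.cdf(6, cfg.lambda_high)
        fp = ss.poisson.sf(6, cfg.lambda_low)
        expected = 1.0 - present * miss - (1 - present) * fp
        assert agreement == pytest.approx(expected, abs=0.02)
        assert agreement < 1.0  # error rates are nonzero by design


class TestExpression:
    def test_noise_free_stable_archetype(self):
        cfg = small_config(noise_sd=0.0)
        expr, modules = generate_expression(cfg)
        stable = expr.loc[modules == "stable_high_1"]
        assert (stable.nunique(axis=1) == 1).all()

    def test_induced_d9_zero_before(self):
        cfg = small_config()
        expr, modules = generate_expression(cfg)
        late = expr.loc[modules == "induced_d9"]
        assert (late[["D-2", "D0", "D3"]] == 0).all().all()
        assert (late["D9"] > 0).all()

    def test_repressed_d0_zero_after(self):
        cfg = small_config()
        expr, modules = generate_expression(cfg)
        rep = expr.loc[modules == "repressed_d0"]
        assert (rep[["D0", "D3", "D9"]] == 0).all().all()
        assert (rep["D-2"] > 0).all()

    def test_mean_profiles_match_lognormal_closed_form(self):
        cfg = small_config(
            n_genes=19 * 100,
            module_spec=[(a, 100, 1.0) for a in sorted(load_archetypes())],
            noise_sd=0.1,
            seed=6,
        )
        expr, modules = generate_expression(cfg)
        templates = load_archetypes()
        correction = np.exp(0.1**2 / 2)  # E[lognormal(0, sd)] = exp(sd^2 / 2)
        for name, spec in templates.items():
            observed = expr.loc[modules == name].mean(axis=0).to_numpy()
            expected = spec["fpkm"] * correction
            nz = expected > 0
            assert np.abs(observed[nz] / expected[nz] - 1).max() < 0.05
            assert (observed[~nz] == 0).all()

    def test_unknown_archetype_rejected(self):
        cfg = small_config()
        cfg.module_spec = [("no_such_shape", 19, 1.0)]
        with pytest.raises(KeyError, match="no_such_shape"):
            generate_expression(cfg)

    def test_templates_mutually_distinguishable(self):
        """Pairwise distance between noise-free templates in the clustering
        metric (Euclidean on log1p profiles) exceeds 10x the noise sd."""
        templates = load_archetypes()
        names = sorted(templates)
        noise_sd = SyntheticConfig.noise_sd
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = np.linalg.norm(
                    np.log1p(templates[a]["fpkm"]) - np.log1p(templates[b]["fpkm"])
                )
                assert d > 10 * noise_sd, (a, b, d)


class TestSimulate:
    def test_fixed_seed_reproducible_end_to_end(self):
        cfg = small_config(dynamics_coupling={1: 0.4, 2: 0.01}, seed=13)
        a = simulate(cfg)
        b = simulate(cfg)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        for tp in cfg.time_points:
            np.testing.assert_array_equal(a.tracks.data[tp], b.tracks.data[tp])
            np.testing.assert_array_equal(a.truth.true_paths[tp], b.truth.true_paths[tp])

    def test_planted_states_follow_coupling(self):
        cfg = small_config(dynamics_coupling={3: 0.5, 2: 0.001})
        ds = simulate(cfg)
        assert ds.truth.planted_dynamic_state == 3
        assert ds.truth.planted_stable_state == 2

    def test_every_bin_has_one_state_per_time_point(self):
        ds = simulate(small_config())
        for tp in ds.config.time_points:
            path = ds.truth.true_paths[tp]
            assert path.shape == (ds.bins.total_bins,)
            assert path.min() >= 1 and path.max() <= ds.config.n_states

    def test_written_dataset_roundtrips(self, tmp_path):
        from chromdyn import read_expression, read_gene_annotation

        ds = simulate(small_config(seed=3))
        ds.write(tmp_path)
        genes = read_gene_annotation(tmp_path / "genes.bed")
        pd.testing.assert_frame_equal(genes, ds.annotation.reset_index(drop=True))
        expr = read_expression(tmp_path / "expression.tsv")
        pd.testing.assert_frame_equal(expr, ds.expression)
        assert (tmp_path / "truth.json").exists()

    def test_expression_coupling_links_counts_to_fpkm(self, small_dataset):
        from chromdyn import (
            StateSegmentation,
            attribute_states,
            expression_state_regression,
            state_count_per_gene,
        )

        cfg = small_dataset.config
        coupled = simulate(
            SyntheticConfig(**{**cfg.__dict__, "expression_state_coupling": True})
        )
        seg = StateSegmentation(
            coupled.bins, cfg.time_points, dict(coupled.truth.true_paths), cfg.n_states
        )
        pres = attribute_states(seg, coupled.annotation, window=0)
        counts = state_count_per_gene(pres)
        res = expression_state_regression(coupled.expression, counts)
        assert res.r > 0.3
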