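# Methods

This note documents the models and procedures implemented in
`chromdyn`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Chromatin-state model

**Binarization.** Binned counts are called present per mark by a
Poisson upper-tail rule: the threshold is the smallest count *c* with
P(X ≥ c; λ) ≤ p, with p = 10⁻⁴ by default and λ estimated as the
genome-wide mean count of the mark unless supplied. At λ = 1 this gives
c\* = 7. This is the standard convention for converting ChIP-seq
enrichment into binary presence at fixed bin width; input-normalized or
local-background variants are not implemented.

**HMM.** Emissions are product-Bernoulli: state *s* carries one presence
probability per mark, clamped to [10⁻⁶, 1 − 10⁻⁶] so log-emissions stay
finite. One parameter set is learned jointly from all time points;
every (time point, chromosome) pair is an independent observation
sequence, i.e. the chain restarts at sequence boundaries but states are
shared across the whole time course. Learning per-time-point models is
deliberately not supported: a common state space is what makes
segmentations comparable over time.

Baum–Welch runs with per-position scaling (log-emissions are shifted by
their per-position maximum before exponentiation; the shift is restored
in the log-likelihood). Initialization draws emissions from
uniform(0.2, 0.8) and sets transitions diagonal-dominant (self 0.9,
remainder uniform), reflecting the segmental persistence of chromatin
domains; several seeded restarts are supported and the best
log-likelihood wins. EM stops at `n_iter` (default 100) or when the
relative log-likelihood improvement drops below `tol` (default 10⁻⁴).
The trace is checked to be non-decreasing within 10⁻⁸ and a violation
raises. After training, states are renumbered canonically — descending
expected genome coverage, ties by lexicographic emission row — so state
labels are stable across runs.

**Decoding.** Default decoding is the per-bin argmax of the
forward–backward posterior (Viterbi available as an option). Exact
posterior ties are broken toward the lower state index after rounding
the marginals at 10⁻¹² to absorb floating-point asymmetry; this makes
outputs deterministic, including the degenerate all-uniform model.

**Summaries.** Genome coverage per state and time point; merged
segment-length distributions; per-state modal off-diagonal successor
with a Shannon-entropy sparsity score of the transition row. States
whose every emission is below 0.1 are flagged "blank" (the unmarked
bulk of the genome); one minus the blank coverage estimates the marked
genome fraction.

## Expression modules

Genes with FPKM > 0 at at least one time point are retained.
Differential calls between two time points use the pseudocount-
regularized fold change (FPKM₂ + 1)/(FPKM₁ + 1) against a threshold of
2; no significance test is attached by default because the input is one
FPKM value per time point, without replicates — a test hook can be
layered on the returned fold changes. CV² (variance over squared mean
of raw FPKM) is profiled against log₁₀ FPKM bins per time point, with
zero-FPKM genes excluded from the binning and bins of fewer than two
genes reported missing. PCA places the time points on the first two
components of log(FPKM + 1), with component signs fixed by making the
largest-magnitude gene loading positive.

Module clustering is agglomerative (scipy `linkage`) on per-gene
profiles, cut to k flat clusters, or with k chosen by silhouette
maximization over a range (ties to the smallest k). Three profile
scalings are offered: per-gene z-scored log(FPKM + 1) (default, groups
by shape), plain log(FPKM + 1) (`"log"`, keeps magnitude), and raw
FPKM. The default follows common practice for time-course clustering —
shape, not level, defines a temporal module. Note its blind spot: a
flat profile has zero variance and z-scores to the origin, so cohorts
that differ only in expression level (stable-low vs stable-high)
collapse into one shape class. Recovering the shipped 19 archetypes,
four of which are flat at two levels, therefore uses `scaling="log"`;
this is the setting exercised in the recovery studies. Genes are sorted
by identifier before linkage and clusters are relabelled by
(size, smallest member), making the partition independent of input
order.

## State attribution

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted at the parse boundary only. A state is
attributed to a gene at a time point when at least one bin carrying it
overlaps [start − W, end + W) clipped to the chromosome. Strand is
ignored: the extension is symmetric because regulatory regions flank
genes on both sides.

The window W is derived from the data: for each adjacent time-point
transition, every bin whose state changes contributes the distance from
its midpoint to the nearest gene edge (zero inside genes; bins on
gene-free chromosomes are excluded). The per-transition 75th percentile
("upper quartile") of these distances is averaged across transitions,
halved, and rounded to the nearest bin multiple. Both the raw and
rounded values are reported. W is global — a single symmetric window
everywhere — rather than per gene or per transition; attribution is
monotone in W by construction, so moderate misestimation changes
little.

Gene ratios divide by the full module size, so genes lacking a state
still count toward its normalization, and ρ·|module| is always an
integer count. The per-gene state count (chromatin-signature
complexity) includes the blank state by default, with an exclusion
option; blank states are excluded from enrichment averaging and, by
default, from the temporal tests and dynamics scores.

## Dynamics statistics

**Temporal-change test.** For module *c* and transition t→t+1, let
Δ_s = ρ(c,s,t+1) − ρ(c,s,t). The test for state *s* is a one-sample
two-sided t-test of the sample {Δ_s′ over non-blank states, *s*
included} against the null mean Δ_s: an outlier flag for states whose
change departs from the module's overall change. The self-excluded
variant is available (`include_self=False`). Degenerate zero-variance
samples return P = 1 when Δ_s equals the common value and P = 0
otherwise.

This statistic is a flagging heuristic, not a calibrated test. Because
the tested delta is a member of the sample it is compared against, the
null variance of the t-statistic is inflated by a factor of about
K − 1 (for sample {x, 0, …, 0}, t = −(K − 1) identically), so at raw
α = 0.05 the rejection rate under an exchangeable null is ≈ 0.38 at
K = 8 — measured by the null-simulation study and reported by the
acceptance script. Deployed with its Bonferroni correction (families:
all state × transition tests within a module by default, or one global
family) the flag rate drops to ≈ 0.05–0.09. Conclusions drawn from it
in this package are comparative — rankings of states or modules by
dynamics score and count contrasts between transitions — which the
planted-truth studies validate directly.

**Dynamics score.** −log₁₀ of the sum of a group's raw (unadjusted)
P-values, per module or per state; higher means more remodelling. The
score is unclamped and may be negative when the P-values sum above 1.
A zero sum (underflow) raises with advice to configure a P floor.

**Pairwise matrices.** Module-enrichment comparisons pool each module's
gene ratios over non-excluded states and all time points and apply
two-sample two-sided Wilcoxon rank-sum tests; dynamics comparisons
apply one-sided rank-sum tests to the groups' raw P-value sets
(alternative: the first group's P-values are smaller, i.e. it is more
dynamic), one-sided because P-value distributions are strongly skewed.
Exact null distributions are used for group sizes up to 25 without
ties, otherwise the normal approximation with continuity and tie
corrections. Bonferroni is over the number of unordered pairs; family
sizes are recorded on every result object.

**Regression.** Chromatin-signature complexity is regressed on
log(FPKM + 1) by ordinary least squares over all (gene, time point)
pairs, reporting the Pearson r.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with every latent quantity exposed as ground truth.

*Genome and genes.* Chromosomes are uniform-length; genes have
log-normal lengths (default median 2 kb, log-sd 0.6) and are placed
round-robin across chromosomes, uniformly over the remaining free gaps,
so placement fails only when a gene cannot fit anywhere. Strand is
random and unused downstream.

*Chromatin states.* The planted model gives each non-blank state a
distinct high-emission mark pair (0.9 against a 0.1 background) and
makes the last state blank (all emissions 0.02); transitions are
diagonal-dominant (self 0.95 by default). The first time point is a
Markov-chain sample. Later time points resample whole same-state
segments: a segment flips with its state's per-transition flip
probability and lands on a destination drawn proportionally to the
destination's own flip probability (source excluded, uniform fallback
when all other states are frozen). Two properties motivated this
design over independent per-bin flips: segment-level moves preserve the
segment-length structure, whereas per-bin flips fragment later time
points into single-bin states and spuriously inflate every state's
gene-region presence over time; and flip-weighted destinations balance
each state's influx against its efflux, so genome shares stay
stationary while the *magnitude* of gene-ratio change scales with the
planted flip rate — a near-frozen state neither loses nor accumulates
territory. The expected per-state changed-bin fraction equals the
configured flip probability, with sampling error governed by the number
of segments rather than bins.

*Expression.* Nineteen named archetype templates (shipped in
`chromdyn/data/archetypes.yaml`) cover four stable cohorts (two low,
two high), three induced from zero FPKM at successive time points, one
expressed-and-up-regulated cohort, three repressed to zero, and eight
transient single-pulse or oscillatory shapes. Template levels are free
parameters of the simulator: they were chosen so strong cohorts exceed
weak ones by ≥ 10× and all template pairs are separated by more than
ten times the default noise sd (0.1) in log(FPKM + 1) Euclidean
distance. Noise is multiplicative log-normal, so template zeros remain
exactly zero. An optional coupling flag rewrites gene-body states so
the number of distinct states tracks log(FPKM + 1), for exercising the
complexity–expression regression; by default chromatin truth and
expression are independent.

*Counts mode.* Binary presence can be layered with Poisson counts
(signal λ = 8 where the mark fired, background λ = 1), separable under
the default binarization threshold (miss rate P(X < 7; 8) ≈ 0.31,
false-positive rate ≈ 8 × 10⁻⁵) so the binarization path has realistic,
nonzero error rates.

*What is not emulated:* read-level data (no FASTQ, no fragment-size or
mappability structure), replicates, copy-number or chromatin-domain
heterogeneity, and any mechanistic link between marks and transcription
beyond the optional coupling. Passing recovery studies therefore show
the pipeline is correct and well-calibrated against its own model
class, not that the model class captures everything in real
differentiation data.

*Determinism.* All randomness flows through NumPy's PCG64 generator
seeded from the configuration (restarts use `SeedSequence.spawn`);
fixed seeds give byte-identical outputs across platforms.

## Reference study scales

The evaluation protocols (`chromdyn.protocols`) use: a 2 × 5 Mb,
8-state, 7-mark, 4-time-point genome for HMM recovery (three restarts);
19 archetypes × 50 genes for module recovery with silhouette-selected k
over 10..30; a 200-gene, 10⁴-bin fixture for the attribution oracle; a
deterministic fixture with per-transition upper-quartile distances of
19.9 and 20.1 kb (mean 20 kb → 10 kb window) for window derivation; 200
exchangeable-null simulations for test calibration; and, for the
planted-dynamics analyses, 19 modules × 300 genes on a 4 × 5 Mb genome
with flips 0.4 / 0.01 / 0.1 (ranking; gene ± 2 kb) or a 0.8-flip
remodelling event at the middle transition against quiet bulk
(transition ordering; gene ± 1 kb). These sizes keep each study to
seconds-to-a-minute on one CPU while leaving comfortable statistical
margins; the ranking study's success criterion was verified over 40
independent replicates.

## Known limitations

- The temporal-change t-test is intentionally the uncalibrated
  outlier-flagging statistic described above; its raw P-values should
  only be consumed comparatively (scores, rankings, counts).
- Binarization ignores input tracks and local background variation.
- A single global extension window cannot represent distal regulation;
  enhancer–gene assignment beyond ±W (e.g. via chromatin looping) is
  out of scope.
- `cluster_modules` with the default z-score scaling cannot separate
  cohorts that differ only in expression level (see above).
- FPKM computation, read alignment, isoform assembly, replicate-based
  differential testing and gene-ontology enrichment are outside the
  package's scope.
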