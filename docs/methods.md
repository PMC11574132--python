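# Methods

This note documents the models, decision rules, numerical choices and
known limitations of `isrdep`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The factorial dependence model

The experimental unit is a 2×2 factorial crossing stress (control vs.
stressed) with genotype (signaling relay intact vs. knocked out), with
sex recorded as a covariate. Writing the four groups g1–g4 as in the
README, the scientific question per gene is epistasis-like: *does the
stress response require the relay?* The operational answer is the
conjunction

- stress response: `g3_vs_g1` significant and large
  (microarray/features: FDR ≤ 0.05 and |log2FC| ≥ 1; RNA-seq: Tukey post
  hoc p < 0.05 and |log2FC| > 1, after an omnibus gate),
- rescue: `g4_vs_g3` significant (FDR ≤ 0.05, or post hoc p < 0.05 on
  the RNA-seq path),
- reversion: the two fold-changes have opposite signs,
- (RNA-seq only) omnibus gate: BH-corrected ANCOVA group p < 0.05.

The rule is a pure conjunction, so condition order is irrelevant; the
classifier always emits the per-condition trace for audit. The two
platform presets differ deliberately at the thresholds' boundaries
(inclusive on the microarray path, strict on the RNA-seq path) to match
the two rule lists as printed. The rescue contrast carries no fold-change
magnitude requirement in either preset; a `abs_log2fc_min_rescue` knob
exists for sensitivity analyses.

`dependence_fraction` reports the share of stress DEGs that are
dependent, the quantity used to compare models/tissues.

## Differential statistics

**Microarray path.** Per-gene one-way ANOVA on the two contrast groups
(equivalently a pooled-variance t² with two groups), BH-adjusted across
all genes in the table, per contrast. No variance moderation is applied
(the generating software's internal moderation, if any, is undocumented);
this is recorded as an approximation and exact replication of archival
DEG counts is not promised.

**RNA-seq path.** Per-gene additive ANCOVA `Expression ~ Group + Sex`
fitted by least squares, vectorized over genes with one QR decomposition
per design matrix. The group test is the Type II F (model comparison
against the sex-only reduced model — identical to Type II sums of squares
since the model has no interaction). With the covariate dropped
(`include_sex=False`) the same machinery *is* the 4-group one-way ANOVA;
this nesting identity is exact and is checked against an independent
oracle. Note that with the covariate *in* the model the group F cannot
equal the one-way F even when the fitted sex effect is zero — the
residual df differ (n−5 vs. n−4) — which is why the identity is stated
for the nested model. In balanced designs the group sum of squares is
identical either way (factor orthogonality), which is asserted
separately.

Post hoc testing is Tukey HSD on the sex-adjusted group means: q = |Δ| /
(SE/√2) with Tukey–Kramer SEs from the pooled residual MSE and the
model's residual df, referred to the studentized-range distribution. This
approximates the single-step max-t procedure of R's `glht/mcp(Tukey)`;
for balanced designs the difference is negligible. Because the exact
studentized-range tail costs ~20 ms per evaluation, genome-wide calls use
log-linear interpolation on a cached 201-point grid per (k, df)
(relative error ≲ 3×10⁻³; batches of ≤ 64 values are evaluated exactly).

**Feature tables** (proteomics/metabolomics) use two-sided Student or
Welch t-tests with BH across all features. Zero-variance degenerate
inputs get deterministic p-values (1 when means agree, 0 otherwise) with
a logged warning rather than NaN propagation.

BH adjustment delegates to the standard step-up implementation and is
verified against a brute-force oracle computed straight from the
definition.

## Normalization chain (RNA-seq path)

Order: gene-length normalization (reads per kilobase) → counts per
million → pedestal (+2) then log2 → cyclic loess → noise model. The
pedestal stabilizes zeros (log2(0+2) = 1) and compresses Poisson noise at
low counts. The microarray path skips this module entirely; microarray
inputs enter downstream already log2-scaled by their platform pipeline.

**Cyclic loess.** For every unordered sample pair, a lowess trend of
M = xi − xj on A = (xi + xj)/2 is fitted; each sample moves half the
fitted trend toward the other. All pairwise trends within a cycle are
fitted against the cycle's starting matrix and applied together (averaged
over each sample's n−1 pairs), which makes one cycle a single balanced
correction per sample, preserves the grand mean exactly, and makes the
result equivariant under sample permutation. One cycle removes a global
pairwise offset completely in the two-sample case; with more samples the
averaged step is damped and additional iterations converge toward the
common trend. Span defaults to 0.3; iterations to 1.

**Noise floor/ceiling.** Per group, genes are ranked by group-mean
expression and a lowess trend of mean vs. rank is fitted (monotonicity
enforced by a cumulative maximum). A straight line is fitted to the
central rank band (25th–75th percentile by default); ranks below the band
where |trend − line| exceeds the tolerance (default 0.5 log2) mark the
noise regime. The floor cutoff is the trend value at the end of the noise
plateau — the highest deviating rank whose trend value is still within
tolerance of the plateau level. Placing the cutoff at the plateau end
rather than at the last deviating rank matters: the last deviating rank
sits on the smoothing-dependent transition into the signal range, and its
value varies with the random interleaving of noise and signal genes,
whereas the plateau end tracks the floor itself. The ceiling is handled
symmetrically above the band. If no rank deviates, the floor defaults to
the smallest observed group mean and the ceiling is absent (both inert).
Cutoffs combine conservatively across groups (highest floor, lowest
ceiling) so no group's noise regime leaks through. Values below the floor
are clamped to it; genes with no sample above the floor are removed as
noise-biased (ceiling symmetric). Flooring is idempotent.

Resolving a floor block requires a lowess window narrower than the block:
with span s and G genes the window is sG genes, so a block occupying
fraction f of the genome needs s < f. The planted-floor tests therefore
fit the trend at span 0.1 for a 20 % block; the chain default stays 0.3.

## Synthetic data

The generator emulates the study design, not any particular dataset. Per
gene the log2 mean model is

    mu(g, s) = baseline + effect·[stressed] − effect·reversion·[g4]
               + sex_effect·[male]

with classes: `dependent_up/down` (|effect| = 2.0 log2 by default,
reversion fraction 1.0 — full reversion; a continuous fraction lets tests
probe the decision boundary), `stress_only` (reversion 0), `ko_only`
(effect loads on the knockout groups instead), `null` and `floor_noise`
(baseline below the detection floor, no effects). Null and floor genes
carry no effects of any kind, including sex effects; sex effects
(N(0, 0.5) on a random 20 % of effect-carrying genes) model the
observation that some stress-responsive genes are sex-modulated while the
dependence pattern itself is sex-consistent. Class counts follow
largest-remainder rounding for exact reproducible totals.

Intensity simulation adds N(0, noise_sd) noise (default 0.25 log2);
within-group variance is a calibration choice — no platform variance is
published for this design. Count simulation draws negative-binomial
counts (variance m + φm², φ = 0.05 by default; φ = 0 degenerates to
Poisson) around expected counts proportional to abundance × gene length,
scaled to the library size (2×10⁶ by default), so the length-normalization
stage is exercised non-trivially. Gene lengths are uniform on
200–10 000 bp. `simulate_multi_model` plants an identical (same-sign)
dependent core across k models plus per-model private dependent genes,
with per-model seeds spawned from one seed sequence.

What the generator does **not** model: read-level sequencing artifacts,
probe effects, batch structure beyond sex, correlated genes, composition
effects, or gradual (non-censored) detection floors. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure under idealized noise — not
performance on any archival dataset.

## Tunable parameters

| knob | default | units | where |
|------|---------|-------|-------|
| pedestal c | 2 | linear CPM | `pedestal_log2` |
| loess span | 0.3 | fraction of genes | cyclic loess, noise trend |
| linearity tolerance | 0.5 | log2 | `fit_noise_model` |
| central band | 25th–75th pct | ranks | `fit_noise_model` |
| cyclic-loess iterations | 1 | cycles | `cyclic_loess` |
| stress FDR / post hoc p | 0.05 | — | dependence presets |
| stress \|log2FC\| | 1 | log2 | dependence presets |
| ANCOVA gate (group FDR) | 0.05 | — | rnaseq preset |
| mean fold-change filter | > 2 | linear | `cross_study_signature` |
| effect size / reversion | 2.0 / 1.0 | log2 / fraction | generator |
| noise_sd / dispersion | 0.25 / 0.05 | log2 / NB φ | generator |

## Design choices where the design was open

- Enrichment universe defaults to the genes surviving detection/filtering
  in all contributing datasets, not the whole genome.
- Direction consistency is required for the core signature (concordant
  fold-changes across models); a flag can disable it for plain Venn
  counting.
- Cross-study mean fold-change is arithmetic on the linear scale;
  geometric is available.
- Gene identifiers are opaque case-sensitive strings; species conventions
  are handled only through the explicit ortholog map.
- TSV is the canonical table dialect (UTF-8, "." decimal); `"null"` is a
  valid class label, so truth tables are read with NA detection disabled.
- `generate_design` layouts are fully determined by the balance rule
  (sexes split to parity, majority sex alternating by group index for odd
  n); the seed parameter exists for interface uniformity.

## Problem sizes

The bundled demo and the acceptance computations use 2 000-gene genomes,
n = 4 per group, 3 models, and 5 seeded replicates for the recovery
statistics; the null-calibration run uses 10 000 genes. These sizes give
stable statistics (binomial SE ≈ 0.002 on the type-I fraction) while the
whole suite plus acceptance script completes in well under a minute.

## Known limitations

- No empirical-Bayes variance moderation; with n = 4 per group the
  per-gene variance estimates are noisy and real-data sensitivity will
  trail moderated pipelines at the same thresholds.
- The Tukey approximation to the max-t single-step procedure is exact
  only for balanced designs; unbalanced designs use Tukey–Kramer.
- The noise-floor model assumes a censored (saturating) detection floor;
  gradual compression yields conservative cutoffs.
- The dependence rule is binary by design; "partially reverted" grades
  are out of scope.
- Reported enrichment p-values depend strongly on the universe choice;
  archival universes are generally unrecoverable, so cross-paper p-value
  comparisons are qualitative.
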