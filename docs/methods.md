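# Methods

## Scope and conventions

`fragdecipher` analyzes fragment-level cfDNA data: every record is a
genomic interval (chrom, start, end) in BED 0-based half-open coordinates,
with length `end - start` and position summarized by the midpoint. Strand
is ignored (fragments, not reads). The global length filter is 100–220 bp
inclusive at both ends, matching the 5-bp size bins that end at 219 bp.
BAM input (proper pairs, MAPQ ≥ 30, leftmost-mate template length) is
optional; BED is the canonical interchange format. Library-level QC
statistics of the sequencing protocol (insert-size window, minimum depth,
duplicate rate) are recorded as documentation only and are not applied as
fragment filters.

## Copy-number features

The genome is tiled into uniform bins taken from the genome model (not
hard-coded), fragment midpoints are counted per bin, and counts are
normalized to proportions `r_t` (so total depth cancels). The baseline
`h_t` is the per-bin median of a healthy panel's proportions, renormalized
to sum 1; bins with zero median are unusable and stay masked (NaN, never
±inf). The bin-level feature is `l_t = log2(r_t / h_t)`; the model
additionally receives per-arm means over the canonical 39-arm vocabulary.
An optional smoother assigns {loss, neutral, gain} by a Viterbi path with
Gaussian emissions at means (−μ, 0, +μ), shared σ, and symmetric
stay-probability transitions (defaults μ = 0.3, σ = 0.15, stay = 0.99 —
chosen so a single-bin excursion does not open a segment). Missing bins are
bridged by the transition matrix and inherit the carried state. This is a
deliberate simplification of full copy-number callers: no GC/mappability
correction by default (a hook accepts an external GC track with
median-by-decile normalization), no tumor-fraction or ploidy estimation.

## Fragment-size-distribution features

Lengths 100–219 bp are binned in 24 five-bp intervals per arm; per-arm
counts are divided by the arm's in-range total (a per-genome denominator is
available as an option). The 936-entry vector (24 × 39; arms absent from a
scaled model occupy zero slots so the schema is fixed) is then z-scored
over the full vector within the sample, using the population (n)
standard deviation; a constant vector maps to zeros. Within-sample
normalization is deliberate: it makes the features independent of any
cohort-level reference and therefore portable across datasets.

## Promoter fragmentation entropy

For each gene the fragment-length histogram over the TSS ± 1 kb window is
collected at 1-bp resolution on the 100–220 bp support (121 cells). The
prior is the pooled, normalized histogram from regions 750 bp–1 kb up- and
downstream of each nucleosome-depleted region (NDR) — flanks where
nucleosome protection is regular regardless of promoter activity. Five
control entropies come from five independent draws of 20 genes (without
replacement) from a 330-gene background set; each repeat pools the genes'
promoter fragments and takes the Shannon entropy (natural log; the base
cancels in the ratios below) of the pooled distribution.

**Control size matching.** The plug-in entropy of an empirical histogram is
biased downward by an amount that grows as counts shrink. A 20-gene pool
holds roughly 20× the fragments of one gene, so at ~5× depth (~60 fragments
per promoter window) an unmatched control entropy exceeds every gene-level
entropy for bias reasons alone and the score degenerates to exactly zero
for all genes. Each pooled control histogram is therefore subsampled
without replacement (multivariate hypergeometric) to the median per-gene
promoter fragment count before the entropy is taken, putting both sides of
the ratio on the same bias scale. `PFEConfig(control_size_match=False)`
restores the unmatched computation.

The gene score: with prior weight W = 20, the Dirichlet parameter is
`alpha = W * p_prior + counts`; 2,000 draws are taken (cells with zero
alpha remain at zero via the standard-gamma construction); draw *j* with
entropy `E_j` forms ratios `q_ij = E_j / control_i` and contributes
`F_Gamma(min_i q_ij − 1)` if `min_i q_ij > 1`, else 0, where `F_Gamma` is
the Gamma(shape 0.5, rate 1) CDF — the probability that a single shared
margin `k` satisfies all five `q_ij > 1 + k`. The score is the mean
contribution, a value in [0, 1]. The closed form follows from the shared-k
reading of "all five ratios exceed 1 + k"; an independent-k variant (the
product of per-ratio CDF terms) is available via `shared_k=False`. The
closed form is verified against a 10^6-draw Monte-Carlo oracle in the test
suite.

Gene scores are z-normalized across genes within each sample (missing
genes excluded and left missing; imputed as 0 — the post-normalization
sample mean — only when building model matrices). Feature selection runs
on the training cohort only: two-sided Wilcoxon rank-sum per gene (exact
null when both groups ≤ 12, otherwise normal approximation with continuity
correction), keeping genes with p < 0.01 and a positive cancer-minus-
non-cancer mean difference. The `pfe_summary` helper exposes the mean of
the selected normalized features as an integrated per-sample score.

## Ensemble risk model

Per feature family, a randomized search draws candidates across
regularized logistic regression, gradient-boosted trees, random forests,
and logistic stacked combiners over random subsets of the other
candidates' cross-validated predictions (about 15% of the candidate
budget). Every candidate is evaluated by stratified 5-fold cross-validation
with fold membership derived from a SHA-256 hash of (seed, sample id) —
reproducible and independent of row order — and its out-of-fold (OOF)
predictions cover each training sample exactly once. Candidates are ranked
by OOF AUC (ties broken by candidate id), the top K = 10 per family are
refit on the full training set, their mean probability is the per-family
score, and the risk score is the equal-weight mean of the three family
scores. The default search budget is 30 candidates per family — a
desk-scale surrogate for a large AutoML sweep that preserves the
search → rank → average architecture; all counts are configurable upward.
Validation predictions always come from the refit models (the simplest
leak-free reading); OOF predictions are used only for ranking and for
fixing the decision cutoff, which is the largest threshold whose training
OOF sensitivity is at least the target (default 0.95) — maximizing
specificity among feasible thresholds by construction. `predict` refuses
sample ids seen in training unless explicitly told the OOF-vs-refit
distinction is understood (`allow_training_ids=True`).

## Evaluation statistics

AUC uses the Mann–Whitney pairwise formulation (ties ½) with
DeLong structural-component variance; paired model comparison uses the
DeLong test with midrank tie handling. All proportion CIs
(Se/Sp/PPV/NPV/accuracy) are exact Clopper–Pearson. Prevalence-adjusted
predictive values follow Bayes' rule from fixed Se/Sp over a configurable
prevalence grid. The Wilcoxon effect size is r = |Z|/√N with a
within-group percentile bootstrap CI (2,000 replicates). Multiplicity uses
Benjamini–Hochberg. Calibration reports the Brier score, equal-width
reliability bins, and the intercept and slope of a logistic fit of labels
on logit(score) (scores clipped to [1e-6, 1−1e-6]); a single-class input
flags the fit degenerate. The Jonckheere–Terpstra statistic sums
between-group concordant pairs (ties ½) over ordered group pairs, with a
seeded permutation p-value (default 10^4 permutations) or a normal
approximation for large samples. Displayed tables round to 3 decimals.

## Depth-stability analysis

Within each label stratum, samples are merged (never across strata) into
composite references holding `target_multiple` (default 10) times the
nominal per-sample fragment count — the analogue of building ≥50×
composites from ~5× samples; on the scaled genome "depth" maps to fragment
count, which preserves all ratios. Each composite is randomly downsampled
to fractions {40, 30, 20, 10, 5}/50 and the entire PFE computation —
prior, controls, gene scores, normalization — is redone per depth (the
stricter reading; reusing the reference prior is available behind a flag
at the call level by passing precomputed inputs). Concordance is the
Pearson correlation between each depth's normalized gene-score vector and
the reference vector, genes missing at either depth dropped pairwise.

## Synthetic cohort generator

The generator defines the study conditions for all tests. Scaled genome:
up to 39 arms of 100 kb (1/1000 scale), 10 kb CNV bins, 14 genes per arm
with TSS every ~7 kb, NDR = TSS ± 150 bp, promoter window = TSS ± 1 kb.
Fragment lengths: mononucleosomal truncated normal(167, σ) on [100, 220]
plus a short uniform(100, 150) component with healthy weight 0.12 that
grows by `tumor_fraction × short_fragment_boost` (default boost 0.5).
Placement is uniform within arms, arm probabilities proportional to
`length × (1 + tumor_fraction × (copy_factor − 1))`; cancer profiles carry
recurrent gains (1q, 5p, 6q ×1.5) and losses (4p, 6p, 8p ×0.6) so the
copy-number family has a cohort-consistent signal.

Promoter biology: each gene has a baseline activity drawn once per genome
model from Beta(1, 3) (most promoters silent in the blood-derived cfDNA
background). At a promoter, a fragment is "disordered" — drawn uniformly
over the full 100–220 bp support, emulating nucleosome-free cleavage —
with probability 0.5 × activity (roughly the share of window fragments
touching the NDR at a fully open promoter), and otherwise mononucleosomal
with σ interpolating 4 bp (tightly phased nucleosomes at closed promoters)
to 12 bp with activity; non-promoter fragments use σ = 10 bp. The
tumor-marker gene set (30 genes, sampled from the lower 60% of blood
activities — tissue-specific genes largely silent in plasma) becomes
disordered with additional probability equal to the tumor fraction in
cancer samples; the 330-gene background control set is the lowest-activity
remainder, disjoint by construction. A tumor fraction of zero reproduces
the healthy generative law exactly. Benign-disease samples are healthy
plus an optional inflammation shift of the short-fragment weight (default
off). Stage maps to tumor fraction through a configurable table
({I: 0.02, II: 0.05, III: 0.12} × uniform(0.7, 1.3) jitter) without any
claim of clinical fidelity. Per-sample seeds derive from
`SeedSequence(master_seed, spawn_key=(sample_index,))`.

What the generator does **not** emulate: GC bias, mappability, sequencing
error, duplicates, real genome coordinates, inter-individual germline
variation, and the full breadth of real promoter chromatin states. Passing
tests therefore demonstrate correctness and internal consistency of the
statistics under a controlled generative model, not clinical performance.

## Problem sizes used by the test and acceptance runs

Unit tests run on a 12-arm × 6-gene model with 10–30 k fragments per
sample and 200–1,000 Dirichlet draws (assertions there do not depend on
draw-level precision). The end-to-end detection checks use 20 + 20
training and validation cohorts at tumor fraction 0.2 with ten candidates
per family. The depth-stability analysis and the acceptance script run at
the full default scale: 39 arms, 546 genes, 120 k fragments nominal
(~5× on the scaled genome), composites at 10× nominal, 2,000 draws.

## Measured depth-stability behavior and a known limitation

At the defaults above, the median Pearson correlation between PFE vectors
at the 5/50 fraction and at the composite reference is ≈ 0.85 (the
40/50–20/50 fractions sit well above 0.95). The limiting factor is
irreducible: ~60 fragments per promoter window at the lowest depth give a
per-gene entropy sampling error of ~0.12 nats against a between-gene
entropy spread of ~0.35–0.4 nats under this generator, and correlation
attenuates accordingly. Real promoter chromatin spans a wider
entropy range than a defensible synthetic model, so concordance on real
data can exceed what the generator supports; the generator's disorder
parameters were fixed from the mechanistic arguments above and are not
inflated to close this gap.

## Numerical choices and degenerate inputs

Entropy uses 0·ln 0 = 0. Zero-alpha Dirichlet cells stay at exactly zero.
Z-scores of constant vectors are zero vectors. Empty BED files give empty
fragment sets; inverted records are counted and dropped; malformed lines
raise with their line number. Midpoints exactly on a half-open interval
boundary belong to the next interval. AUC ties count one half; exact AUC
ties in model ranking resolve to the lower candidate id. `log2(0/h)` is
reported missing rather than −inf. All stochastic steps take explicit
seeds and replay bit-identically.
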