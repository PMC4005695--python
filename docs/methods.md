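# Methods

This note documents the models, parameter choices and numerical conventions
behind `seq2abundance`, and what the synthetic-data tests do and do not
establish about real data.

## Regions and filters

Gene coordinates are read 1-based inclusive (GenBank / GFF3); all internal
slicing is 0-based half-open.  The translation initiation region (TIR) is
the 55-nt window −25..−1, +1..+30 where **+1 is the first base of the start
codon and there is no position 0**; the upstream convention is configurable
because published definitions vary on whether +30 counts from the start
codon's first base.  The CDS runs start through stop codon inclusive.  On
the minus strand all coordinates are interpreted on the reverse complement;
on circular contigs the upstream window wraps across the origin (verified
by a rotation round-trip test).  Genes with fewer than 25 nt of upstream
sequence on a linear contig, or CDS shorter than the 30-nt in-CDS window,
are skipped with a warning rather than padded.

Aberrant genes are removed when the CDS length is not a multiple of 3
(frameshift), the start codon is outside the allowed set (default {ATG,
GTG, TTG}, configurable), or an in-frame stop precedes the terminal codon.
The expression outlier filter regresses z(log10 protein) on z(log10 mRNA)
and removes genes with |residual| > 3 residual standard deviations; log10
space is used because abundances span orders of magnitude.

## RNA energetics

The folding engine computes the minimum-free-energy *nested* structure by
dynamic programming under a deliberately simplified nearest-neighbor model:
stacking energies for adjacent base pairs (Watson–Crick + GU), a
hairpin-loop penalty increasing with loop length, and no penalty for
internal/bulge/multibranch loops.  `min_hairpin = 3`; lonely pairs are
allowed.  The parameter set is a constructed, versioned table
(`data/energy_params.tsv`, kcal/mol) with magnitudes in the range of
published stacking parameters; it is **not** the Turner/UNAfold set.  The
rationale is a fully specified, desk-scale model that an exhaustive
structure enumerator can verify exactly (the test suite checks DP =
enumeration over hundreds of short random sequences); an expert can swap in
any complete table with the same schema, and an external-folder adapter can
replace the engine entirely — downstream feature names and types are stable
under an engine swap.

The hybridization engine finds the minimum-energy antiparallel duplex
between a target and a probe (no intramolecular pairs), allowing bulges and
internal loops of up to 3 nt per strand at a cost of 3.0 + 0.5/nt.  Its
energy decomposes exactly as `dg_total = dg_duplex + dg_exterior +
duplex_init` (init = +4.1).  The *exterior loop* term is defined here as
the sum of dangling-end contributions of unpaired bases immediately
flanking the duplex on both molecules; this is an explicit stand-in for the
exterior-loop decomposition of full-featured folders, which is not publicly
specified.  If no duplex achieves `dg_total < 0` a sentinel is returned and
the three energy features are later imputed with the column median — the
design matrix stays complete without inventing energies.  The anti-SD probe
defaults to the 13 3'-terminal nucleotides of *E. coli* 16S rRNA
(5'-GAUCACCUCCUUA-3'), configurable.

## The feature catalog

The manifest is fixed at 107 features: 16 TIR (SD PWM best score/position/
spacing, deviation from the 7-nt optimal spacing, four hybridization
quantities, fold ΔG, accessibility in the window −4..+16 around the start,
unpaired count, three start-codon indicators, motif count above a 0-bit
threshold, and an external-initiation-score pass-through column defaulting
to 0) plus 91 CDS (61 sense-codon frequencies, 20 amino-acid frequencies,
CAI, tAI, AT/A/GC/GC3 content, protein length, three stop-codon
indicators).  The authoritative published feature list is not available;
this manifest is a reconstruction constrained by the documented feature
families, and its size (and the 108-predictor design table including log10
mRNA) is enforced by test.  PWM scoring is `Σ log2((f + pseudocount) /
background)`; spacing counts the nucleotides between the motif's last base
and the start codon's first base.  CAI is the geometric mean of
within-family relative adaptiveness (zero-count codons floored at 0.01),
excluding stop and the single-codon families ATG/TGG; tAI weights follow
the dos Reis construction from tRNA gene copy numbers with wobble penalties
(s = 0.41/0.28/0.9999/0.68 for G:U, I:C, I:A, U:G readings), zero-coverage
codons receiving the geometric mean of the rest.  The shipped SD PWM and
CAI reference counts are constructed, consensus-based stand-ins
(documented in the files); the tRNA copy numbers are approximate
representative values.

## Regression, cross-validation, selection

Predictors and response are z-scored with the population-sd (divide by n)
convention; in standardized space the intercept is 0.  PLS1 components are
extracted by NIPALS with deflation; at full rank the coefficients equal the
OLS normal-equation solution, which is the central correctness oracle
(checked to 1e−8 on random instances, and against scikit-learn).
Cross-validation uses a seeded random partition into k = 10 near-equal
folds, standardizes within the training part of each fold only (no
leakage), and pools held-out predictions for R².  The component count is
the smallest A whose CV R² is within 0.002 of the maximum over A =
1..min(15, rank).  Jackknife standard errors treat the k fold-wise
coefficient vectors as delete-a-group replicates: `se = sqrt(((k−1)/k) Σ
(β_i − β̄)²)`.

Backward elimination repeatedly proposes removing the predictor with the
smallest |β|/se (ties: smaller |β|, then name), accepts when CV R² drops by
at most tol = 0.002, shields rejected candidates for the pass, and stops
when nothing can be removed.  One predictor is removed per step for
auditability; the component count is re-chosen after every removal.
Constant (zero-variance) predictors are dropped up front as ordinary
removals.  `mrna_level` is not protected by default, but the config allows
protecting any predictor set.

## Contributions, shares, noise

For a linear model the prediction splits exactly into group sums
`Σ_{i∈g} βᵢ xz_i`; this identity (to 1e−10) defines the per-gene mRNA /
TIR / CDS contributions, the model's transcription estimate (mRNA term) and
translation-efficiency estimate (TIR + CDS).  Variance attribution uses the
normalized covariance decomposition: raw_g = `Σ_{i∈g} βᵢ r(xz_i, yz)`,
rescaled so the shares sum exactly to the model R²; under orthogonal
predictors this reduces to per-predictor r², which motivated the choice
since the published attribution method is unstated.  A sequential-R²
alternative is available behind a flag for sensitivity analysis.  Negative
raw covariance terms are possible and flagged.  Abundance and noise groups
use linear-interpolation quartiles with boundary ties assigned to the
middle group.

The noise differential sorts genes by mean abundance and subtracts the
median CoV within a centered rank window (default 51, odd, truncated at the
edges — the cited running-median procedure does not state a window).  The
Mann–Whitney test returns U = min(U_a, U_b) with midrank ties; for pooled
n ≤ 12 the two-sided p comes from exact enumeration over all group
assignments, otherwise from a normal approximation with tie and continuity
corrections.  Partial correlations use the standard first-order formula
(Spearman: after midrank transform) with p from a t statistic on n−3 df;
when the controlled variable is collinear with either argument the value is
0 by convention.  BH-FDR is the step-up adjustment with monotonicity
enforcement; significance stars at 0.05/0.01/0.001.

## The synthetic generator

The generator realizes exactly the structure the analysis assumes, with the
coupling injected **through the realized sequences** — the features entering
the planted linear model are the ones the catalog computes from the
generated genes, so extraction, folding and scoring are all on the tested
path.  Per gene: a latent level e ~ N(0,1); protein length lognormal around
150 codons (60–400); amino acids from a fixed bacterial-like background;
codons from a mixture (1−m)·uniform-synonymous + m·preferred with m =
logistic(1.2 e); an SD hexamer drawn from the PWM blended with uniform
background at weight logistic(0.6 e + 0.8), at spacing Uniform{4..12};
genes placed on both strands with 30-nt spacers.  mRNA is log-normal with
latent correlation 0.6; z(log10 protein) = Σ β xz + ε with ε ~ N(0, 0.55).
The default 16 active predictors put β = 0.55 on mRNA and 0.25 on CAI, with
fourteen further effects |β| ∈ [0.10, 0.15] placed on mutually weakly
correlated features (non-preferred codons, amino acids from disjoint
families, independently drawn TIR spacing/fold/length/stop properties) so
each active carries identifiable marginal signal; protein means span
roughly 1–10⁴ molecules per cell.  Single-cell noise follows CoV =
sqrt(a/µ + c0) + δ_g with a = 1, c0 = 0, planted offsets δ = 0.3 on the 10%
of genes with the most extreme low-transcription/high-translation contrast
(z-scored and balanced), plus gene-specific scatter N(0, 0.05) on the CoV
scale — without that scatter, the running median is contaminated by the
planted cluster and the low-noise quartile degenerates to the planted
genes' abundance-neighbors, an artifact no real dataset shows.

What passing these tests shows: every algorithmic stage is correct against
independent oracles, and the pipeline recovers planted structure under the
model's own assumptions at realistic effect sizes.  What they do not show:
that real expression data satisfy those assumptions — linearity in z-scored
features, Gaussian residuals, an exact inverse-mean CoV law, or feature
manifests matching any particular published list.  Real-data runs (GenBank
or FASTA+GFF3 genome plus an expression TSV) are supported as an input mode
but carry no synthetic guarantees.

## Problem sizes and runtime

Recovery tests use the generator's stated conditions (n = 800 genes, 5
seeds; n = 1000 for noise recovery); oracle tests use 100–200 random
instances at the sizes where enumeration is exact (sequences ≤ 12 nt,
pooled samples ≤ 12, p ≤ 10 predictors).  The full suite runs in ~30 s and
the acceptance script in ~10 s on one CPU.

## Known limitations

- The energy model is a teaching-grade parameterization: no
  internal/bulge/multiloop penalties in unimolecular folding, no
  temperature dependence, no partition function or suboptimal ensembles.
- The exterior-loop definition (dangle sum) is a stand-in for the
  unpublished decomposition used with full-featured folders.
- tAI wobble handling ignores organism-specific tRNA modifications and the
  initiator/elongator Met distinction.
- The backward-elimination path is greedy; it audits one removal per step
  and does not explore alternative subsets.
- Variance shares are one of several defensible attribution schemes; the
  covariance decomposition is exact in aggregate but can assign small
  negative raw terms to suppressor-like groups.
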