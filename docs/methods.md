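# Methods

## Background and scope

`sortmave` implements the computational pipeline of a sort-seq multiplexed
assay of variant effect (MAVE) for the extracellular domain of the human
insulin receptor (INSR, isoform B; preproprotein residues 28–955, numbered
1-based with the signal peptide included). In the assayed system every cell
carries a single barcoded receptor variant; cells are FACS-sorted into four
fluorescence bins per assay (insulin or anti-receptor antibody binding, and
insulin- or antibody-stimulated AKT phosphorylation), barcodes are sequenced
per bin, and function scores are inferred from each barcode's distribution
over bins. The package takes barcode-level bin counts and a barcode–variant
map as input; it does not perform read alignment, long-read consensus
calling, or any wet-lab-adjacent processing beyond exact-match barcode
counting.

## Library design arithmetic

The mutagenised region spans 928 codons. Each codon is replaced with the NNS
degenerate codon (N = A/C/G/T, S = G/C): 32 codons encoding all 20 amino
acids plus exactly one stop (TAG; TAA and TGA end in A and are excluded).
Oligo pools cover 20 sequential codons each, giving ceil(928/20) = 47 pools.
Per position the possible protein-level outcomes are 19 missense plus 1
nonsense, i.e. 20 × 928 = 18,560 single variants over the region.

Barcode hygiene: barcode pairs within Hamming distance 2 that are assigned
to *different* variants are treated as conflicts (a distance-1 pair is a
fortiori conflicting). The member with the higher long-read (CCS) support is
retained; on a support tie both are dropped — the conservative choice, since
the underlying tie-break is not determined by the data. The rule operates on
the map only and is idempotent.

## Synthetic sort-seq generator

The generator exists so that every downstream stage can be tested, end to
end and with known ground truth, without external sequencing data. It is a
first-class, tested module, not a fixture.

Model, per (assay, replicate):

* each variant `v` has a latent effect `e[v, assay]` on an arbitrary linear
  fluorescence scale with the wild type at 0;
* each barcode tags a clonal population of `Poisson(cells_per_barcode_mean)`
  cells (default 400, of the order of the cells-per-barcode implied by
  ~13 M sorted cells per bin over ~10^5 barcodes in a full-scale screen),
  scaled by a per-variant abundance multiplier;
* cell fluorescence is `Normal(e, cell_noise_sd)` (default sd 1.0); cells
  fall into four bins at three gates, by default the quartiles of the WT
  distribution (gate placement in a real sorter is instrument-specific, so
  quartile gates are the neutral default). The per-barcode bin allocation is
  drawn as a multinomial with the Normal-CDF gate probabilities, which is
  distributionally identical to simulating each cell;
* sequencing draws exactly `reads_per_bin` reads per bin (default 100,000),
  multinomially over barcodes in proportion to sorted cell counts. This
  matches the per-bin normalisation of the scoring model; an optional
  Dirichlet-multinomial switch adds PCR-style overdispersion but is off by
  default.

Effect mixture: a missense variant is loss-of-function with probability
0.32 and gain-of-function with probability 0.07 — the per-assay proportions
of function-decreasing and -increasing variants observed in the full-scale
screen — with effect magnitudes uniform on [−2.5, −0.5] and [0.3, 1.0]
respectively. The ranges are chosen to span the dynamic range of the
four-bin readout: with weights 0.25…1 the barcode score is bounded, so the
variant score (log2 ratio to WT) cannot fall below ≈ −1.32, and latent
effects far beyond the bottom gate are indistinguishable from one another by
construction. Class membership is drawn once per variant and shared across
assays (a poorly expressed variant is poor in every readout); magnitudes are
redrawn per assay.

Stop codons: in the assayed construct the resistance marker sits downstream
of the receptor ORF, so truncating clones are largely removed by antibiotic
selection yet a minority persist (read-through). The generator models this
as an abundance multiplier of 0.05 rather than 0, so stop-codon barcodes are
globally read-depleted but not absent.

Planted controls mirror the study's validation variants: A119V and S350L
lose function in every assay (expression-loss); D734A loses insulin binding
and insulin-stimulated signalling only, with intact surface expression and
antibody responsiveness. The wild-type residues at the three control
positions are pinned in the otherwise pseudo-random synthetic WT sequence so
the control variant identifiers exist in any region covering them.

Determinism: one global seed; per-(assay, replicate) substreams are derived
via `numpy.random.SeedSequence` with a CRC32 of the assay label (Python's
builtin `hash` is salted per process and unusable for reproducibility).
Identical seeds reproduce count tables byte for byte.

What the generator does **not** emulate: PCR jackpotting (unless the
overdispersion switch is used), barcode-level abundance skew from cloning
bottlenecks, sorter impurity/spillover between bins, index hopping, and any
structure-mediated correlation between positions. Passing tests therefore
demonstrate the correctness and statistical behaviour of the *analysis*
under a clean generative model, not the robustness of the assay itself to
those artefacts.

## Scoring model

For one replicate of one assay, with counts `C[b, bin]`:

1. barcodes with `sum_bin C[b, bin] < 150` are removed (the read filter
   precedes everything else; frequencies are computed over retained barcodes
   only);
2. `F[b, bin] = C[b, bin] / sum_b C[b, bin]` — each bin column sums to 1;
   an empty bin raises an explicit degenerate-bin error;
3. barcode score `S_b = sum_bin F[b, bin] w_bin / sum_bin F[b, bin]` with
   weights (0.25, 0.5, 0.75, 1.0), hence `S_b ∈ [0.25, 1]`;
4. replicate variant score `S_v = mean_b(S_b | v) / mean_b(S_b | WT)`;
   the WT reference set is barcodes with unmutated or synonymous-only coding
   sequence (configurable to unmutated-only);
5. final score `S̄_v = log2(mean over replicates of S_v)` — the mean of
   ratios is taken first and the log second, implementing the aggregation
   formula literally rather than averaging log-ratios. A variant unscored in
   a replicate is missing there, and the mean runs over available
   replicates; per-analysis minimum-replicate filters default to 2 for
   binding/expression analyses and 3 for signalling analyses.

## Bootstrap FDR

Confidence that a variant differs from WT is non-parametric. All of a
variant's barcode scores across replicates are pooled (k observations);
`B_v = log2(mean of the k scores / mean of all WT barcode scores)`. The
printed form of the pooled statistic is a plain mean of barcode scores,
which is strictly positive and would make a sign-split FDR vacuous; the
estimator is therefore applied on the log2 WT-ratio scale, where 0 = WT and
the sign convention matches `S̄_v`. The null is 10,000 resampled sets of k
WT barcodes, drawn uniformly **with replacement** (standard bootstrap),
reduced to centred scores the same way; one null per distinct k, shared by
all variants with that k. Then

    FDR = N(B_wt < B_v) / N(B_wt < 0)   (B_v < 0)
    FDR = N(B_wt > B_v) / N(B_wt > 0)   (B_v > 0)

with a pseudocount of 1 replacing a zero numerator, FDR = 1 by convention at
B_v = 0, values clipped to 1, and a degenerate-null error if the null has no
mass on the relevant side. The estimator is monotone in |B_v| by
construction and is not an exact p-value; on fully-null synthetic libraries
the fraction of variants with FDR < 0.05 is bounded loosely (≤ 0.10) rather
than calibrated to 0.05.

## Expression-score merging

Cell-surface expression is read out by two anti-receptor antibodies (83-7,
83-14) with distinct epitopes. The expression score is the mean of the two
antibody binding scores, except at epitope residues, where mutating the
residue perturbs one antibody's binding independently of abundance: there
the other antibody's score (and FDR) is used alone. The epitope residue
list is configuration — in the original analysis it is a set of 16 residues
identified graphically from the two-antibody scatter, which cannot be
recovered from printed numbers — and a helper flags candidate outliers
(per-position median residual beyond a threshold) for users without a
curated list. The merged FDR away from epitopes is the maximum of the two
antibody FDRs (conservative). LoF/GoF calling uses an explicit score cutoff
(default log2(0.5), i.e. half of WT function) with FDR < 0.05; an extreme
score without FDR support is labelled low-confidence.

## Regional statistics

Scores from the two assays being compared are first ECDF-normalised
(average ranks / n, ties share the average), which removes the difference in
score ranges; note the transform is invariant to any monotone rescaling, so
only *regional* rank differences between assays are detectable, never a
global offset. Variants are paired by exact (position, substitution) match.
A one-sided Wilcoxon signed-rank test is applied in 15-residue windows,
stepping one residue, indexed by the window centre (the centre convention is
a documented choice; the alternative start-indexing shifts traces by 7
residues). Windows with fewer than five matched pairs are not tested;
zero differences are dropped before ranking (Wilcoxon's treatment; Pratt's
is available), and a window whose differences are all zero is omitted.

The signed-rank null is computed exactly for up to 25 non-zero pairs by a
dynamic programme over all 2^n sign assignments (valid under ties — average
ranks are doubled to integers), and by the Normal approximation with tie
correction and a 0.5 continuity correction above 25. Exactness matters at
the five-pair minimum, where the smallest attainable one-sided p is 1/32.
Runs of consecutive significant window centres (p < 0.05) are reported as
intervals.

## Selective sensitivity (antibody activatability)

Robust loss-of-insulin-signalling variants are those scored in all five
insulin-signalling replicates, with median replicate log2 score in the
lowest 80 % of the observed loss-of-function range, and scored in all
replicates of both antibody-signalling assays. "Lowest 80 % of the range"
is read as the span-based subinterval of [min median, 0) nearest the
minimum, i.e. median ≤ 0.2 × min; a quantile-based reading (the lowest 80 %
of negative medians by empirical quantile) is available via configuration
since the arithmetic is genuinely ambiguous. For each robust LoF variant
the selective sensitivity score is (antibody signalling score − insulin
signalling score) per antibody; a variant is called activatable when the
score strictly exceeds +0.204 (a value exactly at the threshold is not
activatable), and the two-antibody scatter is partitioned into quadrants at
that threshold.

## Biallelic diagnostics

Patient genotypes are two alleles; the per-assay patient score is the mean
of the two allele scores. Scored missense alleles use their empirical
score; extracellular truncating alleles (nonsense, frameshift, whole-exon
deletion) take a surrogate `truncating_score` — by default the lowest
high-confidence (FDR < 0.05) score in the assay at hand, since the original
anchor value is not printed and the parameter is deliberately explicit;
intracellular mutations take 1.5 × that surrogate (a punitive factor for
their dominant-negative behaviour). Composite scores are the sum and the
minimum over expression, insulin binding and insulin signalling, computed
per-assay-first (the alternative order of operations is not determined; this
one keeps per-assay tables inspectable). ROC analysis treats lower scores
as evidence for the pathogenic class; the AUC from the threshold sweep
equals the Mann–Whitney concordance probability with ties counted ½, which
the tests assert exactly against a pairwise oracle.

The synthetic cohort generator draws allele target scores around group
means ordered DS < RMS < TA < benign (defaults −1.2, −0.8, −0.45, 0 — kept
inside the assay's observable score range, see above) and picks the nearest
scored variant per allele. It exists to exercise the patient-level code
path and the severity-ordering property, not to model any clinical
distribution.

## Problem sizes and numerical choices

The default synthetic experiment — 500 variants × 2 barcodes, 35 % WT
barcodes, six assays with 3–5 replicates, 100,000 reads per bin, 10,000
bootstrap resamples — was chosen as the smallest configuration at which the
parameter-recovery and calibration properties are comfortably testable;
the full pipeline runs in a few seconds on one CPU. Spearman recovery of
latent effects at these defaults is ≈ 0.86–0.90; the ceiling is well below
1 because ~60 % of variants are true nulls whose recovered ranks are noise
by construction.

Ties and degenerate inputs: equal-support barcode collisions drop both
members; an all-zero frequency row, an empty bin, an empty WT reference and
a single-class ROC input all raise explicit errors rather than propagating
NaNs. FDR at B_v = 0 is 1 by convention. All randomness flows from
`numpy.random.SeedSequence` substreams of a single seed.

## Known limitations

* The generator's clean multinomial noise model understates real-data
  dispersion; FDR calibration on real libraries will be less tight.
* The epitope-exception residue list must be supplied; the outlier helper
  is a heuristic, not a reconstruction of the curated list.
* Enrichment-style alternatives (log-ratio regression across bins) are not
  implemented; the weighted-average estimator is the only scorer.
* Coordinates are amino-acid-level only; nucleotide-level phenomena
  (splice effects, codon usage) are out of scope.
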