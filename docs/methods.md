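# Methods

## Design under analysis

The pipeline targets a trio expression design: two parents (P1, P2) and
their F1 hybrid, profiled in multiple tissue contexts with biological
replicates, for one or more hybrids of a shared breeding program.  The
scientific question is which genes the F1 expresses unlike either parent
(candidate heterosis genes), whether F1 expression sits at the additive
expectation — the mid-parent value MPV = (P1 + P2)/2 — or deviates from
it, and how those genes relate to yield QTL intervals and whole-plant
heterosis.

## Differential expression model

Counts for gene *g* in sample *s* are modelled as negative binomial with
mean s_s·μ_g and dispersion α: var = μ + αμ².

**Normalization.** Median-of-ratios size factors: each sample's factor is
the median over genes of count/geometric-mean, computed over genes with
no zero in any sample.  If no such gene exists the estimator falls back
to total-count ratios (normalized to geometric mean 1) with a warning;
the fallback can be disabled.

**Dispersion.** A single common α per contrast, by pooled method of
moments: per gene, the within-group variance of normalized counts is
compared to the overall mean via α_g = (v − m)/m², and per-gene estimates
(clipped at zero) are combined by a 5%-per-side trimmed mean.  The trim
is deliberately light: the per-gene moment estimates are right-skewed at
2–3 replicates, and heavier symmetric trimming biases the pooled estimate
downward (measured against known simulation dispersions).  Common
dispersion (rather than per-gene shrinkage) is a deliberate
simplification: it is adequate and fully testable at three replicates,
at the cost of some power for genes whose dispersion is far from the
pooled value.

**Exact conditional test.** Normalized counts are rounded to integers
(half away from zero) and summed per group.  Conditional on the total
T = k_A + k_B, the distribution of the split under H0 (equal means) does
not depend on the mean: writing r_A = n_A/α, r_B = n_B/α,

    P(a | T) ∝ C(a + r_A − 1, a) · C(T − a + r_B − 1, T − a),

because the NB success probability is common to both groups and cancels.
At α = 0 this is the binomial conditional (Poisson) test.  The two-sided
p-value sums the probabilities of all splits whose conditional
probability does not exceed the observed one; a relative tolerance of
1e-8 in that comparison is part of the definition (it makes
mathematically tied splits — e.g. mirror splits in a balanced design —
count as ties regardless of floating-point rounding).  An all-zero gene
is reported with p = 1 and flagged untested.

**Calling.** BH adjustment across genes (position-stable, NaN
propagating); a gene is called at FDR strictly < 0.01 and
|log2 fold change| ≥ 1, where the fold change is computed on size-factor
normalized group means with a 0.5 pseudocount in numerator and
denominator.  The strict/inclusive boundary choices mirror the call
rule's wording ("< 0.01", "≥ 2-fold").  Fold changes can equivalently be
computed on FPKM ratios; normalized counts are the default because they
are what the test statistics see.

## Trio classification

Per (hybrid, tissue): DEG2P from P1 vs P2, DEGP1 from F1 vs P1, DEGP2
from F1 vs P2.  The F1-unique set uses the stricter of the two readings
of "unique to the F1":

* `both_parents` (default): DEGFu = (DEGP1 ∩ DEGP2) \ DEG2P — the F1
  differs from *each* parent while the parents do not differ from each
  other.  Under this rule DEGFu ∩ DEG2P = ∅ always.
* `either_parent`: DEGFu = (DEGP1 ∪ DEGP2) \ DEG2P, kept as a switch
  because published trio analyses are ambiguous between the two.

Tissue specificity ("-sp") keeps a gene only in the single tissue context
where it appears in DEGFu within a hybrid; genes in two or more contexts
are dropped from all of them (a pass-through switch disables this).

**Additivity.** Only DEGFu-sp genes are tested (the non-additive fraction
is reported relative to DEGFu-sp).  For each gene, a Welch t-test
compares log2(F1 normalized counts + 0.5) replicate values against
per-replicate-pair mid-parent constructs (P1_r + P2_r)/2 (logged the same
way), BH across the tested genes of a context; non-additive iff
FDR < 0.05 and |log2(F1/MPV)| ≥ 1, signed up/down, else additive.  The
0.05/1.0 thresholds parallel the DE call and are configurable — they are
a package convention, not an externally fixed constant.  A gene with all
F1 and mid-parent values zero is classified additive and flagged
uninformative.

## FPKM and replicate QC

FPKM[g, s] = counts × 10⁹ / (gene length × library size).  Replicate
quality is the Pearson correlation of log2(FPKM + 1) for every
within-condition replicate pair; pairs below r = 0.8 (strict) are
flagged, and zero-variance vectors are flagged with an explicit reason
rather than producing an undefined r.  The log transform and the fixed
pseudocount of 1 are implementation decisions chosen for stability at
zeros; the correlation type on raw published data is typically not
stated, and Pearson-on-log is standard practice.

## Heterosis statistics

MPH = (F1 − MP)/MP × 100, HPH = (F1 − HP)/HP × 100, MP the parental
average, HP the better parent under the trait's direction map (default:
larger is better for all yield traits; configurable per trait, since
"better" is trait-dependent for e.g. plant height).  Significance:
one-way ANOVA across {P1, P2, F1} plus Welch t-tests of F1 vs the high
parent (HPH) and F1 vs a mid-parent construct — per-replicate-pair
averages for sample input, mean (m1+m2)/2 with variance (s1²+s2²)/4 and
n = min(n1, n2) for summary input — flagged at 0.05 and 0.01.  Summary
and per-plant inputs agree to numerical precision on identical data.
Seasons are analyzed separately or pooled by concatenation; no mixed
model is fitted.

## QTL interval mapping

Coordinates are 1-based inclusive end to end (GFF3 convention); BED I/O
converts at the boundary, and chromosome names are matched
case-insensitively with optional `chr` prefix and zero padding removed.
The default overlap rule counts any shared base pair; full containment
is available.  Hits are grouped per QTL with gene lists and counts,
filtered to a trait list (the seven standard yield categories by
default), and the common set across hybrids/experiments is intersected
by QTL id with per-chromosome tallies.

## Annotation and enrichment

Keyword categorization is case-insensitive whole-word matching of
configurable keyword lists (defaults: kinase; synthase; NBS-LRR /
disease resistance / LRR receptor; transcription factor) over free-text
descriptions, multi-label by design.  Term over-representation is the
one-sided upper-tail hypergeometric test with BH across terms; no GO
graph propagation is performed, so results depend on the term-to-gene
table as supplied.

## qPCR quantification

The Livak 2^−ΔΔCt convention: replicates averaged on the Ct scale, ΔCt =
target − reference per (sample, gene), ΔΔCt against a required calibrator
sample, RQ = 2^−ΔΔCt; amplification efficiency is fixed at 2 (no
efficiency correction).  RQ is invariant to per-sample additive Ct
shifts and antisymmetric (in log2) under swapping sample and calibrator.
Concordance with RNA-seq is sign agreement of log2(RQ) with the log2
fold change over shared genes.

## Synthetic data generator

The generator emulates the two-hybrid, eight-tissue-context,
three-replicate design with NB counts.  Defaults (fixed as the package's
study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| genes | 2000 | desk-scale genome slice |
| mean counts | log10-uniform in [1.5, 3.0] | expressed-gene scale at which a 4-fold effect is identifiable with 3 replicates |
| dispersion α | 0.1 | typical biological replicate variability |
| replicates | 3 | matches the emulated design |
| planted effect | 2.0 log2 units | strong (4-fold) planted signal |
| class fractions | null .70, parent_diff .10, additive .04, f1_unique .06, nonadd_up .05, nonadd_down .05 | mostly-null transcriptome with a rich effect block |
| library-size factors | log-uniform [0.5, 2] | exercises normalization |
| shared across tissues | 0.1 | exercises the tissue-specific exclusion |

Class labels are allocated deterministically (largest-remainder), so
planted counts are exact; the effect block rotates between tissue
contexts with a controlled overlap fraction.  Planted structure per
class: parent-differential genes have a 2^e parent ratio with the F1
following P1 (dominance); additive genes have differing parents and
F1 = MPV exactly; F1-unique and non-additive genes have equal parents
with the F1 at MPV·2^(±e).  Because equal-parent F1-unique genes
necessarily deviate from the MPV by the same amount, they are labelled
as excluded from the additive/non-additive scoring truth — no
expression-level test can separate them from non-additive genes — and
recovery metrics omit them from the non-additive precision denominator.

What the generator does **not** emulate: read-level artifacts (mapping
bias, multi-mapping, positional coverage), per-gene dispersion
heterogeneity, correlated genes, batch structure, isoform switching, or
the actual mean-dispersion relationship of any real library.  Passing
recovery tests therefore demonstrates the correctness and calibration of
the statistical machinery under the stated model, not performance on any
particular real dataset.

## Recovery metrics

Recovery against the planted truth is scored per stage, matching each
operation's contract:

* **F1-unique membership**: DEGFu-sp sets vs genes planted with an
  F1-unique-like class in exactly one tissue context of the hybrid
  (genes planted in several contexts are unrecoverable by the
  tissue-specific rule by construction and are excluded from the recall
  denominator).
* **Non-additive up/down**: additivity calls vs planted non-additive
  genes among those that entered the tested (DEGFu-sp) set; the
  unconditional end-to-end product of both stages is reported alongside
  as `recall_end_to_end`.

At the default conditions the membership stage sits at its theoretical
power ceiling (a 4-fold effect at three replicates and CV ≈ 0.33 must
clear FDR < 0.01 in two contrasts simultaneously, ≈ 0.97 each), so the
end-to-end non-additive recall is the product of two ≈ 0.93 stages,
around 0.86–0.88 — the per-stage metrics are the meaningful calibration
checks, and both are reported.

## Numerical conventions

* Percent cells in summaries are rounded half-up to 2 decimals; empty
  denominators report an undefined (null) percent, never 0.
* All randomness flows from a single seed; pipeline stages derive
  sub-seeds by hashing `seed:stage` (folded below 2³¹), so adding a stage
  never perturbs another stage's stream.
* Degenerate inputs are explicit: zero library sizes, all-zero genes,
  zero-variance replicate vectors, zero parent means, and missing
  calibrators each produce a typed error or a flagged row, never a
  silent NaN.

## Known limitations

* The exact conditional test is mildly conservative for small totals
  (discreteness) and relies on the common-dispersion assumption.
* The Welch additivity test at three replicates is sensitive to single
  heavy-tailed NB outlier replicates; a moderated-variance test would be
  more powerful but is deliberately out of scope.
* Published trio studies do not always state which set rule, fold-change
  basis, or additivity thresholds they used; the defaults here are
  documented choices with switches, and per-tissue published summary
  cells can be reproduced only through the fixture arithmetic, not from
  the deposited reads.
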