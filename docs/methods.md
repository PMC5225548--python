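# Methods

## What the package computes

`riptargetkit` implements the computational arm of a RIP-seq study of an
RNA-binding protein (the motivating case is PCBP1, a poly(C)-binding
protein): starting from a gene × sample count matrix of IP, input and IgG
libraries, it identifies the protein's mRNA targets, characterizes the
target set by poly(C) motif-frequency enrichment and UTR length, and
validates enrichment with amplification-efficiency-corrected qPCR. A
synthetic-data generator with planted truth makes every stage testable
end to end without external data.

## Enrichment model

Libraries are depth-normalized with median-of-ratios size factors
(computed over genes with nonzero counts in every sample, rescaled to
geometric mean 1). Per biological replicate *i* the fold enrichment of
gene *g* is

    fold_gi = [(IP'_gi + c) / (input'_gi + c)] / [(IgG'_gi + c) / (input'_gi + c)]

on normalized counts with pseudocount c = 0.5 (which keeps fold = 1 for
all-zero genes and algebraically reduces to (IP'+c)/(IgG'+c)); the score
is the arithmetic mean across replicates. Significance is a per-gene
negative-binomial Wald test of the IP replicates against the IgG
replicates — the IgG mock pulldown is the null for bead background, input
enters only through the fold — with z = log2FC / SE(log2FC) and a
two-sided gaussian p-value, BH-adjusted over testable genes. A gene is a
target when mean fold ≥ 2 **and** adjusted p ≤ 0.05 (both boundaries
inclusive). The ranked target list is split into quartiles (quartile 4 =
top 25%, ceiling size), from which top/bottom-k validation panels and the
"high"/"low" 50+50 sets for UTR analysis are drawn; ties are broken by
adjusted p then gene id so every ordering is deterministic.

### Dispersion estimation

With 2–3 replicates a per-gene dispersion is barely estimable, so the
test uses a moderated method-of-moments estimator: per group,
α̂ = (v̂ − μ̂·mean(1/s_j)) / (μ̂² − v̂/n) with ddof = 1 variance (the
denominator correction removes the E[μ̂²] bias at small n), pooled across
IP and IgG, floored at 0.01, then shrunk 50% toward a 1%-per-tail trimmed
mean over all genes. The trimmed *mean* (not a median) is deliberate: the
per-gene estimator's distribution is strongly right-skewed at n = 3, a
median center underestimates the typical dispersion and makes the Wald
test anti-conservative (measured global-null type-I error ≈ 0.08 at
α = 0.05 versus ≈ 0.06 with the trimmed-mean center). The acceptance
suite verifies calibration by simulation (type-I within [0.03, 0.07] at
10⁴ genes, 3 vs 3, dispersion 0.1).

## Motif-frequency enrichment

Occurrences of the poly(C) element CTCCTCCTCCTCC and its companion string
GAGGAGGAGGAGG are counted as exact substring matches, overlapping by
default (the element has period 3; non-overlapping counting undercounts
long poly(C) stretches; a greedy non-overlapping mode exists). The
companion literal is the string conventionally reported with the element;
it is *not* the mathematical reverse complement (which is GGAGGAGGAGGAG)
— `MotifSpec(strict_rc=True)` searches the true reverse complement
instead. Characters outside A/C/G/T never match.

Per transcript, counts in the four features (spliced exon, concatenated
introns, 5'UTR, 3'UTR) are divided by transcript length (per-base
frequencies; feature-length normalization is a config option). Only
transcripts with all four features non-empty ("complete") are used, and
every complete transcript of a target gene inherits the gene's label.
The target set's frequency distribution is compared, per feature, against
R = 100 random transcript sets of equal size drawn without replacement
from the non-target ("general") transcripts, using a one-sided two-sample
KS test (alternative: target frequencies stochastically greater),
BH-adjusted across the R comparisons within each feature. Random sets are
drawn over transcripts, not genes, because transcripts carry the
features; the per-feature summary reports the mean adjusted p and the
count of comparisons with adjusted p < 0.05.

The KS statistic is D⁺ = sup over pooled points of
(ECDF_reference − ECDF_target), evaluated at pooled unique points so ties
are deterministic. For pooled sizes ≤ 16 the p-value is the exact
labeling-enumeration fraction; otherwise the classical one-sided bound
exp(−2 D⁺² nm/(n+m)), which is conservative — acceptable for a screen
whose null behaviour must never be anti-conservative.

## UTR-length comparison

Target UTR lengths (from the high+low enrichment sets) are compared to
the transcriptome-wide reference with a one-sided Wilcoxon rank-sum test
(targets greater), reporting medians and means for both sides. A
one-sample signed-rank test against the reference median is available as
an option; the rank-sum two-sample test is the default.

## qPCR validation

Technical-triplicate Ct values are averaged per gene and role. With
amplification efficiency AE ∈ (1, 2] (per-gene input; 2 = perfect
doubling), the input-referenced recoveries are
AE^−(Ct_IP − Ct_input) and AE^−(Ct_IgG − Ct_input); their ratio is the
IgG-normalized enrichment, and recovery × 100 is percent input (reported
both raw and IgG-corrected). Adding a constant to all Ct values of a gene
cancels exactly. Cross-platform consistency is the Pearson correlation of
log2 qPCR recovery versus log2 sequencing IP/input (mean replicate
(IP'+c)/(input'+c)) over the genes measured on both platforms.

## Synthetic-data generator

The generator emulates the study conditions and is the source of every
test dataset:

- **Annotation/sequence.** Each gene sits on its own chromosome with 1–3
  transcripts, each with ≥ 1 intron and non-empty UTRs. Feature lengths
  are log-normal (log-sd 0.8, a geometric spread of ≈ 2.2× typical of
  UTR-length distributions) with medians 160 nt (5'UTR), 607 nt (3'UTR),
  900 nt (CDS, rounded to codons), 300 nt (intron) — the UTR medians
  follow the mouse UTRome scale. Enriched genes carry longer UTRs
  (5'UTR × 258/160 ≈ 1.6, 3'UTR × 2881/607 ≈ 4.7, the published median
  regimes). Motif copies are planted as a Poisson process per segment
  (defaults: 0.3/kb in UTRs, 0.15/kb in CDS and introns, tripled to
  0.9/kb in the UTRs of enriched genes); the rest of the sequence is
  i.i.d. uniform A/C/G/T. Planted positions are recorded, but tests use
  *re-counted* occurrences as truth, so chance overlaps cannot bias
  recovery checks. Minus-strand genes are laid down reverse-complemented.
- **Counts.** Per gene a baseline abundance λ is log-normal (log-sd 1).
  Counts are negative-binomial (Gamma–Poisson, dispersion 0.1) with mean
  s_role · β_role · λ · F, where β = 0.02 is the background capture rate
  of the pulldowns, F = 4 for the 5% enriched genes in the IP and 1
  otherwise. The per-sample scale s is set from the *background*
  composition so each library's expected total matches its configured
  depth (2 × 10⁶), mirroring a sequencer run to target depth: β then
  cancels in expected counts, the expected per-gene IP/IgG ratio is
  exactly F, and IP totals exceed nominal depth by the planted enrichment
  mass (~15% at defaults). β still sets the qPCR percent-input scale.
- **qPCR.** Ct = C₀ − log_AE(relative abundance) + N(0, sd) in technical
  triplicate, with abundances reusing the same λ (input: λ; pulldowns:
  βλ, times F in the IP), so the AE-corrected IP recovery equals βF on
  average and the default Ct noise is sd 0.3 cycles.

All randomness descends from one seed through independent child streams
(annotation, counts, qPCR, gene selection), so each generator is
individually reproducible and a fixed seed reproduces every output file
byte-for-byte.

What the generator does **not** emulate: alignment and mappability
artifacts, GC/length bias, isoform-level quantification ambiguity,
overlapping gene loci, non-uniform background sequence composition, and
batch effects. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistical machinery under the
declared model, not robustness to those real-data complications.

## Problem sizes and numerical choices

The default study scale is 10,000 genes (≈ 20,000 complete transcripts),
3 replicates per role, 100 random sets — large enough that selection
sensitivity/FDR and motif recovery are statistically stable, while a full
pipeline run takes seconds. Tests use the same defaults (reduced gene
counts only where a property does not depend on scale). Degenerate inputs
are handled explicitly: all-zero genes are flagged untestable (p = 1,
log2FC = 0); size factors refuse matrices with no universally nonzero
gene and advise a pseudocount; empty samples, zero-length normalization
and oversized random-set requests raise validation errors. GTF
coordinates are converted to 0-based half-open at the I/O boundary and
CDS spans are taken exactly as annotated (no stop-codon extension), so
lengths are exact to the input file.

## Known limitations

- The NB test is a deliberate, explicit substitute for a full
  DESeq-style analysis: no dispersion trend fitting, no independent
  filtering, no moderated fold changes. Its contract is calibration
  under its own model, verified by simulation.
- The asymptotic one-sided KS p is an upper bound; with many tied zero
  frequencies the test is conservative.
- Gene-level counts are distributed to transcripts by label inheritance;
  the package does not quantify isoforms.
- Real-study headline counts (thousands of targets from whole-brain
  libraries) depend on data not shipped here; the package's claims are
  recovery and calibration on its own generator.
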