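# Methods

This note documents the statistical models, the decision rules and their
defaults, the synthetic-data generator, and the numerical choices behind
`endotx`.  The package targets the downstream half of a bulk RNA-seq
comparison — two conditions, three biological replicates each — and
consumes post-alignment artifacts only (counts, annotation, allele counts,
splicing-event tables, repeat intervals, coding-potential scores).

## Coordinates

All coordinates are 0-based half-open internally.  GTF I/O converts to and
from the 1-based inclusive GTF convention; variant positions and
user-facing `chrom:site` strings are 1-based (VCF convention).  Chromosome
names are compared as exact strings; no "chr" aliasing is applied.
Interval queries are served by an interval tree and are checked in the test
suite against brute-force linear scans.

## Differential expression

**Normalisation.** Median-of-ratios size factors: for sample *s*,
`f_s = median_g (c_gs / geomean_g)`, taken over features with nonzero
counts in every sample.  An error (advising a pseudo-reference fallback)
is raised when no such feature exists rather than silently degrading.

**Test.** Per feature, a Wald test on the log of the normalised group
means under NB sampling.  The dispersion α (var = μ + αμ²) is a
method-of-moments estimate pooled across the two groups with a floor of
1e-8; the delta-method variance of ln μ̂ is (μ + αμ²)/(nμ²) with μ floored
at 0.5 to keep low-count features finite.  The log2 fold change carries a
0.5 pseudocount.  All-zero features report log2FC 0, p 1.  BH adjustment
runs across all tested features.

With three replicates a moment dispersion estimate is noisy and the test
runs anti-conservative (empirically ~12% at nominal 5% on null NB data at
n = 3); at ten replicates per group it calibrates within Monte-Carlo error
(checked in the suite).  This is the motivation for the consensus design:
`consensus_de` intersects several methods' significant sets and requires a
concordant fold-change sign, which strips most single-method false
positives.  The sign-concordance requirement is a deliberate choice — a
feature "confirmed" by two methods in opposite directions is not a
confirmation.

**Sample diagnostics.** The between-sample distance is the Euclidean
distance on 2·√(normalised counts) — the Anscombe-style square-root
stabilisation appropriate for Poisson-like noise — scaled by 1/√(features).
This is a closed-form stand-in for Poisson-model distances; it preserves
the diagnostic purpose (replicate concordance) and is checked only for
that property (within-group < between-group on shifted simulations).  PCA
runs on centered log2(normalised + 1) via SVD.

**Over-representation.** One-sided hypergeometric tail per gene set,
`P(X ≥ k)` with the set intersected with the universe first, BH across
sets.  Gene-set collections are user-supplied; no database ships with the
package.

**qPCR validation.** ΔCT = target CT − arithmetic mean of ≥ 2 reference
CTs (the CT-space equivalent of a geometric-mean reference in expression
space); ΔΔCT subtracts the control-group mean; fold = 2^(−ΔΔCT); the group
comparison is a two-sided equal-variance Student t-test on per-sample ΔCT.

## lncRNA discovery

The cascade order is fixed: annotated protein-coding → short (< 200 bp,
summed exon length) → mono-exonic → coding-potential consensus → Rfam
removal.  All four coding-potential sources must agree noncoding
(CPC2 score < 0, FEELnc coding potential < 0.558, CPAT < 0.43, and no Pfam
domain hit with e-value < 1e-5); every cutoff is a strict inequality, so a
CPAT score of exactly 0.43 is coding.  Scores are inputs — the package
does not re-implement the scoring engines.  Per-step survivor counts are
reported so the identification funnel is inspectable.

Cis links use the boundary-to-boundary distance between the lncRNA locus
and the gene span (overlap = 0), strict `< 2000 bp`, strand-agnostic —
the least-assumption reading of "vicinity"; TSS-anchored distance is a
stricter alternative a caller can build from the same primitives.  Trans
links require |Pearson r| > 0.9 on normalised expression with ≥ 3 samples;
constant profiles yield no link.

## Differential splicing

PSI is the raw ratio inc/(inc+exc) per sample, undefined (NaN) at zero
evidence; no effective-length normalisation is applied, since the event
tables arrive as junction counts with no length information.  ΔPSI is the
difference of group-mean PSI (treated − control).  Significance combines a
chi-square two-proportion test on the within-group pooled
inclusion/exclusion counts (BH, FDR < 0.05) with |ΔPSI| > 0.1 — the
absolute value matters, as intron-exclusion events carry negative ΔPSI.
Events with no defined PSI in an entire group are excluded and counted.

Two-caller consensus matches significant events by location: same gene id
and ≥ 1 bp span overlap, each event used once, pairs chosen greedily by
largest overlap with ties broken by leftmost start then event id (fully
deterministic).  Event types are *not* required to match — the two callers
use 5- and 7-type vocabularies (SE, A5SS, A3SS, MXE, RI, plus AF/AL) and
type disagreement on a shared locus is informative, so per-type tallies
are reported per source instead.

## Allele-specific expression

**Hard filters.** Keep iff DP ≥ 10, MQ ≥ 40, QD ≥ 2, MQRankSum ≥ −12.5,
ReadPosRankSum ≥ −8 (values strictly below a threshold drop the site).
Missing rank-sum statistics pass — homozygous-like sites legitimately lack
them — while a missing DP/MQ/QD drops the site.

**Positional exclusions.** (1) within ±5 bp of an internal exon–intron
junction point; (2) inside the overlap of two genes on opposite strands
("bidirectional"; the divergent-promoter reading — promoters within 1 kb —
is a config alternative not enabled by default); (3) inside paralog
intervals padded ±50 bp; (4) inside SSRs.  Each exclusion is a pure
predicate over an interval index and is tested against a brute-force scan.

**SSR finder.** Maximal perfect tandem repeats, motif lengths 1–6, minimum
full-copy counts 10 (mono), 6 (di), 5 (tri–hexa); primitive motifs only
(a poly-A run is not a di-repeat); `N` breaks repeats; overlapping reports
are merged.  Implemented by vectorised shifted-sequence comparison; runs
extend through a trailing partial motif.

**Test.** The allelic-imbalance statistic is the closed-form 2×2
chi-square (no continuity correction) on pooled per-group [ref, alt]
counts, df = 1; a zero marginal yields stat 0, p 1.  ΔAAF is the pooled
treated AAF minus the pooled control AAF — pooled counts rather than means
of per-sample fractions, matching the pooled test and robust to uneven
depth; per-sample AAFs are still reported.  Sites observed (AAF > 0) in
fewer than half the libraries are excluded before testing; BH runs across
all tested sites in a single family.  ASE requires |ΔAAF| > 0.1 and
FDR < 0.001.

**Heterozygote classes.** The class boundaries are not standardised
anywhere we know of; the package bins the mean defined AAF at 0.4/0.6
(below → heteroref, above → heteroalt, between → "true" balanced) and
flags the rule in its reports as a documented stand-in.

**Region annotation.** Precedence CDS > 5'UTR > 3'UTR > intron >
ncRNA-exon > upstream/downstream > intergenic; flanks are 5000 bp (the
common annotator default) and strand-aware; the first transcript matching
at the winning precedence level is reported.  An explicit `intergenic`
class absorbs sites no rule claims rather than forcing totals.

## RNA editing

Candidates must already have passed the ASE-stage quality and positional
filters.  The cascade: observed in ≥ 3 samples → canonical class (A→G on
+/T→C on − is A-to-I; C→T/G→A is C-to-U; unknown strand classifies by the
pair and flags `strand_resolved = False`; the host gene's strand is used
when the site is genic) → no known SNP id → AAF ≤ 0.7 in every sample
(near-complete conversion is more plausibly a genomic variant) → inside a
SINE interval.  All filters are independent predicates, so the surviving
set is order-invariant.  Known-editome matching is by exact coordinate,
no window.  The imbalance flag (FDR < 0.05) is BH-adjusted **within the
candidate family**, separate from the ASE family, because the two decision
rules use different thresholds.  Both canonical classes are kept and
reported separately.  The bundled worked-example table of 57 in-SINE
A-to-I sites (21 UTR / 14 downstream / 17 intron / 5 upstream, 22
editome-confirmed) ships as a transcribed TSV; the source tables disagree
internally on whether 53 or 57 sites survived, and the 57-row table is
taken as ground truth for the worked examples.

## Synthetic data

The generator (`endotx.synthetic`) defines the study conditions every
calibration and recovery test runs under.  Defaults: 3 vs 3 replicates;
200 genes on synthetic chromosomes (50 genes/chromosome, 12 kb spacing,
2–4 exons with CDS/UTR structure, every 10th gene given an opposite-strand
overlapping partner); NB counts with log-normal base means (log-mean
ln 100, sd 1) and dispersion 0.05; 10% of genes spiked at log2FC 2;
300 variant sites at mean depth 60, null AAF shared uniform(0.35, 0.65),
10% of sites shifted by ΔAAF 0.35 (0.2 → 0.55); 40 A→G editing sites
inside SINE intervals with per-sample AAF ~ uniform(0.15, 0.5), plus
decoy classes for every editing filter (known-SNP, AAF ≈ 0.9,
non-canonical, non-SINE); 200 splicing events at mean depth 50 with 10%
shifted by ΔPSI 0.4, reported by two pseudo-callers with ±10 bp span
jitter and a handful of private events each.  Planted editing sites are
rejection-sampled until observably edited (≥ 4 nonzero samples, max AAF
≤ 0.6) so the planting oracle is exact; planted variant sites avoid genes
in bidirectional overlaps so positional filtering cannot silently remove
truth.  A configurable fraction (default 5%) of null variant sites carries
one failing quality statistic.

Everything flows from one integer seed through `numpy.random.default_rng`;
identical seeds give byte-identical output directories.

What the generator does *not* emulate: read-level error, mapping bias
(including reference bias in allele counts), GC/length effects,
correlated gene-gene expression, overdispersion heterogeneity across
biological conditions, and sequence-realistic SINE content.  Passing
recovery tests therefore demonstrates that the decision rules and
machinery are implemented correctly and are well-calibrated under the
stated sampling models — not that the pipeline is robust to the artifacts
real alignments carry.

## Problem sizes and tolerances

The test suite and the acceptance script use simulation sizes chosen to
make Monte-Carlo bounds tight while keeping runs short: 2000 features for
DE null calibration (99% binomial CI around the nominal 5%), 1000 sites /
1000 events for the ASE and DAS null runs (expected false positives ≈ 0
at FDR 0.001, ≤ nominal at FDR 0.05), and the default generator
configuration for end-to-end recovery (threshold: ≥ 80% of each planted
class).  Recovery margins are wide at these settings — typical runs
recover 95–100% of each class.

## Known limitations

- The native DE test is one NB Wald test, not a re-implementation of the
  established DE packages; exact numeric agreement with them is a
  non-goal.  The consensus layer is where multi-method robustness lives.
- PSI has no effective-length correction; events quantified by callers
  that apply one will differ in PSI scale (the ΔPSI decision rule is much
  less sensitive to this than raw PSI).
- The heterozygote-class binning and the bidirectional-gene definition are
  documented stand-ins for under-specified conventions.
- Region annotation reports one class per site by precedence; sites with
  several plausible annotations (overlapping transcripts) keep only the
  highest-precedence one.
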