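# Methods

`zeitshift` analyses diurnal transcription-factor ChIP-seq experiments that
contrast inbred parents with their reciprocal F1 hybrids across zeitgeber
times, together with the companion expression-heterosis and circadian-rhythm
assays.  Because studies of this design are frequently published without
deposited raw data, the package ships a synthetic study generator with full
planted truth, and every analysis stage is validated by parameter recovery on
that truth.  This note records the models, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## Study design emulated by the generator

Four genotypes — inbreds P1 and P2 and reciprocal hybrids H12 and H21 — are
sampled at three zeitgeber times (ZT3, ZT9, ZT15; hours after lights-on),
with two ChIP replicates and matched input controls per condition.  Chromatin
fragments average 400 bp (sd 60 bp), matching typical sonication, and are
emitted directly as genomic intervals: base-calling and read alignment are
out of scope, and no downstream statistic in the pipeline uses base-level
information.  All genotypes share one coordinate system, since none of the
pipeline's statistics depend on allele of origin.

Per gene and genotype the truth table plants a binding flag, a binding phase,
and an occupancy vector over the three ZTs.  Hybrid phases default to
(0.65, 0.20, 0.15) over (ZT3, ZT9, ZT15) and inbred phases to
(0.40, 0.35, 0.25) — a morning-skewed hybrid binding program against a
flatter inbred one, which is the effect the phase-shift statistics are built
to detect.  Occupancy at the planted phase is 1.0; the other two time points
draw from U(0.10, 0.40), so the planted phase is always the strict maximum.
A small `flat_fraction` (default 5%) of bound genes has equal occupancy at
every ZT; these exist to exercise the exclusion rule.  ChIP samples allocate
`signal_fraction` (default 0.30) of their depth to bound promoters in
proportion to occupancy, with fragment centres Gaussian around the promoter
summit (`bump_width` 400 bp); inputs are uniform background.  PCR duplication
appends a `duplicate_rate` (default 10%) of exact copies.  Enrichment
magnitudes and noise levels are free parameters of the generator — this class
of experiment does not publish them — and the defaults above were fixed once
as plausible values for a strongly bound factor; they are config-exposed.

A fast path (`generate_target_abundances`) emits per-replicate enrichment
abundances directly from truth (background 1, plus `abundance_gain` = 3 times
occupancy, with 10% multiplicative Gaussian noise).  Parameter-recovery
experiments that need many independent studies (50-run recovery, 200-run null
calibration) use this path; the fragment-level route is exercised end-to-end
in the integration tests at 20 genes x 20k fragments per sample, a problem
size chosen so the whole suite stays desk-scale.

What the generator does *not* emulate: mappability structure, GC and
chromatin-accessibility bias, genotype-specific reference bias, overdispersed
(non-uniform) input background, and gene-length/density heterogeneity of a
real genome.  Passing recovery tests therefore demonstrates the statistical
machinery is correct under its stated model, not that the pipeline is robust
to every artefact of real sequencing data.

## Depth normalization

Duplicates are exact (chrom, start, end, strand) tuples — the fragment-space
equivalent of paired-end duplicate removal.  After deduplication every
library is down-sampled, uniformly without replacement and seeded, to the
smallest library's count, so that peak numbers and abundances are comparable
across genotypes and time points (e.g. libraries of 4, 5, 6 and 7 million
fragments all become 4 million).  By default ChIP and input libraries pool
into a single minimum; a flag restricts the minimum to ChIP libraries, since
either reading of "all samples" is defensible.  Replicate concordance is the
Pearson correlation of fragment-midpoint counts in consecutive 1-kb bins
(midpoint assignment conserves fragment count; overlap-weighted counting is
available behind a flag), with a QC threshold defaulting to 0.9.

## Peak calling

The caller tests the treatment pileup at every base against a Poisson rate
estimated from the matched input: lambda_local(x) is the maximum of the
genome-wide mean and the 1-kb, 5-kb and 10-kb window means centred on x —
the dynamic local-lambda scheme popularized by MACS-style callers.  Bases
with upper-tail probability below `p_cut` (default 1e-3) are merged when
closer than `merge_gap` (100 bp); peaks shorter than `min_length` (150 bp)
are dropped.  The summit is the leftmost treatment-pileup maximum, the peak
p-value the minimum over the peak, and fold enrichment the summit pileup over
its local lambda.  Because true fragments are available, no fragment-size
model is built.  An all-zero control falls back to a treatment-estimated
background with a logged warning.

Peaks must overlap (>= 1 bp) between the two biological replicates; the
concordant peak takes the union span of the overlapping pair, preserving all
signal for downstream abundance quantification.  Per-genotype master peaks
are the interval union of concordant peaks across time points, each recording
its contributing ZTs.  An input-subtracted signal track (pointwise treatment
minus control, floored at zero) supports visualization.

## Target assignment and feature composition

A gene is a binding target when any peak overlaps the gene span extended by
10 kb on both sides (span-based rather than TSS-based; a TSS-centric mode is
available).  A peak within range of several genes is assigned to all of them.
Peak summits are classified into promoter (2 kb upstream of the TSS,
strand-aware) > 5'UTR > coding > downstream (2 kb past the TES) > intergenic,
in that priority, and the category composition is compared against the
genome's base-pair composition with two-sided Fisher's exact tests (genome
fractions scaled to the observed peak total).

## Phase assignment and genotype contrasts

A target's abundance at one time point and replicate is the pseudocounted
ratio of treatment to control fragment counts over its master-peak interval,
(t + 1) / (c + 1).  The ratio form makes abundances comparable across targets
of different peak widths, and the pseudocount keeps the statistic finite in
empty intervals.  Phase assignment runs a one-way ANOVA across the three ZT
groups (alpha 0.05): non-significant targets are excluded; otherwise the
phase is the ZT of maximal mean unless an equal-variance two-sample t-test at
the same alpha cannot separate the top two ZT means, in which case the target
is excluded as having the "same abundance" at two or more time points.  The
tie rule uses the simplest test at the already-chosen alpha; Tukey's HSD is
the obvious alternative and is left as a flag-level extension.

Group-level contrasts are two-sided Fisher's exact tests on the 2x2 table of
(phase == ZT vs other) by (hybrids vs inbreds), genotypes pooled within each
group; per-genotype-pair contrasts can be formed the same way.  Target sets
partition into shared-by-all-four, hybrid-specific, inbred-specific and
other, with union semantics for class membership (present in either class
member, absent from both members of the opposite class).  Set overlaps are
scored by the upper-tail hypergeometric distribution; the four-way shared
class additionally supports a seeded permutation test that reshuffles target
labels over the gene universe.

Calibration, measured by the test suite and the acceptance script: under a
null with identical phase distributions in both groups the contrast rejects
at close to its nominal 5%, and under the default hybrid/inbred skew with
400 genes and 2 replicates the recovered per-group ZT3 proportions land
within 5 points of truth with contrast p < 1e-3 in >= 95% of seeded runs.

## Motif and GO enrichment

Motif analysis scans peak sequences for known consensus strings — the evening
element (AAATATCT), the CCA1-binding site (AAAAATCT), their maize hexamer
variants (AAAATA, AAGAAA) and the Dof core (AAAGC) — by exact matching on
both strands.  Consensus-only matching is deliberate: these motifs are
reported as consensus strings, not position weight matrices, and de novo
discovery is out of scope.  Enrichment is empirical: peak sequences are
shuffled preserving dinucleotide composition (Altschul–Erickson Euler-path
shuffling) and the add-one-corrected p is the fraction of shuffled sets whose
hit fraction reaches the observed one.

GO enrichment is an upper-tail hypergeometric test per term over a flat
gene-to-term annotation (no DAG propagation), Benjamini–Hochberg corrected
across tested terms; terms with fewer than `min_term_size` (2) universe genes
are skipped.  The universe defaults to all annotated genes supplied.

## Expression heterosis

Relative expression uses the delta-Ct model, 2^-(Ct_gene - Ct_ref), against a
reference transcript (18S rRNA in the emulated assays); amplification
efficiency correction is out of scope.  Series can be rescaled so the
mid-parent value at the first time point equals 1, the conventional
presentation.  The MPV is the mean of the parental means; for testing,
replicate-level MPV pseudo-samples pair parental replicate i with replicate i
(a seeded random pairing is available).  Nonadditivity at each time point is
a two-sample Student's t-test (Welch behind a flag) of F1 replicates against
the MPV pseudo-samples, reported with log2(F1/MPV).  Note the pseudo-samples
have roughly half the variance of a single genotype's replicates, which
makes the equal-variance test slightly anticonservative (measured type-I
error ~0.06 at alpha 0.05 with 3 replicates); this is accepted as the cost
of matching the conventional analysis.  Better-parent heterosis is
%BPH = (hybrid - best parent) / best parent x 100 with the best parent being
the larger parental mean.

## Rhythm analysis

A trace x(t) is modelled as c0 + c1 t + sum_i a_i e^(-d_i t)
cos(2 pi t / tau_i + phi_i).  After linear detrending, local maxima of the
FFT amplitude spectrum seed candidate periods in descending amplitude order;
components are added greedily, refitting all parameters jointly by
least squares, and kept while the residual variance drops by more than 1%
(up to 4 components).  Damped rather than pure cosines reflect the amplitude
decay of reporter rhythms under constant light.  The circadian component is
the largest-amplitude component with period inside the window (default
15–40 h).  The relative amplitude error is the half-width of the amplitude's
approximate 95% confidence interval — from the fit covariance with a
t-quantile at the residual degrees of freedom — divided by the amplitude;
when the covariance is singular (an exact fit) the analytic sinusoid
amplitude standard error sqrt(2 sigma^2 / n) substitutes.  This RAE is an
approximation to the joint-confidence definition used by legacy rhythm
software, whose exact construction is unpublished; it reproduces the
operative behaviour (near 0 for clean rhythms, above the 0.6 arrhythmicity
cut-off for noise).  A trace is rhythmic iff a circadian component exists and
RAE <= 0.6.  Traces must be uniformly sampled and at least two window-midpoint
cycles long.

## Numerical and degenerate-input choices

- Seeds: every stochastic routine takes an explicit seed or derives one from
  `SimDesign.seed`; identical seeds give byte-identical outputs.
- Ties: summits take the leftmost maximum; phase assignment breaks exact mean
  ties toward the earlier ZT before the tie test excludes them; zero-variance
  equal-mean inputs are excluded (phases) or flagged degenerate (heterosis).
- Empty inputs: deduplicating an empty fragment set is a no-op; down-sampling
  an empty sample, correlating a zero-variance track, testing an empty group,
  and enriching an empty universe are errors that name the offending input.
- Exact tests delegate to scipy's Fisher/hypergeometric implementations; the
  test suite pins them against enumeration oracles (exact rational
  arithmetic) to 1e-10 on tables with margins up to 200.

## Known limitations

- Uniform background only; real input libraries are overdispersed, so the
  caller's null calibration on real data will be less clean than measured.
- Consensus motif matching cannot express degenerate positions.
- Flat GO annotation without ancestor propagation.
- The RAE approximation is per-parameter, not joint-confidence.
- Fragment counts, not base-level reads: artefacts upstream of alignment are
  outside the model.
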