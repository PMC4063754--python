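# Methods

## The estimation problem

A polyploid individual carries one allele of each gene per haplome. Given
RNA-seq from the individual and from each parental strain separately, the
goal is one expression value per allele per transcript. Read counting over
strain-diagnostic SNPs is biased in polyploids: each haplome is tagged by a
*different* set of diagnostic positions, so a haplome with 20 such positions
accumulates ~10× the countable reads of one with 2, and a diagnostic
position that happens to sit in a coverage trough or spike misrepresents
its allele. The package therefore separates the two quantities: *how much*
a transcript is expressed (a whole-transcript coverage summary) and *in
what proportion* the alleles contribute (per-site read fractions).

## Consensus genotyping of the parents

Each parental mpileup column is reduced to quality-filtered base tallies
and genotyped with six rules (defaults in `consensus.Thresholds`):

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 15 | total reads required to evaluate a site at all |
| `min_base_quality` | 25 (phred) | per-read floor for entering base tallies |
| `min_var_frequency` | 0.20 | variant support fraction (inclusive) |
| `min_var_reads` | 5 | variant read count (inclusive) |
| `max_p` | 0.01 | Fisher's-exact p, strict |
| `hom_frequency` | 0.75 | at/above: homozygous variant, else heterozygous |
| `strand_min_fraction` | 0.10 | minority-strand share of variant reads |

The Fisher test compares the observed (ref, var) split against an
all-reference table with the same total, one-sided; with these margins the
p-value reduces to the hypergeometric point mass at the observed count,
which is monotone in the variant count at fixed depth. The variant
frequency denominator is the count of quality-passing A/C/G/T observations
at the site (the exact denominator is not pinned down by the original
VarScan description; this is the least surprising choice and is frozen
here). Decision order matters: a candidate that never reaches the
frequency/min-read gates is called homozygous reference (absence of
evidence), while one that reaches them but fails significance or the
strand filter taints the whole site ('N' with `INSIGNIFICANT` /
`STRAND_FAIL`) — a site with substantial but untrustworthy variant
evidence must not masquerade as confidently reference. Only the single
most frequent non-reference base is considered per site (alphabetical
tie-break); tri-allelic pileups are beyond the calling model.
`hom_frequency = 0.75` follows the widely used VarScan default, since the
calling thresholds are otherwise VarScan's.

## dSNP discovery

Strain *s* is discriminated at a position iff its call is one unambiguous
base, every other strain's call is non-'N', and that base is outside every
other strain's IUPAC expansion. A heterozygous strain can never be the
discriminated strain but does not block another strain's dSNP so long as
the expansions exclude that strain's base, and one site may discriminate
several strains independently (the definition is per-strain). Verdicts for
rejected sites record why: heterozygous overlap, an uncallable strain
('N'), unanimous disagreement with the reference, or no difference.
Transcripts lacking a dSNP for any haplome are dropped before ASE; indel
evidence is consumed by the pileup grammar but never used.

## Expression, normalization, ASE

Whole-transcript expression is G = exp(mean(log d_i)) over positions with
d_i ≥ 1 (log-space to avoid overflow; G = 0 when nothing is covered).
Cross-sample comparability uses median-of-ratios size factors computed on
G exactly as DESeq computes them on counts: per-transcript geometric-mean
representative across samples, per-sample median of ratios to it,
transcripts with any zero excluded. Note the factors are *relative*: they
are invariant under a global rescaling of all samples (so normalized
values scale with the data), and per-sample depth differences are absorbed
up to one global constant.

Normalization is applied to G *before* fractional expression. Within a
sample the allele fractions n_s/n are ratios and unaffected; the ordering
only matters for the absolute scale of ASE values, and normalizing first
makes every downstream number directly comparable across samples. At a
dSNP, n is the full read depth and n_s counts only reads carrying the
discriminating base — reads carrying any third base dilute the allele
rather than credit it. Per strain, strictly positive per-dSNP values are
averaged (a dSNP sitting in a local coverage hole contributes nothing
rather than dragging the mean); if all values are zero, zero is reported.

## Imbalance classification

The equality test treats the allele values as count-like quantities in a
Pearson χ² goodness-of-fit with expected value total/ploidy and
ploidy − 1 degrees of freedom — the simplest reading of a "goodness of
fit test against equal expression", applied to the ASE scale directly. No
multiple-testing correction is applied (raw p < 0.01), matching how the
thresholds are used as descriptive boundaries rather than inference. The
c_v uses the sample (n−1) standard deviation; that choice is forced by
the landmarks: for (x, x, 0) it gives √3/2 ≈ 0.87 and for (x, 0, 0) √3 ≈
1.73, which the population form does not reproduce. Categories use the
median of allele values as the comparison basis (robust to the single
outlier that is often the interesting allele) with a 2-fold threshold; at
ploidy 3 at most one allele can cross each side of the threshold, so the
`spread` fallback for multiple same-direction crossings only binds at
higher ploidy. Quadrants cross |log2 fold-change| > 1 versus the parental
arithmetic-mean expression with c_v > √3/2. When two individuals are
compared, classification is per-individual and concordance is counted on
the shared classified transcripts.

## The synthetic-data generator

`simulate_experiment` emulates the validation design: random uniform
A/C/G/T transcripts, `dsnps_per_strain` planted substitutions per strain
at distinct positions, allele fractions drawn from Dirichlet(1, 1, 1) (or
fixed), fragment totals uniform on 200–2,000 per transcript, paired 100 bp
reads on 250 bp fragments at uniform starts, error-free by default (an
optional uniform substitution-error rate exists for robustness
experiments). Defaults: 300 transcripts of length 1,500 with 5 dSNPs per
strain and 3 strains, the scaled study conditions; parental samples get
300 fragments per transcript (~40× mean coverage), a value chosen once as
representative deep parental RNA-seq — parental depth only gates the
consensus stage and is not a measured quantity. Pileups are constructed
directly from the known fragment placements instead of realigning
simulated reads; this removes any aligner dependency while preserving the
measured quantity, at the cost of not modelling alignment failure.

What the generator does *not* emulate — and hence what passing recovery
tests do not demonstrate about real data: non-uniform coverage from splice
isoforms and annotation gaps, mappability-driven multi-alignment
artifacts, real quality profiles, reference-bias against the strain most
distant from the reference, indels, and library-preparation strand bias.
Fragment-end coverage ramps and mate-orientation strand structure *are*
reproduced, which is why a planted site near a transcript end can
legitimately fail the coverage or strand filter and drop out.

Recovery is scored per transcript as the Pearson correlation between
estimated and true per-strain ASE triples; with three points the score is
scale- and shift-free, and it is undefined (flagged, counted as a failure
in summaries) when either triple is constant — near-equal truth can score
near zero despite tiny absolute error, an acknowledged property of the
metric rather than of the estimator.

## Numerical and degenerate-input choices

* Boundary comparisons: inclusive for coverage/frequency/read-count gates,
  strict for the p-value, inclusive for the strand minority fraction
  (9:1 at 0.10 passes).
* Largest-remainder rounding allocates fragment totals exactly; remainder
  ties break by strain order. Example: 500 fragments at weights
  (10, 20, 30) → (83, 167, 250).
* Transcripts shorter than the fragment length are sequenced as unpaired
  reads of min(length, 100) bp.
* Empty pileups produce empty outputs and zero counts, not errors. When no
  transcript is positive in every sample, size factors are undefined; the
  pipeline falls back to unit factors with a warning instead of aborting.
* All randomness flows from one `numpy` generator seeded explicitly;
  simulation and pipeline outputs are byte-reproducible given the seed.
* Mapping-quality columns in mpileup input are ignored; `*`/`<`/`>`
  placeholders count toward depth but never toward base tallies.

## Problem sizes

The shipped validation and acceptance runs use 300 transcripts × 1,500 bp
with three parental samples and one polyploid sample (~600k fragments in
total), which exercises every stage at realistic per-transcript depths
while completing in well under a minute; the pipeline itself streams
pileups line by line and scales linearly in total pileup length.

## Known limitations

Genome-coordinate dSNPs, indel-based discrimination, isoform
deconvolution, TPM/FPKM-style length normalization, and extrapolating the
allele lacking dSNPs from the other alleles' values are all out of scope.
The equality test on ASE values inherits the count-like-scale assumption;
its p-values are descriptive. Real-data funnels (e.g. how many of ~250k
variant positions survive to informational sites) depend on the input
libraries and are reported by the pipeline log rather than asserted.
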