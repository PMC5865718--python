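# Methods

## The quantity being mapped

A Hi-C read pair whose two ends derive from spatially adjacent loci is
informative about rDNA localization when exactly one end maps to an rDNA
reference unit (the 2,121 bp 5S repeat with flanks, or the 45S unit
comprising 18S/5.8S/28S, ETS/ITS and the intergenic spacer) and the mate
maps uniquely to the non-repetitive genome. Because the rDNA arrays are
absent from the genome assembly, these pairs must be mined directly from
raw reads rather than from aligned contact matrices. The package measures,
for each dataset and array, where the genomic mates land — per 1 Mb bin,
per gene span, and per annotation state — and compares contact densities
across datasets and against uniform-rate expectations.

## Read mining

Both mates are trimmed from the 3' end at Phred ≤ 20 and discarded below
51 bp, then mapped independently (a Hi-C insert spans arbitrary genomic
distance, so paired-end constraints would be wrong). Mapping is exact
unique full-length substring matching over a packed 24-mer seed index of
all references. This is a deliberate simplification: synthetic reads are
error-free after trimming, and the pipeline's contribution is the
classification logic, not aligner heuristics. Real-mode users can run any
aligner and feed per-end calls to `classify_pair` through `MappedEnd`.

Classification: both ends rDNA → `rdna_both` (tallied separately; in real
45S data this is a large class, on the order of a third of rDNA reads);
rDNA + repeat-library mate → `repeat_excluded` (dropped, since repeat
mates are unplaceable); rDNA + unique genome mate → `rdna_genome` (the
informative class); rDNA + ambiguous/unmapped mate → `ambiguous` (dropped
but reported — the convention for mates without a unique placement is a
choice; they are never counted as contacts). A pair with no rDNA end is
`non_rdna`. Category counts partition the input exactly.

## Pseudogene masking

rDNA pseudogenes elsewhere in the genome would absorb rDNA-mapping reads
and fake contacts. The scan is gap-free seed-and-extend: exact 11-mer
seeds between genome and rDNA unit (both strands), ungapped extension at
match +1 / mismatch −2 with an X-drop of 10, per-diagonal de-duplication,
and Karlin–Altschul significance E = K·m·n·e^(−λS) over the two-stranded
search space, with λ solved exactly for the scoring scheme under uniform
base composition (λ ≈ 1.333) and K = 0.621 (the standard ungapped value
for +1/−2). Hits with E < 1e-4 are merged per array; any 1 Mb bin or gene
span overlapping a merged hit by ≥ 1 bp is excluded for that array. Gapped
extension is out of scope: at the E-threshold scores involved (≈ 25+), a
gap-free segment of a real pseudogene is essentially always present, and
the tests verify detection down to 85% identity at 300 bp. Scores are
validated in the tests against an exhaustive per-diagonal maximum-subarray
oracle (gap-free Smith–Waterman); with an X-drop of 10 the extension can
in principle terminate before a dip the optimum crosses, but at ≥ 0.85
identity this is rare and the oracle comparison in the suite is exact.

## Binning, CPM, rates

Coordinates are 0-based half-open everywhere (GTF is converted on read);
bins tile each chromosome with a ceiling final bin, so hg19 chr1–22 at
1 Mb yields 2897 bins. A contact increments the bin containing the 5'-most
mapped base of its genomic mate. CPM divides by the dataset-array's total
binned rDNA–genome contacts (not by all rDNA reads: both-end and excluded
categories say nothing about genomic position). Three per-nucleotide rates
serve as expectations: total contacts / genome length; unmasked-bin
contacts / unmasked length; in-gene contacts / retained gene length. Genic
rates use contacts-per-bp units throughout.

## Gene contacts and CPGN

A gene's span runs from first exon start to last exon end across all its
transcripts; intronic mates count. A record in overlapping spans counts
toward each (the alternative — fractional or first-only assignment — is a
defensible choice; the mean multiplicity is reported so users can filter).
Raw counts scale with span length under any roughly uniform contact
process, so the working statistic is CPGN = count / span length; the test
suite verifies on length-proportional synthetic contacts that
Spearman(count, length) > 0.5 while |Spearman(CPGN, length)| < 0.1.
Quantile gene sets take the ceil(fraction·n) extreme CPGN genes with
lexicographic tie-breaking for determinism. Gene-set enrichment is a
two-sided Fisher exact test per category with BH correction — an offline
stand-in for web GO tools, against user-supplied sets.

## Differential contact density

Counts per feature (bin or gene) and sample are modeled NB(μ, φ) with log
link: log μ = log L_s + β, library sizes as offsets, one β per condition
under the alternative and a shared β under the null; the LRT is referred
to χ² with 1 df and BH controls the FDR at 0.05. Means are fitted by a
vectorized per-feature Newton iteration (score/information steps, clipped,
converged at |Δβ| < 1e-10 within 100 iterations; non-converged features
are reported NA and skipped by the BH correction, as are all-zero
features).

Two numerical choices matter at small replicate numbers:

* **Effective library sizes.** Plain column sums are distorted by
  composition: if a minority of features genuinely gains counts in one
  condition, every other feature appears depleted, inflating type-I error
  (measured: 0.075 at α = 0.05 with 5% features at 4-fold). The default
  offsets are therefore median-of-ratios effective sizes (median ratio to
  the geometric-mean reference profile over always-positive features),
  falling back to column sums when fewer than 50 such features exist.
* **Dispersion.** The common dispersion maximizes the Cox–Reid adjusted
  profile likelihood (−½ log det X'WX per feature) pooled across non-zero
  features; without the adjustment the profile MLE is biased low by about
  (n−p)/n — a factor of two at two replicates per condition. Per-feature
  moment estimates (df-corrected by n_g/(n_g−1), singleton groups
  skipped) are shrunk 0.8 toward the common value and exposed in the
  `DispersionModel`; the LRT however runs at the common dispersion by
  default, because at two replicates per condition the ~2-df moment noise
  measurably degrades the uniformity of null p-values even after
  shrinkage. From roughly four replicates per condition,
  `use_per_feature_dispersion=True` is reasonable.

With these choices the null p distribution is indistinguishable from
uniform by KS at n = 2000 and the type-I error at α = 0.05 stays at ~0.06
(the residual excess is the χ² approximation at four samples). A volcano
annotation flags features with |fold change| > 2 and raw p < 3e-4.

Power at this design is intrinsically modest: the variance of the log
fold estimate is bounded below by φ·(1/n₁ + 1/n₂) = 0.2 at φ = 0.2 and
2+2 replicates, capping |z| near 3.1 for a 4-fold effect; after BH the
self-consistent recovery of a 5% planted fraction is ~0.3–0.4, and an
oracle Wald test given the true dispersion, means and library sizes
measures the same. Detecting most 4-fold features at this dispersion
requires more replicates, not a better estimator.

## The synthetic generator

The generator defines the study conditions the tests run under. Toy
genomes are uniform-random sequence; rDNA units (5S 2,121 bp as in the
real repeat; 45S 5 kb by default, a desk-scale stand-in for the 45,337 bp
unit so scanning and mapping run in seconds) and repeat units are
rejection-sampled to share no 21-mer with the genome, so planted
pseudogenes are the only rDNA-like genomic sequence and ground truth is
exact. Pseudogenes are planted copies mutated per-base to a stated
identity. Read pairs draw a category from the model fractions (defaults:
80% rDNA pairs, of which 29% both-end — matching the large both-end class
reported in real 45S data — and 10% repeat-mate); genomic mates draw a
bin proportional to bin weight × planted annotation multipliers, uniform
within the bin, avoiding plants so read-level truth stays exact. A
configurable fraction of reads (10%) carries a random low-quality (Q2) 3'
tail to exercise trimming. Bin propensities default to log-normal(0, 0.5)
— the real distribution across 1 Mb bins is unknown; this is a modeling
choice, not an observation. A record-level fast path
(`simulate_contact_records`) skips read synthesis for statistics-stage
tests at scale.

What the generator does not emulate: restriction-fragment chemistry and
ligation artifacts, sequencing errors inside the informative prefix,
distance-decay of intra-chromosomal contacts, copy-number structure
within the arrays, and real repeat families. Passing tests therefore
demonstrate the correctness of the classification, masking and
statistical machinery under known truth — not performance on real
libraries, where aligner choice and repeat content dominate.

## Study/problem sizes used by the suite

Mining truth-recovery runs 50,000 pairs on a 5 Mb genome; masking uses
planted copies at identities 1.0/0.85/0.55 on a 3.5 Mb genome; the
differential suite uses 2000 features with 2+2 replicates; enrichment
plants multipliers {4, 1, 0.5} on 10-bin tracks over 1000 bins (tracks
deliberately small relative to the genome, as real annotation classes
are, so the genome-wide rate remains a valid baseline — with large
annotated fractions the observed/expected ratio recovers the multiplier
only up to the genome-wide normalization); CPGN de-biasing uses 500
genes and 150,000 records. These sizes make every stage's check sharp
(binomial error well inside the stated tolerances) while the whole suite
runs in well under a minute of compute per stage.

## Known limitations

* Exact-match mapping ignores sequencing error and close paralogy;
  real-mode use requires an external aligner.
* The NB machinery is deliberately plain: no empirical-Bayes tagwise
  moderation, no quasi-likelihood F-tests, condition is the only
  covariate. Numeric agreement with edgeR is not claimed.
* The pseudogene scan is ungapped; a pseudogene fragmented by many indels
  would be reported as multiple merged hits (still excluded correctly) or
  missed if every gap-free segment falls below threshold.
* The one-proportion test switches from exact binomial to a
  continuity-corrected normal approximation above n = 10,000; at that
  scale the approximation error is negligible.
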