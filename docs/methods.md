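# Methods

## Problem and model

Spliced aligners encode an intron as a reference-skip (`N`) CIGAR operation
inside a split-read alignment. `splicefilter` treats the distinct intron
intervals observed across all split reads as candidate splice junctions and
decides, per junction, whether the supporting evidence looks like genuine
splicing or like a mapping artifact. The decision is made by a random
forest trained *on the dataset itself*: rule-based filtering first labels
only the junctions whose evidence is extreme in either direction, and the
forest then interpolates over the remaining majority. No pre-trained model
is shipped; every dataset gets a classifier adapted to its read length,
depth, error rate and species.

## Coordinates and keying

All internal coordinates are 0-based half-open; conversions happen only at
format boundaries (GTF/GFF3 are 1-based inclusive, BED is 0-based
half-open). Junctions are keyed on (contig, intron start, intron end) only.
Strand is deliberately excluded from the key: it is resolved *after*
collapsing, from the boundary dinucleotides, and mappers disagree about
strand conventions for unstranded libraries.

## Split-read extraction

One record is emitted per `N` operation per primary alignment, provided the
skip length lies within the configured intron bounds (defaults 4 and
500,000 — wide enough for all plausible introns, tight enough to exclude
tiny-deletion artifacts and chimeric skips). Secondary and supplementary
records are excluded by default so a read is never counted twice.
A read is *uniquely mapped* when its `NH` tag equals 1; when the tag is
absent, mapping quality ≥ 30 is used instead (configurable) because mappers
encode multiplicity inconsistently. Mismatch counts come from the `NM` tag
when present and are otherwise recomputed against the genome. Reads with
clipped bases adjacent to the skip are counted like any other support.

## Alignment-derived metrics

* Read-start *offset* = length of the upstream (left) anchor, i.e. the
  distance from the read's leftmost aligned base to the donor-side boundary.
  Under random sampling these offsets are near-uniform across the anchor.
* Shannon entropy of the offset histogram is reported in bits (log base 2);
  any monotone rescaling would be equivalent for the classifier, bits are
  simply conventional.
* Anchor deviations: the field describes the concept (sharp deviations from
  the expected per-position coverage are a failure signal) without fixing a
  formula; we use the per-position standardized residual |O−E|/√E against a
  uniform expectation E = N/A, where A is the anchor capacity capped at 20
  positions. Positions beyond the anchor are exactly 0. Only the upstream
  anchor is scored; scoring both anchors would be a straightforward
  extension but doubles the feature block for little observed gain on
  synthetic data.
* MaxMMES: per read, each side's contiguous match length is truncated at
  the first mismatch walking away from the junction; MMES = min(left,
  right); MaxMMES = max over reads. Mismatch positions are localized by
  comparing the read sequence to the genome base-by-base over the aligned
  blocks (correct for any mapper, regardless of MD-tag availability), and
  the per-side runs are cached on the support record when reads are
  streamed, so the metric itself needs no further genome access.

## Genome-derived metrics

* Splice sites: the first/last two intronic bases are tested as-is and
  reverse-complemented; strand resolves to whichever orientation gives a
  canonical (GT–AG) or semi-canonical (GC–AG, AT–AC) pair, preferring
  canonical; ambiguous bases (N) force a novel call with unknown strand.
* Hamming repeat scores compare a window of W = 10 bases on each side:
  last-W of the left anchor vs last-W of the intron, and first-W of the
  intron vs first-W of the right anchor. A score near 0 means the junction
  boundary duplicates its anchor — the signature of a repeat-triggered
  misalignment. W = 10 balances specificity against the chance of random
  matches; it is configurable.
* Intron-size score: 0 up to the 95th-percentile (nearest-rank) intron
  length of the positive training set, log2(L/L95) beyond it. The log form
  grows without bound but slowly, keeping the feature numerically tame for
  the forest.
* PWMs: donor window (−3, +8) and acceptor window (−20, +3) relative to the
  splice sites on the resolved strand (negative = exonic), spanning the
  positions classical splice-site models use; windows are configurable.
  Probabilities are (count + c)/(n + 4c) with pseudocount c = 0.5;
  background is the genome-wide mononucleotide distribution. Two distinct
  features come out of this machinery: the *PWM score* (log-odds of the
  windows against background under the positive-set model) and the
  *splicing signal* (log-likelihood ratio of positive vs negative models) —
  keeping them separate preserves their non-redundant information. Unknown
  strands are scored on both strands and the maximum taken. If no negative
  junction has a resolvable strand the negative model falls back to a flat
  matrix, degrading the splicing signal to a positive-model log-likelihood
  rather than aborting the run.

## Self-training and classification

Positive rules (all must hold): canonical or semi-canonical sites, ≥5
reliable reads, entropy ≥ 1 bit, MaxMMES ≥ 12, mean mismatches ≤ 1,
min hamming ≥ 5. Negative rules (any suffices): novel sites with ≤2 raw
reads; zero entropy with ≤5 raw reads; min hamming ≤ 2; MaxMMES ≤ 6 with no
reliable read. These thresholds label only extreme cases on purpose — the
labelled sets must be high-precision, not exhaustive — and are all exposed
in `PipelineConfig`. A floor of 20 junctions per class guards against
meaningless training; the error message advises relaxing the rules.

The genome-model features (intron score, PWM score, splicing signal) are
fitted from the rule-labelled sets and then computed for *all* junctions,
completing the 28-feature vector (reliable reads, reliable ratio, MaxMMES,
mean mismatches, intron score, min hamming, PWM score, splicing signal,
20 anchor deviations — a fixed, versioned order).

Class imbalance is corrected with SMOTE (implemented in-package on
scikit-learn's NearestNeighbors): each synthetic minority point is a uniform
convex combination of a minority sample and one of its k = 5 nearest
minority neighbours; k is capped at class size − 1, and a singleton class
falls back to duplication. The forest uses 100 fully grown trees, so
`predict_proba` equals the fraction of trees voting genuine; junctions with
probability ≥ 0.5 are kept. Thresholding is inclusive at the boundary and
yields nested genuine sets as the threshold rises.

## Determinism

A single pipeline seed feeds SMOTE and the forest; junction analysis is
partitioned by contig and merged in sorted order, so outputs are
byte-identical across reruns and independent of the thread count. Floats in
the tab format are written with `repr`, which round-trips exactly, making
write→read→write byte-identical.

## Synthetic data

The generator writes alignments directly as SAM rather than simulating
sequencing and mapping: the fixture *plants* the misalignment signatures a
mapper would produce, which is precisely what the filter must learn.
Genuine junctions get GT–AG introns, uniformly distributed anchor offsets,
Poisson-distributed support (mean = coverage, floor 3) from uniquely mapped,
properly paired reads. Four spurious archetypes each violate exactly one
signature: `low_entropy` (3 stacked multi-mapping reads, canonical sites),
`non_canonical` (AA–TT sites, ≤2 reads), `repeat` (the intron head is a
verbatim copy of the right anchor head, hamming 0), `single_read` (one
reliable but lone read). Default scale — 2 contigs × 100 kb, 300 genuine +
300 spurious junctions, 76-base reads at 30× junction coverage, introns
60–180 bp — runs the full pipeline in seconds on one CPU while leaving
every archetype populous enough to train on.

What the fixtures do **not** emulate: expression-level variation beyond
Poisson support, indels, clipped or multi-intron reads, overlapping genes,
alternative splicing, GC bias, and mapper-specific error correlations.
Passing on synthetic data therefore demonstrates that the metrics measure
what they claim and that the self-training loop separates the planted
signatures; it does not certify performance on any particular real mapper's
output.

## Numerical and design choices

* Nearest-rank percentile for L95 (no interpolation) keeps the statistic an
  observed intron length.
* Empty support profiles raise rather than return sentinels; a junction
  with no support cannot exist downstream of collapsing.
* Hamming windows at contig edges are truncated; the length difference
  counts as mismatches so truncation cannot fake a repeat.
* PWM windows beyond contig ends are padded with N, which score as
  background (contribution 0).
* The BED12 score column carries round(1000·probability) for genome-browser
  compatibility; reading it back recovers the probability to 3 decimals,
  documented as lossy.
* Evaluation conventions: precision of an empty prediction is 0; F1 is 0
  when both recall and precision are 0; an empty truth set is an error.

## Known limitations

* Uniqueness inference without an `NH` tag depends on the mapper's MAPQ
  convention; the cutoff is configurable but no universal value exists.
* The deviation features assume the upstream anchor; junctions supported
  only by reads with long soft-clips may understate entropy.
* The negative-PWM fallback makes the splicing-signal feature less
  informative on datasets whose artifacts are all strand-unresolvable.
* Set operations key on coordinates only; two samples calling opposite
  strands for the same interval merge into one junction.
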