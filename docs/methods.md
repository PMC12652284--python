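# Methods

`trnadup` re-implements, as a tested library, a comparative analysis of
nuclear tRNA-coding genes: descriptive conservation statistics (gene
length, introns, GC architecture, anticodon abundance) and a
tandem-duplication detection procedure (proximal pairing, identity
classification, cluster chaining, repeat-unit decomposition).  Because no
public accessions accompany the analysis, the package ships a seeded
synthetic-fixture generator that emulates the statistical structure the
analysis assumes; every pipeline stage is exercised against fixtures whose
ground truth is known by construction.

## Data model

A tRNA gene record carries 1-based inclusive coordinates (the tRNAscan-SE
convention), a strand, an isotype label (20 standard amino acids plus
iMet, SeC and Und), an anticodon stored as uppercase DNA, the
coding-strand genomic sequence including introns, and gene-relative intron
spans.  Minus-strand rows (begin > end in tRNAscan-SE output) are
normalised at parse time so `start <= end` always holds and the stored
sequence is always the coding strand.  The iMet/elongator-Met distinction
is an annotation attribute; it cannot be derived from the anticodon (both
are CAT).  Genes labelled Und or flagged as pseudogenes are retained in
the data model but excluded from statistics by default.

**Gene length.** Intron lengths (up to 261 bp) dwarf the 62–98 bp body,
so the length distribution is computed on the mature (intron-spliced)
sequence by default, which is the scale on which tRNA gene lengths are
conventionally quoted; `spliced=False` measures the genomic span instead.

## GC profiling

GC content is computed in sliding windows of 5 bp at 1 bp steps (both
configurable).  Each window is placed at its centre position normalised by
the total gene length; centres rather than starts keep the two gene ends
symmetric.  Profiles are computed on the coding-strand genomic sequence
including introns; a spliced mode is available by profiling
`splice_introns(gene)` instead.

Aggregation pools all (position, GC) points into 100 equal-width bins,
averages within bins, and smooths the bin means with a tricube-weighted
local *linear* regression (span 0.75 of the points per window, evaluated
at bin centres) — i.e. a pinned-down loess of degree 1, chosen over a
library loess because loess defaults differ across ecosystems and the
algorithm here is part of the contract.  Degenerate windows (zero
bandwidth or collinear abscissae) fall back to the weighted mean.  The
confidence band is the pointwise mean ± 1.96·SE from within-bin variance.

## Abundance and correlation

The abundance matrix counts genes by (species, anticodon) over the full
64-anticodon space.  The canonical 64-column view merges iMet into the
CAT column; a supplementary 65-column view keeps iMet separate.  The
absent-anticodon set is computed on the 64-column view, so "k observed
types" always leaves 64−k absent.

The gene-count–genome-size relationship is summarised by Pearson r with a
two-sided p-value (t transform, n−2 df) and the matching OLS
slope/intercept/R².  Zero variance in either variable makes the
correlation undefined and is reported as missing rather than as a number.

## Global alignment and clustering

Pairwise identity uses a Gotoh three-state affine-gap global alignment
with a needle-style parameterisation: match +5, mismatch −4, gap open 10,
gap extend 0.5, N neutral, end gaps free.  A gap run of length L costs
`open + L·extend`; terminal runs are free.  Identity is identical columns
divided by *all* alignment columns (the EMBOSS definition), as a
percentage.  Coverage per sequence is the fraction of its residues inside
the core region (columns between the first and last position where both
sequences have a residue), which mirrors bidirectional-coverage
clustering semantics.

Determinism and symmetry: traceback ties resolve diagonal > up > left,
and the two sequences are aligned in a canonical orientation (longer,
then lexicographically smaller, first) with the result swapped back.
Without the canonical orientation, equally scoring alignments with
different column counts can be picked depending on argument order, making
identity asymmetric; with it, `identity(a, b) == identity(b, a)` exactly.
The row recurrence is vectorised: the match and gap-in-b states depend
only on the previous row, and the gap-in-a state's within-row scan
collapses to a running maximum with constant drift because the extend
cost is constant.

Sequence-family clustering is a deterministic greedy centroid pass at
identity ≥ 0.9 and coverage ≥ 0.8: sequences are scanned by (length
descending, lexicographic) order and join the first cluster whose
representative passes both thresholds, else found a new cluster.  Since
matches cannot exceed the shorter length while columns are at least the
longer length, identity ≥ 0.9 forces a length ratio ≥ 0.9; shorter
candidates are skipped without aligning.  This replaces a heavyweight
external clustering binary; at the scale of tens of thousands of ~75-mers
the exact DP is affordable, and the resulting partition is verified
post hoc against the thresholds rather than against any external tool's
internal heuristics.

Exact duplicate sequences are deduplicated case-insensitively; each
unique sequence is named `<isotype>_<anticodon>_u<k>` with k assigned per
label in lexicographic sequence order, majority label winning on
conflicts (ties lexicographic).

## Tandem-duplication detection

Two genes form a *proximal pair* when they lie on the same (species,
scaffold) and their inter-gene distance — start of the downstream gene
minus end of the upstream gene minus 1, clamped to 0 for overlaps — is
strictly below 1 kb.  The sweep emits *every* pair within the bound, not
just rank-adjacent ones, and ignores strand (identity is computed on each
gene's own coding strand; an opposite-strand reverse-complement mode is a
possible extension, deliberately not default).

Pairs are classified *identical* by byte equality of the full genomic
sequence (introns included), matching a strict 100%-identity definition;
all other pairs get an alignment identity.  Clusters are connected
components of the pair graph, built separately for two tracks, as the
analysis requires: identical-only pairs, and all pairs.  Components of a
single gene are not clusters.  Each cluster's ordered (isotype,
anticodon) label string is decomposed into its smallest exact repeat unit
via the KMP border array: with smallest period p dividing n the cluster
is unit^(n/p); otherwise the whole string with repeats 1, plus an
informative longest-exactly-periodic-prefix report for ragged arrays.

Degenerate-anticodon analysis keeps classified pairs that decode the same
amino acid (SeC-aware decoding through the reverse-complement codon) with
different anticodons, tabulated per amino acid and species with identity
ranges.

## Synthetic fixtures

The generator emulates the features the analysis depends on, under a
single seeded `numpy` RNG so identical specs give byte-identical output:

- **Gene bodies** follow a schematic cloverleaf: fixed-size stems
  (acceptor 7+7, D 4+4, anticodon 5+5, T 5+5) drawn GC-rich (expected GC
  0.8) and loops drawn GC-poor (expected 0.2), with the literal anticodon
  placed in the anticodon loop.  The D loop and variable loop absorb the
  remaining length, confining mature lengths to 62–98 bp.  Sequences are
  not thermodynamically foldable; only the positional GC architecture and
  the anticodon placement are modelled.
- **Lengths** are drawn from a two-component normal mixture peaked at 72
  and 82 bp, clipped to [62, 98].
- **Introns** are inserted immediately 3′ of the anticodon (the canonical
  position), with lengths peaked at 12 bp (difference of two geometrics,
  rare long tail, clipped to [3, 261]).  Intron probability defaults to
  0.45 for CAT and 0.60 for GTA anticodons and 0.01 otherwise, which
  concentrates introns in Met/Tyr genes as observed in plant annotations.
- **Background genes** are placed with inter-gene gaps sampled uniformly
  from [1000, 3000] bp, so they can never enter tandem range by accident;
  contamination is opt-in by lowering `min_gap`.
- **Planted arrays** repeat an (isotype, anticodon) unit at fixed
  intra-gaps.  One template body is drawn per unit slot; divergence d
  applies exactly d substitutions per copy after the first, uniform over
  non-anticodon positions and over the three alternative bases — a
  deliberately minimal substitution model, since only identity
  percentages, not a mutation process, are being emulated.
- The default three-species spec (~480 genes, two ~300 kb scaffolds per
  species) is a deliberately desk-scale rendition of a 50-species /
  28k-gene survey: large enough to exercise every code path (arrays of
  26/18/14 identical copies, a 27-copy Pro array, a Tyr–Tyr–Ser periodic
  array, a diverged mixed-Pro array, iMet and SeC genes), small enough
  that the full pipeline runs in about a minute.
- The generator's set of 15 unpopulated anticodons (two stop-pairing plus
  thirteen sense) is a stylised choice: real plant genomes avoid a
  specific wobble-driven set, but the analysis only depends on the count
  and on presence/absence accounting, not on which anticodons are absent.

Passing tests on these fixtures demonstrate that the detection procedure
recovers planted structure exactly and that the statistics match
generator truth; they do not demonstrate robustness to annotation noise,
scaffold fragmentation, nested or interleaved arrays, or pseudogene
contamination, none of which the generator models.

## Numerical and edge-case choices

- All alignment scoring constants are dyadic rationals, so DP arithmetic
  is exact in floating point and traceback equality tests are safe.
- Gap boundary is strict: a 999 bp gap pairs, 1000 bp does not.
- Mode ties are all reported (length distributions are genuinely bimodal).
- Species with zero genes get a missing I/T ratio, not 0.
- Empty inputs: an empty annotation yields a zero abundance matrix with
  all 64 anticodons absent; empty cluster sets yield header-only TSVs and
  valid empty BED files.
- All TSV floats print with 4 decimals; JSON is key-sorted; BED output is
  0-based half-open converted from 1-based inclusive spans.  Identical
  configs reproduce outputs byte-for-byte.

## Limitations

The aligner is exact but quadratic per pair with no k-mer prefilter
(out of scope), so greedy clustering beyond ~10⁴ unique sequences becomes
slow.  Divergent-cluster membership is purely distance-chained; how much
internal divergence should still count as one biological cluster is left
to the user, with per-cluster identity statistics reported instead of a
threshold.  Phylogenetics, folding-energy computation, and
substitution-rate (Kn/Ks) dating are out of scope.
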