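# Methods

## Problem setting

Motif enrichment compares motif occurrence in a foreground sequence set
against a background set representing the null. Because genomes carry local
composition biases (GC content above all, and dinucleotide structure such as
CpG depletion), the background must match the foreground's composition or the
test inherits the bias. `backgen` provides four background models — two
synthetic (shuffling the foreground itself) and two genomic (selecting real
sequences from a pool) — plus the pool construction and QC tooling around
them.

## The k-let shuffle (model `k`)

A k-let shuffle of sequence s is a permutation of its residues whose k-mer
count multiset equals that of s (which implies equality of all j-mer counts,
j ≤ k). For k = 1 this is a uniform permutation of the letters. For k ≥ 2 we
use the Euler-path construction: build the de Bruijn multigraph whose
vertices are the (k−1)-mers of s and whose edges are its k-mer occurrences
(prefix → suffix); k-let-preserving rearrangements are exactly the Eulerian
walks from the first (k−1)-mer to the last one.

Sampling is exact and uniform:

1. A uniform random in-arborescence toward the terminal vertex is drawn with
   Wilson's loop-erased-random-walk algorithm, using transition probabilities
   proportional to edge multiplicity (this makes the draw uniform over
   *multigraph* arborescences).
2. Each non-terminal vertex's arborescence edge is reserved as its last exit;
   its remaining out-edges, and all out-edges of the terminal vertex, are
   uniformly permuted.
3. The walk from the initial vertex consumes out-edges in that order and
   spells the output.

By the BEST theorem the walk is always Eulerian, and every valid output
string corresponds to the same number of (arborescence, ordering) pairs, so
the distribution over strings is exactly uniform. The test suite confirms
this empirically: sampled shuffles of short sequences hit every member of the
brute-force-enumerated valid set at near-uniform frequency and nothing
outside it. Consequences worth knowing: for k ≥ 2 the first and last
(k−1)-mers of the output equal the input's (Eulerian endpoints), and some
sequences (e.g. `ACGTACGT` at k = 2) have a *unique* valid rearrangement —
the shuffle then returns the input, which is correct, not a failure. A
sequence shorter than k + 1 residues is returned unchanged.

Ambiguity codes are ordinary symbols: a sequence containing N keeps its exact
N-containing k-mer counts. No expansion into ACGT possibilities is attempted,
since that would break exact-count semantics.

## The windowed shuffle (model `w`)

Windows of W bp (default 100) starting at offsets 0, S, 2S, … (default
S = 50) are k-let-shuffled **sequentially in place**: with overlapping
windows, a later window re-shuffles the overlap as left by the earlier one.
Residues past the last full window are shuffled as a shrunk tail window
(skipped if shorter than k, where shuffling is the identity anyway). This
in-place reading was a genuinely open design point (shuffle-and-concatenate
disjoint copies is the alternative); it was chosen as the simplest semantics
consistent with a 50%-overlap default. The practical contract is: global
mononucleotide counts are conserved exactly for every k, and local k-let
counts are guaranteed only for the last window touching each region. For
L ≤ W the model degenerates to the global shuffle.

## GC-bin genomic matching (model `g`)

Each sequence is assigned the integer bin floor(100·GC fraction); a fraction
of exactly 1.0 lands in bin 100 (101 bins total). Binning uses integer
arithmetic (100·strong_count // length) so edge cases like 29/100 are never
misplaced by floating-point rounding. For each foreground, one pool sequence
is drawn uniformly from the same bin. If the bin is empty, an expanding ring
search tries distance 1, 2, … up to `max_bin_distance` (default 100, i.e.
effectively unbounded; 0 disables fallback), pooling the bins at ±d before
sampling; the distance used is recorded in the `MatchResult` so match quality
can be audited. Sampling is with replacement by default — pools binned at one
size can be smaller than the foreground set — and `--no-replacement` restores
the stricter behavior, under which a pool record is never emitted twice and
exhaustion yields unmatched foregrounds rather than repeats.

## Windowed GC genomic matching (model `c`)

The foreground's sliding-window %GC profile (same W, S defaults) is summarized
by its mean and **population** (divide-by-n) standard deviation — the windows
are the complete profile, not a sample, and the acceptance band depends
directly on this choice. A pool candidate is accepted when *every* one of its
own window %GC values lies within mean ± m·sd (default m = 2.6); the match is
a uniform draw over accepted candidates. The acceptance criterion had several
defensible readings (candidate mean within the band; mutual band overlap);
whole-profile containment was chosen because it needs no parameter beyond m,
reduces sensibly as sd → 0 (a homogeneous foreground then demands candidates
homogeneous at the same %GC), and makes acceptance monotone in m, which the
tests verify. The model deliberately does not additionally require global
GC-bin equality: window containment already constrains the mean.

Trailing partial windows are never emitted in any profile (fixed-width
windows keep %GC values comparable); a sequence shorter than W contributes a
single whole-sequence window with sd = 0.

## %GC and the IUPAC alphabet

Only G, C and the strong code S count toward %GC; the denominator is the full
length. This is conservative and reduces to the standard definition on
ACGT-only sequence. Codes R/Y/K/M/N contribute nothing fractional — a policy
worth revisiting if matching against heavily masked genomes matters, since a
long N run depresses %GC toward 0 rather than toward the ambient composition.
The partitioner's N filter is the mitigation in practice.

## Genome partitioning

Each contig is tiled into non-overlapping bins [i·b, (i+1)·b) (0-based,
half-open; identifiers `contig:start-end`, optional BED3 sidecar). Bins whose
N fraction exceeds `max_n_fraction` (default 0.1) are dropped so assembly
gaps do not flood the low-GC bins; the short final bin is dropped by default.
Both thresholds are configurable and declared rather than inherited — with
the filter disabled and remainders kept, concatenating a contig's bins
reconstructs it exactly, which is the invariant the tests rely on. Only the
forward strand is emitted: %GC is strand-symmetric, so reverse complements
add no matching power while doubling near-duplicate content.

## QC metrics

Four comparisons (per-sequence %GC density over the 101 bins, pooled
overlapping dinucleotide frequencies over the full IUPAC alphabet and
restricted to A/C/G/T, and record lengths in 10 bp half-open bins), each
scored with MAE between the frequency vectors and three goodness-of-fit
statistics computed on counts: Pearson's χ², the G statistic, and the
Cressie–Read power divergence at λ = 2/3 (the family's recommended exponent;
λ = 1 recovers χ² exactly and λ → 0 the G statistic, identities the tests
check numerically). Background counts are rescaled to the foreground total
before the statistics, which require matched totals. Cells empty in both sets
are dropped; a cell with zero background but nonzero foreground leaves the
statistics undefined — the report then emits NaN and flags the offending
labels, and `--pool-sparse` merges all cells with rescaled background count
below 5 into one pooled cell to restore definedness. Statistics are reported
raw, without p-values: degrees of freedom after pooling are ill-defined, and
these are audit metrics, not hypothesis tests. %GC density is computed per
sequence (one observation per record), not pooled across residues.

## Synthetic data

The generators emulate a motif-enrichment study's inputs. Foreground sets
draw each base independently with P(G or C) equal to the target (default
lengths and targets are arguments, not constants), optionally ramping that
probability linearly along the sequence to give every record a heterogeneous
window profile for the windowed models. The bin-spanning pool places an exact
count of strong residues per sequence so every 1% GC bin is populated by
construction. The toy genome alternates 1 kb blocks at 30% and 60% GC and
overwrites random 200 bp N runs to exercise the partitioner's gap filter.
What these fixtures do **not** model: dinucleotide structure (CpG depletion),
repeats, masking, or length heterogeneity beyond a uniform range — so passing
tests demonstrate the algorithms' contracts, not performance on real
chromatin data.

## Reproducibility and numerics

One seed drives any run; per-record substreams are derived from (seed, record
index, replicate) so batch output is invariant to splitting. When no seed is
given the CLI draws one from system entropy and logs it, making every run
reproducible after the fact. Problem sizes in the test suite and acceptance
script (1000 sequences × k ≤ 5 for shuffle conservation, 5000 foregrounds for
GC matching, 100-case grids elsewhere) were chosen as the smallest sizes at
which the properties are meaningfully exercised; all complete in well under a
minute on one core.

## Known limitations

- The genomic models match mononucleotide composition only; dinucleotide-
  matched genomic selection is out of scope (the QC dinucleotide comparison
  is the audit for the residual).
- Neither genomic model matches lengths; pool bin size should be chosen
  commensurate with foreground lengths, and the QC length comparison flags
  mismatches.
- The windowed matcher is exhaustive over the pool per foreground (no GC
  pre-indexing); fine for pools up to ~10⁵ sequences, quadratic beyond.
- Uniformity of the shuffle is exact, but the windowed shuffle's distribution
  over outputs has no closed form; only its conservation contracts are
  guaranteed.
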