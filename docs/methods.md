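# Methods

## The classification model

A sample's origin is inferred without any taxonomic interpretation: each
origin class is represented by the set of canonical k-mers its reference
samples contain, and query reads vote for classes in proportion to how much
of their sequence those sets cover. The pipeline has four stages — database
construction, read preparation, read-level scoring, and sample-level
aggregation — each exposed as library functions and composed by the CLI.

### Canonical k-mer databases

All k-mers are canonical (min of forward and reverse-complement under
A<C<G<T), making databases strand-agnostic; windows containing any symbol
outside ACGT are discarded at extraction. Databases are 2-bit encoded sorted
`uint64` arrays, which caps k at 32 — a deliberate narrowing to desk scale
(the default, k = 24, is the value used throughout; larger k would need a
different container). Lowercase (soft-masked) input is uppercased.

Counting happens per sample; the count filter `ci` (default 4) rejects k-mers
seen fewer than `ci` times, the standard guard against error k-mers, which
are overwhelmingly singletons. Two merge modes exist because the filter can
be applied before or after pooling:

* **sample_level** (default): filter each sample, then union. A k-mer must be
  supported `ci` times *within one sample*; error k-mers cannot accumulate
  across samples. Empirically the better mode.
* **class_level**: sum counts across the class, then filter. Rare-but-real
  k-mers spread over samples survive, but so do recurrent artifacts.

Host subtraction `D_j = D⁰_j \ D_H` runs after filtering and merging; the
host set is built from the host reference at `ci = 1` (a genome is not
error-bearing read data, so every k-mer counts). Order of subtraction versus
filtering is a genuine design choice — subtracting first would also change
which k-mers reach the `ci` threshold; we subtract last so the filter sees
the data as sequenced.

### Read preparation

Paired-end mates are fused as `fwd + 'N' + revcomp(rev)`: the mate is
reverse-complemented onto the forward strand and the single-'N' separator
guarantees no k-mer spans the junction (property-tested: the k-mer multiset
of the fused read equals the disjoint union of both halves'). Host filtering
drops any fused read containing at least one host k-mer — operating on the
fused unit means a host hit in either mate removes the whole pair, which
matches the unit of classification. No quality trimming is performed;
qualities are read and discarded.

### Match rate score

The score of read i against class j is position coverage:

    Xi_ij = 100 * |{p : p covered by some window w, canonical(w) in D_j}| / L

realized with a difference array over window hits (O(windows + length) per
read-class pair). This coverage-union formulation keeps Xi in [0, 100] by
construction. **Denominator convention:** L counts the non-'N' positions of
the read. The artificial pair separator is not part of either sequenced
fragment, and an 'N' basecall can never be covered by a valid window, so
counting such positions would cap scores below 100 for reasons unrelated to
database content. `include_ns=True` switches to the full read length for
users who want the stricter ratio.

### Gating and aggregation

With A = {j : Xi_ij >= T and Xi_ij > 0}, a read is skipped when A is empty or
|A| > M. The strict-positivity clause matters only at T = 0: a zero score
means zero shared k-mers, and a read with no overlap anywhere should not vote
at all, so T = 0 means "any actual overlap counts" rather than "everything
counts". M defaults to N (no promiscuity cap); T defaults to 50%.

The three accumulation schemes (simple / fractional / weighted) are as in the
README. Fractional and weighted conserve one point per matched read, so the
per-class similarities 100 * points / q sum to 100 * matched/q <= 100; the
simple scheme deliberately over-counts multi-class reads. q counts *all*
reads including skipped ones — a sample full of uninformative reads should
score low everywhere rather than have its few matched reads inflated.

A subtle non-property worth recording: raising T is **not** monotone in the
points a class collects when M < N, because a read matched to more than M
classes at low T can fall back under the cap at higher T and start
contributing. Lowering M is monotone (it only skips more reads), and raising
T is monotone when M = N under the simple scheme; only those parts are
asserted as invariants.

Ties in the final argmax go to the lexicographically smallest class label,
with an explicit `tie_flag`; an all-zero similarity vector yields
`UNASSIGNED` rather than an arbitrary class. All arithmetic is double
precision; rounding to two decimals happens only in output formatting. (One
consequence: the normalized similarities printed by tools that round the
point totals first — 1.39/3 = 46.33% — differ in the second decimal from the
full-precision value 46.20%; the acceptance script reports the printed
chain.)

## Leave-one-out evaluation

LOO classifies each labeled sample against databases built from all other
samples. Only the held-out sample's own class changes between folds, so the
implementation precomputes per-sample filtered sets (sample_level) or pooled
class counts (class_level) and rebuilds a single class per fold — in
class_level mode by subtracting the held-out sample's counts and
re-filtering, which is exact, not approximate. Equivalence with a naive
rebuild of every database every fold is property-tested.

Confusion-matrix conventions: rows are true classes, columns predictions;
UNASSIGNED outcomes occupy a separate per-row column and are excluded from
every class's false positives (they are abstentions, not errors attributable
to a class). PPV of a class that was never predicted is NaN, not 0. A class
with a single sample yields an empty own-class database for its fold; the
fold still runs and usually lands in UNASSIGNED.

## Mutual similarity and clustering

For unlabeled collections each sample is scored against every *other*
sample's single-sample database (ci-filtered, host-subtracted). The matrix is
asymmetric — the database and the query swap roles across the diagonal — and
the diagonal is NaN: self-similarity is uninformative and would otherwise
dominate row normalization. Row normalization rescales each row so its
maximum defined cell is 100%, compensating for large differences in database
size between samples; all-zero rows are left untouched and flagged.
Clustering then takes connected components of the graph with an edge where
max(value[r,c], value[c,r]) >= threshold — the optimistic symmetrization, so
one strong direction suffices. Connected components were chosen over
density-based methods because the normalized matrices of interest are nearly
block-structured; the threshold (default 50%) can sit anywhere in the gap
between within-group and between-group similarity.

## The synthetic data generator

The simulator emulates the *structure* of a multi-city collection, not its
biology: per-class i.i.d. uniform ACGT genomes (optionally sharing a common
segment controlled by `shared_fraction`), samples of paired reads drawn
uniformly with per-base substitution errors, and a fraction of pairs drawn
from an independent host genome. Defaults — 4 classes × 3 samples, 50 kb
genomes, 2,000 pairs of 100 nt reads, 1% substitutions, 10% host reads,
50 nt insert gap — give ≈8× within-sample coverage, enough that genuine
k-mers clear ci = 4 while error k-mers (mostly singletons) do not.

What the simulator does *not* model: realistic community composition and
abundance skew, shared content between unrelated real cities, platform error
profiles (indels, quality-dependent errors), GC bias, or duplicated reads.
Passing the synthetic recovery test therefore demonstrates the pipeline's
correctness and its noise/contamination handling, not field accuracy on real
urban metagenomes, where between-class overlap is far higher and accuracies
well below 1.0 are expected.

Determinism: one global seed; per-sample seeds derive from blake2b hashes of
sample ids combined with the global seed, so regenerating any subset of
samples reproduces them byte-for-byte.

## Problem sizes and runtime

The shipped tests and examples run on collections of 2–4 classes, 2–3
samples each, genomes of 2–50 kb and 50–2,000 read pairs per sample — sizes
chosen so the full suite completes in well under a minute of CPU while still
exercising ci filtering, host subtraction, gating and both merge modes at
realistic coverage. The containers scale linearly in unique k-mers; tens of
millions of k-mers per class are practical in memory, beyond which an
external-memory counter should replace the construction stage.

## Known limitations

* k ≤ 32 (2-bit uint64 packing).
* Whole databases live in RAM; no streaming or on-disk query mode.
* The coverage-union score is one concrete realization of "nucleotides in
  shared k-mers / read length"; scoring algorithms that extend matches across
  near-identical windows could differ on adversarial reads.
* Mutual-similarity clustering via connected components chains groups through
  single strong links; block structure in the normalized matrix is assumed.
* Open-world classification (queries from none of the reference classes) is
  out of scope; UNASSIGNED arises only from all-zero similarity vectors.
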