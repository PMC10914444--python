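# Methods

## Model of a read

A read is modelled as junk, a *structure* (ordered segments: constant
flanks with known sequence; a barcode and a UMI known only by length), an
insert, and more junk, possibly reverse-complemented, possibly
concatenated with a second such molecule (a chimera), all corrupted by
per-base substitutions, insertions and deletions.  The default structure
is the 10x Genomics 3' v3 layout: the 22 nt 3' end of the read-1 primer
(`CTACACGACGCTCTTCCGATCT`), a 16 nt cell barcode, a 12 nt UMI, and 9 nt of
polyT.  The primer/polyT letters are the published standard sequences and
every element — sequences, lengths, order — is overridable; a structure
may also order the barcode before a flank, or omit the barcode entirely
(pure search mode).

## Alignment core

All matching is unit-cost Levenshtein distance.  Two extensions make it a
structure-aware search:

* `?` wildcards (the barcode+UMI region of the pattern) substitute
  against `A/C/G/T/N` at cost 0; indels touching `?` cost 1 like any other
  symbol, so the metric remains a true edit distance.  Replacing any
  pattern position by `?` can therefore never increase a distance
  (monotonicity, property-tested).
* The mask sentinel `X`, written over already-found structure, mismatches
  everything *including itself*.  A fully masked region has infix distance
  ≥ pattern length, so iterated search cannot rediscover a masked hit.

`N` in a read matches only `N` and `?`; this is deliberately conservative
so that N-runs cannot impersonate a flank.

Semi-global ("infix") search finds the substring of the read minimising
the pattern's edit distance, both substring ends free.  Ties are broken
deterministically: smallest start, then smallest end.  The minimal start
is obtained from the same DP run on the reversed pair; the minimal end
from a global DP over the suffix.  Tie-break order mirrors scan order,
which keeps the mask-and-iterate loop reproducible.  The DP is vectorised
with numpy row by row; the in-row dependency is a prefix-minimum
(`cur = min.accumulate(cand − j) + j`).  When `edlib` is importable it is
used as a k-bounded pre-filter (with `?` equivalences) that answers "no
hit within `max_d`" cheaply; any actual hit's distance and coordinates
are recomputed by the package's own DP, whose tie-breaks are the
contract.  `edlib` also serves as an independent cross-check in the test
suite; the two never share a code path.

Bounded distance (`bounded_levenshtein`) aborts a row whose minimum
exceeds the bound; correctness is defined by agreement with the unbounded
distance whenever within the bound, which the tests check exhaustively on
short strings and on random pairs against a memoised textbook recurrence.

## Window extraction

After a flank hit (default tolerance: 8 edits over the whole pattern) the
wildcard region is delimited by traceback of a single global alignment of
the pattern against the matched substring; traceback ties prefer
match/substitution, then pattern-gap, then text-gap, making the interval
deterministic.  The interval is widened by ±5 bp (window padding) and
clipped to the read: with up to `flank_max_d` edits confined to flanks,
boundary slippage is bounded, and the padding keeps the true barcode
inside the window (tested by construction).

## Barcode assignment and its limits

Each whitelist barcode is scored semi-globally against the window
(vectorised across the whole whitelist in one DP).  The unique minimiser
within `barcode_max_d` (default 2) is assigned; ties are AMBIGUOUS;
minima above the bound are NO_BARCODE.  The whitelist is sorted and
de-duplicated on ingest, so results do not depend on input order.

Two quantitative consequences worth knowing:

* **Yield ceiling under noise.**  With per-base rates sub 0.05 / ins
  0.025 / del 0.025 the expected number of edits inside a 16 nt barcode
  is 1.6, so only ≈ 78–82% of reads can satisfy `d ≤ 2` regardless of
  method.  Assignment *accuracy among assigned reads* is the right
  quality metric at this error rate (≥ 95% in the stress test; typically
  ≥ 99% at whitelist spacing ≥ 5).
* **The spacing guarantee is approximate.**  Whitelist minimum pairwise
  distance ≥ 2k+1 guarantees a unique nearest neighbour for ≤ k edits
  *measured against the barcode region alone*.  Because assignment scores
  barcodes against the padded window, a shifted window substring
  (pad/flank context plus a true-barcode prefix) can occasionally lie
  within k of a *different* whitelist barcode, producing a legitimate tie
  (observed ≈ 2 × 10⁻³ per read at whitelist size 48, k = 2).  The
  unique-minimum rule then reports AMBIGUOUS rather than guessing, which
  is the designed behaviour.

The UMI is read off the strand-normalised read immediately after the
located barcode (before it, for structures that order the UMI first); a
shorter-than-expected tail yields a truncated UMI plus a flag.

## Chimera handling and trimming

Found structure (flanks + variable region) is masked and the search
repeats, at most 10 rounds per strand, until nothing new is found; the
reverse complement of the masked read is then scanned identically, with
forward hits' images masked by coordinate reflection so both passes share
one coordinate system.  Loci whose barcode could not be assigned still
mask their interval — otherwise one bad locus would deadlock discovery of
a second molecule downstream.  Records are ordered by position on the
original read; each record's insert runs from the end of its own
structure to the start of the nearest downstream structure in its strand
frame (or the read end), so two-part same-strand chimeras tile exactly
into their constituent inserts.  For opposite-strand chimeras the cut
point between back-to-back inserts is not identifiable from structure
positions alone; the full inter-structure gap is attributed to each
record's own frame.  With splitting disabled the engine performs a single
search-assign pass (forward, then reverse complement) and returns at most
one record.  Reads with no assignable structure pass through untrimmed to
a separate unassigned stream.

## Discovery and the knee filter

Without a whitelist, the barcode-length substring immediately following
the left flank (delimited by the same traceback) is tallied; substrings
containing `N` or truncated below the barcode length are skipped.  Both
strands and chimera iteration are honoured, so every embedded structure
contributes one putative barcode.

The filter sorts barcodes by count (ties lexicographic, each barcode its
own rank) and computes the rolling-window derivative of the knee curve in
log10–log10 space with 1-based ranks:

    s_i = (log10 c_{i+w} − log10 c_i) / (log10 (i+w) − log10 i),  w = 20

The most negative slope within the search range is the inflection point;
barcodes ranked at or above it are kept.  The default range starts at
rank 10 (skipping super-loaded droplet artifacts) and — a deliberate
design choice — ends at the last rank whose count is at least
`min_search_count` (default 5).  Among barcodes seen only once or twice,
integer counts form long plateaus (… 2, 2, 1, 1, 1) whose single-rank
steps make a per-rank log derivative arbitrarily steep (the denominator
`log10((r+w)/r)` vanishes as r grows), so an unbounded search would
always select the 2→1 plateau edge instead of the real knee.  Both ends
of the range are overridable.  When the inflection slope is not at least
twice the median slope magnitude the result is flagged low-confidence
(a knee-less, power-law-like curve).  An optional log–log diagnostic plot
marks the inflection.  A user whitelist, when supplied, restricts the
table *before* the knee; non-whitelist counts are discarded, not
reassigned.

## Simulator

The generator emulates the read model above with iid errors applied
segment-wise (substitutions, then insertions, then deletions) so truth
coordinates stay exact; error statistics are identical to template-wide
application.  Defaults are the study conditions used throughout: ONT-like
rates (0.05/0.025/0.025 ≈ 10% per-base edits), 3% chimeras (the rate
observed in real long-read single-cell data), both strands equally
likely, inserts 50–150 nt, junk 0–50 nt per side, uniform barcode
abundance (lognormal optional).  A barcode-only mode applies exactly k
edit operations to the barcode and nothing else, isolating the correction
guarantee from flank noise.  Whitelists are rejection-sampled to a
minimum pairwise distance.  Output (FASTQ plus truth table) is
byte-identical per seed.

What the simulator does *not* model: homopolymer-biased or
quality-correlated ONT errors, transcriptome-derived inserts, barcode
sharing between gel beads, or UMI collisions.  Passing tests therefore
demonstrate the correctness of the search/correction/splitting machinery
under a calibrated iid error load, not performance on any particular real
instrument run.

## Numerical and interface choices

* All sequences are uppercased on ingest; FASTQ qualities are carried
  verbatim and sliced alongside trimming.
* I/O streams record by record (constant memory), autodetecting gzip and
  FASTA/FASTQ; output FASTA is never line-wrapped so round trips are
  byte-exact.  Logs go to stderr only; stdout is reserved for records,
  which is what makes `demuxlr | demuxlr` pipelines composable.
* `--threads` is accepted for interface compatibility but processing is
  serial and batch-ordered; outputs are byte-identical for any thread
  count by construction.
* Problem sizes in the test suite and acceptance script (e.g. 50,000
  reads for the noise stress, 5,000 for zero-error completeness, 8,000 in
  the acceptance summary) are chosen so the whole suite runs in minutes
  on one CPU while keeping binomial confidence intervals on the reported
  rates below about one percentage point.
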