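# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `horscan`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Alpha-satellite DNA organizes primate centromeres as tandem arrays of
~171 bp monomers. Monomers mutually diverged by less than 5% form a
*monomer type*; an ordered sequence of *n* types repeated in tandem with
low inter-copy divergence is an *n*-mer higher-order repeat (HOR). In
Willard-type HORs each type occurs once per unit. Cascading HORs repeat
some types within the unit; laid out with one column per type and rows of
distinct types, they form a multi-row schematic whose row lengths are a
compact structural signature (e.g. a 58-monomer unit over 44 types with
rows 13/16/7/4/18).

## Monomer extraction

The consensus monomer is aligned semi-globally (edlib, infix mode) against
both strands. **Identity** is matching columns over total alignment columns
(matches + mismatches + gaps), the standard indel-tolerant definition;
hits at ≥ `min_identity` (default 0.95) and length 150–200 bp are
retained.

*Candidate generation.* Exact 12-mer seeds of the (oriented) consensus are
matched genome-wide with a vectorized rolling-code index; each seed match
proposes a monomer start, and each distinct candidate window (±16 bp pad)
is aligned once. At the 95% identity threshold a monomer carries at most 8
mismatches over 171 bp, which always leaves an intact run of ≥19 bp, so
every retainable monomer is guaranteed at least one exact 12-mer seed; a
separate tandem-extension step is therefore unnecessary.

*Overlap resolution.* Hits are accepted greedily by identity (ties:
leftmost start, '+' strand first) into a non-overlapping tiling. Tandem
neighbours produce co-optimal alignments whose boundaries jitter by a few
bases; a hit overlapping an accepted one by ≤10 bp per side is trimmed to
the uncovered interval (identity recomputed) rather than discarded, and
sub-10 bp gaps between adjacent same-strand hits are absorbed into the
left hit. Without these repairs, whole monomer classes at tandem
boundaries are lost or acquire spurious indels.

*N-gaps.* Any monomer whose interval contains an undefined base is
excluded. Non-ACGTN IUPAC codes are normalized to N on input and handled
by the same rule.

*Arrays.* Consecutive hits more than `max_join_gap` (default 500 bp, about
three monomer lengths) apart start a new array. Monomer enumeration is
1-based across arrays in genomic order.

## Monomer typing

Pairwise divergence is global-alignment edit distance divided by alignment
length. Clustering is greedy with **static centroids**: scanning in
enumeration order, a monomer joins the first type whose centroid (the
founding monomer's sequence) is strictly less than `type_threshold`
(default 0.05) away, else founds a new type. Static centroids avoid
single-linkage chaining, which could transitively merge types more than 5%
apart, and make assignment order-stable and deterministic.

After a provisional HOR segmentation, a **column reconciliation** pass
re-checks each monomer against the aligned column it occupies across
copies: if the column majority is another type and the monomer lies within
the threshold of that type's centroid, it is reassigned. This integrates
sequence similarity with positional context and is idempotent.

## MD and GRM diagrams

An MD-point (*l*, *p*) marks monomer *l* whose next same-type occurrence
is exactly *p* positions downstream (nothing of that type in between), for
*p* ≤ `max_period` (default 90). The GRM content is the per-period
MD-point frequency; the reported frequency table lists periods with counts
above a threshold (default 90).

**MD line segments** are called greedily: a segment absorbs the next point
of its period while the running density (points per enumeration position)
stays ≥ `min_density` (default 0.5), and must contain ≥ `min_run`
(default 20) points. Both are tunable: a cascading unit with *k* distinct
once-per-unit types out of *n* monomers can reach density at most *k/n* at
the full period, so doublet-heavy architectures (e.g. an 18mer of t1-tn
doublets, density ≤ 8/18) need `min_density` ≈ 0.4, and short test
fixtures use smaller `min_run`.

## HOR family detection

*Period selection.* Candidate (period, segment) pairs are ranked by the
segment's **type-sequence autocorrelation mass**: the number of positions
with `type[i] == type[i+p]`. At the true unit period this holds at every
position of every adjacent canonical pair, so the full unit outranks
intra-unit subfragment periods (which match at only a fraction of
positions — e.g. one half for a doublet period-2 inside an 18mer, even
though its raw MD frequency is higher) and variant-offset periods (n±k
across indel variants, which match only near the variants). Accepted
segments claim their region; overlapping lower-ranked candidates are
skipped. A claimed segment is expanded to its enclosing monomer array
(when the array holds no other family), so leading/trailing variant copies
outside the strictly periodic core are still segmented.

*Anchor and unit cutting.* Within a region at period *n*, candidate
anchors are types that begin an exact *n*-cycle and recur at exactly
distance *n* (once-per-unit types). Among candidates the anchor (a)
excludes types recurring at sub-unit distances (< n/2), which sit in
duplicated rows and would cut inside variant copies; (b) prefers the type
whose total occurrence count is closest to the expected unit count
(region length / n) — a type deleted in some variants merges copies, one
duplicated in some variants splits them; (c) pins the phase to the
earliest-occurring candidate, i.e. the first monomer of the first complete
copy. Copies are cut at every anchor occurrence; stretches before the
first and after the last anchor are dropped as partial edge units, so an
array of N planted copies is recovered as N−1 (the edge semantics are
deliberate and reported as computed).

*Canonical and variants.* The canonical unit is the most frequent exact
*n*-length type sequence (ties: earliest). A copy is canonical (`C`) only
on exact type-sequence match; otherwise it is a variant `V<m>` named by
its monomer count, with a unit-cost monomer-level alignment to the
canonical recorded for downstream row alignment. Distinct same-length
variants share a name but differ in the detailed scheme output.

*Consensus and divergence.* Canonical copies share a type sequence, so
monomers align position-by-position. Within a position, every monomer is
globally aligned to the position's **modal monomer sequence** and bases
are voted per column (ties alphabetical; a column is dropped only when
deletions hold a strict majority; insertions relative to the reference do
not vote). The modal reference matters: an atypical reference (e.g. a
boundary-trimmed founding monomer) would systematically shift or drop
columns for every copy. Divergence is measured per canonical copy against
this consensus, in percent; the family statistic is the arithmetic mean.
Consensus-referenced divergence is roughly half the mean pairwise value
under independent noise; the package consistently reports the
consensus-referenced quantity.

## Cascading layout

The layout is a greedy left-to-right rule with a column cursor: a monomer
of an already-columned type is placed in its column when that column lies
right of the cursor, otherwise it starts a new row there; a new type opens
a fresh column immediately right of the cursor. The rule provably yields
rows of distinct types and single-type columns, and flattening the scheme
reproduces the unit exactly (property-tested). A unit with no repeated
type is a single row — Willard's type; anything else is cascading. Variant
schemes reuse the canonical column order; novel types append flagged
columns. Variant rows are aligned to canonical rows by maximal type
overlap (integer-scored global alignment; at ties the later of two equal
rows becomes the inserted one, so a duplicated row lands in the slot after
the row it repeats), producing the per-copy row-count table with dashes
for missing rows.

## Synthetic arrays and the species analogs

The generator plants a type library as mutated copies of the consensus:
small libraries use disjoint mutation-position sets (pairwise separation
met by construction, then verified against the alignment-based divergence
and the mutation count bumped if normalization dips below target); larger
libraries use random sets with rejection resampling. Constraints are
`inter_type_div` between types (must exceed twice the type threshold, so
planted types are unambiguous) and an optional ceiling on divergence from
the consensus so that every type stays within scan reach
(≤ 1 − min_identity, minus margin). Copies receive i.i.d. per-base
substitutions; indels are a separate opt-in knob so divergence arithmetic
stays exact for calibration. Structural variants are expressed as unit
edits (duplicate/delete a slice, insert a novel-type monomer). Flanks are
uniform-random DNA (default 2 kb); an optional N-gap exercises the gap
rule. Truth tables list every monomer interval and every copy label.

With the default geometry (types ~7% from the consensus, ≥11% apart) the
synthetic arrays must be scanned at `min_identity` ≈ 0.89–0.90 — the
planted types are intentionally far from the single scan consensus, as
real monomer types are; the 0.95 default applies to a consensus chosen for
the array under study.

The `benchmarks` module instantiates desk-scale and full-scale analogs of
the published great-ape Y-centromere architectures: the orangutan 58mer
cascading superHOR (44 distinct/14 repeated types, rows 13/16/7/4/18, 310
copies arranged per the published C/V string, 0.25%-scale mutations) with
its 45mer companion (37 types, rows 35/9/1, 0.81% scale), the human 34mer
(54 copies/49 canonical), chimpanzee 28mer (259/237) and gorilla doublet
18mer (779/405). Variant mixes follow the published row signatures where
given (V74/V90/V59/V57/V55/V42 as row/monomer edits of the canonical
58mer); where the arrangement is not published (human/chimp/gorilla C/V
order, gorilla/chimp/human mutation scale 0.0025), variants sit at the
array peripheries — the standard observation for satellite arrays — and
the divergence scale matches the highly-homogeneous canonical arrays
reported across species. These choices are fixed study conditions, not
tuning knobs.

What the analogs do *not* emulate: real monomer sequence content,
suprachromosomal-family structure, long-range homogenization gradients,
assembly artifacts, or inter-array linkage. Passing tests demonstrate that
the algorithms recover planted higher-order structure under realistic
noise; they do not validate biological conclusions about any particular
assembly.

## Numerical and degenerate-input choices

- All coordinates 0-based half-open internally and in BED; 1-based only in
  enumerations and human-readable reports.
- Ties everywhere are broken deterministically (identity then leftmost;
  alphabetical bases; earliest occurrence), so reruns are byte-identical.
- Empty FASTA, records without headers and empty records raise descriptive
  errors; the CLI maps usage errors to exit 2 and runtime errors to 1.
- Problem sizes in the test suite are chosen for quick feedback (arrays of
  tens of copies, 20 recovery seeds); the acceptance script runs the
  species analogs at full published copy numbers in about half a minute.

## Known limitations

- Anchor-based cutting assumes the anchor type survives in (nearly) all
  copies. A variant that deletes or duplicates *every* once-per-unit type
  region (e.g. a variant dropping the unit's entire first half plus
  duplicating the rest) can merge or split copies at its boundary; labels
  adjacent to runs of consecutive variants can shift by one position.
- A variant whose inserted row contains the anchor type (e.g. a
  duplicated first row) is split into two shorter copies rather than
  reported as one long variant.
- The canonical unit's phase is pinned by the anchor rule; published
  schemes have their own (unexplained) phase, so row-count vectors match
  up to rotation of the unit. In the shipped analogs the earliest-type
  rule reproduces the published phase.
- Monomer types are compared against one configured consensus; arrays
  whose monomers diverge beyond ~(1 − min_identity) from it are invisible
  to the scan. Divergence-based results shift slightly under a different
  consensus choice.
- The MD/GRM histogram is computed before column reconciliation; the rare
  reassignments do not feed back into the diagram.
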