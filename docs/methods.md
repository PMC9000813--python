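# Methods

## Model

A *nucleotide signature* for a target taxon is a window `w` over the 15
IUPAC nucleotide symbols satisfying two criteria against reference sets of
unaligned sequences:

* **Conservation** (ingroup `I`): `f(w) = |{s ∈ I : w occurs in s}| / |I| ≥ τ`.
  Occurrence is exact forward-strand substring presence. This alignment-free
  definition is equivalent, for an invariant region, to column identity in a
  multiple alignment of the ingroup, but needs no aligner and is unambiguous
  for inputs trimmed differently. Ingroup records represent one locus in one
  orientation (a curated barcode set), so conservation is forward-strand.
* **Specificity** (outgroup `O`): `d(w) = min` over records, strands and all
  full-length placements of the per-position mismatch count; `w` is specific
  when `d(w) ≥ d_min`. Outgroup orientation is arbitrary, so both strands
  are searched. Placements overhanging a record are not considered; a record
  shorter than `w` contributes +∞ ("this region" is compared full-length).
  An empty outgroup gives +∞ with a warning (vacuous specificity).

Two monotonicity laws make the minimal-length search exact:

1. *Conservation is anti-monotone in length*: any sub-window of `w` occurs
   wherever `w` occurs, so `f` can only rise when `w` shrinks.
2. *Hamming specificity is monotone in length*: any placement of an
   extension `w' ⊇ w` restricts to a placement of `w` with no more
   mismatches, so `d(w') ≥ d(w)`.

Hence all admissible lengths at a fixed anchor form two opposing prefix
ranges and the shortest window that is both conserved and specific can be
found by (a) enumerating maximal conserved regions (every conserved window
is a sub-window of one, by law 1), then (b) per anchor inside a region,
binary-searching the smallest length with `d ≥ d_min` (law 2). Ties among
equal-length winners break deterministically: earliest region, leftmost
anchor. With the optional edit-distance metric (semi-global, via edlib, for
indel-containing outgroups) law 2 is not guaranteed and the per-anchor
search falls back to a linear scan.

## Match policies

`strict` — a symbol matches only itself. Default for conservation: a
signature must be literally invariant, so an `N` in a reference record
breaks conservation rather than silently matching.

`compatible` — symbols match when their base sets intersect. Default for
specificity and detection: an ambiguity code in an outgroup or
Sanger-consensus record *could* be the matching base, and counting it as a
match is the conservative direction (it can only lower `d`, never
manufacture specificity; in detection it avoids missing a hit hidden behind
a consensus code).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `τ` (threshold) | 1.0 | required conservation fraction; values < 1 tolerate database errors and emit a warning |
| `d_min` | 1 | required outgroup distance — "at least one variation" |
| `min_len`, `max_len` | 15, 55 | length bounds of the sweep; the packaged example explores 20–55 bp, and both failure directions (long → not conserved, short → not specific) are visible in its candidate ladder |
| `metric` | hamming | positional variation within the region; `edit` for indel-rich outgroups |
| primer matching | ≤ 2 mismatches, 3′-terminal 3 bases exact | placement tolerance reflecting PCR practice (extension aborts on 3′ mismatches); configurable |
| detection | 0 mismatches | a signature is retrieved, not aligned; compatible policy for consensus codes |
| `max_product_len` | 500 | product cap; product length includes both primers |

Coordinates are 0-based half-open internally, 1-based inclusive in reports.

## Synthetic data: what it emulates and what it does not

The generators produce plain `{A,C,G,T}` sequences (ambiguity codes are a
property of real records, not of the planted truth) and every planted claim
is re-verified by independent scanning after generation — never trusted
from construction; assembly is re-drawn (seeded) on the rare verification
failure.

* **Ingroup**: records are `flank + core + flank`, the flanks per-record
  mutated copies of a shared ancestor at a per-site rate (default 0.1;
  the demonstration scenario uses 0.3), the core never touched. This
  emulates a barcode region with a conserved block embedded in variable
  context. It does *not* model transition/transversion bias, rate
  heterogeneity, indels, or phylogenetic correlation among records.
* **Outgroup with planted period `p`**: the outgroup contains a copy of the
  core substituted at every `p`-th core position (so its longest exact
  shared run is `p−1`), plus every core sub-window of length `p−1`
  (spacer-separated), plus unrelated decoy records. Spacers, junctions,
  flanks and decoys are rejection-sampled away from core `p`-windows; the
  periodic-copy construction alone would leave short windows spanning a
  substitution specific, which is why the `(p−1)`-window embedding is part
  of the construction. Verified before returning: every core window shorter
  than `p` occurs exactly somewhere in the outgroup (not specific), and at
  least one core `p`-window is absent from both strands of every record
  (specific). Against a core-sharing ingroup the minimal qualifying length
  is therefore exactly `p`. Periods below 4 are rejected: random decoys
  contain most 3-mers, making a planted minimum that small unreliable.
* **Mixture queries**: each batch is a shuffled concatenation of one
  signature-bearing fragment and `n` unrelated fragments (lengths 120–180 bp
  by default, the mini-barcode scale), optionally end-truncated by a
  `degrade` fraction — the signature itself is never truncated. A
  `plant=False` variant is the negative control. This emulates detection in
  a multi-ingredient, degraded preparation; it does not model chromatogram
  noise, chimeric reads or quantitative composition.
* **Demonstration scenario**: ingroup of 12 records planted with the 55-bp
  fragment, one record carrying a single substitution at core position 19
  (0-based) plus broken flank bases adjacent to the core, against a
  period-23 outgroup. The substitution splits the conserved block so the
  five longest ladder candidates lose full conservation while the 23-mer
  and the 20-mer inside it remain invariant; the period makes windows below
  23 non-specific. The mined winner is then exactly the packaged 23-mer,
  and the per-candidate verdict pattern matches the packaged labels. The
  scenario is verified (its conserved regions are exactly the two expected
  blocks) and re-seeded on the rare failure.

Passing tests on these generators show the algorithms are exact with
respect to the stated criteria and recover planted structure; they do not
show that a signature mined from any particular real outgroup set is unique
in nature — that claim is only as strong as the outgroup provided.

## Numerical and design choices

* Conserved-region discovery computes, per start position, the maximal
  conserved length by binary search (valid by anti-monotonicity), keeps
  left/right-maximal windows, anchors each distinct region on the first
  record containing it, and drops content-nested regions. With τ = 1 only
  the first record needs anchoring (every conserved window occurs there).
* Specificity ties are broken by set order, then smallest plus-strand
  offset, then `+` before `−`; minus-strand placements are computed as the
  reverse-complemented window against the plus strand, so reported offsets
  are always plus-strand. Mismatch counting is vectorized (numpy sliding
  windows over 4-bit base masks).
* The global sweep searches *all* sub-windows of conserved regions, not one
  nested candidate family: minimality of "the" signature is only
  well-defined against the full search space. The audit trail records every
  probe; every audited window shorter than the winner fails at least one
  criterion.
* Mining with an empty outgroup returns the shortest conserved window and
  warns; an empty ingroup is an error.
* Duplicate FASTA ids are an error (detection reports key on id); gaps are
  stripped on ingest; `U→T` and case normalization applied; non-IUPAC
  symbols are an error naming the record.
* Problem sizes in tests and the acceptance script (ingroups of 4–12
  records for mining scenarios, a 349-record panel for the conservation
  figure, 60-mer cores, 3 seeds × 26 periods in the script and 20 × 26 in
  the test suite) are chosen as the smallest sizes at which every claim is
  non-trivially exercised; all are seeded and re-verified rather than
  assumed.

## Known limitations

* Specificity is only meaningful against the outgroup actually supplied;
  the toolkit does not query remote databases and reports no E-values —
  scoring is exact, not heuristic.
* In-silico PCR uses placement + mismatch counts only: no melting
  temperature, secondary structure or dimer checks.
* The Hamming metric ignores indels between ingroup and outgroup homologs;
  use the edit metric (linear-scan search) when that matters.
* Detection is presence/absence of the window; it gives no quantitative
  estimate of the target's proportion and no below-genus resolution when
  the signature is genus-level.
* The edit metric's per-anchor search is linear in length, so sweeps with
  it are slower and tie-break order among equal-distance placements follows
  edlib's reported first location.
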