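# Methods

## Coordinates and records

All coordinates are 0-based, half-open, on the deposited linearization of
the circular molecule. Circularity is explicit on the record and on
intervals (a `wraps` flag), never inferred. GenBank `n..m` locations become
`[n−1, m)`; joins become multi-part features in biological exon order.
tRNA symbols are canonicalised to `trnX_ANTICODON` (`trnI-CAU` →
`trnI_CAU`) because the spacer analysis keys on that symbol.

Base composition excludes ambiguous bases (N) from both the AT and GC
tallies; the denominator is the unambiguous count, matching standard GC%
practice. Printed percentages are rounded half-up to the table precision
(1–2 decimals), so published values are reproduced digit-for-digit.

## Inverted-repeat detection and partition

IR arms in plastomes are near-identical, so the detector demands exact
reverse-complement identity by default; that makes maximality a testable
property (extending any boundary by one base breaks the identity). The
search k-mer-seeds (k = 25) matches between the sequence and its reverse
complement. A true inverted match keeps `i + j` constant over its seeds
(`i`, `j` the left/right arm k-mer starts), so seeds are grouped by that
antidiagonal, split into contiguous runs (distinct pairs can share an
antidiagonal), verified, and extended outward and inward to maximality.
The longest pair wins; ties go to the smallest left-arm start, making the
result deterministic. The search runs on the deposited linearization: arms
spanning the origin are out of scope, which holds for deposited plastomes
and for everything the generator emits (both start in the LSC).

The two arcs between the arms are assigned longer → LSC, shorter → SSC.
Junction points are the first IR base moving from single copy into the
repeat (so JLB sits at the IRb start, JSB at the IRb end, and so on).
A junction inside a gene reports that gene with `overlap_bp` = gene bases
on the IR side; containment is half-open, so a junction at a gene's first
base is containment and one at the base past its end is intergenic
context. Intergenic labels name the repeat-side gene first
(`trnH_GUG/rps19`), matching how junction spacers are conventionally named
from the IR outward. Genes must lie within 5 kb (configurable) of a
junction to resolve its context; otherwise the junction is reported
`unresolved` rather than raising.

## rps16 integrity classes

Each reference exon is located by local alignment (Biopython
`PairwiseAligner`, match 1 / mismatch −1 / gap open −2 / extend −1; both
strands). An alignment qualifies when its overall identity is ≥ 80%
(`min_identity`) *and* it contains at least one contiguous ungapped block
of ≥ 20 bp (`min_anchor_bp`) at that identity — without the contiguity
requirement, local alignment occasionally assembles a qualifying mosaic of
short random matches in ~1 kb of unrelated sequence, which no real
retained fragment looks like. `retained_bp` is the reference coverage of
the best qualifying alignment.

An exon is *full* at ≥ 90% retained (`full_fraction`), *anchored* at
≥ 20 bp. The class follows: both full → INTACT; exon 2 anchored but not
full → EXON2_PARTIAL; exon 2 absent with exon 1 anchored → EXON2_LOST;
exon 2 full without exon 1 → EXON1_LOST; neither anchored →
COMPLETE_LOSS. Only the endpoint states are observed in nature, so the
thresholds that make the spectrum decidable are exposed as parameters.
When `trnK_UUU` and `trnQ_UUG` are annotated, the pipeline restricts the
search to that neighbourhood, which further suppresses spurious anchors.

## In-silico PCR and the section marker

A product requires the forward primer on one strand and the reverse primer
on the opposite strand downstream within `max_amplicon` (default 3,000 bp),
each within `max_mismatch` (default 0) mismatches and with an exact
3′-terminal base — the polymerase-extension-critical base. Product length
runs between the outer primer ends inclusive, the standard sizing that
makes a 20 + 360 + 20 construct a 400 bp product. Circular templates are
scanned across the origin; the wrapped image of a linearly paired site is
suppressed so each physical product is reported once. The section caller
is a pure function of product lengths: one product in [1,200, 1,800] bp →
sect. Veratrum, in [300, 500] bp → sect. Fuscoveratrum, anything else
indeterminate.

## Spacer architecture and tandem repeats

Both `rpl23` and `ycf2` lie in the IR, so the spacer exists twice as
reverse complements; the copy with the shortest `rpl23`-end →
`ycf2`-start gap (either strand) is profiled and the mirror skipped to
avoid double counting. `trnI_CAU` copies are counted by full-length
ungapped similarity (≥ 95% identity, either strand, greedy best-first
non-overlapping) rather than from annotation, because duplicated copies
are frequently under-annotated in deposited records. Sub-spacer lengths
are measured from those similarity hits.

A tandem tract `(start, p, c)` is `c` consecutive `p`-periodic copies,
each within `⌊0.1·p⌋` mismatches of the **first** copy (the first copy is
the consensus — deterministic). All candidates with `c ≥ 2` and
`p ∈ [18, 250]` are enumerated and right-extended maximally; overlapping
reports collapse to the tract with most copies, ties to smaller period,
then smaller start. A partial trailing copy is reported as `tail_bp`,
never as a unit; the table-style "repeat unit count" is the total integer
copy count across qualifying arrays. Because of the per-copy mismatch
allowance, the reported start of an exact planted tract can sit up to
`⌊0.1·p⌋` bases left of the planted position (a shifted window still
qualifies and the tie-break prefers the smaller start); copy counts and
unit lengths are unaffected. The detector is verified exhaustively against
a brute-force enumeration of all (start, period, run) triples on sequences
up to 500 nt.

Motif scanning is exact substring search over the catalog
{R1, R1a, R1b, D7, U16}; overlapping and nested hits are all reported
(R1 contains R1b; U16 starts with D7), forward strand by default.

## Scenario decision table

The repeat-origin scenarios were narrated, not algorithmised, in the
literature; the six-rule table in `ssm_classify` is this package's
formalisation, evaluated top-down with first match winning:

1. no arrays with unit ≥ 18 bp → **NONE**
2. ≥ 3 trnI copies, a unit carrying the full trnI_CAU (≥ 95% identity,
   rotations included), no U16 → **I**
3. exactly 3 trnI copies and U16 present → **III-B**
4. exactly 2 trnI copies, exactly 2 units, R1a present → **II**
5. 1 trnI copy and an array inside the trnI–ycf2 sub-spacer → **III-A**
6. otherwise → **COMPLEX**

Rule 2 uses ≥ 3 (not = 3) to tolerate over-planted generators; rule 4
requires the R1a motif to be observed in sequence, not merely inferred
from the duplication — the ambiguity is resolved conservatively and the
evidence flag says so. Survey rows whose published labels carry
unexplained footnote marks are excluded from the reproduction test rather
than guessing an unprinted legend. The <24 bp / ≥24 bp length spectrum
aggregates unit copies across profiles; its ratio is undefined (flagged)
when no long units exist.

## Synthetic data

The generator emits LSC | IRb | SSC | IRa with IRa the exact reverse
complement of IRb, then forces the single bases flanking both boundaries
to break the identity, so planted partitions are recovered
coordinate-exactly at mutation rate 0. Substitutions (configurable rate
≤ 5%) are applied to LSC, SSC and IRb before mirroring — IR copies evolve
in concert (copy correction), which keeps the arms identical and is why
low mutation rates only jitter junction placement by at most the length of
a boundary-adjacent mutated run.

Fixed content: psbA near the LSC start; a trnK–rps16–trnQ block whose
segment layout realises the marker products (intact 1,729 bp, exon-2 loss
1,500 bp, whole-gene loss 400 bp, 47 bp exon-2 remnant 507 bp); the
junction cassette rps3–rpl22–rps19–trnH_GUG split across the LSC/IRb
boundary per the requested junction element and overlap (the IR-side
fragment of a spanning gene is mirrored into IRa as a pseudogene, exactly
as deposited records annotate it); rpl23, the simulated spacer, ycf2 and
rrn23 inside the IR; ndhF and ccsA in the SSC. Gene sequences are fixed,
versioned, seeded-random stand-ins — not deposited sequences — except the
trnI_CAU reference (a synthetic 74 nt constant with the D7 motif embedded
in its "coding" region) and the printed motif strings. Background
composition defaults to GC 37.5%, the family-typical plastome value.

The cassette simulator replays each scenario generatively on an ancestral
spacer (gaps 165/68 bp — the conserved layout outside Parideae, with the
downstream gap near-invariant at 68 bp; D7 planted upstream of and inside
trnI_CAU, R1b 40 bp upstream of trnI, R1 20 bp into the downstream gap):

* **I** — duplicate the R1b-anchored 164 bp window spanning trnI ×3;
* **II** — mutate the planted R1's second base A→C (creating R1a), then
  duplicate a 139 bp window spanning trnI and the R1a site once;
* **III-A** — insert a fresh random unit (default 24 bp ×4) 40 bp
  downstream of trnI, modelling unequal recombination plus SSM;
* **III-B** — replace the trnI-proximal D7 with U16 (HFIR), then duplicate
  a 117 bp window spanning U16 and trnI ×3.

Defaults follow the architectures the survey reports for each scenario's
exemplar lineages (3 long units for I/III-B, 2 for II, short downstream
units for III-A). Every event is appended to an event log that classifiers
never read; ground-truth coordinates are derived arithmetically from the
construction, never by running the detectors.

What a green synthetic test does **not** establish: recovery on real
accessions (annotation dialects, mismatch-tolerant IR boundaries that may
differ by a few bases from exact-match boundaries, diverged trnI copies
below 95% identity), sequencing error, or indels outside the modelled
events. Reproducing published per-accession lengths requires downloading
those records and is deliberately outside the test suite.

## Numerical and scale choices

Rounding of printed percentages is decimal half-up. Read-depth/coverage is
not computed (read lengths are never printed alongside counts). Bulk tests
use reduced genomes (LSC 8–12 kb, SSC 2–4 kb, IR 3–5 kb): the IR detector
is seed-and-extend and therefore size-independent, and one 157 kb-scale
genome is still exercised to guard against scale-dependent regressions.
The pipeline degrades per record (NA fields plus a logged warning) instead
of aborting a batch, because comparative surveys routinely mix records
with heterogeneous annotation quality.

## Known limitations

* IR arms spanning the deposited origin are not detected (not observed in
  deposited plastomes, which linearise at the LSC).
* Exact IR matching may disagree by a few bases with boundaries published
  from mismatch-tolerant tools on real accessions.
* The scenario table is architecture-based; it cannot distinguish
  convergent architectures produced by different histories (those fall to
  COMPLEX or to the first matching rule).
* No indel model beyond the scenario events; no phylogenetic or
  population-genetic simulation.
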