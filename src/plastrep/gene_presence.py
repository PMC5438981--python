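"""rps16 integrity typing and in-silico PCR section markers.

The plastid rps16 gene (two exons, group-II intron) is lost in stages across
Melanthiaceae lineages: intact, exon 1 deleted, exon 2 deleted, a short
remnant of exon 2 retained, or the locus gone entirely. The five-state
classifier anchors each reference exon in a query region by local alignment
and measures how much of it is retained.

The same locus backs a section marker within Veratrum: a primer pair
flanking the rps16 coding region yields a ~1.5 kb product where only exon 2
was deleted (sect. Veratrum) versus a 400 bp product where the whole gene is
gone (sect. Fuscoveratrum). ``insilico_pcr`` predicts those products on any
template and ``veratrum_section_call`` maps product length to the section.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio import Align

from .plastome_io import PlastomeRecord, revcomp

#: primer pair spanning the rps16 coding region (section-marker assay)
RPS16_PRIMERS: "PrimerPair"


class Rps16Class(str, Enum):
    INTACT = "INTACT"
    EXON1_LOST = "EXON1_LOST"
    EXON2_LOST = "EXON2_LOST"
    EXON2_PARTIAL = "EXON2_PARTIAL"
    COMPLETE_LOSS = "COMPLETE_LOSS"


@dataclass(frozen=True)
class Rps16Status:
    rps16_class: Rps16Class
    retained_bp: dict  # exon name -> aligned reference bp retained

    @property
    def label(self) -> str:
        return self.rps16_class.value


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if len(p) < 15 or set(p) - set("ACGT"):
                raise ValueError(f"primer {p!r}: need >= 15 unambiguous bases")


RPS16_PRIMERS = PrimerPair(forward="GTCAATATGAATGTTGATAA",
                           reverse="TTTTCTATTCCATACACATG",
                           name="rps16")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product; length includes both primer footprints."""

    start: int
    end: int  # exclusive, may exceed template length for origin-spanning products
    length_bp: int
    strand_of_forward: str  # "+" | "-"


# ---------------------------------------------------------------------------
# rps16 five-state classifier
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _retained_bp(region_seq: str, ref_exon: str, min_identity: float,
                 min_anchor_bp: int) -> int:
    """Reference bp covered by the best local alignment at >= min_identity.

    Searches both strands. An alignment only qualifies when, besides overall
    identity, it contains at least one *contiguous* (ungapped) block of
    >= ``min_anchor_bp`` at >= ``min_identity`` — short gappy mosaics that
    local alignment assembles from unrelated sequence never represent a real
    retained exon fragment. Returns 0 when nothing qualifies.
    """
    aligner = _make_aligner()
    best = 0
    for query in (ref_exon, revcomp(ref_exon)):
        alns = aligner.align(region_seq, query)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        t, q = aln.aligned  # aligned blocks on target and query
        matches = 0
        covered = 0
        anchored = False
        for (ts, te), (qs, qe) in zip(t, q):
            covered += qe - qs
            tb = aln.target[ts:te]
            qb = aln.query[qs:qe]
            block_matches = sum(1 for a, b in zip(tb, qb) if a == b)
            matches += block_matches
            if te - ts >= min_anchor_bp and \
                    block_matches / (te - ts) >= min_identity:
                anchored = True
        aligned_cols = sum(te - ts for ts, te in t)
        if anchored and aligned_cols and matches / aligned_cols >= min_identity:
            best = max(best, int(covered))
    return best


def classify_rps16(region_seq: str, ref_exon1: str, ref_exon2: str,
                   min_identity: float = 0.80, min_anchor_bp: int = 20,
                   full_fraction: float = 0.90) -> Rps16Status:
    """Type the rps16 locus into the five-state loss spectrum.

    Each reference exon is located in ``region_seq`` (the trnK_UUU–trnQ_UUG
    neighbourhood, or the whole genome) by local alignment. An exon counts as
    *full* when >= ``full_fraction`` of its length is retained at
    >= ``min_identity``, *anchored* when >= ``min_anchor_bp`` is, and absent
    otherwise. The thresholds are decision knobs, exposed because only the
    endpoint states are observed in nature.
    """
    if not ref_exon1 or not ref_exon2:
        raise ValueError("reference exons must be non-empty")
    r1 = _retained_bp(region_seq, ref_exon1, min_identity, min_anchor_bp)
    r2 = _retained_bp(region_seq, ref_exon2, min_identity, min_anchor_bp)
    full1 = r1 >= full_fraction * len(ref_exon1)
    full2 = r2 >= full_fraction * len(ref_exon2)
    anchored1 = r1 >= min_anchor_bp
    anchored2 = r2 >= min_anchor_bp
    if not anchored1:
        r1 = 0
    if not anchored2:
        r2 = 0
    retained = {"exon1": r1, "exon2": r2}
    if full1 and full2:
        cls = Rps16Class.INTACT
    elif anchored2 and not full2:
        cls = Rps16Class.EXON2_PARTIAL
    elif not anchored2 and anchored1:
        cls = Rps16Class.EXON2_LOST
    elif full2 and not full1:
        cls = Rps16Class.EXON1_LOST
    else:
        cls = Rps16Class.COMPLETE_LOSS
    return Rps16Status(rps16_class=cls, retained_bp=retained)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

def _site_positions(template: str, primer: str, max_mismatch: int,
                    three_prime_is_right: bool) -> list[int]:
    """Start positions where ``primer`` matches the + strand of ``template``.

    ``three_prime_is_right`` selects which end of the written primer string
    must match exactly (the primer's 3' terminus).
    """
    n, L = len(template), len(primer)
    if n < L:
        return []
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    mism = np.zeros(n - L + 1, dtype=np.int32)
    for off in range(L):
        mism += t[off:n - L + 1 + off] != p[off]
    ok = mism <= max_mismatch
    anchor = L - 1 if three_prime_is_right else 0
    ok &= t[anchor:n - L + 1 + anchor] == p[anchor]
    return np.nonzero(ok)[0].tolist()


def insilico_pcr(template: PlastomeRecord | str, primers: PrimerPair,
                 max_amplicon: int = 3_000, max_mismatch: int = 0) -> list[Amplicon]:
    """Predict all PCR products of ``primers`` on ``template``.

    A product needs the forward primer on one strand and the reverse primer
    on the opposite strand downstream, within ``max_amplicon`` bp, each with
    <= ``max_mismatch`` mismatches and an exact 3'-terminal base. Product
    length runs between the two outer primer ends, inclusive. Circular
    templates are scanned across the origin; products are reported with
    ``start`` modulo the template length.
    """
    if isinstance(template, PlastomeRecord):
        seq, circular = template.sequence, template.is_circular
    else:
        seq, circular = template.upper(), False
    n = len(seq)
    scan = seq + seq[:min(max_amplicon, n)] if circular else seq
    fwd, rev = primers.forward, primers.reverse

    products: list[Amplicon] = []
    seen: set[tuple] = set()
    # orientation 1: forward on +, reverse annealing to the - strand (its
    # reverse complement appears on + downstream); 3' of the rc(rev) segment
    # is its first written base.
    f_sites = _site_positions(scan, fwd, max_mismatch, three_prime_is_right=True)
    r_sites = _site_positions(scan, revcomp(rev), max_mismatch, three_prime_is_right=False)
    # orientation 2: forward on - strand: rc(fwd) on +, 3' at segment start;
    # reverse primer written 5'->3' on + upstream.
    f2_sites = _site_positions(scan, revcomp(fwd), max_mismatch, three_prime_is_right=False)
    r2_sites = _site_positions(scan, rev, max_mismatch, three_prime_is_right=True)

    def pair(left_sites, left_len, right_sites, right_len, strand):
        right_sorted = sorted(right_sites)
        import bisect
        for p in left_sites:
            if p >= n:  # anchors must start in the first copy
                continue
            lo = bisect.bisect_left(right_sorted, p + left_len)
            for q in right_sorted[lo:]:
                length = q + right_len - p
                if length > max_amplicon:
                    break
                if q >= n and q - n >= p:
                    # the wrapped image of a site already paired linearly:
                    # not a genuine origin-spanning product
                    continue
                key = (p % n, length, strand)
                if key not in seen:
                    seen.add(key)
                    products.append(Amplicon(start=p % n, end=p + length,
                                             length_bp=length,
                                             strand_of_forward=strand))

    pair(f_sites, len(fwd), r_sites, len(rev), "+")
    pair(r2_sites, len(rev), f2_sites, len(fwd), "-")
    products.sort(key=lambda a: (a.start, a.length_bp, a.strand_of_forward))
    return products


def veratrum_section_call(amplicons: list[Amplicon]) -> str:
    """Map rps16 marker product length to a Veratrum section.

    A single product of 1,200–1,800 bp is the sect. Veratrum state (exon 1
    retained), 300–500 bp the sect. Fuscoveratrum state (whole gene deleted);
    anything else is indeterminate. Pure function of product lengths.
    """
    if len(amplicons) != 1:
        return "indeterminate"
    length = amplicons[0].length_bp
    if 1_200 <= length <= 1_800:
        return "sect. Veratrum"
    if 300 <= length <= 500:
        return "sect. Fuscoveratrum"
    return "indeterminate"
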