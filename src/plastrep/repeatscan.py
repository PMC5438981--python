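"""rpl23–ycf2 intergenic architecture: trnI copies, tandem repeats, motifs.

In tribe Parideae the intergenic spacer between rpl23 and ycf2 (which
contains trnI_CAU) is a hot spot for tandem-repeat accumulation: unit lengths
of 18–209 bp, up to ~20 copies, and 1–3 copies of trnI_CAU itself. Flanking
the repeats sit two groups of small conserved sequences — a 7 bp direct
repeat (D7) upstream of and inside the trnI_CAU coding region, and a cluster
of R1-family motifs downstream — which act as the initial units for
slipped-strand mispairing.

This module extracts the spacer from an annotated record, counts trnI_CAU
copies by sequence similarity (annotation-independent, since duplicated
copies are often under-annotated), detects tandem repeat tracts, and scans
the conserved-motif catalog. The tandem-repeat detector is deliberately
simple and fully specified so that it can be checked exactly against a
brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .plastome_io import Interval, PlastomeRecord, extract_region, revcomp

#: conserved motifs of the rpl23-ycf2 spacer (R1 family, D7/U16 group)
MOTIF_CATALOG: dict[str, str] = {
    "R1": "CAAATTCCAAT",
    "R1a": "CCAATTCCAAT",
    "R1b": "ATTCCA",
    "D7": "ATGGATG",
    "U16": "ATGGATGCTTAACAGG",
}

#: fixed synthetic trnI_CAU reference (74 nt). Not a deposited gene sequence:
#: a versioned stand-in with the D7 motif embedded in the "coding" region,
#: used for similarity-based copy counting and by the genome generator.
DEFAULT_TRNI = (
    "GGGCTATTAGCTCAGTGGTAGAGCGCATGGATGCATAACCATGAGGTCACGGGTTCGATCCCCGTAGGGCCCA"
    "C"
)

assert len(DEFAULT_TRNI) == 74
assert MOTIF_CATALOG["D7"] in DEFAULT_TRNI


class MissingGeneError(ValueError):
    """A gene needed to delimit the spacer is not annotated."""


@dataclass(frozen=True)
class TrnIHit:
    """One similarity hit of the trnI_CAU reference inside the spacer."""

    start: int
    end: int
    strand: str
    identity: float


@dataclass(frozen=True)
class TandemRepeatArray:
    """A maximal tandem tract: ``copies`` full units from ``start``."""

    unit_seq: str
    unit_len: int
    copies: int
    start: int
    identity: float
    tail_bp: int = 0

    @property
    def end(self) -> int:
        return self.start + self.copies * self.unit_len


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    position: int
    strand: str = "+"


@dataclass(frozen=True)
class IgsProfile:
    """Architecture summary of one rpl23–ycf2 spacer."""

    record_id: str
    igs_seq: str
    total_len: int
    rpl23_trnI_len: int
    trnI_ycf2_len: int
    trnI_copies: int
    trnI_hits: tuple[TrnIHit, ...] = ()
    repeat_arrays: tuple[TandemRepeatArray, ...] | None = None
    motif_hits: tuple[MotifHit, ...] | None = None


def total_repeat_units(arrays: Sequence[TandemRepeatArray],
                       min_unit: int = 18) -> int:
    """Total integer copy count across qualifying arrays (table semantics)."""
    return sum(a.copies for a in arrays if a.unit_len >= min_unit)


# ---------------------------------------------------------------------------
# similarity-based trnI_CAU counting
# ---------------------------------------------------------------------------

def _window_mismatches(seq: str, probe: str) -> np.ndarray:
    """Mismatch count of ``probe`` against every window of ``seq``."""
    n, L = len(seq), len(probe)
    if n < L:
        return np.zeros(0, dtype=np.int32)
    t = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    mism = np.zeros(n - L + 1, dtype=np.int32)
    for off in range(L):
        mism += t[off:n - L + 1 + off] != p[off]
    return mism


def count_trnI(seq: str, ref_trnI: str = DEFAULT_TRNI,
               min_identity: float = 0.95) -> list[TrnIHit]:
    """Ungapped similarity hits of the trnI_CAU reference, either strand.

    Full-length windows at >= ``min_identity`` qualify; overlapping
    candidates are resolved greedily best-first (fewest mismatches, then
    leftmost, then + strand). Annotation is never consulted, so duplicated
    copies in under-annotated records are still counted.
    """
    if not 60 <= len(ref_trnI) <= 100:
        raise ValueError("ref_trnI must be 60-100 nt")
    L = len(ref_trnI)
    max_mism = int((1.0 - min_identity) * L)
    candidates: list[tuple[int, int, str]] = []
    for strand, probe in (("+", ref_trnI), ("-", revcomp(ref_trnI))):
        mism = _window_mismatches(seq, probe)
        for pos in np.nonzero(mism <= max_mism)[0]:
            candidates.append((int(mism[pos]), int(pos), strand))
    candidates.sort(key=lambda c: (c[0], c[1], c[2] != "+"))
    hits: list[TrnIHit] = []
    for m, pos, strand in candidates:
        if any(pos < h.end and pos + L > h.start for h in hits):
            continue
        hits.append(TrnIHit(start=pos, end=pos + L, strand=strand,
                            identity=(L - m) / L))
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# tandem repeat detection
# ---------------------------------------------------------------------------

def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def find_tandem_repeats(seq: str, min_unit: int = 18, max_unit: int = 250,
                        min_copies: int = 2,
                        max_mismatch_frac: float = 0.1) -> list[TandemRepeatArray]:
    """Maximal tandem tracts with unit length in ``[min_unit, max_unit]``.

    A tract ``(start, p, c)`` consists of ``c`` consecutive ``p``-periodic
    copies, each within ``floor(max_mismatch_frac * p)`` mismatches of the
    *first* copy (the consensus is the first copy — deterministic). All
    candidate tracts with ``c >= min_copies`` are enumerated and maximally
    right-extended; overlapping reports are then collapsed to the tract with
    most copies, ties broken by smaller period, then smaller start. A partial
    trailing copy is reported as ``tail_bp``, never as an extra unit.
    """
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[tuple[int, int, int]] = []  # (start, p, copies)
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        allowed = int(max_mismatch_frac * p)
        # ok[i] <=> copy at i+p matches copy at i (coarse candidate filter)
        m = (a[p:] != a[:-p]).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(m)))
        if len(cs) <= p:
            continue
        window = cs[p:] - cs[:-p]  # mismatches between copy@i and copy@i+p
        starts = np.nonzero(window <= allowed)[0]
        for s in starts:
            s = int(s)
            unit = a[s:s + p]
            c = 2
            while s + (c + 1) * p <= n and _hamming(a[s + c * p:s + (c + 1) * p], unit) <= allowed:
                c += 1
            # verify every copy against the first (filter used lag-p identity)
            valid = all(_hamming(a[s + i * p:s + (i + 1) * p], unit) <= allowed
                        for i in range(1, c))
            while not valid and c > 2:
                c -= 1
                valid = all(_hamming(a[s + i * p:s + (i + 1) * p], unit) <= allowed
                            for i in range(1, c))
            if valid and c >= min_copies:
                candidates.append((s, p, c))
    return _collapse_tracts(seq, candidates, max_mismatch_frac)


def _collapse_tracts(seq: str, candidates: list[tuple[int, int, int]],
                     max_mismatch_frac: float) -> list[TandemRepeatArray]:
    """Greedy collapse: most copies, then smaller period, then smaller start."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(seq)
    chosen: list[tuple[int, int, int]] = []
    for s, p, c in sorted(candidates, key=lambda t: (-t[2], t[1], t[0])):
        lo, hi = s, s + c * p
        if any(lo < cs + cc * cp and hi > cs for cs, cp, cc in chosen):
            continue
        chosen.append((s, p, c))
    out = []
    for s, p, c in sorted(chosen):
        unit = a[s:s + p]
        mism = sum(_hamming(a[s + i * p:s + (i + 1) * p], unit) for i in range(1, c))
        identity = 1.0 - mism / (p * (c - 1))
        tail = 0
        end = s + c * p
        for t in range(1, p):
            if end + t > n:
                break
            if _hamming(a[end:end + t], unit[:t]) <= int(max_mismatch_frac * t):
                tail = t
        out.append(TandemRepeatArray(unit_seq=seq[s:s + p], unit_len=p,
                                     copies=c, start=s, identity=identity,
                                     tail_bp=tail))
    return out


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def scan_motifs(seq: str, catalog: dict[str, str] | None = None,
                both_strands: bool = False) -> list[MotifHit]:
    """All exact motif occurrences, overlapping hits included.

    Forward strand by default; a U16 hit therefore always implies a D7 hit
    at the same position (U16 starts with D7).
    """
    catalog = MOTIF_CATALOG if catalog is None else catalog
    hits: list[MotifHit] = []
    strands = [("+", seq)] + ([("-", revcomp(seq))] if both_strands else [])
    for strand, s in strands:
        for name, motif in catalog.items():
            pos = s.find(motif)
            while pos != -1:
                at = pos if strand == "+" else len(seq) - pos - len(motif)
                hits.append(MotifHit(motif_name=name, position=at, strand=strand))
                pos = s.find(motif, pos + 1)
    hits.sort(key=lambda h: (h.position, h.motif_name, h.strand))
    return hits


# ---------------------------------------------------------------------------
# spacer extraction and profiling
# ---------------------------------------------------------------------------

def _gene_spans(record: PlastomeRecord, name: str) -> list[Interval]:
    spans = [f.span() for f in record.genes(name)]
    if not spans:
        raise MissingGeneError(f"record {record.identifier}: no {name} annotated")
    return spans


def extract_igs(record: PlastomeRecord, left_gene: str = "rpl23",
                right_gene: str = "ycf2", internal_gene: str = "trnI_CAU",
                ref_trnI: str = DEFAULT_TRNI) -> IgsProfile:
    """Extract the left_gene–right_gene spacer and its sub-IGS bookkeeping.

    Both genes sit in the IR, so each has two copies; the copy pair giving
    the shortest circular gap (reading left_gene end -> right_gene start
    5'->3' on either strand) is profiled — the other IR copy is its reverse
    complement and is skipped to avoid double counting. Sub-IGS lengths are
    measured from similarity hits of the trnI_CAU reference, not from
    annotation. Repeat arrays and motif hits are left unfilled; see
    :func:`complete_profile`.
    """
    n = len(record)
    lefts = _gene_spans(record, left_gene)
    rights = _gene_spans(record, right_gene)
    best: tuple[int, Interval, bool] | None = None  # (gap, interval, rc?)
    for ls in lefts:
        for rs in rights:
            gap_fwd = (rs.start - ls.end) % n
            if best is None or gap_fwd < best[0]:
                best = (gap_fwd, Interval(ls.end % n, rs.start,
                                          wraps=(ls.end % n) > rs.start), False)
            gap_rev = (ls.start - rs.end) % n  # cassette on the - strand
            if gap_rev < best[0]:
                best = (gap_rev, Interval(rs.end % n, ls.start,
                                          wraps=(rs.end % n) > ls.start), True)
    gap, interval, needs_rc = best
    igs = extract_region(record, interval)
    if needs_rc:
        igs = revcomp(igs)
    hits = count_trnI(igs, ref_trnI)
    total = len(igs)
    if hits:
        rpl23_trnI = hits[0].start
        trnI_ycf2 = total - hits[-1].end
    else:
        rpl23_trnI, trnI_ycf2 = total, 0  # degenerate: no internal trnI
    return IgsProfile(record_id=record.identifier, igs_seq=igs, total_len=total,
                      rpl23_trnI_len=rpl23_trnI, trnI_ycf2_len=trnI_ycf2,
                      trnI_copies=len(hits), trnI_hits=tuple(hits))


def complete_profile(profile: IgsProfile, **repeat_kwargs) -> IgsProfile:
    """Fill ``repeat_arrays`` and ``motif_hits`` on a bare profile."""
    arrays = tuple(find_tandem_repeats(profile.igs_seq, **repeat_kwargs))
    motifs = tuple(scan_motifs(profile.igs_seq))
    return replace(profile, repeat_arrays=arrays, motif_hits=motifs)


def profile_from_seq(igs_seq: str, record_id: str = "",
                     ref_trnI: str = DEFAULT_TRNI) -> IgsProfile:
    """Full profile (trnI, repeats, motifs) straight from a spacer sequence."""
    hits = count_trnI(igs_seq, ref_trnI)
    total = len(igs_seq)
    if hits:
        rpl23_trnI, trnI_ycf2 = hits[0].start, total - hits[-1].end
    else:
        rpl23_trnI, trnI_ycf2 = total, 0
    profile = IgsProfile(record_id=record_id, igs_seq=igs_seq, total_len=total,
                         rpl23_trnI_len=rpl23_trnI, trnI_ycf2_len=trnI_ycf2,
                         trnI_copies=len(hits), trnI_hits=tuple(hits))
    return complete_profile(profile)
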