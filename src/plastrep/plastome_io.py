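"""Reading, writing and coordinate arithmetic for plastome records.

Plastid genomes are circular molecules deposited as a linearization; every
coordinate in this package is 0-based, half-open, on that linearization.
Circularity is explicit (:attr:`PlastomeRecord.is_circular`), never inferred,
and intervals that cross the origin carry a ``wraps`` flag so that region
extraction and length arithmetic stay unambiguous.

GenBank and FASTA parsing/writing is delegated to Biopython; this module owns
the coordinate conversion (GenBank ``n..m`` -> ``[n-1, m)``), gene-name
canonicalisation (tRNAs as ``trnX_ANTICODON``) and the base-composition and
read-fraction bookkeeping reported in comparative plastome tables.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastrep")

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: feature kinds carried through from annotation sources
FEATURE_KINDS = ("CDS", "tRNA", "rRNA")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeFormatError(ValueError):
    """Raised for unreadable or malformed sequence/annotation input."""


class UndefinedCompositionError(ValueError):
    """Raised when a sequence has no unambiguous bases to tally."""


# ---------------------------------------------------------------------------
# intervals on a (possibly circular) linearization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Half-open interval ``[start, end)``; ``wraps`` marks origin crossing.

    For a wrapping interval ``start > end`` and the covered positions are
    ``[start, n) + [0, end)`` for genome length ``n``.
    """

    start: int
    end: int
    wraps: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping interval needs the genome length")
            return (self.end - self.start) % genome_length
        return self.end - self.start

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping interval needs the genome length")
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def overlap_bp(self, other: "Interval", genome_length: int) -> int:
        """Number of positions covered by both intervals on a circle."""
        return sum(
            1 for p in self.positions(genome_length) if other.contains(p, genome_length)
        ) if (self.wraps or other.wraps) else max(
            0, min(self.end, other.end) - max(self.start, other.start)
        )

    def positions(self, genome_length: int) -> Iterable[int]:
        if self.wraps:
            yield from range(self.start, genome_length)
            yield from range(0, self.end)
        else:
            yield from range(self.start, self.end)


@dataclass(frozen=True)
class GeneFeature:
    """A gene annotation: named, stranded, possibly multi-exon."""

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # "+" | "-"
    parts: tuple[Interval, ...]
    is_pseudo: bool = False

    def __post_init__(self):
        if not self.parts:
            raise ValueError(f"feature {self.name}: parts must be non-empty")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")

    def span(self) -> Interval:
        """Envelope from first part start to last part end (no wrap handling
        across parts; plastome genes in scope never straddle the origin)."""
        return Interval(self.parts[0].start, self.parts[-1].end,
                        wraps=self.parts[0].wraps or self.parts[-1].wraps)

    def total_exon_length(self, genome_length: int | None = None) -> int:
        return sum(p.length(genome_length) for p in self.parts)


@dataclass
class PlastomeRecord:
    """A plastome sequence plus its typed gene features."""

    identifier: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise PlastomeFormatError(f"record {self.identifier}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise PlastomeFormatError(
                f"record {self.identifier}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def genes(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]


# ---------------------------------------------------------------------------
# gene-name canonicalisation
# ---------------------------------------------------------------------------

_TRN_RE = re.compile(r"^trn(?P<aa>[A-Za-z]{1,3})[\s_-]*(?P<anti>[ACGUTacgut]{3})?$")


def canonical_gene_name(raw: str, product: str | None = None) -> str:
    """Normalise a gene symbol; tRNAs become ``trnX_ANTICODON``.

    Source dialects vary: ``trnI-CAU``, ``trnI_CAU``, ``trnI CAU`` and plain
    ``trnI`` all occur. The anticodon, when present, is upper-cased with U->T
    left as given in DNA records (GenBank uses DNA letters).
    """
    raw = raw.strip()
    m = _TRN_RE.match(raw)
    if m:
        aa = m.group("aa")
        anti = m.group("anti")
        if anti:
            return f"trn{aa}_{anti.upper()}"
        return f"trn{aa}"
    return raw


# ---------------------------------------------------------------------------
# GenBank / FASTA / annotation-table readers and writers
# ---------------------------------------------------------------------------

def _feature_from_seqfeature(sf: SeqFeature, genome_length: int) -> GeneFeature | None:
    if sf.type not in FEATURE_KINDS:
        return None
    quals = sf.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [None])[0]
    if name is None:
        return None
    name = canonical_gene_name(name, (quals.get("product") or [None])[0])
    strand = "-" if (sf.location.strand or 1) < 0 else "+"
    parts = []
    for part in sf.location.parts:
        s, e = int(part.start), int(part.end)
        s %= genome_length
        wraps = s + (int(part.end) - int(part.start)) > genome_length
        parts.append(Interval(s, e % genome_length if wraps else e, wraps=wraps))
    if strand == "-" and len(parts) > 1 and parts[0].start > parts[-1].start:
        # Biopython lists minus-strand join parts in biological order already;
        # keep exon order biological (5'->3' of the gene).
        pass
    return GeneFeature(name=name, kind=sf.type, strand=strand,
                       parts=tuple(parts),
                       is_pseudo="pseudo" in quals or "pseudogene" in quals)


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Read the first record of a GenBank flat file as a :class:`PlastomeRecord`.

    GenBank 1-based inclusive locations become 0-based half-open parts; joins
    become multi-part features; features with unparseable locations are
    skipped with a logged warning.
    """
    path = Path(path)
    try:
        seqrec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise PlastomeFormatError(f"{path}: no GenBank records found")
    seq = str(seqrec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise PlastomeFormatError(f"{path}: record has no usable sequence")
    is_circular = (seqrec.annotations.get("topology", "circular") == "circular")
    features: list[GeneFeature] = []
    for sf in seqrec.features:
        try:
            gf = _feature_from_seqfeature(sf, len(seq))
        except Exception as exc:  # malformed location -> skip, keep the batch
            logger.warning("%s: skipping feature %s (%s)", path, sf, exc)
            continue
        if gf is not None:
            features.append(gf)
    return PlastomeRecord(identifier=seqrec.id, sequence=seq,
                          is_circular=is_circular, features=features,
                          source=str(path))


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write a record (sequence + features) as a GenBank flat file."""
    seqrec = SeqRecord(Seq(record.sequence), id=record.identifier,
                       name=record.identifier[:16], description="")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.is_circular else "linear"
    for gf in record.features:
        strand = -1 if gf.strand == "-" else 1
        locs = [FeatureLocation(p.start, p.end, strand=strand) for p in gf.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [gf.name]}
        if gf.is_pseudo:
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(loc, type=gf.kind, qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta(path: str | Path) -> list[PlastomeRecord]:
    """Read FASTA records; sequences are case-normalised to upper."""
    records = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        seq = str(seqrec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise PlastomeFormatError(
                f"{path}: record {seqrec.id} has non-nucleotide characters {sorted(bad)}"
            )
        records.append(PlastomeRecord(identifier=seqrec.id, sequence=seq,
                                      source=str(path)))
    return records


def write_fasta(records: Sequence[PlastomeRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.identifier, description="") for r in records],
        str(path), "fasta",
    )


def read_annotation_table(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Read the TSV annotation fallback.

    Columns: record_id, gene, kind, strand, part_start, part_end (0-based
    half-open). Consecutive rows with the same (record_id, gene, kind, strand)
    merge into one multi-part feature in file order.
    """
    grouped: dict[tuple, list[Interval]] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"record_id", "gene", "kind", "strand", "part_start", "part_end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PlastomeFormatError(f"{path}: annotation table needs columns {sorted(required)}")
        for row in reader:
            key = (row["record_id"], canonical_gene_name(row["gene"]),
                   row["kind"], row["strand"])
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            grouped[key].append(Interval(int(row["part_start"]), int(row["part_end"])))
    out: dict[str, list[GeneFeature]] = {}
    for key in order:
        rid, gene, kind, strand = key
        out.setdefault(rid, []).append(
            GeneFeature(name=gene, kind=kind, strand=strand, parts=tuple(grouped[key]))
        )
    return out


def attach_annotations(record: PlastomeRecord,
                       table: dict[str, list[GeneFeature]]) -> PlastomeRecord:
    """Return a copy of ``record`` with features from an annotation table."""
    feats = table.get(record.identifier, [])
    return replace(record, features=list(feats))


# ---------------------------------------------------------------------------
# region extraction and composition
# ---------------------------------------------------------------------------

def extract_region(record: PlastomeRecord, interval: Interval) -> str:
    """Sequence of ``interval``; wrapping intervals concatenate suffix+prefix."""
    n = len(record)
    if interval.wraps:
        if not record.is_circular:
            raise ValueError(
                f"record {record.identifier}: wrapping interval on a linear record"
            )
        return record.sequence[interval.start:] + record.sequence[:interval.end]
    if not (0 <= interval.start <= interval.end <= n):
        raise ValueError(f"interval [{interval.start},{interval.end}) outside [0,{n})")
    return record.sequence[interval.start:interval.end]


def round_half_up(value: float | Decimal, ndigits: int) -> float:
    """Decimal round-half-up (printed tables round 0.5 away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionSummary:
    at_percent: float
    gc_percent: float
    length_bp: int
    ambiguous_bp: int = 0


def composition(seq: str, ndigits: int = 1) -> CompositionSummary:
    """AT/GC content; ambiguous bases (N) are excluded from both tallies."""
    seq = seq.upper()
    if not seq:
        raise UndefinedCompositionError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    unambiguous = gc + at
    if unambiguous == 0:
        raise UndefinedCompositionError("sequence has no unambiguous bases")
    return CompositionSummary(
        at_percent=round_half_up(100.0 * at / unambiguous, ndigits),
        gc_percent=round_half_up(100.0 * gc / unambiguous, ndigits),
        length_bp=len(seq),
        ambiguous_bp=len(seq) - unambiguous,
    )


def read_fraction(cp_reads: int, total_reads: int) -> float:
    """Percentage of reads assigned to the plastome, half-up to 2 decimals."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= cp_reads <= total_reads:
        raise ValueError("cp_reads must lie in [0, total_reads]")
    return round_half_up(100.0 * cp_reads / total_reads, 2)
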