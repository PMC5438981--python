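"""Quadripartite partitioning of plastomes and IR/LSC junction mapping.

A typical plastome carries two inverted repeats (IRa, IRb) — exact
reverse-complement copies of each other — separating a large and a small
single-copy region (LSC, SSC). Boundary ("junction") positions shift between
lineages as the IR expands into, or retreats from, the junction gene cassette
(trnH_GUG, rps19, rpl22, rps3 on the LSC side), and the extent of that
expansion is a comparative character.

IR detection is k-mer seeded (default k=25): seeds between the sequence and
its reverse complement lie on a common antidiagonal (i + j constant) for a
true inverted match, are grouped there, verified, and extended base-by-base
to maximality. Matching is exact by default; plastome IR arms are
near-identical so exactness gives a testable maximality criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .plastome_io import GeneFeature, Interval, PlastomeRecord, revcomp

JUNCTION_NAMES = ("JLB", "JSB", "JSA", "JLA")


class NoInvertedRepeatError(ValueError):
    """No reverse-complement pair of at least ``min_len`` was found."""


class DegeneratePartitionError(ValueError):
    """One of the single-copy arcs between the IRs has zero length."""


@dataclass(frozen=True)
class QuadripartitePartition:
    """The four region intervals; lengths tile the circle exactly once."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int

    @property
    def lengths(self) -> tuple[int, int, int, int]:
        n = self.genome_length
        return (self.lsc.length(n), self.irb.length(n),
                self.ssc.length(n), self.ira.length(n))

    @property
    def lsc_len(self) -> int:
        return self.lsc.length(self.genome_length)

    @property
    def ssc_len(self) -> int:
        return self.ssc.length(self.genome_length)

    @property
    def ir_len(self) -> int:
        return self.irb.length(self.genome_length)


@dataclass(frozen=True)
class JunctionContext:
    """Gene context of one single-copy/IR boundary.

    ``containing_element`` is a gene symbol when the junction point falls
    inside an annotated gene (with ``overlap_bp`` = bases of that gene on the
    IR side of the boundary), an IGS label ``"geneA/geneB"`` when it falls
    between genes, or ``"unresolved"`` when no annotation lies within the
    search window.
    """

    junction_name: str
    containing_element: str
    overlap_bp: int


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------

def _extend_pair(seq: str, i: int, j_end: int, length: int) -> tuple[int, int, int]:
    """Maximally extend an inverted match S[i:i+L] == revcomp(S[j:j+L]).

    ``j_end`` is the exclusive end of the right arm. Extension moves the
    left arm's start left together with the right arm's end right, and the
    left arm's end right together with the right arm's start left; stops when
    the arms would overlap or the identity breaks.
    """
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "X"}
    # outward: i-1 pairs with j_end
    while i > 0 and j_end < n and seq[i - 1] == comp[seq[j_end]]:
        i -= 1
        j_end += 1
        length += 1
    # inward: i+length pairs with j_end - length - 1
    while (i + length < n and j_end - length - 1 >= i + length
           and seq[i + length] == comp[seq[j_end - length - 1]]):
        length += 1
    return i, j_end, length


def find_inverted_repeat(record: PlastomeRecord, min_len: int = 10_000,
                         k: int = 25) -> tuple[Interval, Interval]:
    """Locate the maximal pair of disjoint reverse-complement intervals.

    Returns ``(irb, ira)`` in coordinate order (irb.start < ira.start). Among
    equal-length candidates the pair with the smallest left-arm start wins
    (deterministic tie-break). Raises :class:`NoInvertedRepeatError` when no
    pair of at least ``min_len`` exists — some lineages have lost an IR and
    the caller decides how to proceed.

    The search runs on the deposited linearization; IR arms spanning the
    circular origin are out of scope (deposited plastomes start in the LSC).
    """
    seq = record.sequence
    n = len(seq)
    if n < 2 * k:
        raise NoInvertedRepeatError(f"sequence too short ({n} bp) for k={k} seeding")

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer_pos.setdefault(seq[i:i + k], []).append(i)

    rc = revcomp(seq)
    # antidiagonal key -> set of left-arm seed starts
    diags: dict[int, list[int]] = {}
    for q in range(n - k + 1):
        hits = kmer_pos.get(rc[q:q + k])
        if not hits:
            continue
        j = n - q - k  # S[i:i+k] == revcomp(S[j:j+k])
        for i in hits:
            if i < j:  # keep each pair once, left arm first
                diags.setdefault(i + j, []).append(i)

    best: tuple[int, int, int] | None = None  # (length, i, j_end)
    for key, starts in diags.items():
        # distinct inverted pairs can share an antidiagonal; split the seeds
        # into contiguous runs and extend each run to maximality separately
        starts = sorted(set(starts))
        runs: list[tuple[int, int]] = []
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i - prev > k:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for i0, i1 in runs:
            length = i1 + k - i0
            j_start = key - i1
            j_end = j_start + length
            if seq[i0:i0 + length] != revcomp(seq[j_start:j_end]):
                # residual collisions inside the run; extend the last seed only
                length = k
                i0, j_end = i1, key - i1 + k
            i0, j_end, length = _extend_pair(seq, i0, j_end, length)
            if length < min_len:
                continue
            if best is None or length > best[0] or \
                    (length == best[0] and i0 < best[1]):
                best = (length, i0, j_end)

    if best is None:
        raise NoInvertedRepeatError(
            f"record {record.identifier}: no inverted repeat >= {min_len} bp"
        )
    length, i0, j_end = best
    return Interval(i0, i0 + length), Interval(j_end - length, j_end)


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

def partition(record: PlastomeRecord, irb: Interval, ira: Interval) -> QuadripartitePartition:
    """Assign the two arcs between the IR arms: longer -> LSC, shorter -> SSC.

    The returned ``irb`` is the IR arm that follows the LSC in coordinate
    order (the junction sequence reads LSC-IRb-SSC-IRa around the circle).
    """
    n = len(record)
    if irb.start > ira.start:
        irb, ira = ira, irb
    if irb.length(n) != ira.length(n):
        raise ValueError("IR arms must have equal length")
    inner = Interval(irb.end, ira.start)  # between the arms
    outer = Interval(ira.end % n, irb.start, wraps=ira.end % n > irb.start or ira.end % n == 0 and irb.start == 0)
    # normalise outer: from ira.end around the origin to irb.start
    outer = Interval(ira.end % n, irb.start, wraps=(ira.end % n) >= irb.start)
    if inner.length(n) == 0 or outer.length(n) == 0:
        raise DegeneratePartitionError(
            f"record {record.identifier}: zero-length single-copy arc"
        )
    if outer.length(n) >= inner.length(n):
        lsc, ssc = outer, inner
        first_ir, second_ir = irb, ira  # LSC wraps; IRb = arm after LSC = irb
    else:
        lsc, ssc = inner, outer
        first_ir, second_ir = ira, irb  # LSC between arms; arm after LSC = ira
    return QuadripartitePartition(lsc=lsc, irb=first_ir, ssc=ssc,
                                  ira=second_ir, genome_length=n)


def detect_partition(record: PlastomeRecord, min_len: int = 10_000,
                     k: int = 25) -> QuadripartitePartition:
    """Convenience: IR detection followed by partitioning."""
    irb, ira = find_inverted_repeat(record, min_len=min_len, k=k)
    return partition(record, irb, ira)


# ---------------------------------------------------------------------------
# junction gene context
# ---------------------------------------------------------------------------

def _junction_points(part: QuadripartitePartition) -> dict[str, tuple[int, Interval, str]]:
    """Junction point = first IR base moving from single copy into the repeat.

    Each point comes with the IR interval it belongs to (gene overlap is
    measured on the IR side) and which flank of the point is repeat:
    ``"right"`` for points at an IR start, ``"left"`` at an IR end.
    """
    n = part.genome_length
    return {
        "JLB": (part.irb.start, part.irb, "right"),          # LSC -> IRb
        "JSB": ((part.irb.end - 1) % n, part.irb, "left"),   # SSC -> IRb
        "JSA": (part.ira.start, part.ira, "right"),          # SSC -> IRa
        "JLA": ((part.ira.end - 1) % n, part.ira, "left"),   # LSC -> IRa
    }


def _circular_gap(a: int, b: int, n: int) -> int:
    return (b - a) % n


def junction_context(part: QuadripartitePartition,
                     features: list[GeneFeature],
                     window: int = 5_000) -> list[JunctionContext]:
    """Map each of the four junctions to its gene context (point-in-interval).

    A junction inside a gene names that gene with ``overlap_bp`` = bases of
    the gene lying inside the IR; a junction between genes names the flanking
    IGS with the repeat-side gene first (``"trnH_GUG/rps19"`` at an IR start
    whose LSC neighbour is rps19); no annotation within ``window`` bp ->
    ``"unresolved"``. Containment is half-open, so a junction at a gene's
    first base is inside the gene while one at the base past its end is IGS
    context.
    """
    n = part.genome_length
    out = []
    for jname, (point, ir, ir_side) in _junction_points(part).items():
        containing = None
        for f in features:
            if f.span().contains(point, n):
                containing = f
                break
        if containing is not None:
            overlap = containing.span().overlap_bp(ir, n)
            out.append(JunctionContext(jname, containing.name, overlap))
            continue
        # nearest gene ending at/before the point and nearest starting after
        left = min(features,
                   key=lambda f: _circular_gap(f.span().end % n, point, n) if _circular_gap(f.span().end % n, point, n) <= window else n + 1,
                   default=None)
        right = min(features,
                    key=lambda f: _circular_gap(point, f.span().start, n) if _circular_gap(point, f.span().start, n) <= window else n + 1,
                    default=None)
        lgap = _circular_gap(left.span().end % n, point, n) if left is not None else n + 1
        rgap = _circular_gap(point, right.span().start, n) if right is not None else n + 1
        if lgap <= window and rgap <= window:
            if ir_side == "right":
                label = f"{right.name}/{left.name}"
            else:
                label = f"{left.name}/{right.name}"
            out.append(JunctionContext(jname, label, 0))
        else:
            out.append(JunctionContext(jname, "unresolved", 0))
    return out
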