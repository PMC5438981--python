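"""Synthetic plastomes and rpl23–ycf2 cassettes with planted ground truth.

Every upstream analysis stage in this package is tested against genomes this
module generates: a circular quadripartite molecule with two exact inverted
repeats, a junction gene cassette (rps3, rpl22, rps19, trnH_GUG) positioned
to realise a requested IR/LSC boundary, an rps16 locus in one of five
integrity states flanked by the section-marker primer sites, and an
rpl23–trnI_CAU–ycf2 spacer built by simulating the repeat-origin events
themselves (SSM duplication, R1->R1a point mutation, unequal recombination,
HFIR welding of two D7 copies into U16).

Gene sequences are fixed internal constants — arbitrary, versioned,
seeded-random stand-ins, not deposited sequences — except the trnI_CAU
reference and the conserved motifs, which come from :mod:`plastrep.repeatscan`.
Event simulation is generative only: classifiers never see the event log.

Background base composition defaults to GC 37.5%, the family-typical
plastome value, so composition tests exercise realistic rounding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from .gene_presence import RPS16_PRIMERS, Rps16Class
from .plastome_io import GeneFeature, Interval, PlastomeRecord, revcomp
from .quadripartite import JunctionContext, QuadripartitePartition
from .repeatscan import DEFAULT_TRNI, MOTIF_CATALOG, IgsProfile, \
    TandemRepeatArray, TrnIHit
from .ssm_classify import Scenario

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.375) -> str:
    """Seeded random background with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(rng.choice(_BASES, size=n, p=p)).decode()


def mutate(seq: str, rate: float, seed: int) -> str:
    """i.i.d. per-base substitution to a uniformly different base.

    N bases are replaced by a uniform random ACGT base when hit. Expected
    substitution count is ``rate * len(seq)``.
    """
    if not 0.0 <= rate < 1.0 + 1e-12:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return seq
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_index[b] = i
    cur = base_index[arr[idx]]
    offs = rng.integers(1, 4, size=idx.size)
    new = (cur + offs) % 4
    new[cur < 0] = rng.integers(0, 4, size=int(np.count_nonzero(cur < 0)))
    arr[idx] = _BASES[new]
    return bytes(arr).decode()


# ---------------------------------------------------------------------------
# fixed gene constants (synthetic, versioned)
# ---------------------------------------------------------------------------

_GENE_SEED = 1405  # bump when regenerating the constants below
_GENE_LENGTHS = {
    "psbA": 1062, "trnH_GUG": 74, "rps19": 279, "rpl22": 450, "rps3": 657,
    "trnK_UUU": 72, "trnQ_UUG": 72, "rps16_exon1": 42, "rps16_exon2": 227,
    "rpl23": 282, "ycf2": 600, "rrn23": 600, "ndhF": 600, "ccsA": 500,
}


def _make_gene_constants() -> dict[str, str]:
    rng = np.random.default_rng(_GENE_SEED)
    return {name: random_seq(rng, n) for name, n in _GENE_LENGTHS.items()}


GENE_SEQS: dict[str, str] = _make_gene_constants()
GENE_SEQS["trnI_CAU"] = DEFAULT_TRNI

RPS16_EXON1 = GENE_SEQS["rps16_exon1"]
RPS16_EXON2 = GENE_SEQS["rps16_exon2"]

#: gene order crossing the LSC/IRb junction, LSC side first
_JUNCTION_ORDER = ("rps3", "rpl22", "rps19", "trnH_GUG")


# ---------------------------------------------------------------------------
# SSM cassette simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassetteParams:
    """Layout knobs for the rpl23–ycf2 spacer before any event.

    ``g1``/``g2`` are the rpl23–trnI and trnI–ycf2 gaps of the ancestral
    (repeat-free) cassette; 165/68 is the conserved layout seen outside
    Parideae, with the trnI–ycf2 gap near-invariant at 68 bp. ``n_units`` and
    ``unit_len`` parameterise the simulated repeat tract.
    """

    g1: int = 165
    g2: int = 68
    n_units: int | None = None
    unit_len: int | None = None
    gc: float = 0.375


_SCENARIO_DEFAULTS = {
    Scenario.NONE: (0, 0),
    Scenario.I: (3, 164),     # long units spanning the whole trnI_CAU
    Scenario.II: (2, 139),    # one duplication seeded by the mutated R1a
    Scenario.III_A: (4, 24),  # short downstream units, SSM-expanded
    Scenario.III_B: (3, 117), # U16-bearing units spanning trnI_CAU
}


def _base_cassette(params: CassetteParams, rng: np.random.Generator) -> str:
    """Ancestral spacer: G1 (D7@5, D7@g1-30, R1b@g1-40) + trnI + G2 (R1@20)."""
    g1, g2 = params.g1, params.g2
    if g1 < 50 or g2 < 40:
        raise ValueError("cassette gaps too small: need g1 >= 50, g2 >= 40")
    G1 = list(random_seq(rng, g1, params.gc))
    G1[5:12] = MOTIF_CATALOG["D7"]
    G1[g1 - 30:g1 - 23] = MOTIF_CATALOG["D7"]
    G1[g1 - 40:g1 - 34] = MOTIF_CATALOG["R1b"]
    G2 = list(random_seq(rng, g2, params.gc))
    G2[20:31] = MOTIF_CATALOG["R1"]
    return "".join(G1) + DEFAULT_TRNI + "".join(G2)


def _truth_profile(record_id: str, total: int, trnI_starts: list[int],
                   arrays: list[TandemRepeatArray]) -> IgsProfile:
    L = len(DEFAULT_TRNI)
    hits = tuple(TrnIHit(s, s + L, "+", 1.0) for s in trnI_starts)
    if hits:
        r1, r2 = hits[0].start, total - hits[-1].end
    else:
        r1, r2 = total, 0
    return IgsProfile(record_id=record_id, igs_seq="", total_len=total,
                      rpl23_trnI_len=r1, trnI_ycf2_len=r2,
                      trnI_copies=len(hits), trnI_hits=hits,
                      repeat_arrays=tuple(arrays), motif_hits=None)


def simulate_ssm_cassette(scenario: Scenario | str,
                          params: CassetteParams | None = None,
                          seed: int = 0) -> tuple[str, IgsProfile, list[dict]]:
    """Build an rpl23–ycf2 spacer by replaying one repeat-origin scenario.

    Returns ``(igs_seq, truth_profile, event_log)``. The truth profile's
    coordinates are derived arithmetically from the construction, never by
    running the detectors. Events are appended to the log in the order they
    would have occurred.
    """
    scenario = Scenario(scenario)
    if scenario is Scenario.COMPLEX:
        raise ValueError("COMPLEX is a classifier outcome, not a generative scenario")
    params = params or CassetteParams()
    n_def, L_def = _SCENARIO_DEFAULTS[scenario]
    n = params.n_units if params.n_units is not None else n_def
    L = params.unit_len if params.unit_len is not None else L_def
    rng = np.random.default_rng(seed)
    g1, g2 = params.g1, params.g2
    tlen = len(DEFAULT_TRNI)
    base = _base_cassette(params, rng)
    log: list[dict] = []

    if scenario is Scenario.NONE:
        return base, _truth_profile("", len(base), [g1], []), log

    if scenario is Scenario.I:
        x = g1 - 40  # anchored at the planted R1b
        if not (40 + tlen <= L <= 40 + tlen + g2):
            raise ValueError(f"scenario I unit_len must span trnI: "
                             f"[{40 + tlen}, {40 + tlen + g2}]")
        unit = base[x:x + L]
        seq = base[:x] + unit * n + base[x + L:]
        log.append({"event": "ssm_duplication", "anchor": "R1b", "start": x,
                    "unit_len": L, "copies": n})
        arr = TandemRepeatArray(unit, L, n, x, 1.0)
        starts = [x + i * L + 40 for i in range(n)]
        return seq, _truth_profile("", len(seq), starts, [arr]), log

    if scenario is Scenario.II:
        m = g1 + tlen + 21  # second base of the planted R1 -> R1a
        assert base[m] == "A"
        base = base[:m] + "C" + base[m + 1:]
        log.append({"event": "point_mutation", "position": m, "change": "A>C",
                    "result": "R1a"})
        x = g1 - 30
        if not (30 + tlen + 31 <= L <= 30 + tlen + g2):
            raise ValueError("scenario II unit_len must span trnI and the R1a site")
        unit = base[x:x + L]
        seq = base[:x] + unit * n + base[x + L:]
        log.append({"event": "ssm_duplication", "anchor": "R1a", "start": x,
                    "unit_len": L, "copies": n})
        arr = TandemRepeatArray(unit, L, n, x, 1.0)
        starts = [x + i * L + 30 for i in range(n)]
        return seq, _truth_profile("", len(seq), starts, [arr]), log

    if scenario is Scenario.III_A:
        y = g1 + tlen + 40  # downstream of trnI, past the R1 cluster
        if L < 18:
            raise ValueError("scenario III-A unit_len must be >= 18")
        unit = random_seq(rng, L, params.gc)
        log.append({"event": "unequal_recombination", "position": y,
                    "unit_len": L})
        log.append({"event": "ssm_duplication", "anchor": "initial unit",
                    "start": y, "unit_len": L, "copies": n})
        seq = base[:y] + unit * n + base[y:]
        arr = TandemRepeatArray(unit, L, n, y, 1.0)
        return seq, _truth_profile("", len(seq), [g1], [arr]), log

    # Scenario III-B: HFIR welds the two D7 copies into U16, the initial unit
    u16 = MOTIF_CATALOG["U16"]
    base = base[:g1 - 30] + u16 + base[g1 - 23:]  # replaces the 7 bp D7
    log.append({"event": "hfir", "position": g1 - 30, "result": "U16"})
    x = g1 - 30
    off = 39  # trnI offset inside the unit: 16 (U16) + 23 (G1 tail)
    if not (off + tlen <= L <= off + tlen + g2):
        raise ValueError(f"scenario III-B unit_len must span U16 and trnI: "
                         f"[{off + tlen}, {off + tlen + g2}]")
    unit = base[x:x + L]
    seq = base[:x] + unit * n + base[x + L:]
    log.append({"event": "ssm_duplication", "anchor": "U16", "start": x,
                "unit_len": L, "copies": n})
    arr = TandemRepeatArray(unit, L, n, x, 1.0)
    starts = [x + i * L + off for i in range(n)]
    return seq, _truth_profile("", len(seq), starts, [arr]), log


# ---------------------------------------------------------------------------
# whole-genome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    lsc_len: int = 85_000
    ssc_len: int = 18_000
    ir_len: int = 27_000
    junction_element: str = "trnH_GUG/rps19"  # gene symbol or "irGene/lscGene"
    junction_overlap: int = 0
    rps16_state: Rps16Class = Rps16Class.INTACT
    scenario: Scenario = Scenario.NONE
    cassette: CassetteParams = field(default_factory=CassetteParams)
    mutation_rate: float = 0.0
    gc: float = 0.375

    def __post_init__(self):
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        object.__setattr__(self, "rps16_state", Rps16Class(self.rps16_state))
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("all region lengths must be positive")
        if not 0.0 <= self.mutation_rate <= 0.05:
            raise ValueError("mutation_rate must lie in [0, 0.05]")


@dataclass
class GroundTruth:
    partition: QuadripartitePartition
    junctions: list[JunctionContext]
    rps16_class: Rps16Class
    igs_profile: IgsProfile
    event_log: list[dict]

    def to_json(self) -> str:
        part = self.partition
        payload: dict[str, Any] = {
            "partition": {"lsc": [part.lsc.start, part.lsc.end, part.lsc.wraps],
                          "irb": [part.irb.start, part.irb.end],
                          "ssc": [part.ssc.start, part.ssc.end],
                          "ira": [part.ira.start, part.ira.end],
                          "lengths": list(part.lengths)},
            "junctions": [asdict(j) for j in self.junctions],
            "rps16_class": self.rps16_class.value,
            "igs_profile": {
                "total_len": self.igs_profile.total_len,
                "rpl23_trnI_len": self.igs_profile.rpl23_trnI_len,
                "trnI_ycf2_len": self.igs_profile.trnI_ycf2_len,
                "trnI_copies": self.igs_profile.trnI_copies,
                "repeat_arrays": [
                    {"start": a.start, "unit_len": a.unit_len, "copies": a.copies}
                    for a in (self.igs_profile.repeat_arrays or ())],
            },
            "event_log": self.event_log,
        }
        return json.dumps(payload, indent=2)


class _Builder:
    """Accumulates sequence segments and absolute-coordinate features."""

    def __init__(self, offset: int = 0):
        self.parts: list[str] = []
        self.pos = offset
        self.features: list[GeneFeature] = []

    def filler(self, seq: str) -> None:
        self.parts.append(seq)
        self.pos += len(seq)

    def gene(self, name: str, seq: str, kind: str = "CDS", strand: str = "+",
             pseudo: bool = False) -> Interval:
        iv = Interval(self.pos, self.pos + len(seq))
        self.features.append(GeneFeature(name=name, kind=kind, strand=strand,
                                         parts=(iv,), is_pseudo=pseudo))
        self.filler(seq)
        return iv

    def multi_gene(self, name: str, parts_seqs: list[tuple[str, str]],
                   kind: str = "CDS", strand: str = "+",
                   pseudo: bool = False) -> None:
        """Interleave (exon_seq, following_filler) pairs into one feature."""
        ivs = []
        for exon, gap in parts_seqs:
            ivs.append(Interval(self.pos, self.pos + len(exon)))
            self.filler(exon)
            self.filler(gap)
        self.features.append(GeneFeature(name=name, kind=kind, strand=strand,
                                         parts=tuple(ivs), is_pseudo=pseudo))

    def sequence(self) -> str:
        return "".join(self.parts)


_KIND = {"trnH_GUG": "tRNA", "trnK_UUU": "tRNA", "trnQ_UUG": "tRNA",
         "trnI_CAU": "tRNA", "rrn23": "rRNA"}


def _marker_block(state: Rps16Class, rng: np.random.Generator, gc: float,
                  builder: _Builder) -> None:
    """rps16 locus between the section-marker primer footprints.

    Segment layouts are chosen so the predicted product lengths reproduce the
    marker arithmetic: intact 1,729 bp, exon-2-only loss 1,500 bp
    (sect. Veratrum state), whole-gene loss 400 bp (sect. Fuscoveratrum
    state), exon-1 loss + 47 bp exon-2 remnant 507 bp.
    """
    fwd = RPS16_PRIMERS.forward
    rev_site = revcomp(RPS16_PRIMERS.reverse)
    builder.filler(fwd)
    if state is Rps16Class.INTACT:
        builder.filler(random_seq(rng, 100, gc))
        builder.multi_gene("rps16", [(RPS16_EXON1, random_seq(rng, 1200, gc)),
                                     (RPS16_EXON2, "")])
        builder.filler(random_seq(rng, 120, gc))
    elif state is Rps16Class.EXON2_LOST:
        builder.filler(random_seq(rng, 100, gc))
        builder.multi_gene("rps16", [(RPS16_EXON1, "")], pseudo=True)
        builder.filler(random_seq(rng, 1318, gc))
    elif state is Rps16Class.EXON1_LOST:
        builder.filler(random_seq(rng, 1000, gc))
        builder.multi_gene("rps16", [(RPS16_EXON2, "")], pseudo=True)
        builder.filler(random_seq(rng, 120, gc))
    elif state is Rps16Class.EXON2_PARTIAL:
        builder.filler(random_seq(rng, 300, gc))
        builder.multi_gene("rps16", [(RPS16_EXON2[-47:], "")], pseudo=True)
        builder.filler(random_seq(rng, 120, gc))
    else:  # COMPLETE_LOSS
        builder.filler(random_seq(rng, 360, gc))
    builder.filler(rev_site)


def _junction_split(element: str, overlap: int, rng: np.random.Generator,
                    gc: float) -> tuple[list, list]:
    """Lay out the junction cassette genes on either side of the LSC/IRb
    boundary.

    Returns (lsc_tail, irb_head): lists of ("gene"|"frag"|"filler", name,
    seq) tuples in forward order. ``frag`` marks the IR-side fragment of a
    junction-spanning gene (annotated separately, as real records do).
    """
    gap = lambda n: ("filler", None, random_seq(rng, n, gc))
    order = _JUNCTION_ORDER
    if "/" in element:
        ir_side, lsc_side = element.split("/")
        if (lsc_side, ir_side) not in zip(order, order[1:]):
            raise ValueError(f"unknown junction IGS {element!r}; expected "
                             f"adjacent genes from {order}")
        if overlap != 0:
            raise ValueError("IGS junction cannot carry a gene overlap")
        split_after = order.index(lsc_side) + 1
        lsc_genes, ir_genes = order[:split_after], order[split_after:]
        lsc_tail: list = []
        for g in lsc_genes:
            lsc_tail += [("gene", g, GENE_SEQS[g]), gap(30)]
        lsc_tail[-1] = gap(10)  # short gap up to the junction point
        irb_head: list = [gap(10)]
        for g in ir_genes:
            irb_head += [("gene", g, GENE_SEQS[g]), gap(30)]
        return lsc_tail, irb_head
    if element not in order[:-1]:
        raise ValueError(f"junction element must be an IGS label or one of "
                         f"{order[:-1]}, got {element!r}")
    seq = GENE_SEQS[element]
    if not 0 < overlap <= len(seq):
        raise ValueError(f"junction overlap {overlap} not realisable for "
                         f"{element} (length {len(seq)})")
    idx = order.index(element)
    lsc_tail = []
    for g in order[:idx]:
        lsc_tail += [("gene", g, GENE_SEQS[g]), gap(30)]
    lsc_tail.append(("gene-lsc-part", element, seq[:len(seq) - overlap]))
    irb_head = [("frag", element, seq[len(seq) - overlap:]), gap(30)]
    for g in order[idx + 1:]:
        irb_head += [("gene", g, GENE_SEQS[g]), gap(30)]
    return lsc_tail, irb_head


def generate_plastome(config: SynthConfig) -> tuple[PlastomeRecord, GroundTruth]:
    """Emit a circular quadripartite record and its full ground truth.

    Same config (including seed) -> byte-identical output. The IR pair is
    exact by construction and non-extendable (the flanking bases are forced
    to break reverse-complement identity), so detection at mismatch
    tolerance 0 is coordinate-exact at mutation rate 0.
    """
    ss = np.random.SeedSequence(config.seed)
    s_lsc, s_ssc, s_cas, s_mut = [int(s) & 0x7FFFFFFF for s in ss.generate_state(4)]
    rng = np.random.default_rng(s_lsc)
    gc = config.gc
    n_total = config.lsc_len + 2 * config.ir_len + config.ssc_len

    igs_seq, igs_truth, event_log = simulate_ssm_cassette(
        config.scenario, config.cassette, seed=s_cas)

    # ---- LSC ---------------------------------------------------------------
    b = _Builder(0)
    b.filler(random_seq(rng, 100, gc))
    b.gene("psbA", GENE_SEQS["psbA"])
    b.filler(random_seq(rng, 200, gc))
    b.gene("trnK_UUU", GENE_SEQS["trnK_UUU"], kind="tRNA")
    b.filler(random_seq(rng, 100, gc))
    _marker_block(config.rps16_state, rng, gc, b)
    b.filler(random_seq(rng, 100, gc))
    b.gene("trnQ_UUG", GENE_SEQS["trnQ_UUG"], kind="tRNA")

    lsc_tail, irb_head = _junction_split(config.junction_element,
                                         config.junction_overlap, rng, gc)
    tail_len = sum(len(s) for _, _, s in lsc_tail)
    mid = config.lsc_len - b.pos - tail_len
    if mid < 100:
        raise ValueError(f"lsc_len {config.lsc_len} too small for the fixed "
                         f"LSC content ({b.pos + tail_len + 100} bp minimum)")
    b.filler(random_seq(rng, mid, gc))
    spanning_gene: tuple[str, int] | None = None
    for kind, name, seq in lsc_tail:
        if kind == "filler":
            b.filler(seq)
        elif kind == "gene":
            b.gene(name, seq, kind=_KIND.get(name, "CDS"))
        else:  # gene-lsc-part: spans into the IR; annotate the full gene
            full = GENE_SEQS[name]
            iv = Interval(b.pos, b.pos + len(full))
            b.features.append(GeneFeature(name=name, kind="CDS", strand="+",
                                          parts=(iv,)))
            b.filler(seq)
            spanning_gene = (name, len(full) - len(seq))
    assert b.pos == config.lsc_len
    lsc = b.sequence()
    lsc_features = b.features

    # ---- IRb ---------------------------------------------------------------
    ib = _Builder(config.lsc_len)
    for kind, name, seq in irb_head:
        if kind == "filler":
            ib.filler(seq)
        elif kind == "frag":  # IR-side fragment of the spanning gene
            ib.filler(seq)  # covered by the full-gene feature from the LSC side
        else:
            ib.gene(name, seq, kind=_KIND.get(name, "CDS"))
    ib.filler(random_seq(rng, 200, gc))
    ib.gene("rpl23", GENE_SEQS["rpl23"])
    cassette_start = ib.pos
    ib.filler(igs_seq)
    for h in igs_truth.trnI_hits:
        ib.features.append(GeneFeature(
            name="trnI_CAU", kind="tRNA", strand="+",
            parts=(Interval(cassette_start + h.start, cassette_start + h.end),)))
    ib.gene("ycf2", GENE_SEQS["ycf2"])
    fixed_tail = len(GENE_SEQS["rrn23"]) + 200
    pad = config.ir_len - (ib.pos - config.lsc_len) - fixed_tail
    if pad < 50:
        raise ValueError(f"ir_len {config.ir_len} too small for the IR content "
                         f"({ib.pos - config.lsc_len + fixed_tail + 50} bp minimum)")
    ib.filler(random_seq(rng, pad, gc))
    ib.gene("rrn23", GENE_SEQS["rrn23"], kind="rRNA")
    ib.filler(random_seq(rng, 200, gc))
    assert ib.pos == config.lsc_len + config.ir_len
    irb_seq = ib.sequence()
    irb_features = ib.features

    # ---- SSC ---------------------------------------------------------------
    rng2 = np.random.default_rng(s_ssc)
    sb = _Builder(config.lsc_len + config.ir_len)
    sb.filler(random_seq(rng2, 50, gc))
    sb.gene("ndhF", GENE_SEQS["ndhF"])
    smid = config.ssc_len - 50 - len(GENE_SEQS["ndhF"]) - len(GENE_SEQS["ccsA"]) - 100
    if smid < 50:
        raise ValueError(f"ssc_len {config.ssc_len} too small")
    sb.filler(random_seq(rng2, smid, gc))
    sb.gene("ccsA", GENE_SEQS["ccsA"])
    sb.filler(random_seq(rng2, 100, gc))
    ssc_seq = sb.sequence()
    ssc_features = sb.features

    # ---- optional mutation (IR copies mutate in concert) -------------------
    if config.mutation_rate > 0:
        lsc = mutate(lsc, config.mutation_rate, s_mut)
        irb_seq = mutate(irb_seq, config.mutation_rate, s_mut + 1)
        ssc_seq = mutate(ssc_seq, config.mutation_rate, s_mut + 2)

    # break reverse-complement identity just outside both IR boundaries
    if lsc[0] != lsc[-1]:
        lsc = lsc[-1] + lsc[1:]
    if ssc_seq[0] != ssc_seq[-1]:
        ssc_seq = ssc_seq[-1] + ssc_seq[1:]

    # ---- assembly: LSC | IRb | SSC | IRa=revcomp(IRb) ----------------------
    genome = lsc + irb_seq + ssc_seq + revcomp(irb_seq)
    assert len(genome) == n_total

    b1 = config.lsc_len + config.ir_len        # IRb end
    a0 = b1 + config.ssc_len                   # IRa start
    features = list(lsc_features) + list(irb_features) + list(ssc_features)
    # mirror IRb features into IRa (clipped to the IR: junction-spanning genes
    # leave only their IR-side fragment, annotated as a pseudogene)
    for f in irb_features + [f for f in lsc_features
                             if spanning_gene and f.name == spanning_gene[0]]:
        iv = f.span()
        s = max(iv.start, config.lsc_len)  # clip to the IR
        e = min(iv.end, b1)
        if e <= s:
            continue
        ms, me = a0 + (b1 - e), a0 + (b1 - s)
        clipped = (s != iv.start or e != iv.end)
        features.append(GeneFeature(
            name=f.name, kind=f.kind, strand="-" if f.strand == "+" else "+",
            parts=(Interval(ms, me),), is_pseudo=f.is_pseudo or clipped))

    record = PlastomeRecord(identifier=f"synth_{config.scenario.value}_"
                                       f"{config.seed}",
                            sequence=genome, is_circular=True,
                            features=features, source="synthetic")

    # ---- ground truth ------------------------------------------------------
    part = QuadripartitePartition(
        lsc=Interval(0, config.lsc_len),
        irb=Interval(config.lsc_len, b1),
        ssc=Interval(b1, a0),
        ira=Interval(a0, n_total),
        genome_length=n_total)
    if spanning_gene is not None:
        name, v = spanning_gene
        jlb = JunctionContext("JLB", name, v)
        jla = JunctionContext("JLA", name, v)
    else:
        jlb = JunctionContext("JLB", config.junction_element, 0)
        jla = JunctionContext("JLA", "trnH_GUG/psbA", 0)
    junctions = [jlb,
                 JunctionContext("JSB", "rrn23/ndhF", 0),
                 JunctionContext("JSA", "rrn23/ccsA", 0),
                 jla]
    truth = GroundTruth(partition=part, junctions=junctions,
                        rps16_class=config.rps16_state,
                        igs_profile=igs_truth, event_log=event_log)
    return record, truth
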