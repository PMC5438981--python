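"""IR detection, quadripartite partitioning, junction gene context."""

import numpy as np
import pytest

from plastrep import (GeneFeature, Interval, NoInvertedRepeatError,
                      PlastomeRecord, detect_partition, find_inverted_repeat,
                      junction_context, partition, revcomp)
from plastrep.synthetic_data import random_seq

from conftest import small_config
from plastrep import generate_plastome


def _plant_ir(rng, lsc, ir, ssc):
    """Assemble LSC|IRb|SSC|IRa with exact, non-extendable planted arms."""
    l = random_seq(rng, lsc)
    r = random_seq(rng, ir)
    s = random_seq(rng, ssc)
    if l[0] != l[-1]:
        l = l[-1] + l[1:]
    if s[0] != s[-1]:
        s = s[-1] + s[1:]
    return PlastomeRecord("planted", l + r + s + revcomp(r), is_circular=True)


def test_planted_exact_ir_recovered(rng):
    """A planted exact 4 kb IR pair in a 20 kb circle is found at its exact
    coordinates."""
    rec = _plant_ir(rng, 9_000, 4_000, 3_000)
    irb, ira = find_inverted_repeat(rec, min_len=1_000)
    assert (irb.start, irb.end) == (9_000, 13_000)
    assert (ira.start, ira.end) == (16_000, 20_000)


def test_largest_of_two_candidate_pairs_wins(rng):
    """With a 1.2 kb and a 0.8 kb inverted pair planted in a toy sequence,
    the longer pair is returned (checked against brute-force expectation)."""
    a = random_seq(rng, 1_200)
    b = random_seq(rng, 800)
    fill = [random_seq(rng, 400) for _ in range(4)]
    seq = fill[0] + a + fill[1] + b + fill[2] + revcomp(b) + fill[3] + revcomp(a)
    rec = PlastomeRecord("two", seq, is_circular=True)
    irb, ira = find_inverted_repeat(rec, min_len=500)
    assert irb.length() == ira.length() >= 1_200
    assert irb.start <= 400 + 1  # the long arm, allowing chance 1 bp extension
    assert seq[irb.start:irb.end] == revcomp(seq[ira.start:ira.end])


def test_no_ir_raises(rng):
    rec = PlastomeRecord("noir", random_seq(rng, 5_000), is_circular=True)
    with pytest.raises(NoInvertedRepeatError):
        find_inverted_repeat(rec, min_len=1_000)


def test_partition_assigns_longer_arc_to_lsc(rng):
    rec = _plant_ir(rng, 9_000, 4_000, 3_000)
    part = partition(rec, Interval(9_000, 13_000), Interval(16_000, 20_000))
    assert part.lengths == (9_000, 4_000, 3_000, 4_000)
    assert part.lsc_len > part.ssc_len
    n = part.genome_length
    assert revcomp(rec.sequence[part.ira.start:part.ira.end]) == \
        rec.sequence[part.irb.start:part.irb.end]


def test_partition_tiles_circle_on_random_genomes():
    """Region lengths always sum to the genome length (arithmetic oracle)."""
    for seed in range(12):
        rng = np.random.default_rng(seed)
        lsc = int(rng.integers(6_000, 12_000))
        ir = int(rng.integers(2_000, 4_000))
        ssc = int(rng.integers(1_500, 3_000))
        rec = _plant_ir(rng, lsc, ir, ssc)
        part = detect_partition(rec, min_len=1_000)
        assert sum(part.lengths) == len(rec)
        assert part.lengths == (lsc, ir, ssc, ir)


def test_junction_point_in_gene_with_overlap():
    """A gene whose 3' portion lies inside the IR names the junction with the
    bp duplicated into the repeat."""
    rec, truth = generate_plastome(small_config(seed=7, junction_element="rps3",
                                                junction_overlap=6))
    part = detect_partition(rec, min_len=1_000)
    ctxs = {c.junction_name: c for c in junction_context(part, rec.features)}
    assert (ctxs["JLB"].containing_element, ctxs["JLB"].overlap_bp) == ("rps3", 6)
    assert (ctxs["JLA"].containing_element, ctxs["JLA"].overlap_bp) == ("rps3", 6)


def test_junction_in_igs_names_flanking_pair():
    rec, truth = generate_plastome(small_config(seed=8))
    part = detect_partition(rec, min_len=1_000)
    ctxs = {c.junction_name: c for c in junction_context(part, rec.features)}
    assert ctxs["JLB"].containing_element == "trnH_GUG/rps19"
    assert ctxs["JLB"].overlap_bp == 0


def test_junction_at_gene_first_base_is_containment():
    """Half-open containment: a junction at a gene's first base is inside the
    gene; at the base past its end it is IGS context."""
    n = 2_000
    part_genes = [
        GeneFeature("geneA", "CDS", "+", (Interval(400, 500),)),
        GeneFeature("geneB", "CDS", "+", (Interval(700, 800),)),
    ]
    rng = np.random.default_rng(0)
    rec = _plant_ir(rng, 500, 400, 300)  # irb starts at 500
    from plastrep.quadripartite import QuadripartitePartition
    part = QuadripartitePartition(lsc=Interval(0, 500), irb=Interval(500, 900),
                                  ssc=Interval(900, 1_200),
                                  ira=Interval(1_200, 1_600),
                                  genome_length=1_600)
    # gene starting exactly at the JLB point
    genes = [GeneFeature("starts_here", "CDS", "+", (Interval(500, 600),)),
             GeneFeature("lsc_gene", "CDS", "+", (Interval(300, 420),))]
    ctxs = {c.junction_name: c for c in junction_context(part, genes)}
    assert ctxs["JLB"].containing_element == "starts_here"
    assert ctxs["JLB"].overlap_bp == 100  # whole gene sits inside the IR
    # gene ending exactly at the JLB point -> IGS, half-open
    genes2 = [GeneFeature("ends_here", "CDS", "+", (Interval(400, 500),)),
              GeneFeature("ir_gene", "CDS", "+", (Interval(600, 700),))]
    ctxs2 = {c.junction_name: c for c in junction_context(part, genes2)}
    assert ctxs2["JLB"].containing_element == "ir_gene/ends_here"


def test_junction_context_agrees_with_naive_scan():
    """Containment calls match a point-in-interval scan over every feature on
    random annotation layouts."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = 3_000
        part = None
        from plastrep.quadripartite import QuadripartitePartition, \
            _junction_points
        part = QuadripartitePartition(
            lsc=Interval(0, 1_400), irb=Interval(1_400, 2_000),
            ssc=Interval(2_000, 2_400), ira=Interval(2_400, 3_000),
            genome_length=n)
        genes = []
        for g in range(int(rng.integers(2, 8))):
            s = int(rng.integers(0, n - 200))
            genes.append(GeneFeature(f"g{g}", "CDS", "+",
                                     (Interval(s, s + int(rng.integers(50, 200))),)))
        ctxs = {c.junction_name: c for c in junction_context(part, genes)}
        for name, (point, ir, _side) in _junction_points(part).items():
            oracle = [g.name for g in genes if g.span().contains(point, n)]
            if oracle:
                assert ctxs[name].containing_element == oracle[0]
            else:
                assert "/" in ctxs[name].containing_element or \
                    ctxs[name].containing_element == "unresolved"


def test_detection_on_full_size_genome(full_size_genome):
    """A 157 kb-scale genome partitions exactly at its planted coordinates."""
    rec, truth = full_size_genome
    part = detect_partition(rec)
    assert part.lengths == truth.partition.lengths
    assert (part.irb.start, part.ira.end) == \
        (truth.partition.irb.start, truth.partition.ira.end)
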