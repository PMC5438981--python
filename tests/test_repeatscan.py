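"""Spacer extraction, trnI counting, tandem repeats, motif scanning."""

import numpy as np
import pytest

from plastrep import (DEFAULT_TRNI, MOTIF_CATALOG, MissingGeneError,
                      count_trnI, extract_igs, find_tandem_repeats,
                      generate_plastome, revcomp, scan_motifs,
                      total_repeat_units)
from plastrep.synthetic_data import random_seq

from conftest import small_config


# ---------------------------------------------------------------------------
# brute-force tandem-repeat oracle
# ---------------------------------------------------------------------------

def brute_force_tandem(seq, min_unit=18, max_unit=250, min_copies=2,
                       frac=0.1):
    """Enumerate every (start, period, run) triple and apply the collapse
    rule; independent of the package's vectorised candidate filtering."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(seq)
    cands = []
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        allowed = int(frac * p)
        for s in range(0, n - 2 * p + 1):
            unit = a[s:s + p]
            c = 1
            while s + (c + 1) * p <= n and \
                    int(np.count_nonzero(a[s + c * p:s + (c + 1) * p] != unit)) <= allowed:
                c += 1
            if c >= min_copies:
                cands.append((s, p, c))
    chosen = []
    for s, p, c in sorted(cands, key=lambda t: (-t[2], t[1], t[0])):
        if any(s < cs + cc * cp and s + c * p > cs for cs, cp, cc in chosen):
            continue
        chosen.append((s, p, c))
    return sorted(chosen)


def _triples(arrays):
    return sorted((a.start, a.unit_len, a.copies) for a in arrays)


def test_planted_exact_repeat_found(rng):
    """A 24 bp unit repeated 3x in random background is one array.

    With per-copy mismatch tolerance, the reported start may drift left by up
    to the allowed mismatch count (tie-break prefers the smaller start), so
    coordinates are asserted to that slack."""
    unit = random_seq(rng, 24)
    seq = random_seq(rng, 150) + unit * 3 + random_seq(rng, 150)
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    a = arrays[0]
    assert (a.unit_len, a.copies) == (24, 3)
    assert 150 - 2 <= a.start <= 150
    assert a.identity >= 0.9
    assert find_tandem_repeats(seq, max_mismatch_frac=0.0)[0].start == 150


def test_tandem_matches_brute_force_on_planted_and_random():
    """Array sets equal the brute-force enumeration on short sequences."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 400))
        seq = random_seq(rng, n)
        if seed % 2:  # plant a tract in half the cases
            u = random_seq(rng, int(rng.integers(18, 40)))
            k = int(rng.integers(2, 5))
            pos = int(rng.integers(0, max(1, n - len(u) * k)))
            seq = seq[:pos] + u * k + seq[pos + len(u) * k:]
            seq = seq[:n] if len(seq) > n else seq
        assert _triples(find_tandem_repeats(seq)) == brute_force_tandem(seq)


def test_extra_copy_increments_count(rng):
    """Inserting one more exact copy raises the copy count by exactly one."""
    unit = random_seq(rng, 30)
    left, right = random_seq(rng, 100), random_seq(rng, 100)
    for k in (2, 3, 4):
        arrays = find_tandem_repeats(left + unit * k + right)
        assert sum(a.copies for a in arrays) == k


def test_partial_trailing_copy_is_tail_not_unit(rng):
    unit = random_seq(rng, 30)
    seq = random_seq(rng, 80) + unit * 2 + unit[:16] + random_seq(rng, 80)
    arrays = find_tandem_repeats(seq, max_mismatch_frac=0.0)
    assert len(arrays) == 1 and arrays[0].copies == 2
    assert arrays[0].tail_bp >= 16


def test_unit_spanning_trnI_counts_both_ways(rng):
    """A 164 bp unit carrying the whole trnI_CAU, repeated 3x, yields one
    3-copy array and 3 trnI hits (the long-unit duplication signature)."""
    pad = random_seq(rng, 164 - len(DEFAULT_TRNI))
    unit = DEFAULT_TRNI + pad
    seq = random_seq(rng, 120) + unit * 3 + random_seq(rng, 120)
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    assert (arrays[0].unit_len, arrays[0].copies) == (164, 3)
    assert len(count_trnI(seq)) == 3


# ---------------------------------------------------------------------------
# trnI counting
# ---------------------------------------------------------------------------

def test_count_trnI_verbatim_copies(rng):
    seq = random_seq(rng, 100) + DEFAULT_TRNI + random_seq(rng, 50) + \
        DEFAULT_TRNI + random_seq(rng, 100)
    hits = count_trnI(seq)
    assert len(hits) == 2 and all(h.identity == 1.0 for h in hits)


def test_count_trnI_identity_threshold(rng):
    """74 nt reference with 3 mismatches (95.9%) is a hit; 4 (94.6%) is not."""
    def with_mm(k):
        s = list(DEFAULT_TRNI)
        for i in range(k):
            pos = 5 + 7 * i
            s[pos] = "A" if s[pos] != "A" else "C"
        return "".join(s)

    flank = random_seq(rng, 80)
    assert len(count_trnI(flank + with_mm(2) + flank)) == 1
    assert len(count_trnI(flank + with_mm(3) + flank)) == 1
    assert len(count_trnI(flank + with_mm(4) + flank)) == 0


def test_count_trnI_reverse_strand(rng):
    seq = random_seq(rng, 100) + revcomp(DEFAULT_TRNI) + random_seq(rng, 100)
    hits = count_trnI(seq)
    assert len(hits) == 1 and hits[0].strand == "-"


def test_count_trnI_rejects_bad_reference():
    with pytest.raises(ValueError):
        count_trnI("ACGT" * 100, ref_trnI="ACGT" * 10)  # 40 nt, too short


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def test_motif_exactness():
    """One terminal mismatch kills the R1 hit (its internal R1b remains)."""
    hits = scan_motifs("xxCAAATTCCATxx".replace("x", "G"))
    assert all(h.motif_name != "R1" for h in hits)


def test_u16_implies_d7_at_same_position():
    hits = scan_motifs(MOTIF_CATALOG["U16"])
    by_name = {h.motif_name: h.position for h in hits}
    assert by_name["U16"] == 0 and by_name["D7"] == 0


def test_motifs_match_naive_search(rng):
    """Hit set equals a positional startswith scan on 1 kb random sequence
    with motifs planted."""
    seq = list(random_seq(rng, 1_000))
    for name in ("R1", "R1a", "D7", "U16"):
        pos = int(rng.integers(0, 950))
        m = MOTIF_CATALOG[name]
        seq[pos:pos + len(m)] = m
    seq = "".join(seq)
    naive = sorted(
        (i, name)
        for name, m in MOTIF_CATALOG.items()
        for i in range(len(seq)) if seq.startswith(m, i))
    assert sorted((h.position, h.motif_name) for h in scan_motifs(seq)) == naive


def test_motif_shift_invariance(rng):
    seq = random_seq(rng, 300) + MOTIF_CATALOG["R1"] + random_seq(rng, 100)
    base = scan_motifs(seq)
    shifted = scan_motifs("ACGTACG" + seq)
    assert [(h.position + 7, h.motif_name) for h in base] == \
        [(h.position, h.motif_name) for h in shifted]


def test_r1_family_containment():
    """R1 and R1a both contain R1b, and the scan reports the nested hit."""
    hits = scan_motifs(MOTIF_CATALOG["R1"])
    names = {h.motif_name for h in hits}
    assert names == {"R1", "R1b"}


# ---------------------------------------------------------------------------
# spacer extraction from annotated records
# ---------------------------------------------------------------------------

def test_extract_igs_bookkeeping_identity(small_genome):
    """total = upstream gap + trnI copies + inter-copy spacer + downstream
    gap on a generated record."""
    rec, truth = small_genome
    prof = extract_igs(rec)
    assert prof.total_len == truth.igs_profile.total_len
    assert prof.rpl23_trnI_len == truth.igs_profile.rpl23_trnI_len
    assert prof.trnI_ycf2_len == truth.igs_profile.trnI_ycf2_len
    assert prof.trnI_copies == truth.igs_profile.trnI_copies
    covered = sum(h.end - h.start for h in prof.trnI_hits)
    inter = (prof.total_len - prof.rpl23_trnI_len - prof.trnI_ycf2_len
             - covered)
    assert inter >= 0


def test_extract_igs_missing_gene_raises(small_genome):
    rec, _ = small_genome
    from dataclasses import replace
    stripped = replace(rec, features=[f for f in rec.features
                                      if f.name != "rpl23"])
    with pytest.raises(MissingGeneError, match="rpl23"):
        extract_igs(stripped)


def test_extract_igs_multi_copy_layout():
    """Three planted trnI copies give 3 similarity hits even though only the
    planted annotations exist."""
    rec, truth = generate_plastome(small_config(seed=3, scenario="III-B"))
    prof = extract_igs(rec)
    assert prof.trnI_copies == 3
    assert prof.rpl23_trnI_len == truth.igs_profile.rpl23_trnI_len
    assert prof.trnI_ycf2_len == truth.igs_profile.trnI_ycf2_len


def test_total_repeat_units_threshold():
    from plastrep import TandemRepeatArray
    arrays = [TandemRepeatArray("A" * 18, 18, 5, 0, 1.0),
              TandemRepeatArray("A" * 30, 30, 2, 200, 1.0)]
    assert total_repeat_units(arrays) == 7
    assert total_repeat_units(arrays, min_unit=24) == 2
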