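"""Transcription of the published comparative survey of rpl23-ycf2 spacers.

Each unflagged survey row is rendered as the IgsProfile the narrative
describes: spacer length, trnI_CAU copy number, sub-spacer lengths, repeat
unit count, and which conserved motifs are observable for that lineage
(U16 for the HFIR-derived rows, R1a for the point-mutation rows; R1/R1b/D7
are conserved across nearly all surveyed taxa). Rows annotated with
unexplained footnote marks in the source table are excluded here.
"""

import numpy as np

from plastrep import DEFAULT_TRNI, IgsProfile, MotifHit, TandemRepeatArray, TrnIHit
from plastrep.synthetic_data import random_seq

_BASE_MOTIFS = ("R1", "R1b", "D7")

# species, total, trnI_copies, rpl23_trnI, trnI_ycf2, n_units, scenario, extra motifs
ROWS = [
    ("Paris verticillata",      591, 3, 172,  67,  3, "III-B", ("U16",)),
    ("Paris quadrifolia",       591, 3, 172,  67,  3, "III-B", ("U16",)),
    ("Paris dulongensis",       724, 1, 159, 491, 16, "III-A", ()),
    ("Paris fargesii",          708, 1, 159, 475, 16, "III-A", ()),
    ("Paris mairei",            612, 1, 159, 379, 12, "III-A", ()),
    ("Paris luquanensis",       636, 1, 159, 403, 13, "III-A", ()),
    ("Paris rugosa",            612, 1, 159, 379, 12, "III-A", ()),
    ("Paris dunniana",          420, 1, 159, 187,  4, "III-A", ()),
    ("Paris thibetica",         485, 1, 159, 252,  7, "III-A", ()),
    ("Paris axialis",           501, 1, 159, 268,  6, "III-A", ()),
    ("Paris vietnamensis",      500, 1, 159, 267,  6, "III-A", ()),
    ("Paris polyphylla chinensis",   523, 1, 159, 290, 12, "III-A", ()),
    ("Paris polyphylla polyphylla",  612, 1, 159, 290,  8, "III-A", ()),
    ("Paris polyphylla stenophylla", 636, 1, 159, 403, 13, "III-A", ()),
    ("Pseudotrillium rivale",   299, 1, 164,  61,  0, "-", ()),
    ("Trillium undulatum",      307, 1, 165,  68,  0, "-", ()),
    ("Trillium decumbens",      402, 1, 205, 123,  0, "-", ()),
    ("Trillium cuneatum",       378, 1, 210,  94,  0, "-", ()),
    ("Trillium smalii",         447, 1, 173, 200,  7, "III-A", ()),
    ("Trillium tschonoskii",    483, 1, 240, 169,  7, "III-A", ()),
    ("Trillium chloropetalum",  581, 2, 205, 102,  2, "II", ("R1a",)),
    ("Trillium govanianum",     612, 3, 164,  65,  3, "I", ()),
    ("Xerophyllum tenax",       306, 1, 164,  68,  0, "-", ()),
    ("Xerophyllum asphodeloides", 306, 1, 164, 68,  0, "-", ()),
    ("Chionographis japonica",  302, 1, 160,  68,  0, "-", ()),
    ("Heloniopsis tubiflora",   302, 1, 160,  68,  0, "-", ()),
    ("Veratrum patulum",        304, 1, 157,  73,  0, "-", ()),
    ("Toxicoscordion micranthus", 304, 1, 157, 73,  0, "-", ()),
    ("Schoenocaulon coricifolium", 304, 1, 157, 73, 0, "-", ()),
    ("Zigadenus glaberrimus",   299, 1, 157,  68,  0, "-", ()),
    ("Lilium longiflorum",      307, 1, 165,  68,  0, "-", ()),
    ("Smilax china",            307, 1, 165,  68,  0, "-", ()),
    ("Colchicum autumnale",     298, 1, 165,  59,  0, "-", ()),
    ("Alstroemeria aurea",      307, 1, 165,  68,  0, "-", ()),
    ("Campynema lineare",       312, 1, 170,  68,  0, "-", ()),
]


def profile_from_row(row) -> tuple[IgsProfile, str]:
    """Render one survey row as a completed IgsProfile plus expected label."""
    species, total, k, g1, g2, n_units, scenario, extra = row
    rng = np.random.default_rng(abs(hash(species)) % (2**31))
    tlen = len(DEFAULT_TRNI)
    hits = tuple(TrnIHit(g1 + i * (tlen + 10), g1 + i * (tlen + 10) + tlen,
                         "+", 1.0) for i in range(k))
    arrays = []
    if n_units:
        if scenario in ("I", "III-B"):
            # long units spanning the whole trnI_CAU gene
            unit_len = max(tlen + 20, (total - g1 - g2) // max(n_units, 1))
            unit = DEFAULT_TRNI + random_seq(rng, unit_len - tlen)
            arrays.append(TandemRepeatArray(unit, unit_len, n_units,
                                            max(0, g1 - 20), 1.0))
        elif scenario == "II":
            unit_len = 139
            unit = DEFAULT_TRNI + random_seq(rng, unit_len - tlen)
            arrays.append(TandemRepeatArray(unit, unit_len, n_units,
                                            max(0, g1 - 20), 1.0))
        else:  # III-A: short units confined to the downstream sub-spacer
            unit = random_seq(rng, 18)
            arrays.append(TandemRepeatArray(unit, 18, n_units,
                                            total - g2 + 5, 1.0))
    motifs = tuple(MotifHit(name, 30 + 3 * i)
                   for i, name in enumerate(_BASE_MOTIFS + extra))
    profile = IgsProfile(record_id=species, igs_seq="", total_len=total,
                         rpl23_trnI_len=g1, trnI_ycf2_len=g2, trnI_copies=k,
                         trnI_hits=hits, repeat_arrays=tuple(arrays),
                         motif_hits=motifs)
    return profile, scenario
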