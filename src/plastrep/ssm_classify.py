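"""Rule-based assignment of repeat-origin scenarios in the rpl23–ycf2 spacer.

Tandem-repeat tracts in this spacer can arise by slipped-strand mispairing
(SSM) seeded by different initial units, and the architecture left behind is
diagnostic of the path taken:

* **I** — SSM on an R1b-anchored window that spans the whole trnI_CAU gene,
  leaving >= 3 trnI copies inside long tandem units (Trillium govanianum
  type).
* **II** — a point mutation (A->C) first converts an R1 copy into R1a,
  creating the perfect direct repeat that seeds a single SSM duplication:
  2 trnI copies, 2 units, R1a observable in sequence.
* **III-A** — unequal recombination downstream of trnI_CAU creates the
  initial unit; subsequent SSM expands it: 1 trnI copy, repeats confined to
  the trnI–ycf2 sub-spacer (the common Paris type).
* **III-B** — double-strand-break repair via homology-facilitated
  illegitimate recombination (HFIR) between two D7 copies welds them into
  the 16 bp U16 unit, whose presence marks the path: 3 trnI copies with U16.

The decision table below is this package's formalisation — the scenarios
were narrated, not algorithmised, in the literature — and is evaluated
top-down, first match wins, with the supporting observation recorded as an
evidence flag on every call.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .repeatscan import (DEFAULT_TRNI, IgsProfile, TandemRepeatArray,
                         _window_mismatches, total_repeat_units)


class Scenario(str, Enum):
    I = "I"
    II = "II"
    III_A = "III-A"
    III_B = "III-B"
    NONE = "-"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class ScenarioCall:
    label: Scenario
    evidence: tuple[str, ...]


def _unit_contains_trnI(array: TandemRepeatArray, ref_trnI: str,
                        min_identity: float = 0.95) -> bool:
    """Does the repeat unit carry the full trnI_CAU sequence (>=95% id)?

    The unit is scanned as a tandem doublet so a trnI copy straddling the
    unit boundary (a rotation of the unit) still counts.
    """
    if array.unit_len < len(ref_trnI):
        return False
    max_mism = int((1.0 - min_identity) * len(ref_trnI))
    doubled = array.unit_seq + array.unit_seq
    mism = _window_mismatches(doubled, ref_trnI)
    return bool(len(mism) and mism.min() <= max_mism)


def classify_scenario(profile: IgsProfile,
                      ref_trnI: str = DEFAULT_TRNI,
                      min_unit: int = 18,
                      trnI_for_scenario_I: int = 3) -> ScenarioCall:
    """Assign a repeat-origin scenario to a completed spacer profile.

    Rules, first match wins:

    1. no qualifying arrays (unit >= ``min_unit``)          -> NONE
    2. trnI >= 3, a unit spans trnI, no U16                 -> I
    3. trnI == 3 and U16 present                            -> III-B
    4. trnI == 2, exactly 2 units, R1a present              -> II
    5. trnI == 1, an array inside the trnI–ycf2 sub-spacer  -> III-A
    6. anything else                                        -> COMPLEX

    Rule 4 requires the R1a motif to be *observed* in sequence, not merely
    inferred from the duplication, and says so in its evidence flag.
    """
    if profile.repeat_arrays is None or profile.motif_hits is None:
        raise ValueError(
            "profile lacks repeats/motifs; run complete_profile / scan_motifs first"
        )
    arrays = [a for a in profile.repeat_arrays if a.unit_len >= min_unit]
    units = total_repeat_units(profile.repeat_arrays, min_unit=min_unit)
    motifs = {h.motif_name for h in profile.motif_hits}
    k = profile.trnI_copies

    if not arrays:
        return ScenarioCall(Scenario.NONE, ())

    if (k >= trnI_for_scenario_I and "U16" not in motifs
            and any(_unit_contains_trnI(a, ref_trnI) for a in arrays)):
        return ScenarioCall(Scenario.I, (
            f"{k} trnI_CAU copies", "repeat unit spans trnI_CAU", "no U16",
        ))
    if k == 3 and "U16" in motifs:
        return ScenarioCall(Scenario.III_B, (
            "3 trnI_CAU copies", "U16 present (HFIR initial unit)",
        ))
    if k == 2 and units == 2 and "R1a" in motifs:
        return ScenarioCall(Scenario.II, (
            "2 trnI_CAU copies", "2 repeat units",
            "R1a observed in sequence (point-mutated R1)",
        ))
    if k == 1:
        sub_start = profile.total_len - profile.trnI_ycf2_len
        if any(a.start >= sub_start for a in arrays):
            return ScenarioCall(Scenario.III_A, (
                "1 trnI_CAU copy", "repeat array downstream of trnI_CAU",
            ))
    return ScenarioCall(Scenario.COMPLEX, ("no rule matched",))


def length_spectrum(profiles: Sequence[IgsProfile],
                    threshold: int = 24) -> dict:
    """Aggregate unit counts below/at-or-above the 24 bp threshold.

    Short units dominating long ones is the signature of SSM acting more
    often on short initial repeats. ``ratio`` is short/long, ``None`` when
    undefined (no long units or no units at all).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    short = long = 0
    for p in profiles:
        if p.repeat_arrays is None:
            raise ValueError(f"profile {p.record_id}: repeats not filled")
        for a in p.repeat_arrays:
            if a.unit_len < threshold:
                short += a.copies
            else:
                long += a.copies
    ratio = (short / long) if long else None
    return {"short": short, "long": long, "ratio": ratio,
            "undefined": short + long == 0 or long == 0}
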