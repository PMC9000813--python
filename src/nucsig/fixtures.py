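"""Packaged reference data for the *Ephedra* ITS2 assay.

The toolkit ships the published worked example it was built around: the
nested candidate ladder S1–S7 (sub-windows of a 55-bp relatively conserved
ITS2 fragment, with their database-screen verdicts), the selected 23-bp
genus-level signature, and the MH-1F/MH-1R primer pair that amplifies a
~150-bp mini-barcode spanning the signature. The verdicts are fixture
labels from the original database screen; they are data, not recomputable
facts, and the selection rule applied to them (shortest candidate passing
both criteria) reproduces the 23-mer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conservation import CandidateWindow
from .pcr import PrimerPair

__all__ = [
    "SIGNATURE",
    "MH1F",
    "MH1R",
    "PRIMERS",
    "LadderEntry",
    "CANDIDATE_LADDER",
    "FixtureError",
    "ladder_windows",
    "ladder_table",
    "select_signature_from_ladder",
    "check_fixtures",
]

#: The 23-bp genus-level nucleotide signature for *Ephedra*.
SIGNATURE = "GTCCGGTCCGCCTCGGCGGTGCG"

#: Primer pair amplifying the ~150-bp mini-barcode spanning the signature.
MH1F = "TCATCGAGTCTTTGAACGC"
MH1R = "ATGCGAAGGTCCCCTTTT"
PRIMERS = PrimerPair(fwd=MH1F, rev=MH1R, name="MH-1")


class FixtureError(AssertionError):
    """A packaged-fixture invariant does not hold."""


@dataclass(frozen=True)
class LadderEntry:
    """One candidate of the length sweep with its screen verdicts."""

    name: str
    residues: str
    specific: bool  # intergeneric specificity verdict
    conserved: bool  # intragenus conservation verdict

    @property
    def length(self) -> int:
        return len(self.residues)


#: The candidate ladder, longest to shortest. Longer candidates failed
#: intragenus conservation; the shortest failed intergeneric specificity;
#: exactly one (S6, 23 bp) passed both.
CANDIDATE_LADDER: tuple[LadderEntry, ...] = (
    LadderEntry("S1", "TCGGGGGGACGGCCTTGACCGTCCGGTCCGCCTCGGCGGTGCGGTCGGTTGAAAT", True, False),
    LadderEntry("S2", "GGGGGACGGCCTTGACCGTCCGGTCCGCCTCGGCGGTGCGGTCGG", True, False),
    LadderEntry("S3", "GCCTTGACCGTCCGGTCCGCCTCGGCGGTGCGGTC", True, False),
    LadderEntry("S4", "GACCGTCCGGTCCGCCTCGGCGGTGCGGTC", True, False),
    LadderEntry("S5", "CCGTCCGGTCCGCCTCGGCGGTGCGGT", True, False),
    LadderEntry("S6", SIGNATURE, True, True),
    LadderEntry("S7", "CCGGTCCGCCTCGGCGGTGC", False, True),
)

EXPECTED_LENGTHS = (55, 45, 35, 30, 27, 23, 20)


def ladder_windows() -> list[CandidateWindow]:
    """The ladder as coordinate-anchored windows on the 55-bp fragment (S1)."""
    s1 = CANDIDATE_LADDER[0].residues
    return [
        CandidateWindow(residues=e.residues, source_id="S1", start=s1.find(e.residues))
        for e in CANDIDATE_LADDER
    ]


def ladder_table(human: bool = False) -> pd.DataFrame:
    """The ladder as a table; ``human=True`` renders verdicts as check marks."""
    mark = (lambda b: "√" if b else "×") if human else bool
    return pd.DataFrame(
        [
            {
                "no": e.name,
                "sequence_5p_3p": e.residues,
                "length_bp": e.length,
                "intergeneric_specificity": mark(e.specific),
                "intragenus_conservation": mark(e.conserved),
            }
            for e in CANDIDATE_LADDER
        ]
    )


def select_signature_from_ladder() -> LadderEntry:
    """Apply the selection rule: shortest candidate passing both criteria."""
    passing = [e for e in CANDIDATE_LADDER if e.specific and e.conserved]
    if not passing:
        raise FixtureError("no ladder candidate passes both criteria")
    return min(passing, key=lambda e: e.length)


def check_fixtures() -> list[str]:
    """Validate every packaged-fixture invariant; return the passed checks."""
    checks: list[str] = []

    def ok(cond: bool, what: str) -> None:
        if not cond:
            raise FixtureError(f"fixture check failed: {what}")
        checks.append(what)

    lengths = tuple(e.length for e in CANDIDATE_LADDER)
    ok(lengths == EXPECTED_LENGTHS, f"ladder lengths are {EXPECTED_LENGTHS}")
    s1 = CANDIDATE_LADDER[0].residues
    for e in CANDIDATE_LADDER[1:]:
        ok(e.residues in s1, f"{e.name} is a contiguous substring of S1")
    s6 = CANDIDATE_LADDER[5]
    s7 = CANDIDATE_LADDER[6]
    ok(s7.residues in s6.residues, "S7 is a contiguous substring of S6")
    dual = [e for e in CANDIDATE_LADDER if e.specific and e.conserved]
    ok(len(dual) == 1 and dual[0].name == "S6", "exactly one dual-pass candidate (S6)")
    ok(s6.residues == SIGNATURE, "S6 equals the packaged signature")
    ok(select_signature_from_ladder().length == 23, "selection rule returns the 23-mer")
    ok(PRIMERS.fwd == MH1F and PRIMERS.rev == MH1R, "primer pair matches MH-1F/MH-1R")
    ok((len(MH1F), len(MH1R)) == (19, 18), "primer lengths are 19/18 nt")
    ok(SIGNATURE in s1, "signature lies inside the 55-bp fragment")
    return checks
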