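"""Discovery of windows conserved across an ingroup.

Conservation is defined alignment-free: a window is conserved when it occurs
as an exact forward-strand substring of (at least a ``threshold`` fraction
of) the ingroup records. For unaligned input this is equivalent to the
column-identity criterion a multiple alignment would give for an invariant
region, and it is unambiguous without committing to an aligner.

Two facts drive the algorithms here and in :mod:`nucsig.mining`:

* anti-monotonicity — every contiguous sub-window of a conserved window is
  itself conserved (its containing-record set can only grow), so per anchor
  position the admissible lengths form a prefix and can be binary-searched;
* maximality — a reported region cannot be extended by one base on either
  side without dropping below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .alphabet import contains, validate_policy
from .io import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateWindow",
    "ConservedRegion",
    "conservation_fraction",
    "find_conserved_regions",
    "regions_table",
]


@dataclass(frozen=True)
class CandidateWindow:
    """A contiguous subsequence with source coordinates (0-based, half-open)."""

    residues: str
    source_id: str = ""
    start: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("window must be non-empty")
        if self.start < 0:
            raise ValueError("window start must be >= 0")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def end(self) -> int:
        return self.start + len(self.residues)

    def subwindow(self, rel_start: int, length: int) -> "CandidateWindow":
        if rel_start < 0 or rel_start + length > self.length:
            raise ValueError("sub-window out of range")
        return CandidateWindow(
            residues=self.residues[rel_start : rel_start + length],
            source_id=self.source_id,
            start=self.start + rel_start,
        )


@dataclass(frozen=True)
class ConservedRegion(CandidateWindow):
    """A maximal conserved window, annotated with its conservation fraction."""

    conservation_fraction: float = 1.0


def conservation_fraction(
    window: str, ingroup: SequenceSet, policy: str = "strict"
) -> float:
    """Fraction of ingroup records containing ``window`` as a forward substring.

    ``strict`` (default for mining): IUPAC ambiguity symbols only match
    themselves, so an ``N`` in a record breaks conservation. ``compatible``:
    symbols match when their base sets intersect.
    """
    if not window:
        raise ValueError("window must be non-empty")
    if len(ingroup) == 0:
        raise ValueError("conservation fraction is undefined for an empty ingroup")
    validate_policy(policy)
    hits = sum(1 for rec in ingroup if contains(window, rec.residues, policy))
    return hits / len(ingroup)


def _max_conserved_length(
    seq: str, start: int, cap: int, ingroup: SequenceSet, threshold: float, policy: str
) -> int:
    """Largest L <= cap with fraction(seq[start:start+L]) >= threshold (0 if none).

    Valid because the fraction is anti-monotone in L.
    """
    if cap < 1 or conservation_fraction(seq[start : start + 1], ingroup, policy) < threshold:
        return 0
    lo, hi = 1, cap
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if conservation_fraction(seq[start : start + mid], ingroup, policy) >= threshold:
            lo = mid
        else:
            hi = mid - 1
    return lo


def find_conserved_regions(
    ingroup: SequenceSet,
    min_len: int = 15,
    threshold: float = 1.0,
    policy: str = "strict",
) -> list[ConservedRegion]:
    """All maximal windows of length >= ``min_len`` conserved at ``threshold``.

    Each region is reported with coordinates on the first ingroup record that
    contains it; no returned region is a sub-window (by content) of another.
    Sorted by (anchor record order, start, length).
    """
    if len(ingroup) == 0:
        raise ValueError("ingroup must be non-empty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    validate_policy(policy)
    if threshold < 1.0:
        logger.warning(
            "conservation threshold %.3f < 1: windows may be absent from some "
            "ingroup records",
            threshold,
        )

    candidates: list[tuple[int, ConservedRegion]] = []
    for rec_idx, rec in enumerate(ingroup):
        if threshold == 1.0 and rec_idx > 0:
            # every fully conserved window already occurs in the first record
            break
        seq = rec.residues
        m = len(seq)
        max_len = [
            _max_conserved_length(seq, s, m - s, ingroup, threshold, policy)
            for s in range(m)
        ]
        for s in range(m):
            L = max_len[s]
            if L < min_len:
                continue
            # right-maximal by construction; left-maximal iff the one-base
            # left extension (same right edge) is not conserved
            if s > 0 and max_len[s - 1] >= L + 1:
                continue
            frac = conservation_fraction(seq[s : s + L], ingroup, policy)
            candidates.append(
                (
                    rec_idx,
                    ConservedRegion(
                        residues=seq[s : s + L],
                        source_id=rec.id,
                        start=s,
                        conservation_fraction=frac,
                    ),
                )
            )

    # keep the earliest anchor per content; drop content-nested regions
    best_by_content: dict[str, tuple[int, ConservedRegion]] = {}
    for rec_idx, reg in candidates:
        key = reg.residues
        if key not in best_by_content or (rec_idx, reg.start) < (
            best_by_content[key][0],
            best_by_content[key][1].start,
        ):
            best_by_content[key] = (rec_idx, reg)
    kept = list(best_by_content.values())
    result = [
        (rec_idx, reg)
        for rec_idx, reg in kept
        if not any(
            reg.residues in other.residues and reg.residues != other.residues
            for _, other in kept
        )
    ]
    result.sort(key=lambda t: (t[0], t[1].start, t[1].length))
    return [reg for _, reg in result]


def regions_table(regions: list[ConservedRegion]) -> pd.DataFrame:
    """Human-readable report (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "start_1based": r.start + 1,
                "end_1based": r.end,
                "length": r.length,
                "sequence": r.residues,
                "conservation_fraction": r.conservation_fraction,
            }
            for r in regions
        ],
        columns=[
            "source_id",
            "start_1based",
            "end_1based",
            "length",
            "sequence",
            "conservation_fraction",
        ],
    )
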