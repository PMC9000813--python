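"""Outgroup specificity scoring: how far is a window from every non-target sequence?

The score of a window is its minimum distance to the outgroup over all
full-length placements in every outgroup record, on both strands by default.
A window is *specific* when that minimum is at least ``d_min`` (default 1:
"at least one variation" between the window and anything outside the target
taxon). Under the Hamming metric the distance is monotone non-decreasing
under window extension, which is what makes the minimal-length sweep in
:mod:`nucsig.mining` correct.

This is a local, exact replacement for a BLAST screen of candidates against
a reference database: the user supplies the outgroup set, and scoring
enumerates all placements rather than relying on heuristic seeding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import edlib
import pandas as pd

from .alphabet import (
    IUPAC_BASES,
    mismatch_profile,
    reverse_complement,
    validate,
    validate_policy,
)
from .io import SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "SpecificityPolicy",
    "SpecificityScore",
    "min_outgroup_distance",
    "is_specific",
    "score_table",
]

METRICS = ("hamming", "edit")

# symbol pairs with intersecting base sets, for edlib's compatible matching
_IUPAC_EQUALITIES = [
    (a, b)
    for a in IUPAC_BASES
    for b in IUPAC_BASES
    if a < b and IUPAC_BASES[a] & IUPAC_BASES[b]
]


@dataclass(frozen=True)
class SpecificityPolicy:
    """How specificity is judged.

    d_min: required minimum distance (>= 1); 1 encodes "at least one variation".
    metric: "hamming" (per-position, over all full-length placements) or
        "edit" (semi-global edit distance to the best infix).
    both_strands: also score against the reverse complement of each record.
    match_policy: "compatible" (default — an outgroup N could hide a match,
        so it counts as a match; conservative for specificity claims) or
        "strict".
    """

    d_min: int = 1
    metric: str = "hamming"
    both_strands: bool = True
    match_policy: str = "compatible"

    def __post_init__(self) -> None:
        if self.d_min < 1:
            raise ValueError("d_min must be >= 1")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        validate_policy(self.match_policy)


@dataclass(frozen=True)
class SpecificityScore:
    min_distance: float  # int-valued, or math.inf when no placement exists
    nearest_outgroup_id: Optional[str] = None
    nearest_offset: Optional[int] = None  # 0-based plus-strand offset
    nearest_strand: Optional[str] = None  # "+" or "-"
    d_min: int = field(default=1, compare=False)

    @property
    def specific(self) -> bool:
        return self.min_distance >= self.d_min


def _edit_distance(query: str, target: str, policy: str) -> tuple[int, int]:
    """(distance, best start offset) of query vs best infix of target."""
    extra = {"additionalEqualities": _IUPAC_EQUALITIES} if policy == "compatible" else {}
    res = edlib.align(query, target, mode="HW", task="locations", **extra)
    locs = res["locations"]
    start = locs[0][0] if locs and locs[0][0] is not None else 0
    return res["editDistance"], start


def min_outgroup_distance(
    window: str,
    outgroup: SequenceSet,
    policy: SpecificityPolicy | None = None,
) -> SpecificityScore:
    """Minimum distance of ``window`` to the outgroup over all placements.

    Ties are broken by set order, then smallest plus-strand offset, then
    ``+`` before ``-``. Records shorter than the window contribute +inf under
    the Hamming metric (no full-length placement). An empty outgroup yields
    +inf with a warning (vacuous specificity).
    """
    policy = policy or SpecificityPolicy()
    validate(window, context="window")
    if not window:
        raise ValueError("window must be non-empty")
    if len(outgroup) == 0:
        logger.warning("empty outgroup: window is vacuously specific")
        return SpecificityScore(math.inf, d_min=policy.d_min)

    strands = ["+", "-"] if policy.both_strands else ["+"]
    rc_window = reverse_complement(window) if policy.both_strands else None

    best: tuple[float, int, int, int] | None = None  # (dist, rec_idx, offset, strand_rank)
    best_rec_id: Optional[str] = None
    for rec_idx, rec in enumerate(outgroup):
        for strand_rank, strand in enumerate(strands):
            # minus strand == rc(window) against the plus strand, which keeps
            # offsets in plus-strand coordinates
            q = window if strand == "+" else rc_window
            if policy.metric == "hamming":
                prof = mismatch_profile(q, rec.residues, policy.match_policy)
                if prof.size == 0:
                    continue
                off = int(prof.argmin())
                dist = int(prof[off])
            else:
                if len(rec.residues) == 0:
                    continue
                dist, off = _edit_distance(q, rec.residues, policy.match_policy)
            key = (float(dist), rec_idx, off, strand_rank)
            if best is None or key < best:
                best = key
                best_rec_id = rec.id

    if best is None:
        return SpecificityScore(math.inf, d_min=policy.d_min)
    dist, _, off, strand_rank = best
    return SpecificityScore(
        min_distance=dist,
        nearest_outgroup_id=best_rec_id,
        nearest_offset=off,
        nearest_strand=strands[strand_rank],
        d_min=policy.d_min,
    )


def is_specific(
    window: str,
    outgroup: SequenceSet,
    policy: SpecificityPolicy | None = None,
) -> bool:
    """True iff the window's minimum outgroup distance is >= ``policy.d_min``."""
    policy = policy or SpecificityPolicy()
    return min_outgroup_distance(window, outgroup, policy).specific


def score_table(windows: list[str], outgroup: SequenceSet, policy: SpecificityPolicy | None = None) -> pd.DataFrame:
    """One score row per window (offsets 1-based in the report)."""
    policy = policy or SpecificityPolicy()
    rows = []
    for w in windows:
        s = min_outgroup_distance(w, outgroup, policy)
        rows.append(
            {
                "window": w,
                "length": len(w),
                "min_distance": s.min_distance,
                "nearest_outgroup_id": s.nearest_outgroup_id,
                "offset_1based": None if s.nearest_offset is None else s.nearest_offset + 1,
                "strand": s.nearest_strand,
                "specific": s.specific,
            }
        )
    return pd.DataFrame(rows)
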