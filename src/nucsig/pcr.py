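"""In-silico PCR and signature detection.

A mini-barcode workflow on degraded or mixed material amplifies a short
(~150 bp) product spanning the diagnostic window and then looks the window
up in the called sequence. This module predicts those products from a primer
pair and finds best placements of a signature in query sequences.

Coordinate conventions: all offsets are 0-based on the plus strand of the
template/query. A minus-strand primer or signature placement is computed by
sliding its reverse complement along the plus strand, so reported offsets
always refer to plus-strand positions. Product length includes both primers
(the standard convention for "product size").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .alphabet import mismatch_profile, reverse_complement, validate
from .io import SequenceRecord, SequenceSet

__all__ = [
    "PrimerPair",
    "AmpliconPrediction",
    "DetectionResult",
    "find_primer_sites",
    "amplify",
    "detect_signature",
    "detection_table",
    "amplicon_table",
]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3' in their own sense."""

    fwd: str
    rev: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.fwd or not self.rev:
            raise ValueError("both primers must be non-empty")
        validate(self.fwd, context="forward primer")
        validate(self.rev, context="reverse primer")


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted product: plus-strand half-open span, primers inclusive."""

    template_id: str
    start: int
    end: int
    residues: str
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DetectionResult:
    """Best placement of a signature in one query (or absence)."""

    query_id: str
    found: bool
    position: Optional[int] = None
    strand: Optional[str] = None
    mismatches: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.found and not (
            self.position is None and self.strand is None and self.mismatches is None
        ):
            raise ValueError("a negative detection carries no placement")


def find_primer_sites(
    template: SequenceRecord,
    primer: str,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
) -> list[tuple[int, str, int]]:
    """All (offset, strand, mismatches) placements of a primer on a template.

    A placement qualifies when its Hamming mismatch count is <= ``max_mismatch``
    AND its 3'-terminal ``three_prime_exact`` bases match exactly (extension
    starts at the 3' end, so mismatches there abort PCR). Degenerate primer
    bases match compatibly. Offsets are plus-strand positions of the
    placement's left edge; on the minus strand the primer's 3' end maps to
    that left edge. Sorted by offset, then ``+`` before ``-``.
    """
    validate(primer, context="primer")
    if len(primer) >= len(template.residues):
        raise ValueError("primer must be shorter than the template")
    k = len(primer)
    tpe = min(three_prime_exact, k)
    sites: list[tuple[int, str, int]] = []
    for strand in ("+", "-"):
        q = primer if strand == "+" else reverse_complement(primer)
        prof = mismatch_profile(q, template.residues, "compatible")
        if tpe > 0:
            # 3' end of the primer: rightmost bases on '+', leftmost on '-'
            tail = q[-tpe:] if strand == "+" else q[:tpe]
            tail_off = k - tpe if strand == "+" else 0
            tail_prof = mismatch_profile(tail, template.residues, "compatible")
        for off in range(prof.size):
            if prof[off] > max_mismatch:
                continue
            if tpe > 0 and tail_prof[off + tail_off] != 0:
                continue
            sites.append((off, strand, int(prof[off])))
    sites.sort(key=lambda s: (s[0], s[1] != "+"))
    return sites


def amplify(
    template: SequenceRecord,
    primers: PrimerPair,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    max_product_len: int = 500,
) -> list[AmpliconPrediction]:
    """Predict products: each (fwd on '+', rev on '-') pair with the forward
    5' end upstream of the reverse 5' end and product length <= ``max_product_len``.

    An empty list is an amplification failure (the in-silico negative control).
    """
    fwd_sites = [
        s for s in find_primer_sites(template, primers.fwd, max_mismatch, three_prime_exact)
        if s[1] == "+"
    ]
    rev_sites = [
        s for s in find_primer_sites(template, primers.rev, max_mismatch, three_prime_exact)
        if s[1] == "-"
    ]
    out: list[AmpliconPrediction] = []
    for f_off, _, f_mm in fwd_sites:
        for r_off, _, r_mm in rev_sites:
            end = r_off + len(primers.rev)  # rev 5' end is at end - 1
            if f_off > end - 1:
                continue
            length = end - f_off
            if length > max_product_len:
                continue
            out.append(
                AmpliconPrediction(
                    template_id=template.id,
                    start=f_off,
                    end=end,
                    residues=template.residues[f_off:end],
                    fwd_mismatches=f_mm,
                    rev_mismatches=r_mm,
                )
            )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def best_placement(
    query: str,
    signature: str,
    max_mismatch: int = 0,
    both_strands: bool = True,
    match_policy: str = "compatible",
) -> Optional[tuple[int, str, int]]:
    """Best (position, strand, mismatches) of ``signature`` in ``query``.

    Best = fewest mismatches, ties by smallest plus-strand offset, then
    ``+`` before ``-``. None when nothing is within ``max_mismatch`` or the
    query is shorter than the signature.
    """
    best: tuple[int, int, int] | None = None  # (mm, pos, strand_rank)
    strands = ("+", "-") if both_strands else ("+",)
    for rank, strand in enumerate(strands):
        q = signature if strand == "+" else reverse_complement(signature)
        prof = mismatch_profile(q, query, match_policy)
        for pos in range(prof.size):
            mm = int(prof[pos])
            if mm > max_mismatch:
                continue
            key = (mm, pos, rank)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mm, pos, rank = best
    return pos, strands[rank], mm


def detect_signature(
    queries: SequenceSet,
    signature: str,
    max_mismatch: int = 0,
    both_strands: bool = True,
    match_policy: str = "compatible",
) -> list[DetectionResult]:
    """Per query, the best placement of the signature (or a negative result).

    Detection defaults to exact retrieval (``max_mismatch=0``); ambiguity
    symbols in queries (Sanger consensus codes) match compatibly by default.
    """
    validate(signature, context="signature")
    if not signature:
        raise ValueError("signature must be non-empty")
    results = []
    for rec in queries:
        hit = best_placement(rec.residues, signature, max_mismatch, both_strands, match_policy)
        if hit is None:
            results.append(DetectionResult(query_id=rec.id, found=False))
        else:
            pos, strand, mm = hit
            results.append(
                DetectionResult(
                    query_id=rec.id, found=True, position=pos, strand=strand, mismatches=mm
                )
            )
    return results


def detection_table(results: list[DetectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "found": r.found,
                "position_1based": None if r.position is None else r.position + 1,
                "strand": r.strand,
                "mismatches": r.mismatches,
            }
            for r in results
        ],
        columns=["query_id", "found", "position_1based", "strand", "mismatches"],
    )


def amplicon_table(amplicons: list[AmpliconPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "template_id": a.template_id,
                "start_1based": a.start + 1,
                "end_1based": a.end,
                "length": a.length,
                "fwd_mismatches": a.fwd_mismatches,
                "rev_mismatches": a.rev_mismatches,
                "sequence": a.residues,
            }
            for a in amplicons
        ],
        columns=[
            "template_id",
            "start_1based",
            "end_1based",
            "length",
            "fwd_mismatches",
            "rev_mismatches",
            "sequence",
        ],
    )
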