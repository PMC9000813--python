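"""The length sweep: evaluate candidate windows and select a minimal signature.

A usable signature must satisfy two opposed criteria at once: full
conservation in the ingroup (which degrades as windows get longer) and
distance >= ``d_min`` from every outgroup placement (which degrades as
windows get shorter). The sweep evaluates sub-windows of the conserved
regions and selects the shortest one satisfying both; the audit trail keeps
every evaluation so the trade-off is inspectable, one row per candidate.

The search is global over all sub-windows, not just one nested family of
candidates: minimality is only well-defined against the full search space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .conservation import CandidateWindow, ConservedRegion, conservation_fraction
from .io import SequenceSet
from .specificity import SpecificityPolicy, min_outgroup_distance

__all__ = [
    "CandidateEvaluation",
    "SignatureResult",
    "evaluate_candidates",
    "sweep_lengths",
    "mine_signature",
    "audit_table",
]


@dataclass(frozen=True)
class CandidateEvaluation:
    """One evaluated window: the machine form of one sweep-report row."""

    window: CandidateWindow
    conservation_fraction: float
    conserved: bool
    min_distance: float
    specific: bool


@dataclass
class SignatureResult:
    """The selected minimal window plus the audit trail of the sweep."""

    signature: Optional[CandidateWindow]
    evaluations: list[CandidateEvaluation] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return self.signature is not None

    def to_dict(self) -> dict:
        return {
            "found": self.found,
            "signature": None
            if self.signature is None
            else {
                "residues": self.signature.residues,
                "length": self.signature.length,
                "source_id": self.signature.source_id,
                "start_1based": self.signature.start + 1,
                "end_1based": self.signature.end,
            },
            "parameters": self.parameters,
            "n_evaluations": len(self.evaluations),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_candidates(
    windows: Sequence[CandidateWindow],
    ingroup: SequenceSet,
    outgroup: SequenceSet,
    policy: SpecificityPolicy | None = None,
    threshold: float = 1.0,
    conservation_policy: str = "strict",
) -> list[CandidateEvaluation]:
    """Score each window for conservation and specificity, order preserved."""
    if not windows:
        raise ValueError("windows must be non-empty")
    policy = policy or SpecificityPolicy()
    out = []
    for w in windows:
        frac = conservation_fraction(w.residues, ingroup, conservation_policy)
        score = min_outgroup_distance(w.residues, outgroup, policy)
        out.append(
            CandidateEvaluation(
                window=w,
                conservation_fraction=frac,
                conserved=frac >= threshold,
                min_distance=score.min_distance,
                specific=score.specific,
            )
        )
    return out


def sweep_lengths(
    region: ConservedRegion,
    ingroup: SequenceSet,
    outgroup: SequenceSet,
    lengths: Sequence[int] | None = None,
    min_len: int | None = None,
    policy: SpecificityPolicy | None = None,
    threshold: float = 1.0,
    conservation_policy: str = "strict",
) -> list[CandidateEvaluation]:
    """Evaluate sub-windows of a conserved region, grouped by length descending.

    Explicit-lengths mode (``lengths``): every sub-window at each requested
    length. All-sub-windows mode (``min_len``): every sub-window of length
    ``min_len .. region.length``.
    """
    if (lengths is None) == (min_len is None):
        raise ValueError("pass exactly one of `lengths` or `min_len`")
    if lengths is not None:
        for L in lengths:
            if L > region.length:
                raise ValueError(
                    f"requested length {L} exceeds region length {region.length}"
                )
            if L < 1:
                raise ValueError("lengths must be >= 1")
        wanted = sorted(set(lengths), reverse=True)
    else:
        if min_len < 1:
            raise ValueError("min_len must be >= 1")
        wanted = list(range(region.length, min_len - 1, -1))
    windows = [
        region.subwindow(rel, L)
        for L in wanted
        for rel in range(region.length - L + 1)
    ]
    return evaluate_candidates(
        windows, ingroup, outgroup, policy, threshold, conservation_policy
    )


def mine_signature(
    ingroup: SequenceSet,
    outgroup: SequenceSet,
    policy: SpecificityPolicy | None = None,
    threshold: float = 1.0,
    min_len: int = 15,
    max_len: int = 55,
    conservation_policy: str = "strict",
) -> SignatureResult:
    """Mine the shortest ingroup-conserved, outgroup-specific window.

    Thin wrapper over :class:`nucsig.estimators.SignatureMiner` (the fitted
    estimator's ``result_``).
    """
    from .estimators import SignatureMiner

    policy = policy or SpecificityPolicy()
    miner = SignatureMiner(
        min_len=min_len,
        max_len=max_len,
        d_min=policy.d_min,
        threshold=threshold,
        metric=policy.metric,
        both_strands=policy.both_strands,
        conservation_policy=conservation_policy,
        specificity_policy=policy.match_policy,
    )
    miner.fit((ingroup, outgroup))
    return miner.result_


def audit_table(evaluations: Sequence[CandidateEvaluation]) -> pd.DataFrame:
    """Sweep-report table: one row per evaluated candidate."""
    return pd.DataFrame(
        [
            {
                "sequence": e.window.residues,
                "length": e.window.length,
                "source_id": e.window.source_id,
                "start_1based": e.window.start + 1,
                "conservation_fraction": e.conservation_fraction,
                "conserved": e.conserved,
                "min_distance": e.min_distance,
                "specific": e.specific,
            }
            for e in evaluations
        ],
        columns=[
            "sequence",
            "length",
            "source_id",
            "start_1based",
            "conservation_fraction",
            "conserved",
            "min_distance",
            "specific",
        ],
    )
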