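"""scikit-learn style estimators wrapping the mining and detection machinery.

``SignatureMiner`` is the core fit/predict surface of the toolkit: ``fit``
takes labeled ingroup/outgroup sequences and mines the shortest window that
is fully conserved in the ingroup and at least ``d_min`` variations away
from every outgroup placement; ``predict`` screens query sequences for the
mined signature. ``SignatureDetector`` screens for a known signature, and
``InSilicoPCR`` predicts primer-pair products. All three follow the sklearn
estimator contract (``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``clone``-compatible ``__init__``).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .conservation import find_conserved_regions
from .io import Group, SequenceRecord, SequenceSet
from .mining import CandidateEvaluation, SignatureResult
from .pcr import (
    AmpliconPrediction,
    DetectionResult,
    PrimerPair,
    amplify,
    detect_signature,
)
from .specificity import SpecificityPolicy, min_outgroup_distance
from .conservation import conservation_fraction

logger = logging.getLogger(__name__)

__all__ = ["SignatureMiner", "SignatureDetector", "InSilicoPCR"]

_INGROUP_LABELS = {"ingroup", "in", "target", 1, True}
_OUTGROUP_LABELS = {"outgroup", "out", "nontarget", 0, False}


def _as_set(X: Iterable, group: Group, prefix: str) -> SequenceSet:
    if isinstance(X, SequenceSet):
        if X.group == group:
            return X
        recs = [
            SequenceRecord(id=r.id, residues=r.residues, group=group, taxon=r.taxon)
            for r in X
        ]
        return SequenceSet(records=recs, group=group)
    records = []
    for i, item in enumerate(X):
        if isinstance(item, SequenceRecord):
            records.append(
                SequenceRecord(
                    id=item.id, residues=item.residues, group=group, taxon=item.taxon
                )
            )
        else:
            records.append(
                SequenceRecord(id=f"{prefix}{i + 1}", residues=str(item), group=group)
            )
    return SequenceSet(records=records, group=group)


def _resolve_groups(X, y) -> tuple[SequenceSet, SequenceSet]:
    """Accept either ``fit((ingroup_set, outgroup_set))`` or ``fit(X, y)``
    with per-sequence labels (``"ingroup"``/``"outgroup"`` or 1/0)."""
    if y is None:
        if isinstance(X, tuple) and len(X) == 2:
            return (
                _as_set(X[0], Group.INGROUP, "ing"),
                _as_set(X[1], Group.OUTGROUP, "out"),
            )
        raise ValueError(
            "pass y labels per sequence, or X=(ingroup_set, outgroup_set)"
        )
    X = list(X)
    y = list(y)
    if len(X) != len(y):
        raise ValueError(f"X and y length mismatch: {len(X)} vs {len(y)}")
    ing, out = [], []
    for item, label in zip(X, y):
        key = label.lower() if isinstance(label, str) else label
        if key in _INGROUP_LABELS:
            ing.append(item)
        elif key in _OUTGROUP_LABELS:
            out.append(item)
        else:
            raise ValueError(f"unrecognized group label {label!r}")
    return _as_set(ing, Group.INGROUP, "ing"), _as_set(out, Group.OUTGROUP, "out")


class SignatureMiner(BaseEstimator):
    """Mine a minimal taxon-diagnostic nucleotide signature.

    Parameters
    ----------
    min_len, max_len : int
        Length bounds of the search (defaults 15–55, the practical window
        of short diagnostic markers amplifiable from degraded DNA).
    d_min : int
        Required minimum outgroup distance; 1 = "at least one variation".
    threshold : float
        Required ingroup conservation fraction (default 1.0 — literally
        invariant; lower it only to tolerate database errors).
    metric : {"hamming", "edit"}
        Outgroup distance. Hamming-over-placements is the default and keeps
        specificity monotone in window length, so the per-anchor minimal
        length can be binary-searched; the edit metric falls back to a
        linear scan.
    both_strands : bool
        Score outgroup placements on both strands (database orientation is
        arbitrary).
    conservation_policy, specificity_policy : {"strict", "compatible"}
        IUPAC match semantics for the two criteria. Strict conservation (an
        N breaks invariance) and compatible specificity (an outgroup N could
        hide a match) are the conservative defaults.
    detect_max_mismatch : int
        Mismatch allowance used by :meth:`predict`.

    Attributes
    ----------
    signature_ : str or None
        Residues of the mined signature (None when nothing qualifies).
    result_ : SignatureResult
        Winner plus the full evaluation audit.
    regions_ : list of ConservedRegion
        The conserved regions the sweep searched.
    """

    def __init__(
        self,
        min_len: int = 15,
        max_len: int = 55,
        d_min: int = 1,
        threshold: float = 1.0,
        metric: str = "hamming",
        both_strands: bool = True,
        conservation_policy: str = "strict",
        specificity_policy: str = "compatible",
        detect_max_mismatch: int = 0,
    ):
        self.min_len = min_len
        self.max_len = max_len
        self.d_min = d_min
        self.threshold = threshold
        self.metric = metric
        self.both_strands = both_strands
        self.conservation_policy = conservation_policy
        self.specificity_policy = specificity_policy
        self.detect_max_mismatch = detect_max_mismatch

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None) -> "SignatureMiner":
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        ingroup, outgroup = _resolve_groups(X, y)
        if len(ingroup) == 0:
            raise ValueError("ingroup must be non-empty")
        if len(outgroup) == 0:
            logger.warning(
                "empty outgroup: specificity is vacuous; returning the "
                "shortest conserved window"
            )
        spec_policy = SpecificityPolicy(
            d_min=self.d_min,
            metric=self.metric,
            both_strands=self.both_strands,
            match_policy=self.specificity_policy,
        )

        regions = find_conserved_regions(
            ingroup,
            min_len=self.min_len,
            threshold=self.threshold,
            policy=self.conservation_policy,
        )

        audit: list[CandidateEvaluation] = []

        def probe(region, rel: int, L: int) -> bool:
            w = region.subwindow(rel, L)
            frac = conservation_fraction(
                w.residues, ingroup, self.conservation_policy
            )
            score = min_outgroup_distance(w.residues, outgroup, spec_policy)
            audit.append(
                CandidateEvaluation(
                    window=w,
                    conservation_fraction=frac,
                    conserved=frac >= self.threshold,
                    min_distance=score.min_distance,
                    specific=score.specific,
                )
            )
            return score.specific

        best: tuple[int, int, int] | None = None  # (length, region_idx, rel)
        best_window = None
        for region_idx, region in enumerate(regions):
            if best is not None and best[0] == self.min_len:
                break
            for rel in range(region.length - self.min_len + 1):
                hi = min(self.max_len, region.length - rel)
                if best is not None:
                    hi = min(hi, best[0])  # only strictly shorter can win later
                if hi < self.min_len:
                    continue
                if self.metric == "hamming":
                    # specificity is monotone non-decreasing in length:
                    # binary-search the smallest specific length at this anchor
                    if not probe(region, rel, hi):
                        continue
                    lo, hi_ = self.min_len, hi
                    while lo < hi_:
                        mid = (lo + hi_) // 2
                        if probe(region, rel, mid):
                            hi_ = mid
                        else:
                            lo = mid + 1
                    L_star = lo
                else:
                    L_star = None
                    for L in range(self.min_len, hi + 1):
                        if probe(region, rel, L):
                            L_star = L
                            break
                    if L_star is None:
                        continue
                key = (L_star, region_idx, rel)
                if best is None or key < best:
                    best = key
                    best_window = region.subwindow(rel, L_star)
                if best[0] == self.min_len:
                    break

        params = {
            "min_len": self.min_len,
            "max_len": self.max_len,
            "d_min": self.d_min,
            "threshold": self.threshold,
            "metric": self.metric,
            "both_strands": self.both_strands,
            "conservation_policy": self.conservation_policy,
            "specificity_policy": self.specificity_policy,
        }
        self.regions_ = regions
        self.result_ = SignatureResult(
            signature=best_window, evaluations=audit, parameters=params
        )
        self.signature_ = None if best_window is None else best_window.residues
        self.n_ingroup_ = len(ingroup)
        self.n_outgroup_ = len(outgroup)
        return self

    # -- detection --------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise NotFittedError(
                "this SignatureMiner instance is not fitted yet; call fit first"
            )

    def detect(self, X) -> list[DetectionResult]:
        """Full per-query detection records for the mined signature."""
        self._check_fitted()
        if self.signature_ is None:
            raise ValueError("no signature was mined; nothing to detect")
        queries = _as_set(X, Group.QUERY, "query")
        return detect_signature(
            queries,
            self.signature_,
            max_mismatch=self.detect_max_mismatch,
            both_strands=self.both_strands,
        )

    def predict(self, X) -> np.ndarray:
        """Boolean array: does each query contain the mined signature?"""
        return np.array([r.found for r in self.detect(X)], dtype=bool)


class SignatureDetector(BaseEstimator):
    """Screen query sequences for a known signature.

    ``fit`` only validates the signature (detection is stateless); ``predict``
    returns a boolean hit flag per query and :meth:`detect` the full records
    (position, strand, mismatches). Ambiguity codes in queries (Sanger
    consensus) match compatibly by default; mismatch allowance defaults to 0
    (exact retrieval).
    """

    def __init__(
        self,
        signature: Optional[str] = None,
        max_mismatch: int = 0,
        both_strands: bool = True,
        match_policy: str = "compatible",
    ):
        self.signature = signature
        self.max_mismatch = max_mismatch
        self.both_strands = both_strands
        self.match_policy = match_policy

    def fit(self, X=None, y=None) -> "SignatureDetector":
        if not self.signature:
            raise ValueError("signature must be a non-empty IUPAC string")
        from .alphabet import normalize

        self.signature_ = normalize(self.signature, context="signature")
        return self

    def detect(self, X) -> list[DetectionResult]:
        if not hasattr(self, "signature_"):
            raise NotFittedError("call fit before detect/predict")
        queries = _as_set(X, Group.QUERY, "query")
        return detect_signature(
            queries,
            self.signature_,
            max_mismatch=self.max_mismatch,
            both_strands=self.both_strands,
            match_policy=self.match_policy,
        )

    def predict(self, X) -> np.ndarray:
        return np.array([r.found for r in self.detect(X)], dtype=bool)


class InSilicoPCR(BaseEstimator):
    """Predict PCR products of a primer pair on template sequences.

    Placement requires <= ``max_mismatch`` Hamming mismatches with an exact
    3'-terminal ``three_prime_exact`` bases (extension starts there); paired
    sites facing each other within ``max_product_len`` yield a product whose
    length includes both primers.
    """

    def __init__(
        self,
        fwd: Optional[str] = None,
        rev: Optional[str] = None,
        name: str = "",
        max_mismatch: int = 2,
        three_prime_exact: int = 3,
        max_product_len: int = 500,
    ):
        self.fwd = fwd
        self.rev = rev
        self.name = name
        self.max_mismatch = max_mismatch
        self.three_prime_exact = three_prime_exact
        self.max_product_len = max_product_len

    def fit(self, X=None, y=None) -> "InSilicoPCR":
        self.primers_ = PrimerPair(fwd=self.fwd or "", rev=self.rev or "", name=self.name)
        return self

    def transform(self, X) -> list[list[AmpliconPrediction]]:
        """Per template, the list of predicted amplicons (may be empty)."""
        if not hasattr(self, "primers_"):
            raise NotFittedError("call fit before transform/predict")
        templates = _as_set(X, Group.QUERY, "template")
        return [
            amplify(
                rec,
                self.primers_,
                max_mismatch=self.max_mismatch,
                three_prime_exact=self.three_prime_exact,
                max_product_len=self.max_product_len,
            )
            for rec in templates
        ]

    def predict(self, X) -> np.ndarray:
        """Number of predicted products per template."""
        return np.array([len(a) for a in self.transform(X)], dtype=int)
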