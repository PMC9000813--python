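"""IUPAC nucleotide alphabet: normalization, complementation, and match semantics.

Two match policies run through the whole toolkit:

``strict``
    A symbol matches only itself. This is the mining-side default: a
    diagnostic window must be *literally* invariant in the ingroup, so an
    ``N`` in a database record breaks conservation.

``compatible``
    Two symbols match when their base sets intersect (``R`` matches ``A``,
    ``G``, ``R``, ``D`` ...). This is the specificity- and detection-side
    default: an ambiguity code in an outgroup or Sanger-consensus record
    could hide a real match, so it is counted as one.
"""

from __future__ import annotations

import numpy as np

#: Base sets of the 15 IUPAC nucleotide symbols (DNA, T not U).
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

ALPHABET = frozenset(IUPAC_BASES)

MATCH_POLICIES = ("strict", "compatible")

_GAP_CHARS = "-."
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: 4-bit base mask per symbol; two symbols are compatible iff masks intersect.
MASKS: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_BASES.items()
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# ord -> bitmask (0 for invalid symbols) and ord -> validity, for numpy paths
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _m in MASKS.items():
    _MASK_LUT[ord(_sym)] = _m


class AlphabetError(ValueError):
    """A residue string contains a symbol outside the IUPAC nucleotide alphabet."""


def validate_policy(policy: str) -> str:
    if policy not in MATCH_POLICIES:
        raise ValueError(f"unknown match policy {policy!r}; expected one of {MATCH_POLICIES}")
    return policy


def normalize(residues: str, *, context: str = "") -> str:
    """Normalize a raw residue string: uppercase, U->T, strip gap characters.

    Raises :class:`AlphabetError` naming the first offending symbol (and
    ``context``, typically a record id) if a non-IUPAC symbol remains.
    """
    s = residues.upper().replace("U", "T")
    for g in _GAP_CHARS:
        s = s.replace(g, "")
    bad = set(s) - ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(
            f"non-IUPAC nucleotide symbol {sorted(bad)[0]!r}{where}"
        )
    return s


def validate(residues: str, *, context: str = "") -> str:
    """Check that ``residues`` is already normalized IUPAC; return it unchanged."""
    bad = set(residues) - ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(f"non-IUPAC nucleotide symbol {sorted(bad)[0]!r}{where}")
    return residues


def reverse_complement(residues: str) -> str:
    """Standard IUPAC reverse complement (A<->T, C<->G, R<->Y, B<->V, ...)."""
    validate(residues)
    return residues.translate(_COMPLEMENT)[::-1]


def encode_masks(residues: str) -> np.ndarray:
    """Encode residues as 4-bit base masks (uint8); assumes valid input."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _MASK_LUT[arr]


def encode_ords(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def symbols_match(a: str, b: str, policy: str = "strict") -> bool:
    """Whether two single IUPAC symbols match under ``policy``."""
    if policy == "strict":
        return a == b
    validate_policy(policy)
    return bool(MASKS[a] & MASKS[b])


def mismatch_profile(window: str, target: str, policy: str = "strict") -> np.ndarray:
    """Per-offset Hamming mismatch counts of ``window`` against ``target``.

    Returns an int array of length ``len(target) - len(window) + 1`` (empty if
    the target is shorter than the window). Under ``compatible`` a position
    mismatches only when the two base sets are disjoint.
    """
    validate_policy(policy)
    k, m = len(window), len(target)
    if k == 0:
        raise ValueError("window must be non-empty")
    if m < k:
        return np.zeros(0, dtype=np.intp)
    if policy == "strict":
        w = encode_ords(window)
        t = encode_ords(target)
        views = np.lib.stride_tricks.sliding_window_view(t, k)
        return np.count_nonzero(views != w, axis=1)
    w = encode_masks(window)
    t = encode_masks(target)
    views = np.lib.stride_tricks.sliding_window_view(t, k)
    return np.count_nonzero((views & w) == 0, axis=1)


def contains(window: str, target: str, policy: str = "strict") -> bool:
    """Whether ``window`` occurs as a forward-strand substring of ``target``."""
    if policy == "strict":
        return window in target
    prof = mismatch_profile(window, target, policy)
    return bool(prof.size) and bool((prof == 0).any())
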