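"""Brute-force oracles: exhaustive enumeration, independent of the library's
search strategies. Kept deliberately naive."""

from __future__ import annotations

import math

from nucsig.alphabet import reverse_complement

__all__ = [
    "brute_conserved_windows",
    "brute_maximal_conserved",
    "brute_min_distance",
    "brute_min_signature_length",
]


def _fraction(window: str, seqs: list[str]) -> float:
    return sum(1 for s in seqs if window in s) / len(seqs)


def brute_conserved_windows(seqs: list[str], min_len: int, threshold: float) -> set[str]:
    """Every distinct substring of any sequence conserved at the threshold."""
    out = set()
    for s in seqs:
        for i in range(len(s)):
            for j in range(i + min_len, len(s) + 1):
                w = s[i:j]
                if _fraction(w, seqs) >= threshold:
                    out.add(w)
    return out


def brute_maximal_conserved(seqs: list[str], min_len: int, threshold: float) -> set[str]:
    """Conserved windows that are not substrings of a longer conserved window."""
    conserved = brute_conserved_windows(seqs, min_len, threshold)
    return {
        w
        for w in conserved
        if not any(w != v and w in v for v in conserved)
    }


def brute_min_distance(window: str, outseqs: list[str], both_strands: bool = True) -> float:
    """Min Hamming mismatches over all full-length placements, either strand."""
    k = len(window)
    best = math.inf
    queries = [window]
    if both_strands:
        queries.append(reverse_complement(window))
    for s in outseqs:
        for q in queries:
            for off in range(len(s) - k + 1):
                d = sum(1 for a, b in zip(q, s[off : off + k]) if a != b)
                best = min(best, d)
    return best


def brute_min_signature_length(
    inseqs: list[str],
    outseqs: list[str],
    min_len: int,
    max_len: int,
    d_min: int = 1,
    threshold: float = 1.0,
) -> int | None:
    """Smallest length with some window both conserved and specific, by
    exhaustive scan of every substring of every ingroup sequence."""
    for L in range(min_len, max_len + 1):
        for s in inseqs:
            for i in range(len(s) - L + 1):
                w = s[i : i + L]
                if _fraction(w, inseqs) >= threshold and (
                    brute_min_distance(w, outseqs) >= d_min
                ):
                    return L
    return None
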