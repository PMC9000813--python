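"""Seeded generators of ingroup/outgroup/query sets with planted ground truth.

These stand in for downloaded reference data so every stage of the pipeline
is testable offline. The key construction is the *period-p* outgroup: its
records contain every core sub-window of length p-1 exactly, but no core
sub-window of length p on either strand. Against an ingroup that shares the
core exactly, the shortest conserved-and-specific window therefore has
length exactly p — the planted analogue of the conserved-vs-specific
trade-off that fixes a real signature's length. All truth claims are
re-verified by independent scanning after generation, not trusted from
construction; generation is retried (seeded) until verification passes.

Generated residues are plain ``{A,C,G,T}``: ambiguity symbols are a property
of real database/consensus records, not of the simulated ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import reverse_complement, validate
from .io import Group, SequenceRecord, SequenceSet

__all__ = [
    "SyntheticTruth",
    "GenerationError",
    "generate_ingroup",
    "generate_outgroup",
    "generate_mixture_queries",
    "demo_scenario",
]

_BASES = "ACGT"
_MIN_PERIOD = 4  # below this, decoy collisions make the planted minimum unreliable


class GenerationError(RuntimeError):
    """Generation could not satisfy (or verify) the planted ground truth."""


@dataclass
class SyntheticTruth:
    """What was planted, for downstream assertions."""

    planted_core: str
    planted_signature: str
    seed: int
    outgroup_substitution_period: Optional[int] = None
    #: record id -> [(0-based position on the record, from-base, to-base)]
    mutation_log: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_core": self.planted_core,
            "planted_signature": self.planted_signature,
            "seed": self.seed,
            "outgroup_substitution_period": self.outgroup_substitution_period,
            "mutation_log": {
                k: [list(t) for t in v] for k, v in self.mutation_log.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(0, 3)]


# --------------------------------------------------------------------------
# ingroup
# --------------------------------------------------------------------------

def generate_ingroup(
    n: int,
    core: str,
    flank_len: int = 60,
    flank_mut_rate: float = 0.1,
    seed: int = 0,
    signature: Optional[str] = None,
    id_prefix: str = "ing",
) -> tuple[SequenceSet, SyntheticTruth]:
    """Records = mutated-left-flank + exact core + mutated-right-flank.

    Flanks are per-record mutated copies (per-site rate ``flank_mut_rate``)
    of one shared ancestor flank; the core is never touched, so its
    conservation fraction is 1.0 by construction (and re-checked).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= flank_mut_rate <= 1:
        raise ValueError("flank_mut_rate must be in [0, 1]")
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    validate(core, context="core")
    if not core:
        raise ValueError("core must be non-empty")
    signature = signature if signature is not None else core
    if signature not in core:
        raise ValueError("signature must be a sub-window of the core")

    rng = np.random.default_rng(seed)
    left_anc = _rand_seq(rng, flank_len)
    right_anc = _rand_seq(rng, flank_len)
    records = []
    mutation_log: dict[str, list[tuple[int, str, str]]] = {}

    def mutate(anc: str, offset: int, log: list) -> str:
        out = list(anc)
        for pos in range(len(anc)):
            if rng.random() < flank_mut_rate:
                new = _other_base(rng, out[pos])
                log.append((offset + pos, out[pos], new))
                out[pos] = new
        return "".join(out)

    for i in range(n):
        rec_id = f"{id_prefix}{i + 1:03d}"
        log: list[tuple[int, str, str]] = []
        left = mutate(left_anc, 0, log)
        right = mutate(right_anc, flank_len + len(core), log)
        records.append(
            SequenceRecord(
                id=rec_id,
                residues=left + core + right,
                group=Group.INGROUP,
                taxon="synthetic ingroup",
            )
        )
        mutation_log[rec_id] = log

    seq_set = SequenceSet(records=records, group=Group.INGROUP)
    for rec in seq_set:  # independent re-check of the planted invariant
        if core not in rec.residues:
            raise GenerationError(f"core missing from generated record {rec.id}")
    truth = SyntheticTruth(
        planted_core=core,
        planted_signature=signature,
        seed=seed,
        mutation_log=mutation_log,
    )
    return seq_set, truth


# --------------------------------------------------------------------------
# outgroup
# --------------------------------------------------------------------------

def _guarded_extend(
    chars: list[str], rng: np.random.Generator, n: int, forbidden: set[str], p: int
) -> None:
    """Append n random bases, avoiding suffix p-windows in ``forbidden``.

    Best effort: when every base completes a forbidden window (possible for
    small p), one is appended anyway — the caller's final brute-force
    verification is authoritative."""
    for _ in range(n):
        order = rng.permutation(4)
        for idx in order:
            chars.append(_BASES[idx])
            if len(chars) < p or "".join(chars[-p:]) not in forbidden:
                break
            chars.pop()
        else:
            chars.append(_BASES[order[0]])


def _junction_ok(chars: list[str], block_start: int, forbidden: set[str], p: int) -> bool:
    """Check p-windows spanning the junction at ``block_start``."""
    lo = max(0, block_start - p + 1)
    hi = min(len(chars) - p, block_start - 1)
    s = "".join(chars[lo : hi + p]) if hi >= lo else ""
    return all(s[i : i + p] not in forbidden for i in range(hi - lo + 1)) if s else True


def _append_block(
    chars: list[str],
    rng: np.random.Generator,
    gap_len: int,
    block: list[str] | str,
    forbidden: set[str],
    p: int,
    tries: int = 100,
) -> None:
    """Append gap_len guarded random bases then a fixed block; re-draw the
    gap locally until no p-window spans the junction into ``forbidden``
    (best effort — the last draw is kept when every retry fails)."""
    for attempt in range(tries):
        mark = len(chars)
        _guarded_extend(chars, rng, gap_len, forbidden, p)
        block_start = len(chars)
        chars.extend(block)
        if _junction_ok(chars, block_start, forbidden, p) or attempt == tries - 1:
            return
        del chars[mark:]


def generate_outgroup(
    core: str,
    period: int,
    n_decoys: int = 3,
    seed: int = 0,
    decoy_len: int = 200,
    flank_len: int = 40,
    spacer_len: int = 8,
    id_prefix: str = "out",
) -> SequenceSet:
    """An outgroup whose closest approach to the core has period ``period``.

    The first record carries (i) a copy of the core substituted at 1-based
    core positions p, 2p, ... (substituted base != original), so its longest
    exact shared run with the core is p-1, and (ii) every core sub-window of
    length p-1, spacer-separated. Junctions, spacers, flanks and the
    ``n_decoys`` unrelated records are rejection-sampled away from core
    p-windows. Verified by brute force before returning: every core window
    shorter than p occurs exactly in the outgroup (hence is not specific),
    and at least one core p-window is absent from both strands of every
    record (hence is specific) — so against a core-sharing ingroup the
    minimal conserved-and-specific window length is exactly p. For small p
    chance collisions can make a few individual p-windows non-specific; the
    planted minimum is unaffected.
    """
    validate(core, context="core")
    if set(core) - set(_BASES):
        raise ValueError("core must be over plain {A,C,G,T}")
    if period < _MIN_PERIOD:
        raise ValueError(
            f"period must be >= {_MIN_PERIOD} (shorter planted minima are "
            "unreliable against random decoys)"
        )
    if period > len(core):
        raise ValueError("period must be <= the core length")
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")

    p = period
    forbidden = {core[i : i + p] for i in range(len(core) - p + 1)}
    forbidden |= {reverse_complement(w) for w in set(forbidden)}
    short_windows = [core[i : i + p - 1] for i in range(len(core) - p + 2)]

    rng = np.random.default_rng(seed)
    last_err = None
    for _attempt in range(200):
        try:
            # the periodically substituted core copy; substitution bases are
            # chosen per site to avoid recreating a core p-window where one
            # of the 3 alternatives allows it (sites are >= p apart, so the
            # choices are independent)
            sub = list(core)
            for pos in range(p - 1, len(core), p):
                alts = [b for b in _BASES if b != sub[pos]]
                rng.shuffle(alts)
                for alt in alts:
                    sub[pos] = alt
                    lo = max(0, pos - p + 1)
                    hi = min(len(sub) - p, pos)
                    if all(
                        "".join(sub[i : i + p]) not in forbidden
                        for i in range(lo, hi + 1)
                    ):
                        break

            chars: list[str] = []
            _append_block(chars, rng, flank_len, sub, forbidden, p)
            # every (p-1)-length core sub-window, spacer-guarded
            for w in short_windows:
                _append_block(chars, rng, spacer_len, w, forbidden, p)
            _guarded_extend(chars, rng, flank_len, forbidden, p)
            main = "".join(chars)

            decoys = []
            for _ in range(n_decoys):
                d: list[str] = []
                _guarded_extend(d, rng, decoy_len, forbidden, p)
                decoys.append("".join(d))

            records = [
                SequenceRecord(
                    id=f"{id_prefix}{i + 1:03d}",
                    residues=s,
                    group=Group.OUTGROUP,
                    taxon="synthetic outgroup",
                )
                for i, s in enumerate([main] + decoys)
            ]
            seq_set = SequenceSet(records=records, group=Group.OUTGROUP)

            # independent verification of the planted minimum: every core
            # (p-1)-window present, at least one core p-window absent from
            # both strands of every record
            p_windows = {core[i : i + p] for i in range(len(core) - p + 1)}
            present: set[str] = set()
            for rec in seq_set:
                for s in (rec.residues, reverse_complement(rec.residues)):
                    for i in range(len(s) - p + 1):
                        w = s[i : i + p]
                        if w in p_windows:
                            present.add(w)
            if present >= p_windows:
                raise GenerationError("no specific core p-window remains")
            for w in short_windows:
                if not any(w in rec.residues for rec in seq_set):
                    raise GenerationError("short core window missing")
            return seq_set
        except GenerationError as err:  # re-draw everything from the stream
            last_err = err
            continue
    raise GenerationError(
        f"could not construct a period-{p} outgroup for this core: {last_err}"
    )


# --------------------------------------------------------------------------
# mixture queries
# --------------------------------------------------------------------------

def generate_mixture_queries(
    n_batches: int,
    signature_fragment: str,
    n_nontarget_fragments: int = 5,
    fragment_len_range: tuple[int, int] = (120, 180),
    degrade: float = 0.0,
    seed: int = 0,
    plant: bool = True,
    id_prefix: str = "batch",
) -> SequenceSet:
    """Per batch, one query = shuffled concatenation of DNA fragments.

    Exactly one fragment embeds ``signature_fragment`` (none when
    ``plant=False`` — the negative control); the others are unrelated random
    fragments. ``degrade`` in [0, 1] truncates fragment ends by up to that
    fraction of their length (emulating DNA degradation); the embedded
    signature itself is never truncated. Each batch is re-checked to contain
    the signature exactly ``plant`` times on the plus strand and never on
    the minus strand.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if n_nontarget_fragments < 0:
        raise ValueError("n_nontarget_fragments must be >= 0")
    lo, hi = fragment_len_range
    if not (50 <= lo <= hi <= 500):
        raise ValueError("fragment_len_range must lie within [50, 500]")
    if not 0 <= degrade <= 1:
        raise ValueError("degrade must be in [0, 1]")
    validate(signature_fragment, context="signature_fragment")
    sig = signature_fragment
    if len(sig) + 4 > lo:
        raise ValueError("fragment_len_range too short to embed the signature")

    rng = np.random.default_rng(seed)
    rc_sig = reverse_complement(sig)
    records = []
    for b in range(n_batches):
        for _attempt in range(100):
            fragments: list[str] = []
            for _ in range(n_nontarget_fragments):
                L = int(rng.integers(lo, hi + 1))
                frag = _rand_seq(rng, L)
                while sig in frag or rc_sig in frag:
                    frag = _rand_seq(rng, L)
                trunc = int(round(L * degrade * rng.random()))
                cut_left = int(rng.integers(0, trunc + 1))
                frag = frag[cut_left : L - (trunc - cut_left)]
                fragments.append(frag)
            if plant:
                L = int(rng.integers(lo, hi + 1))
                sig_at = int(rng.integers(2, L - len(sig) - 1))
                frag = (
                    _rand_seq(rng, sig_at)
                    + sig
                    + _rand_seq(rng, L - sig_at - len(sig))
                )
                trunc = int(round(L * degrade * rng.random()))
                max_left = sig_at
                max_right = L - sig_at - len(sig)
                trunc = min(trunc, max_left + max_right)
                cut_left = min(int(rng.integers(0, trunc + 1)), max_left)
                cut_right = min(trunc - cut_left, max_right)
                frag = frag[cut_left : L - cut_right]
                fragments.append(frag)
            order = rng.permutation(len(fragments)) if fragments else []
            query = "".join(fragments[i] for i in order)
            want = 1 if plant else 0
            if query and query.count(sig) == want and rc_sig not in query:
                break
        else:
            raise GenerationError(f"could not assemble batch {b + 1}")
        records.append(
            SequenceRecord(
                id=f"{id_prefix}{b + 1:02d}",
                residues=query,
                group=Group.QUERY,
                taxon="synthetic mixture",
            )
        )
    return SequenceSet(records=records, group=Group.QUERY)


# --------------------------------------------------------------------------
# packaged demonstration scenario
# --------------------------------------------------------------------------

def demo_scenario(
    seed: int = 0,
    n_ingroup: int = 12,
    period: int = 23,
    flank_len: int = 60,
    flank_mut_rate: float = 0.3,
) -> tuple[SequenceSet, SequenceSet, SyntheticTruth]:
    """The packaged worked example around the 55-bp conserved ITS2 fragment.

    The ingroup of ``n_ingroup`` records shares the 55-bp fragment as its
    planted core, except that one record carries a single substitution at
    core position 19 (0-based). That substitution splits the conserved block
    exactly the way the real data did: the five longest ladder candidates
    lose full conservation while the 23-mer signature and the 20-mer inside
    it remain invariant. Against the period-``period`` outgroup the mined
    minimal signature is then precisely the packaged 23-mer.

    One flank base adjacent to each side of the core is also broken in the
    variant record so that conserved blocks cannot leak into the shared
    ancestor flanks. The construction is verified (conserved regions are
    exactly the two expected core blocks) and re-seeded on the rare failure.
    """
    from .conservation import find_conserved_regions
    from .fixtures import CANDIDATE_LADDER, SIGNATURE

    core = CANDIDATE_LADDER[0].residues  # the 55-bp fragment
    var_pos = 19
    var_base = "T" if core[var_pos] != "T" else "A"
    variant_core = core[:var_pos] + var_base + core[var_pos + 1 :]
    expected_regions = {core[:var_pos], core[var_pos + 1 :]}

    for attempt in range(10):
        s = seed + 10_000 * attempt
        main_set, truth = generate_ingroup(
            n_ingroup - 1,
            core,
            flank_len=flank_len,
            flank_mut_rate=flank_mut_rate,
            seed=s,
            signature=SIGNATURE,
            id_prefix="ing",
        )
        var_set, _ = generate_ingroup(
            1,
            variant_core,
            flank_len=flank_len,
            flank_mut_rate=flank_mut_rate,
            seed=s + 1,
            id_prefix="ingv",
        )
        var_rec = var_set[0]
        residues = var_rec.residues
        if flank_len > 0:
            rng = np.random.default_rng(s + 2)
            left_pos = flank_len - 1
            right_pos = flank_len + len(core)
            residues = (
                residues[:left_pos]
                + _other_base(rng, residues[left_pos])
                + residues[left_pos + 1 : right_pos]
                + _other_base(rng, residues[right_pos])
                + residues[right_pos + 1 :]
            )
        var_rec = SequenceRecord(
            id=var_rec.id, residues=residues, group=Group.INGROUP, taxon=var_rec.taxon
        )
        ingroup = SequenceSet(
            records=list(main_set.records) + [var_rec], group=Group.INGROUP
        )
        regions = find_conserved_regions(ingroup, min_len=min(15, var_pos))
        if {r.residues for r in regions} != expected_regions:
            continue
        outgroup = generate_outgroup(core, period=period, n_decoys=3, seed=s + 3)
        truth.outgroup_substitution_period = period
        truth.mutation_log[var_rec.id] = [
            (flank_len + var_pos, core[var_pos], var_base)
        ]
        return ingroup, outgroup, truth
    raise GenerationError("could not assemble the demonstration scenario")
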