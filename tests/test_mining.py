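"""Length sweep and minimal-signature selection."""

import numpy as np
import pytest
from conftest import random_seq
from oracles import brute_min_signature_length

from nucsig.conservation import CandidateWindow, ConservedRegion
from nucsig.fixtures import CANDIDATE_LADDER, SIGNATURE, ladder_windows
from nucsig.io import Group, SequenceSet
from nucsig.mining import (
    audit_table,
    evaluate_candidates,
    mine_signature,
    sweep_lengths,
)
from nucsig.synth import generate_ingroup, generate_outgroup


def seqset(seqs, group):
    return SequenceSet.from_sequences(seqs, Group(group))


def test_ladder_against_demo_scenario_reproduces_verdicts(demo):
    """The packaged scenario reproduces the ladder's verdict pattern: only
    the 23-mer passes both criteria."""
    ingroup, outgroup, _ = demo
    evals = evaluate_candidates(ladder_windows(), ingroup, outgroup)
    flags = [(e.conserved, e.specific) for e in evals]
    assert flags == [
        (False, True),
        (False, True),
        (False, True),
        (False, True),
        (False, True),
        (True, True),
        (False, True),
    ][:5] + [(True, True), (True, False)]
    dual = [e for e in evals if e.conserved and e.specific]
    assert len(dual) == 1 and dual[0].window.residues == SIGNATURE


def test_trivial_window_conserved_but_not_specific():
    ing = seqset(["ACGT"], "ingroup")
    out = seqset(["TGCA"], "outgroup")
    (e,) = evaluate_candidates([CandidateWindow(residues="A")], ing, out)
    assert e.conserved and not e.specific and e.min_distance == 0


def test_window_absent_from_one_ingroup_record_is_not_conserved():
    ing = seqset(["AAAACGTTT", "GGGGGGGG"], "ingroup")
    out = seqset(["TTTTTTTT"], "outgroup")
    (e,) = evaluate_candidates([CandidateWindow(residues="ACGT")], ing, out)
    assert not e.conserved and e.conservation_fraction == 0.5


def region_s1():
    return ConservedRegion(residues=CANDIDATE_LADDER[0].residues, source_id="S1", start=0)


def test_sweep_explicit_length_counts():
    ing = seqset([CANDIDATE_LADDER[0].residues], "ingroup")
    out = seqset([random_seq(np.random.default_rng(0), 60)], "outgroup")
    assert len(sweep_lengths(region_s1(), ing, out, lengths=[55])) == 1
    assert len(sweep_lengths(region_s1(), ing, out, lengths=[23])) == 33
    evals = sweep_lengths(region_s1(), ing, out, min_len=20)
    assert len(evals) == 666  # sum over L=20..55 of (56 - L)
    lengths = [e.window.length for e in evals]
    assert lengths == sorted(lengths, reverse=True)


def test_sweep_rejects_overlong_request():
    ing = seqset(["ACGTACGT"], "ingroup")
    out = seqset(["TTTT"], "outgroup")
    region = ConservedRegion(residues="ACGTAC", source_id="s", start=0)
    with pytest.raises(ValueError):
        sweep_lengths(region, ing, out, lengths=[7])
    with pytest.raises(ValueError):
        sweep_lengths(region, ing, out)  # neither mode selected


def test_mined_length_equals_planted_period():
    core = CANDIDATE_LADDER[0].residues
    ing, _ = generate_ingroup(6, core, flank_len=0, seed=5)
    out = generate_outgroup(core, period=23, seed=5)
    res = mine_signature(ing, out, min_len=15, max_len=55)
    assert res.found and res.signature.length == 23


def test_random_outgroup_gives_min_len_signature(rng):
    """With an unrelated outgroup every conserved window is specific."""
    core = random_seq(rng, 50)
    ing, _ = generate_ingroup(4, core, flank_len=0, seed=11)
    for _ in range(20):
        out_seqs = [random_seq(rng, 80) for _ in range(3)]
        from oracles import brute_min_distance

        if brute_min_distance(core[:15], out_seqs) >= 1:
            break
    out = seqset(out_seqs, "outgroup")
    res = mine_signature(ing, out, min_len=15, max_len=50)
    oracle = brute_min_signature_length([core] * 4, out_seqs, 15, 50)
    assert res.found and res.signature.length == oracle


def test_no_common_substring_yields_empty_result():
    ing = seqset(["AAAAAAAAAA", "CCCCCCCCCC"], "ingroup")
    out = seqset(["GGGG"], "outgroup")
    res = mine_signature(ing, out, min_len=4, max_len=10)
    assert not res.found and res.signature is None


def test_empty_outgroup_returns_shortest_conserved_window(caplog):
    ing = seqset(["TTACGTACGTTT", "AACGTACGTA"], "ingroup")
    with caplog.at_level("WARNING"):
        res = mine_signature(ing, SequenceSet(group=Group.OUTGROUP), min_len=4, max_len=10)
    assert res.found and res.signature.length == 4
    assert "vacuous" in caplog.text or "empty outgroup" in caplog.text


def test_empty_ingroup_is_an_error():
    with pytest.raises(ValueError):
        mine_signature(SequenceSet(group=Group.INGROUP), seqset(["ACGT"], "outgroup"))


def test_selection_optimality_vs_oracle(rng):
    """Winner length equals the exhaustive-search minimum on random instances."""
    agreements = 0
    for trial in range(60):
        n_in = int(rng.integers(2, 5))
        base = random_seq(rng, int(rng.integers(20, 40)))
        # ingroup: shared base with independent flanks so a common block exists
        inseqs = [
            random_seq(rng, int(rng.integers(0, 8))) + base + random_seq(rng, int(rng.integers(0, 8)))
            for _ in range(n_in)
        ]
        outseqs = [random_seq(rng, int(rng.integers(10, 60))) for _ in range(int(rng.integers(1, 4)))]
        ing, out = seqset(inseqs, "ingroup"), seqset(outseqs, "outgroup")
        res = mine_signature(ing, out, min_len=3, max_len=40)
        oracle = brute_min_signature_length(inseqs, outseqs, 3, 40)
        if oracle is None:
            assert not res.found
        else:
            assert res.found and res.signature.length == oracle, f"trial {trial}"
            # the winner itself satisfies both criteria
            win = res.signature.residues
            assert all(win in s for s in inseqs)
            from oracles import brute_min_distance

            assert brute_min_distance(win, outseqs) >= 1
            agreements += 1
    assert agreements > 10


def test_audit_consistency(demo):
    """Every audited window shorter than the winner fails a criterion."""
    ingroup, outgroup, _ = demo
    res = mine_signature(ingroup, outgroup)
    assert res.found
    for e in res.evaluations:
        if e.window.length < res.signature.length:
            assert not (e.conserved and e.specific)
    tab = audit_table(res.evaluations)
    assert set(tab.columns) >= {"sequence", "length", "conserved", "specific"}
    assert len(tab) == len(res.evaluations)


def test_ladder_nesting_fixture():
    s1 = CANDIDATE_LADDER[0].residues
    assert [e.length for e in CANDIDATE_LADDER] == [55, 45, 35, 30, 27, 23, 20]
    assert all(e.residues in s1 for e in CANDIDATE_LADDER[1:])
    assert CANDIDATE_LADDER[6].residues in CANDIDATE_LADDER[5].residues
    assert all(w.residues == s1[w.start : w.end] for w in ladder_windows())


def test_result_json_round_trip(demo):
    import json

    ingroup, outgroup, _ = demo
    res = mine_signature(ingroup, outgroup)
    d = json.loads(res.to_json())
    assert d["found"] and d["signature"]["length"] == 23
    assert d["signature"]["residues"] == SIGNATURE
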