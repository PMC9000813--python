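"""Synthetic-data generators: determinism and planted-truth verification."""

import numpy as np
import pytest
from conftest import random_seq

from nucsig.alphabet import reverse_complement
from nucsig.conservation import conservation_fraction
from nucsig.fixtures import CANDIDATE_LADDER, SIGNATURE
from nucsig.mining import mine_signature
from nucsig.pcr import detect_signature
from nucsig.synth import (
    demo_scenario,
    generate_ingroup,
    generate_mixture_queries,
    generate_outgroup,
)

CORE = CANDIDATE_LADDER[0].residues


def test_single_record_no_flanks_equals_core():
    s, truth = generate_ingroup(1, CORE, flank_len=0, seed=0)
    assert len(s) == 1 and s[0].residues == CORE
    assert truth.planted_core == CORE


def test_core_always_fully_conserved():
    s, _ = generate_ingroup(20, CORE, flank_len=50, flank_mut_rate=0.4, seed=2)
    assert conservation_fraction(CORE, s) == 1.0


def test_ingroup_determinism():
    a, ta = generate_ingroup(5, CORE, flank_len=30, flank_mut_rate=0.2, seed=9)
    b, tb = generate_ingroup(5, CORE, flank_len=30, flank_mut_rate=0.2, seed=9)
    assert a.sequences() == b.sequences()
    assert ta.mutation_log == tb.mutation_log
    c, _ = generate_ingroup(5, CORE, flank_len=30, flank_mut_rate=0.2, seed=10)
    assert a.sequences() != c.sequences()


def test_mutation_log_matches_records():
    s, truth = generate_ingroup(6, CORE, flank_len=40, flank_mut_rate=0.3, seed=4)
    anc, _ = generate_ingroup(1, CORE, flank_len=40, flank_mut_rate=0.0, seed=4)
    for rec in s:
        log = truth.mutation_log[rec.id]
        for pos, old, new in log:
            assert rec.residues[pos] == new
            assert old != new


def test_ingroup_parameter_validation():
    with pytest.raises(ValueError):
        generate_ingroup(0, CORE)
    with pytest.raises(ValueError):
        generate_ingroup(2, CORE, flank_mut_rate=1.5)
    with pytest.raises(ValueError):
        generate_ingroup(2, CORE, signature="NOTINCORE")


def test_outgroup_period_guard():
    with pytest.raises(ValueError):
        generate_outgroup(CORE, period=3)
    with pytest.raises(ValueError):
        generate_outgroup(CORE, period=len(CORE) + 1)


def test_outgroup_planted_period_scanned_independently():
    """Re-verify the planted trade-off by direct scanning, both strands."""
    for period in (8, 23, 55):
        out = generate_outgroup(CORE, period=period, seed=1)
        short = [CORE[i : i + period - 1] for i in range(len(CORE) - period + 2)]
        assert all(any(w in r.residues for r in out) for w in short)
        full = {CORE[i : i + period] for i in range(len(CORE) - period + 1)}
        present = set()
        for r in out:
            for s in (r.residues, reverse_complement(r.residues)):
                present |= {w for w in full if w in s}
        assert full - present, "at least one period-length window must be specific"


def test_outgroup_substitution_period_forces_mined_length():
    ing, _ = generate_ingroup(4, CORE, flank_len=0, seed=3)
    out = generate_outgroup(CORE, period=23, seed=3)
    res = mine_signature(ing, out, min_len=15, max_len=55)
    assert res.found and res.signature.length == 23


def test_outgroup_determinism():
    a = generate_outgroup(CORE, period=12, seed=6)
    b = generate_outgroup(CORE, period=12, seed=6)
    assert a.sequences() == b.sequences()


def test_mixture_batches_all_detectable():
    q = generate_mixture_queries(7, SIGNATURE, seed=3)
    assert len(q) == 7
    results = detect_signature(q, SIGNATURE)
    assert sum(r.found for r in results) == 7
    for rec in q:  # exactly one planted copy per batch
        assert rec.residues.count(SIGNATURE) == 1


def test_mixture_negative_control_detects_nothing():
    q = generate_mixture_queries(7, SIGNATURE, seed=3, plant=False)
    assert sum(r.found for r in detect_signature(q, SIGNATURE)) == 0


def test_degraded_mixture_still_detectable():
    q = generate_mixture_queries(7, SIGNATURE, seed=3, degrade=0.9)
    assert sum(r.found for r in detect_signature(q, SIGNATURE)) == 7


def test_mixture_validation():
    with pytest.raises(ValueError):
        generate_mixture_queries(7, SIGNATURE, fragment_len_range=(10, 40))
    with pytest.raises(ValueError):
        generate_mixture_queries(0, SIGNATURE)
    with pytest.raises(ValueError):
        generate_mixture_queries(2, SIGNATURE, degrade=2.0)


def test_mixture_determinism():
    a = generate_mixture_queries(3, SIGNATURE, seed=8)
    b = generate_mixture_queries(3, SIGNATURE, seed=8)
    assert a.sequences() == b.sequences()


def test_demo_scenario_shape(demo):
    ingroup, outgroup, truth = demo
    assert truth.planted_signature == SIGNATURE
    assert truth.outgroup_substitution_period == 23
    assert len(ingroup) == 12
    # one record carries the core-breaking substitution, the rest the full core
    with_core = [r for r in ingroup if CORE in r.residues]
    assert len(with_core) == len(ingroup) - 1


def test_planted_period_recovery_across_periods(rng):
    for period in (5, 9, 17, 30):
        core = random_seq(rng, 60)
        ing, _ = generate_ingroup(4, core, flank_len=0, seed=period)
        out = generate_outgroup(core, period=period, seed=period)
        res = mine_signature(ing, out, min_len=4, max_len=60)
        assert res.found and res.signature.length == period
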