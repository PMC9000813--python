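"""In-silico PCR and signature detection."""

import numpy as np
import pytest
from conftest import random_seq

from nucsig.alphabet import reverse_complement
from nucsig.fixtures import MH1F, MH1R, PRIMERS, SIGNATURE
from nucsig.io import Group, SequenceRecord, SequenceSet
from nucsig.pcr import (
    DetectionResult,
    PrimerPair,
    amplify,
    detect_signature,
    detection_table,
    find_primer_sites,
)


def rec(seq, rid="t1"):
    return SequenceRecord(id=rid, residues=seq)


def qset(seqs):
    return SequenceSet.from_sequences(seqs, Group.QUERY)


def test_exact_forward_site():
    rng = np.random.default_rng(1)
    tpl = rec(random_seq(rng, 20) + MH1F + random_seq(rng, 20))
    sites = find_primer_sites(tpl, MH1F)
    assert sites == [(20, "+", 0)]


def test_strand_symmetry_of_sites():
    rng = np.random.default_rng(2)
    seq = random_seq(rng, 15) + MH1F + random_seq(rng, 15)
    plus = find_primer_sites(rec(seq), MH1F)
    minus = find_primer_sites(rec(reverse_complement(seq)), MH1F)
    assert len(plus) == len(minus) == 1
    assert minus[0][1] == "-"


def test_internal_mismatch_tolerated_but_not_at_three_prime_end():
    rng = np.random.default_rng(3)
    flank = random_seq(rng, 10)
    primer = MH1F
    internal = list(primer)
    internal[5] = "A" if internal[5] != "A" else "C"  # internal substitution
    tpl_ok = rec(flank + "".join(internal) + flank)
    assert find_primer_sites(tpl_ok, primer, max_mismatch=1, three_prime_exact=3)
    tail = list(primer)
    tail[-2] = "A" if tail[-2] != "A" else "C"  # within the 3'-terminal 3 bases
    tpl_bad = rec(flank + "".join(tail) + flank)
    assert not find_primer_sites(tpl_bad, primer, max_mismatch=1, three_prime_exact=3)
    # the same placement is accepted once the 3' requirement is lifted
    assert find_primer_sites(tpl_bad, primer, max_mismatch=1, three_prime_exact=0)


def test_degenerate_primer_base_matches_compatibly():
    tpl = rec("TTTTACGTACGTTTTT")
    assert find_primer_sites(tpl, "ACGTRCGT", max_mismatch=0)[0][0] == 4


def test_amplicon_length_arithmetic():
    """fwd + 113 nt + rc(rev) amplifies a single 150-bp product."""
    rng = np.random.default_rng(4)
    tpl = rec(MH1F + random_seq(rng, 113) + reverse_complement(MH1R))
    amps = amplify(tpl, PRIMERS)
    assert len(amps) == 1
    a = amps[0]
    assert (a.start, a.end, a.length) == (0, 150, 150)
    assert a.length == len(MH1F) + 113 + len(MH1R)
    assert a.residues == tpl.residues[a.start : a.end]


def test_missing_reverse_site_means_no_product():
    rng = np.random.default_rng(5)
    tpl = rec(MH1F + random_seq(rng, 113))
    assert amplify(tpl, PRIMERS) == []


def test_product_longer_than_cap_is_dropped():
    rng = np.random.default_rng(6)
    tpl = rec(MH1F + random_seq(rng, 113) + reverse_complement(MH1R))
    assert amplify(tpl, PRIMERS, max_product_len=149) == []


def test_amplicon_from_synthetic_template_contains_signature():
    rng = np.random.default_rng(7)
    tpl = rec(
        random_seq(rng, 30)
        + MH1F
        + random_seq(rng, 40)
        + SIGNATURE
        + random_seq(rng, 50)
        + reverse_complement(MH1R)
        + random_seq(rng, 30)
    )
    amps = amplify(tpl, PRIMERS)
    assert len(amps) == 1 and SIGNATURE in amps[0].residues


def test_detect_signature_itself():
    (r,) = detect_signature(qset([SIGNATURE]), SIGNATURE)
    assert (r.found, r.position, r.strand, r.mismatches) == (True, 0, "+", 0)


def test_detect_reverse_complement_embedding():
    rng = np.random.default_rng(8)
    q = random_seq(rng, 40) + reverse_complement(SIGNATURE) + random_seq(rng, 57)
    (r,) = detect_signature(qset([q]), SIGNATURE)
    assert r.found and r.strand == "-" and r.position == 40


def test_detection_strand_flip_property(rng):
    for _ in range(15):
        q = random_seq(rng, 120)
        sig = q[30:53]
        (fwd,) = detect_signature(qset([q]), sig)
        (rev,) = detect_signature(qset([reverse_complement(q)]), sig)
        assert fwd.found and rev.found
        assert {fwd.strand, rev.strand} == {"+", "-"}


def test_exact_detection_is_substring_search(rng):
    """max_mismatch=0 + strict policy agrees with a naive scan."""
    for _ in range(40):
        q = random_seq(rng, 60)
        sig = random_seq(rng, 5)
        (r,) = detect_signature(qset([q]), sig, both_strands=False, match_policy="strict")
        assert r.found == (sig in q)
        if r.found:
            assert r.position == q.find(sig)


def test_ambiguous_consensus_matches_compatibly():
    q = SIGNATURE[:10] + "N" + SIGNATURE[11:]
    (r,) = detect_signature(qset([q]), SIGNATURE)
    assert r.found and r.mismatches == 0
    (r_strict,) = detect_signature(qset([q]), SIGNATURE, match_policy="strict")
    assert not r_strict.found


def test_negative_detection_carries_no_placement():
    with pytest.raises(ValueError):
        DetectionResult(query_id="q", found=False, position=3)
    tab = detection_table([DetectionResult(query_id="q", found=False)])
    assert tab.iloc[0].found == False  # noqa: E712


def test_primer_pair_validation():
    with pytest.raises(ValueError):
        PrimerPair(fwd="", rev="ACGT")
    with pytest.raises(ValueError):
        PrimerPair(fwd="ACGT", rev="AXGT")
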