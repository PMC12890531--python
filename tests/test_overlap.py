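"""Expansion detection, sharing classification, Fisher exact and convergence."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrshare import (
    classify_sharing,
    convergence_summary,
    detect_expansions,
    detect_overrepresented,
    fisher_2x2,
)
from tcrshare.model import CASE, PB, SG, Clonotype, Repertoire
from tcrshare.simulate import FLANK_C, FLANK_N


def _clone(nt, aa, count, subject="S1", tissue=SG, v="TRBV5-1", j="TRBJ2-1"):
    return Clonotype(junction_nt=nt, junction_aa=aa, v_call=v, j_call=j,
                     duplicate_count=count, subject_id=subject, tissue=tissue, cohort=CASE)


def test_detect_expansions_counts_cells_and_fraction():
    # cells [A, A, B, C]: one expansion of 2 cells out of 4
    rep = Repertoire("S1", SG, CASE, [
        _clone("TGTGCC", "CA", 2), _clone("TGTGGC", "CG", 1), _clone("TGTTGC", "CC", 1),
    ])
    records, frac = detect_expansions(rep)
    assert [(r.clonotype.junction_aa, r.n_cells) for r in records] == [("CA", 2)]
    assert frac == pytest.approx(0.5)


def test_all_singletons_yield_no_expansions():
    rep = Repertoire("S1", SG, CASE, [_clone("TGTGCC", "CA", 1), _clone("TGTGGC", "CG", 1)])
    records, frac = detect_expansions(rep)
    assert records == [] and frac == 0.0


def test_classify_sharing_partitions_the_sg_set():
    table = classify_sharing({"A", "B", "C"}, case_pb_union={"A"}, hc_pb_union={"B"})
    assert (table.n_sg_only, table.n_case_pb_only, table.n_hc_pb_only, table.n_both) == (1, 1, 1, 0)
    assert table.n_total == 3
    props = classify_sharing({"A", "B", "C", "D"}, {"A", "B"}, {"B", "C"}).pb_proportions()
    assert sum(props.values()) == pytest.approx(1.0)


def test_fisher_independence_and_enumeration_example():
    p, odds = fisher_2x2([[5, 5], [5, 5]])
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)
    p, _ = fisher_2x2([[3, 1], [1, 3]])
    assert p == pytest.approx(34 / 70)  # full hypergeometric enumeration


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError):
        fisher_2x2([[1, -1], [2, 3]])


def fisher_enumeration_oracle(table):
    """Independent oracle: enumerate all tables with the observed margins and
    sum the probabilities of those no more probable than the observed table."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= p_obs * (1 + 1e-12))


@settings(derandomize=True, max_examples=80, deadline=None)
@given(st.tuples(*[st.integers(min_value=0, max_value=10)] * 4))
def test_fisher_matches_enumeration_and_transpose_invariance(cells):
    a, b, c, d = cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return  # degenerate margins: p = 1 trivially
    table = [[a, b], [c, d]]
    p, _ = fisher_2x2(table)
    assert p == pytest.approx(fisher_enumeration_oracle(table), rel=1e-9)
    p_t, _ = fisher_2x2([[a, c], [b, d]])
    assert p_t == pytest.approx(p, rel=1e-9)


def test_overrepresentation_threshold():
    exp, _ = detect_expansions(Repertoire("S1", SG, CASE, [_clone("TGTGCC", "CA", 3)]))
    pb = Repertoire("S1", PB, CASE, [_clone("TGTGCC", "CA", 7, tissue=PB)])
    detect_overrepresented(exp, pb, min_copies=5)
    assert exp[0].overrepresented is True and exp[0].pb_copies_same_subject == 7
    pb_low = Repertoire("S1", PB, CASE, [_clone("TGTGCC", "CA", 4, tissue=PB)])
    detect_overrepresented(exp, pb_low, min_copies=5)
    assert exp[0].overrepresented is False
    detect_overrepresented(exp, None)
    assert exp[0].overrepresented is None


def test_convergence_summary_counts_encodings():
    # TCTGCC and AGCGCT both encode SA
    rep = Repertoire("S1", PB, CASE, [
        _clone("TCTGCC", "SA", 1, tissue=PB), _clone("AGCGCT", "SA", 2, tissue=PB),
        _clone("TGTGGC", "CG", 1, tissue=PB),
    ])
    counts, frac = convergence_summary(rep)
    assert counts == {"SA": 2, "CG": 1}
    assert frac == pytest.approx(0.5)
    all_unique = Repertoire("S1", PB, CASE, [_clone("TGTGGC", "CG", 1, tissue=PB)])
    assert convergence_summary(all_unique)[1] == 0.0


def test_planted_expansions_are_detected_and_overrepresented(study):
    """Planted SG motif members (expanded, seeded at >= 5 PB copies) are found
    by expansion detection and flagged overrepresented."""
    dataset, truth = study
    motif = truth.motifs[0]
    junctions = {FLANK_N + s + FLANK_C for s in motif.inner_seqs}
    for sid in motif.sg_subjects:
        sg = dataset.repertoire(sid, SG)
        expansions, _ = detect_expansions(sg)
        detect_overrepresented(expansions, dataset.repertoire(sid, PB))
        hits = [e for e in expansions if e.clonotype.junction_aa in junctions]
        assert hits, f"planted expansion missing for {sid}"
        for e in hits:
            assert e.n_cells >= 2
            assert e.overrepresented is True


def test_sharing_on_study_matches_planted_structure(study):
    dataset, truth = study
    case_pb, hc_pb = set(), set()
    for rep in dataset.repertoires:
        if rep.tissue == PB and dataset.pb_adequate(rep.subject_id):
            (case_pb if rep.cohort == CASE else hc_pb).update(rep.aa_set())
    sg = [c for rep in dataset.repertoires if rep.tissue == SG for c in rep.clonotypes]
    table = classify_sharing(sg, case_pb, hc_pb)
    assert table.n_total == len({c.junction_aa for c in sg})
    # exclusive planted motifs live in case PB only
    for motif in truth.motifs:
        if motif.mode != "exclusive":
            continue
        for s in motif.inner_seqs:
            aa = FLANK_N + s + FLANK_C
            assert aa not in hc_pb
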