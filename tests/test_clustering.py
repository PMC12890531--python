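"""Specificity-group clustering, pattern naming, local motifs and scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from tcrshare import name_pattern, score_group
from tcrshare.clustering import (
    MemberRecord,
    ReferenceRepertoire,
    SpecificityGroup,
    _brute_force_components,
    classify_shared_groups,
    filter_shared_groups,
    global_clusters,
    hamming1_components,
    local_motifs,
)
from tcrshare.model import CASE, CONTROL, PB, SG


def _member(seq, subject="S1", tissue=PB, cohort=CASE, v="TRBV5-1", count=1):
    return MemberRecord(seq=seq, junction_aa="CAS" + seq + "YF", v_call=v, j_call="TRBJ2-1",
                        subject_id=subject, tissue=tissue, cohort=cohort, duplicate_count=count)


def test_global_cluster_naming_example():
    groups = global_clusters([_member("SSTAGNT"), _member("SSTPGNT")])
    assert len(groups) == 1
    assert groups[0].pattern == "SST%GNT"


def test_distant_sequences_form_no_group():
    assert global_clusters([_member("AAAA"), _member("CCCC")]) == []


def test_name_pattern_examples():
    assert name_pattern(["KGLAGEYYE"]) == "KGLAGEYYE"
    assert name_pattern(["SSTAGNT", "SSTPGNT"]) == "SST%GNT"
    with pytest.raises(ValueError):
        name_pattern(["AB", "ABC"])


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.text(alphabet="ABC", min_size=3, max_size=4), min_size=2, max_size=50),
       st.randoms(use_true_random=False))
def test_components_match_brute_force_and_are_order_invariant(seqs, rnd):
    fast = hamming1_components(seqs)
    brute = _brute_force_components(seqs, 1)
    assert sorted(map(sorted, fast)) == sorted(map(sorted, brute))
    shuffled = list(seqs)
    rnd.shuffle(shuffled)
    assert sorted(map(sorted, hamming1_components(shuffled))) == sorted(map(sorted, fast))


def test_components_match_brute_force_on_random_sample():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACDG"), size=int(L))) for L in rng.choice([4, 5], size=200)]
    fast = hamming1_components(seqs)
    brute = _brute_force_components(seqs, 1)
    assert sorted(map(sorted, fast)) == sorted(map(sorted, brute))


def test_every_member_matches_its_group_pattern(study):
    from tcrshare.clustering import clustering_records

    dataset, _ = study
    records = clustering_records(dataset)
    groups = global_clusters(records)
    assert groups, "study should produce specificity groups"
    for g in groups[:200]:
        for m in g.members:
            assert g.matches(m.seq)


def _uniform_reference(n=2000, seed=0, v_probs=None):
    rng = np.random.default_rng(seed)
    lengths = rng.choice([6, 7, 8], size=n, p=[0.3, 0.4, 0.3])
    seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=int(L))) for L in lengths]
    genes = ["TRBV5-1", "TRBV9", "TRBV19", "TRBV28"]
    p = v_probs or [0.05, 0.35, 0.3, 0.3]
    vs = [genes[i] for i in rng.choice(4, size=n, p=p)]
    return ReferenceRepertoire(seqs, vs)


def test_local_motif_enrichment_against_hypergeometric_oracle():
    ref = _uniform_reference()
    # plant the 4-mer WWWW into a sample far above its reference frequency
    sample = [_member(f"WWWW{suffix}") for suffix in ("AC", "AD", "AE", "AF", "AG")]
    sample += [_member(s) for s in ref.inner_seqs[:95]]
    groups = local_motifs(sample, ref, ks=(4,), min_fold=10, p_threshold=1e-3)
    planted = [g for g in groups if g.pattern == "WWWW"]
    assert len(planted) == 1
    assert {m.seq for m in planted[0].members} == {f"WWWW{s}" for s in ("AC", "AD", "AE", "AF", "AG")}
    # the reported decision matches a direct hypergeometric tail computation
    n_s = len({m.seq for m in sample})
    n_r = len(ref.inner_seqs)
    b = ref.kmer_counts(4).get("WWWW", 0)
    p_oracle = hypergeom.sf(5 - 1, n_s + n_r, 5 + b, n_s)
    assert p_oracle < 1e-3


def test_unenriched_motif_is_not_reported():
    ref = _uniform_reference()
    sample = [_member(s) for s in ref.inner_seqs[:100]]  # fold ~ 1 for every k-mer
    groups = local_motifs(sample, ref, ks=(4,), min_fold=10)
    assert groups == []


def test_empty_reference_is_an_error():
    with pytest.raises(ValueError):
        ReferenceRepertoire([], [])


def test_v_gene_bias_score_flags_a_concentrated_group():
    ref = _uniform_reference()  # TRBV5-1 used at 5%
    members = [_member("ACDEFG", subject=f"S{i}") for i in range(10)]  # all TRBV5-1
    group = SpecificityGroup(pattern="ACDEF%", group_type="global", members=members)
    scores = score_group(group, ref, n_null=1000, seed=1)
    assert scores.v_gene_bias_p <= 0.001


def test_single_member_group_scores_are_undefined():
    group = SpecificityGroup(pattern="ACDEFG", group_type="global", members=[_member("ACDEFG")])
    scores = score_group(group, _uniform_reference(), seed=0)
    assert scores.v_gene_bias_p is None
    assert scores.length_conservation_p is None
    assert scores.size_p is None
    assert filter_shared_groups([group]) == []


def test_classify_shared_groups_categories_and_flags():
    g_case = SpecificityGroup("A%C", "global", [
        _member("AAC", tissue=SG, count=3), _member("ABC", tissue=PB, cohort=CASE)])
    g_both = SpecificityGroup("D%C", "global", [
        _member("DAC", tissue=SG, count=1), _member("DBC", tissue=PB, cohort=CASE),
        _member("DCC", tissue=PB, cohort=CONTROL)])
    g_pb = SpecificityGroup("E%C", "global", [_member("EAC", tissue=PB)])
    counts = classify_shared_groups([g_case, g_both, g_pb])
    assert g_case.category == "SG+casePB" and g_case.expansion_flag is True
    assert g_both.category == "SG+both" and g_both.expansion_flag is False
    assert g_pb.category == "PB-only"
    assert sum(counts.values()) == 3


def test_planted_motif_kmers_emerge_as_local_motifs(study):
    """Conserved positions of planted motifs surface as enriched k-mers against
    the generator's naive background.  Each planted motif contributes only a
    handful of SG sequences at desk scale, so the check is that the planted set
    as a whole is represented among the enriched local motifs."""
    from tcrshare.clustering import clustering_records

    dataset, truth = study
    ref = ReferenceRepertoire.from_model(truth.model, n=4000, seed=99)
    sg_records = [m for m in clustering_records(dataset) if m.tissue == SG]
    groups = local_motifs(sg_records, ref, ks=(4,), min_fold=5, p_threshold=1e-3)
    kmers = {g.pattern for g in groups}
    planted_kmers = set()
    for motif in truth.motifs:
        shared = None
        for s in motif.inner_seqs:  # k-mers conserved across every member
            mers = {s[i : i + 4] for i in range(len(s) - 3)}
            shared = mers if shared is None else shared & mers
        planted_kmers |= shared
    assert planted_kmers & kmers
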