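"""Synthetic study generator: determinism, planted structure, sampling laws."""

import itertools
import math

import numpy as np
import pytest

from tcrshare import GeneratorConfig, PgenModel, generate_study, null_config, sample_sequence
from tcrshare.model import CASE, CONTROL, PB, SG, CODONS_BY_AA, translate, write_airr
from tcrshare.simulate import FLANK_C, FLANK_N, encode_nt
from tests.conftest import small_generator_config


def test_same_seed_gives_byte_identical_datasets(tmp_path):
    paths = []
    for i in range(2):
        dataset, truth = generate_study(small_generator_config(9))
        p = tmp_path / f"run{i}.tsv"
        write_airr(dataset.repertoires, p)
        truth.to_json(tmp_path / f"truth{i}.json")
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    assert (tmp_path / "truth0.json").read_bytes() == (tmp_path / "truth1.json").read_bytes()


def test_null_config_plants_nothing():
    _, truth = generate_study(null_config(2, n_cases=5, n_controls=5,
                                          pb_mean_case=200.0, pb_mean_control=200.0,
                                          n_public_pool=100))
    assert truth.motifs == []


def test_infeasible_prevalence_raises():
    cfg = GeneratorConfig(n_cases=4, n_controls=4, exclusive_prevalence=5,
                          n_inadequate_pb_per_cohort=0)
    with pytest.raises(ValueError):
        generate_study(cfg)


def test_study_design_shape(study):
    dataset, truth = study
    cfg = truth.config
    assert len(dataset.cohort_subjects(CASE)) == cfg.n_cases
    assert len(dataset.cohort_subjects(CONTROL)) == cfg.n_controls
    for s in dataset.cohort_subjects(CASE):
        assert dataset.repertoire(s.subject_id, SG) is not None
        assert dataset.repertoire(s.subject_id, PB) is not None
    for s in dataset.cohort_subjects(CONTROL):
        assert dataset.repertoire(s.subject_id, SG) is None
    lo, hi = cfg.sg_cells_range
    for rep in dataset.repertoires:
        if rep.tissue == SG:
            assert rep.n_cells >= lo
            assert rep.total_count == rep.n_cells


def test_cases_have_fewer_unique_pb_clonotypes(study):
    dataset, _ = study
    case = [r.n_unique for r in dataset.repertoires
            if r.tissue == PB and r.cohort == CASE and dataset.pb_adequate(r.subject_id)]
    hc = [r.n_unique for r in dataset.repertoires
          if r.tissue == PB and r.cohort == CONTROL and dataset.pb_adequate(r.subject_id)]
    assert np.mean(case) < np.mean(hc)


def test_planted_motifs_reach_their_prevalence(study):
    dataset, truth = study
    pb_aa = {}
    for rep in dataset.repertoires:
        if rep.tissue == PB:
            pb_aa[rep.subject_id] = {c.junction_aa for c in rep.clonotypes}
    for motif in truth.motifs:
        junctions = {FLANK_N + s + FLANK_C for s in motif.inner_seqs}
        n_cases = sum(1 for sid, aa in pb_aa.items()
                      if sid.startswith("P") and junctions & aa)
        assert n_cases >= len(motif.case_subjects)
        if motif.mode == "exclusive":
            for sid, aa in pb_aa.items():
                if sid.startswith("H"):
                    assert not (junctions & aa)  # exclusive motifs never reach control PB


def test_truth_pgen_matches_model_closed_form(study):
    _, truth = study
    for seq, p in itertools.islice(truth.pgen.items(), 200):
        assert p == truth.model.pgen(seq)


def test_sample_sequence_triple_is_consistent():
    rng = np.random.default_rng(0)
    model = PgenModel()
    for _ in range(20):
        inner, nt, p = sample_sequence(model, rng)
        assert translate(nt) == FLANK_N + inner + FLANK_C
        assert p == model.pgen(inner)
        assert len(nt) == 3 * (len(inner) + 5)  # inner length = junction length - 5


def test_nt_encoding_probabilities_sum_to_aa_pgen():
    """Enumerating every synonymous encoding of a short junction recovers the
    amino-acid pGen: sum over encodings of (pGen_aa * per-encoding factor)."""
    model = PgenModel(length_probs={2: 1.0},
                      aa_probs={a: 0.05 for a in "ACDEFGHIKLMNPQRSTVWY"})
    junction = "MW"  # 1 codon each keeps enumeration tiny; also try a rich one
    for junction in ("MW", "LR"):  # L and R have 6 codons each
        total = 0.0
        for codons in itertools.product(*(CODONS_BY_AA[a] for a in junction)):
            total += model.pgen(junction) * model.nt_factor(junction)
        n_encodings = math.prod(len(CODONS_BY_AA[a]) for a in junction)
        assert total == pytest.approx(model.pgen(junction))
        assert model.nt_factor(junction) == pytest.approx(1.0 / n_encodings)


def test_sampled_sequences_match_closed_form_frequencies():
    """Monte-Carlo frequency of a length-1 sequence within 3 SE of its pGen."""
    model = PgenModel(length_probs={1: 1.0}, aa_probs={"A": 0.7, "G": 0.3})
    rng = np.random.default_rng(1)
    n = 4000
    seqs = model.sample_inner(rng, n)
    freq = seqs.count("A") / n
    se = math.sqrt(0.7 * 0.3 / n)
    assert abs(freq - 0.7) <= 3 * se


def test_abundance_marginal_follows_power_law(study):
    """The cDNA-count marginal of a control PB repertoire follows the configured
    zipf law: compare small-count frequency ratios with the analytic pmf."""
    dataset, truth = study
    a = truth.config.abundance_exponent
    rep = next(r for r in dataset.repertoires if r.cohort == CONTROL and r.tissue == PB
               and dataset.pb_adequate(r.subject_id))
    counts = rep.counts()
    counts = counts[counts <= 4]  # planted/seeded copies perturb only the tail
    f = {x: np.mean(counts == x) for x in (1, 2, 3)}
    assert f[2] / f[1] == pytest.approx(2.0 ** -a, abs=0.05)
    assert f[3] / f[1] == pytest.approx(3.0 ** -a, abs=0.05)


def test_convergent_encoding_rate_matches_config(study):
    dataset, truth = study
    from tcrshare import convergence_summary

    rep = next(r for r in dataset.repertoires if r.cohort == CONTROL and r.tissue == PB
               and dataset.pb_adequate(r.subject_id))
    counts, frac = convergence_summary(rep)
    n = len(counts)
    rate = truth.config.convergence_rate
    se = math.sqrt(rate * (1 - rate) / n)
    assert abs(frac - rate) <= 3 * se + 0.01
    # convergent encodings translate identically by construction
    by_aa = {}
    for c in rep.clonotypes:
        by_aa.setdefault(c.junction_aa, []).append(c.junction_nt)
    for aa, nts in by_aa.items():
        for nt in nts:
            assert translate(nt) == aa


def test_control_abundance_couples_to_pgen(study):
    """The planted interaction: control repertoires rank-couple abundance to
    pGen; case repertoires do not."""
    from scipy.stats import spearmanr

    dataset, truth = study
    rhos = {CASE: [], CONTROL: []}
    for rep in dataset.repertoires:
        if rep.tissue != PB or not dataset.pb_adequate(rep.subject_id):
            continue
        logp = [math.log10(truth.pgen[c.junction_aa[3:-2]]) for c in rep.clonotypes
                if c.junction_aa[3:-2] in truth.pgen]
        cnt = [c.duplicate_count for c in rep.clonotypes if c.junction_aa[3:-2] in truth.pgen]
        rhos[rep.cohort].append(spearmanr(logp, cnt).statistic)
    assert np.mean(rhos[CONTROL]) > np.mean(rhos[CASE]) + 0.05
    assert np.mean(rhos[CONTROL]) > 0.05


def test_seeded_sg_clones_appear_nt_identical_in_own_pb(study):
    dataset, truth = study
    for sid, seeded in truth.sg_seeded.items():
        if not seeded:
            continue
        sg = dataset.repertoire(sid, SG)
        pb = dataset.repertoire(sid, PB)
        pb_nt = {c.junction_nt for c in pb.clonotypes}
        sg_by_aa = {}
        for c in sg.clonotypes:
            sg_by_aa.setdefault(c.junction_aa, []).append(c.junction_nt)
        for aa in seeded[:10]:
            assert any(nt in pb_nt for nt in sg_by_aa[aa])
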