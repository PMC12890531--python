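"""Richness/diversity estimators against closed forms and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrshare.diversity import (
    AbundanceSpectrum,
    abundance_classes,
    chao1,
    cohort_compare,
    d50,
    efron_thisted,
    extrapolate,
    mann_whitney,
    rarefy,
    shannon,
    study_profiles,
)
from tcrshare.model import CASE, CONTROL


@pytest.mark.parametrize(
    "counts,expected",
    [([2, 2, 2], 3.0), ([1, 1, 1, 1], 10.0), ([1, 1, 2], 3.5)],
)
def test_chao1_examples(counts, expected):
    assert chao1(AbundanceSpectrum(counts)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "counts,expected",
    [([1, 2], 2.0), ([1, 1, 2], 4.0), ([2, 2, 2], 3.0)],  # last case clamps at S_obs
)
def test_efron_thisted_examples(counts, expected):
    assert efron_thisted(AbundanceSpectrum(counts)) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize(
    "counts,expected",
    [([1] * 10, 5), ([60, 20, 20], 1), ([30, 30, 20, 20], 2)],
)
def test_d50_examples(counts, expected):
    assert d50(AbundanceSpectrum(counts)) == expected


def test_d50_of_uniform_spectrum_is_half_rounded_up():
    for s in (1, 2, 5, 7, 12):
        assert d50(AbundanceSpectrum([3] * s)) == math.ceil(s / 2)


@pytest.mark.parametrize(
    "counts,expected",
    [([7], 0.0), ([1] * 8, math.log(8)), ([2, 1, 1], 1.0397207708399179)],
)
def test_shannon_examples(counts, expected):
    assert shannon(AbundanceSpectrum(counts)) == pytest.approx(expected)


def rarefy_enumeration_oracle(counts, m):
    """Exhaustively average distinct-clonotype counts over all m-subsets of molecules."""
    items = [i for i, c in enumerate(counts) for _ in range(c)]
    total = n = 0
    for sub in itertools.combinations(range(len(items)), m):
        total += len({items[i] for i in sub})
        n += 1
    return total / n


@pytest.mark.parametrize(
    "counts,m",
    [([2, 2], 2), ([3, 2, 1], 3), ([1, 1, 4], 2), ([5, 4, 3, 2, 1], 6),
     ([4, 4, 4, 4, 4], 10), ([10, 5, 3, 2], 10)],
)
def test_rarefaction_equals_exhaustive_enumeration(counts, m):
    spec = AbundanceSpectrum(counts)
    assert rarefy(spec, m) == pytest.approx(rarefy_enumeration_oracle(counts, m), rel=1e-9)


def test_rarefaction_identity_and_bounds():
    spec = AbundanceSpectrum([5, 3, 2, 1, 1])
    assert rarefy(spec, spec.n_total) == pytest.approx(spec.s_obs)
    with pytest.raises(ValueError):
        rarefy(spec, spec.n_total + 1)
    curve = [rarefy(spec, m) for m in range(1, spec.n_total + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(curve, curve[1:]))  # monotone


def test_extrapolation_behaviour():
    spec = AbundanceSpectrum([1, 1, 2, 3])
    values = [extrapolate(spec, m) for m in (0, 1, 10, 1000, 10**6)]
    assert values[0] == pytest.approx(spec.s_obs)
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] <= chao1(spec) + 1e-9
    no_singletons = AbundanceSpectrum([2, 2, 3])
    assert extrapolate(no_singletons, 10**6) == no_singletons.s_obs


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=30))
def test_estimator_invariants(counts):
    spec = AbundanceSpectrum(counts)
    assert chao1(spec) >= spec.s_obs
    assert efron_thisted(spec) >= spec.s_obs
    assert 1 <= d50(spec) <= spec.s_obs
    occ = abundance_classes(spec)
    assert sum(occ.values()) == pytest.approx(1.0)


def test_abundance_class_thresholds():
    # 600 / 200,000 = 0.3 % -> large;  1 / 200,000 = 0.0005 % -> rare
    counts = [600] + [1] * 199400
    spec = AbundanceSpectrum(counts)
    occ = abundance_classes(spec)
    assert occ["large"] == pytest.approx(600 / 200000)
    assert occ["rare"] == pytest.approx(199400 / 200000)
    # a frequency exactly on a boundary joins the larger class
    spec2 = AbundanceSpectrum([25, 99975])  # 25/100000 = 0.025 %
    assert abundance_classes(spec2)["moderate"] == pytest.approx(0.00025)


def mann_whitney_enumeration_oracle(x, y):
    """Exact two-sided p over all group assignments (tie-free data)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(idx)].sum()
        us.append(r1 - n1 * (n1 + 1) / 2)
    us = np.array(us)
    cdf = np.mean(us <= u_obs + 1e-9)
    sf = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(cdf, sf))


def test_mann_whitney_example_and_identical_groups():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)  # 2 / C(6,3)
    x = [1.0, 2.0, 3.0]
    assert cohort_compare(
        [_profile("a", CASE, v) for v in x], [_profile("b", CONTROL, v) for v in x], "shannon"
    )["p"] == 1.0


def test_mann_whitney_matches_enumeration_for_small_groups():
    rng = np.random.default_rng(4)
    for _ in range(15):
        n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct values: tie-free
        x, y = pooled[:n1], pooled[n1:]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mann_whitney_enumeration_oracle(x, y), rel=1e-9)


def _profile(sid, cohort, value):
    from tcrshare.diversity import DiversityProfile

    return DiversityProfile(subject_id=sid, cohort=cohort, s_obs=1, n_total=1,
                            chao1=1.0, efron_thisted=1.0, d50=1, shannon=value,
                            occupancy={"rare": 1.0, "small": 0.0, "moderate": 0.0, "large": 0.0})


def test_cohort_compare_requires_two_per_group():
    with pytest.raises(ValueError):
        mann_whitney([1.0], [2.0, 3.0])


def test_planted_diversity_deficit_is_detected(study):
    dataset, _ = study
    profiles = study_profiles(dataset)
    cases = [p for p in profiles if p.cohort == CASE]
    hcs = [p for p in profiles if p.cohort == CONTROL]
    res = cohort_compare(cases, hcs, "s_obs")
    assert res["case_mean"] < res["hc_mean"]
    assert res["p"] < 0.05
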