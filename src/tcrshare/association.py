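"""Disease-association of specificity-group motifs and clinical correlation.

Candidate motifs (SG-shared specificity groups) are called disease-associated
when, among adequately sampled subjects, their PB members are either

* detected in >= 3 cases and 0 controls (*exclusive*), or
* detected in >= 3 cases and significantly more abundant in cases (two-sided
  Mann-Whitney on per-subject summed cDNA counts, absent subjects contributing
  zeros, with a positive mean-rank difference).

Motif abundance per subject is the summed ``duplicate_count`` of member
clonotypes in PB (cDNA molecules, not clonotype counts).  No multiple-testing
correction is applied by default; a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import SpecificityGroup
from .diversity import mann_whitney
from .model import CASE, CONTROL, PB, SG, SpecificityDbEntry, StudyDataset


@dataclass
class MotifAbundance:
    pattern: str
    case_abundance: dict[str, int]     # adequate case subject -> summed PB cDNA count
    control_abundance: dict[str, int]  # adequate control subject -> summed PB cDNA count

    @property
    def n_cases_detected(self) -> int:
        return sum(1 for v in self.case_abundance.values() if v > 0)

    @property
    def n_controls_detected(self) -> int:
        return sum(1 for v in self.control_abundance.values() if v > 0)


@dataclass
class AssociationResult:
    pattern: str
    n_cases_detected: int
    n_hcs_detected: int
    mw_p: float | None
    mean_rank_difference: float | None
    direction: str | None            # "case-enriched" | "hc-enriched"
    exclusive: bool
    called: bool
    mw_p_adjusted: float | None = None
    clinical: list[dict] = field(default_factory=list)


def motif_abundance(group: SpecificityGroup, dataset: StudyDataset) -> MotifAbundance:
    """Per-adequate-subject summed PB cDNA abundance of a group's members."""
    case_subjects = dataset.adequate_pb_subjects(CASE)
    hc_subjects = dataset.adequate_pb_subjects(CONTROL)
    case = {s: 0 for s in case_subjects}
    hc = {s: 0 for s in hc_subjects}
    for m in group.members:
        if m.tissue != PB:
            continue
        if m.cohort == CASE and m.subject_id in case:
            case[m.subject_id] += m.duplicate_count
        elif m.cohort == CONTROL and m.subject_id in hc:
            hc[m.subject_id] += m.duplicate_count
    return MotifAbundance(pattern=group.pattern, case_abundance=case, control_abundance=hc)


def call_exclusive(abundances: list[MotifAbundance], min_cases: int = 3) -> list[MotifAbundance]:
    """Motifs whose PB members occur in >= min_cases cases and zero controls."""
    return [
        a for a in abundances
        if a.n_cases_detected >= min_cases and a.n_controls_detected == 0
    ]


def mean_rank_difference(case_values, hc_values) -> float:
    """Mean rank (cases) minus mean rank (controls) on the pooled ranking."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(hc_values, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].mean() - ranks[len(x):].mean())


def differential_abundance(abundance: MotifAbundance) -> tuple[float | None, float]:
    """Two-sided Mann-Whitney on per-subject abundances (zeros included).

    Returns (p, mean rank difference); p is ``None`` when every abundance is
    zero (the test is undefined).
    """
    x = np.array([abundance.case_abundance[s] for s in sorted(abundance.case_abundance)], dtype=float)
    y = np.array([abundance.control_abundance[s] for s in sorted(abundance.control_abundance)], dtype=float)
    mrd = mean_rank_difference(x, y)
    if (x.sum() + y.sum()) == 0 or (np.array_equal(np.sort(x), np.sort(y)) and len(x) == len(y)):
        p = None if (x.sum() + y.sum()) == 0 else 1.0
        return p, mrd
    _, p = mann_whitney(x, y)
    return p, mrd


def associate_groups(
    groups: list[SpecificityGroup],
    dataset: StudyDataset,
    min_cases: int = 3,
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[AssociationResult]:
    """Association calls over a candidate group list (Fig-style two-route filter).

    ``called`` is True for exclusive motifs and for motifs detected in
    >= min_cases cases with Mann-Whitney p < alpha in the case-enriched
    direction.  With ``adjust`` a Benjamini-Hochberg-corrected p is used for the
    abundance route (off by default).
    """
    results: list[AssociationResult] = []
    for g in groups:
        ab = motif_abundance(g, dataset)
        p, mrd = differential_abundance(ab)
        direction = None if mrd == 0 else ("case-enriched" if mrd > 0 else "hc-enriched")
        exclusive = ab.n_cases_detected >= min_cases and ab.n_controls_detected == 0
        results.append(
            AssociationResult(
                pattern=g.pattern,
                n_cases_detected=ab.n_cases_detected,
                n_hcs_detected=ab.n_controls_detected,
                mw_p=p,
                mean_rank_difference=mrd,
                direction=direction,
                exclusive=exclusive,
                called=False,
            )
        )
    if adjust:
        idx = [i for i, r in enumerate(results) if r.mw_p is not None]
        if idx:
            adj = multipletests([results[i].mw_p for i in idx], method="fdr_bh")[1]
            for i, q in zip(idx, adj):
                results[i].mw_p_adjusted = float(q)
    for r in results:
        p_eff = r.mw_p_adjusted if (adjust and r.mw_p_adjusted is not None) else r.mw_p
        abundance_route = (
            r.n_cases_detected >= min_cases
            and p_eff is not None
            and p_eff < alpha
            and r.direction == "case-enriched"
        )
        r.called = r.exclusive or abundance_route
    return results


def shared_motif_burden(
    subject_id: str, groups: list[SpecificityGroup], dataset: StudyDataset | None = None
) -> int | None:
    """Number of groups with >= 1 SG member and >= 1 PB member from this subject.

    When a dataset is given, subjects failing either adequacy threshold return
    ``None`` (excluded from clinical correlation, logged by the pipeline).
    """
    if dataset is not None and not (dataset.sg_adequate(subject_id) and dataset.pb_adequate(subject_id)):
        return None
    burden = 0
    for g in groups:
        has_sg = any(m.tissue == SG and m.subject_id == subject_id for m in g.members)
        has_pb = any(m.tissue == PB and m.subject_id == subject_id for m in g.members)
        if has_sg and has_pb:
            burden += 1
    return burden


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact permutation p for Spearman rho (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_perm = rx[perms]  # (n!, n)
    rxc = rx_perm - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc[0] ** 2).sum()) * float((ryc**2).sum()))
    if denom == 0:
        return float("nan")
    rhos = (rxc @ ryc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def clinical_correlation(values_per_subject: dict[str, float], feature_per_subject: dict[str, float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho with two-tailed p (exact permutation for n <= 9).

    Missing feature values are dropped pairwise; requires >= 5 paired
    observations; a constant vector raises ``ValueError`` (undefined rho).
    """
    pairs = [
        (values_per_subject[s], feature_per_subject[s])
        for s in sorted(values_per_subject)
        if s in feature_per_subject
        and feature_per_subject[s] is not None
        and not (isinstance(feature_per_subject[s], float) and math.isnan(feature_per_subject[s]))
        and values_per_subject[s] is not None
    ]
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 paired observations, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= 9:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def burden_clinical_correlations(
    groups: list[SpecificityGroup],
    dataset: StudyDataset,
    features: tuple[str, ...] = ("WUSF", "ESSDAI", "age"),
) -> pd.DataFrame:
    """Correlate per-subject shared-motif burden with clinical features.

    Restricted to cases adequately sampled in both compartments.
    """
    burdens = {}
    for s in dataset.cohort_subjects(CASE):
        b = shared_motif_burden(s.subject_id, groups, dataset)
        if b is not None:
            burdens[s.subject_id] = float(b)
    rows = []
    for feat in features:
        feat_values = {s.subject_id: getattr(s, feat) for s in dataset.cohort_subjects(CASE)}
        try:
            rho, p = clinical_correlation(burdens, feat_values)
        except ValueError:
            rho, p = float("nan"), float("nan")
        rows.append({"feature": feat, "n": len(burdens), "spearman_rho": rho, "p": p})
    return pd.DataFrame(rows)


def annotate_public(
    dataset: StudyDataset,
    db: list[SpecificityDbEntry],
    match_v: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Annotate PB clonotypes against a public specificity database.

    Exact amino-acid junction match (optionally also the V gene).  Returns a
    per-subject x per-pathogen abundance table and a paired t-test (pairing by
    pathogen) comparing cohort mean abundances.
    """
    index: dict[str, list[SpecificityDbEntry]] = {}
    for e in db:
        index.setdefault(e.cdr3_aa, []).append(e)
    rows = []
    pathogens = sorted({e.pathogen_or_antigen for e in db})
    for rep in dataset.repertoires:
        if rep.tissue != PB or not dataset.pb_adequate(rep.subject_id):
            continue
        totals = {p: 0 for p in pathogens}
        for c in rep.clonotypes:
            for e in index.get(c.junction_aa, []):
                if match_v and e.v_call is not None and e.v_call != c.v_call:
                    continue
                totals[e.pathogen_or_antigen] += c.duplicate_count
        row = {"subject_id": rep.subject_id, "cohort": rep.cohort}
        row.update(totals)
        rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict = {"n_pathogens": len(pathogens)}
    if len(pathogens) >= 2 and not table.empty:
        case_means = table[table.cohort == CASE][pathogens].mean(axis=0)
        hc_means = table[table.cohort == CONTROL][pathogens].mean(axis=0)
        t, p = stats.ttest_rel(hc_means.to_numpy(float), case_means.to_numpy(float))
        summary.update(
            {
                "paired_t": float(t),
                "paired_p": float(p),
                "hc_over_case_ratio": float(hc_means.sum() / case_means.sum())
                if case_means.sum() > 0
                else float("nan"),
            }
        )
    return table, summary


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Volcano-ready association table (pattern, mean rank difference, -log10 p)."""
    rows = []
    for r in results:
        rows.append(
            {
                "pattern": r.pattern,
                "n_cases_detected": r.n_cases_detected,
                "n_hcs_detected": r.n_hcs_detected,
                "mw_p": r.mw_p,
                "neg_log10_p": -math.log10(r.mw_p) if r.mw_p else None,
                "mean_rank_difference": r.mean_rank_difference,
                "direction": r.direction,
                "exclusive": r.exclusive,
                "called": r.called,
            }
        )
    return pd.DataFrame(rows)
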