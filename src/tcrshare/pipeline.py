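"""End-to-end study orchestration: overlap -> cluster -> filter -> associate ->
diversity -> pGen interaction, with deterministic, stamped outputs.

Two complementary comparisons are run, mirroring the study design:
(a) SG-versus-PB — SG clonal expansions, SG<->PB sharing categories and their
cohort-asymmetry Fisher tests, SG-shared specificity groups and their
disease-association calls and clinical correlations; and (b) PB-versus-PB —
per-subject diversity with cohort comparisons and the subsampled
pGen x abundance interaction regression.

Every output TSV starts with a ``#`` stamp line carrying the config hash and
seed; ``summary.json`` aggregates the headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import clustering as clus
from . import diversity as div
from . import overlap as ovl
from . import pgen as pg
from .model import CASE, CONTROL, PB, SG, SpecificityDbEntry, StudyDataset
from .simulate import SyntheticTruth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    trim: tuple[int, int] = (3, 2)
    sharing_key: str = "aa"          # cross-subject identity; same-subject checks use nt
    min_cells: int = 2               # SG expansion threshold (cells)
    min_copies: int = 5              # PB overrepresentation threshold (cDNA copies)
    min_cases: int = 3               # exclusivity / abundance-route prevalence
    clinical_min_prevalence: int = 5
    max_mismatch: int = 1
    score_n_null: int = 1000
    score_alpha: float = 0.05
    min_unique_members: int = 3
    reference_size: int = 4000
    null_size_reps: int = 10
    pgen_n_per_cohort: int = 5000
    pgen_iterations: int = 200
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tcrshare {stamp}\n")
        df.to_csv(fh, sep="\t", index=False)


def _sharing_stage(dataset: StudyDataset, config: PipelineConfig) -> dict:
    """SG expansions, SG<->PB sharing categories and Fisher asymmetry tests."""
    case_pb_union: set[str] = set()
    hc_pb_union: set[str] = set()
    for rep in dataset.repertoires:
        if rep.tissue != PB or not dataset.pb_adequate(rep.subject_id):
            continue
        keys = rep.aa_set() if config.sharing_key == "aa" else {c.junction_nt for c in rep.clonotypes}
        (case_pb_union if rep.cohort == CASE else hc_pb_union).update(keys)

    sg_clonotypes = []
    expanded_clonotypes = []
    expansion_rows = []
    n_cases_with_expansions = 0
    for rep in dataset.repertoires:
        if rep.tissue != SG:
            continue
        sg_clonotypes.extend(rep.clonotypes)
        expansions, frac = ovl.detect_expansions(rep, min_cells=config.min_cells)
        pb_rep = dataset.repertoire(rep.subject_id, PB)
        ovl.detect_overrepresented(expansions, pb_rep, min_copies=config.min_copies)
        if expansions:
            n_cases_with_expansions += 1
        expanded_clonotypes.extend(e.clonotype for e in expansions)
        for e in expansions:
            expansion_rows.append(
                {
                    "subject_id": rep.subject_id,
                    "junction_aa": e.clonotype.junction_aa,
                    "junction_nt": e.clonotype.junction_nt,
                    "v_call": e.clonotype.v_call,
                    "n_cells": e.n_cells,
                    "expanded_fraction": frac,
                    "pb_copies_same_subject": e.pb_copies_same_subject,
                    "overrepresented": e.overrepresented,
                }
            )

    out: dict = {"n_cases_with_expansions": n_cases_with_expansions,
                 "n_sg_clonotypes": len({c.junction_aa for c in sg_clonotypes})}
    for label, clonos in (("all_sg", sg_clonotypes), ("expanded_sg", expanded_clonotypes)):
        table = ovl.classify_sharing(clonos, case_pb_union, hc_pb_union, key=config.sharing_key)
        entry = {
            "counts": dataclasses.asdict(table),
            "pb_proportions": table.pb_proportions(),
        }
        if table.n_in_pb > 0 and min(table.n_case_pb_only + table.n_both,
                                     table.n_hc_pb_only + table.n_both) >= 0:
            p, odds = ovl.fisher_2x2(table.fisher_table())
            entry["fisher_p"] = p
            entry["odds_ratio"] = odds
        out[label] = entry
    out["_expansion_rows"] = expansion_rows
    return out


def _cluster_stage(
    dataset: StudyDataset,
    config: PipelineConfig,
    reference: clus.ReferenceRepertoire,
) -> tuple[list[clus.SpecificityGroup], dict]:
    records = clus.clustering_records(dataset, trim=config.trim)
    groups = clus.global_clusters(records, max_mismatch=config.max_mismatch)
    counts = clus.classify_shared_groups(groups, min_cells=config.min_cells)
    sg_groups = [g for g in groups if g.category not in (clus.PB_ONLY,)]
    n_sg_groups = len(sg_groups)
    shared = [g for g in sg_groups if g.category != clus.SG_ONLY]
    summary = {
        "n_groups_total": len(groups),
        "category_counts": counts,
        "n_sg_containing": n_sg_groups,
        "n_sg_pb_shared": len(shared),
        "shared_fraction_of_sg_groups": (len(shared) / n_sg_groups) if n_sg_groups else None,
    }
    return groups, summary


def _association_stage(
    dataset: StudyDataset,
    groups: list[clus.SpecificityGroup],
    reference: clus.ReferenceRepertoire,
    config: PipelineConfig,
    db: list[SpecificityDbEntry] | None,
) -> dict:
    shared = [g for g in groups if g.category in (clus.SG_CASE_PB, clus.SG_HC_PB, clus.SG_BOTH)]
    # candidates: shared groups with enough distinct sequences to constitute a
    # motif and whose PB members reach the prevalence floor
    candidates = []
    for g in shared:
        if g.size < config.min_unique_members:
            continue
        ab = assoc.motif_abundance(g, dataset)
        if ab.n_cases_detected >= config.min_cases:
            candidates.append(g)
    null_sizes = reference.null_component_sizes(
        sample_size=min(len(reference.inner_seqs), 2000),
        n_rep=config.null_size_reps,
        seed=config.seed,
    )
    for i, g in enumerate(candidates):
        g.scores = clus.score_group(
            g, reference, n_null=config.score_n_null,
            seed=config.seed + 7919 * (i + 1), null_component_sizes=null_sizes,
        )
    filtered = clus.filter_shared_groups(
        candidates, alpha=config.score_alpha, min_unique_members=config.min_unique_members
    )
    expanded = [g for g in candidates if g.expansion_flag and g not in filtered]
    tested = filtered + expanded  # "filtered shared" plus "expanded shared" groups
    results = assoc.associate_groups(tested, dataset, min_cases=config.min_cases)
    called = [(g, r) for g, r in zip(tested, results) if r.called]

    clinical = assoc.burden_clinical_correlations(shared, dataset)
    out = {
        "n_shared_groups": len(shared),
        "n_candidates": len(candidates),
        "n_filtered": len(filtered),
        "n_expanded_extra": len(expanded),
        "n_called": len(called),
        "n_called_exclusive": sum(1 for _, r in called if r.exclusive),
        "_results": results,
        "_tested_groups": tested,
        "_called_groups": [g for g, _ in called],
        "_clinical": clinical,
    }
    if db:
        table, db_summary = assoc.annotate_public(dataset, db)
        out["public_specificities"] = db_summary
        out["_public_table"] = table
    return out


def _diversity_stage(dataset: StudyDataset) -> dict:
    profiles = div.study_profiles(dataset, adequate_only=True)
    cases = [p for p in profiles if p.cohort == CASE]
    hcs = [p for p in profiles if p.cohort == CONTROL]
    comparisons = {}
    if len(cases) >= 2 and len(hcs) >= 2:
        for metric in ("s_obs", "chao1", "efron_thisted", "d50", "shannon",
                       "rare", "small", "moderate", "large"):
            comparisons[metric] = div.cohort_compare(cases, hcs, metric)
    return {"n_profiles": len(profiles), "comparisons": comparisons, "_profiles": profiles}


def _pgen_stage(
    dataset: StudyDataset, model: pg.PgenModel, config: PipelineConfig
) -> dict:
    case_rec = pg.mean_abundance_records(dataset, CASE, model=model, trim=config.trim)
    hc_rec = pg.mean_abundance_records(dataset, CONTROL, model=model, trim=config.trim)
    full = pg.interaction_glm(
        np.concatenate([case_rec.log10_pgen, hc_rec.log10_pgen]),
        np.concatenate([case_rec.log10_abundance, hc_rec.log10_abundance]),
        np.concatenate([np.zeros(len(case_rec)), np.ones(len(hc_rec))]),
    )
    summary = pg.subsample_interaction(
        case_rec, hc_rec,
        n_per_cohort=min(config.pgen_n_per_cohort, len(case_rec), len(hc_rec)),
        iterations=config.pgen_iterations,
        seed=config.seed,
    )
    return {
        "full_fit": {"beta": full.beta.tolist(), "p_beta3": full.p_beta3, "n": full.n},
        "subsample": summary.to_dict(),
        "_subsample": summary,
        "_records": (case_rec, hc_rec),
    }


def discover_associated_motifs(
    dataset: StudyDataset,
    config: PipelineConfig | None = None,
    model: pg.PgenModel | None = None,
    db: list[SpecificityDbEntry] | None = None,
) -> dict:
    """Cluster, classify, filter and call disease-associated motifs.

    Convenience wrapper over the clustering and association stages (without the
    diversity/pGen stages); returns the group list, association results and the
    called groups.
    """
    config = config or PipelineConfig()
    model = model or pg.PgenModel()
    reference = clus.ReferenceRepertoire.from_model(
        model, n=config.reference_size, seed=config.seed + 104729
    )
    groups, cluster_summary = _cluster_stage(dataset, config, reference)
    assoc_out = _association_stage(dataset, groups, reference, config, db)
    return {
        "groups": groups,
        "cluster_summary": cluster_summary,
        "results": assoc_out["_results"],
        "tested_groups": assoc_out["_tested_groups"],
        "called_groups": assoc_out["_called_groups"],
        "clinical": assoc_out["_clinical"],
        "summary": {k: v for k, v in assoc_out.items() if not k.startswith("_")},
    }


def evaluate_recovery(
    called_groups: list[clus.SpecificityGroup], truth: SyntheticTruth
) -> dict:
    """Compare called disease-associated groups with the planted truth.

    A planted motif is recovered when some called group contains one of its
    member sequences; a called group is a false discovery when it contains no
    planted member sequence.
    """
    planted = [set(m.inner_seqs) for m in truth.motifs]
    all_planted = set().union(*planted) if planted else set()
    recovered = [
        any(set(g.unique_seqs) & p for g in called_groups) for p in planted
    ]
    false_calls = [g for g in called_groups if not (set(g.unique_seqs) & all_planted)]
    n_called = len(called_groups)
    return {
        "n_planted": len(planted),
        "n_recovered": int(sum(recovered)),
        "sensitivity": (sum(recovered) / len(planted)) if planted else None,
        "n_called": n_called,
        "n_false": len(false_calls),
        "fdr": (len(false_calls) / n_called) if n_called else 0.0,
    }


def run_pipeline(
    dataset: StudyDataset,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    truth: SyntheticTruth | None = None,
    db: list[SpecificityDbEntry] | None = None,
    model: pg.PgenModel | None = None,
) -> dict:
    """Run the full analysis and write the report bundle into ``out_dir``.

    ``truth`` (from the synthetic generator) adds a motif-recovery section and
    supplies the pGen model and specificity DB when not given explicitly.  Any
    stage failure raises with a stage label; outputs written so far remain.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config.hash()} seed={config.seed}"
    if model is None:
        model = truth.model if truth is not None else pg.PgenModel()
    if db is None and truth is not None:
        db = truth.specificity_db
    summary: dict = {"config_hash": config.hash(), "seed": config.seed}

    has_sg = any(rep.tissue == SG for rep in dataset.repertoires)
    reference = clus.ReferenceRepertoire.from_model(
        model, n=config.reference_size, seed=config.seed + 104729
    )

    stage = "sharing"
    try:
        if has_sg:
            sharing = _sharing_stage(dataset, config)
            rows = sharing.pop("_expansion_rows")
            _write_tsv(pd.DataFrame(rows), out / "expansions.tsv", stamp)
            _write_tsv(
                pd.DataFrame([
                    {"subset": k, **v["counts"], "fisher_p": v.get("fisher_p"),
                     "odds_ratio": v.get("odds_ratio")}
                    for k, v in sharing.items() if isinstance(v, dict) and "counts" in v
                ]),
                out / "sharing.tsv", stamp,
            )
            summary["sharing"] = sharing
        else:
            log.warning("no SG repertoires: skipping SG-versus-PB comparison")
            summary["sharing"] = None

        stage = "clustering"
        groups, cluster_summary = _cluster_stage(dataset, config, reference)
        summary["clustering"] = cluster_summary
        _write_tsv(
            pd.DataFrame([
                {"pattern": g.pattern, "type": g.group_type, "category": g.category,
                 "n_unique_seqs": g.size, "n_members": len(g.members),
                 "expansion_flag": g.expansion_flag}
                for g in groups if g.category != clus.PB_ONLY
            ]),
            out / "sg_groups.tsv", stamp,
        )

        stage = "association"
        if has_sg:
            assoc_out = _association_stage(dataset, groups, reference, config, db)
            results = assoc_out.pop("_results")
            assoc_out.pop("_tested_groups")
            called_groups = assoc_out.pop("_called_groups")
            clinical = assoc_out.pop("_clinical")
            public_table = assoc_out.pop("_public_table", None)
            _write_tsv(assoc.results_frame(results), out / "associations.tsv", stamp)
            _write_tsv(clinical, out / "clinical_correlations.tsv", stamp)
            if public_table is not None:
                _write_tsv(public_table, out / "public_specificities.tsv", stamp)
            summary["association"] = {k: v for k, v in assoc_out.items()
                                      if not k.startswith("_")}
            summary["association"]["clinical"] = clinical.to_dict(orient="records")
            if truth is not None:
                summary["recovery"] = evaluate_recovery(called_groups, truth)
        else:
            summary["association"] = None

        stage = "diversity"
        div_out = _diversity_stage(dataset)
        profiles = div_out.pop("_profiles")
        _write_tsv(div.profiles_frame(profiles), out / "diversity.tsv", stamp)
        summary["diversity"] = div_out

        stage = "pgen"
        pgen_out = _pgen_stage(dataset, model, config)
        sub = pgen_out.pop("_subsample")
        pgen_out.pop("_records")
        _write_tsv(sub.to_frame(), out / "pgen_subsample.tsv", stamp)
        summary["pgen"] = pgen_out
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    return summary


def report(out_dir: str | Path) -> dict:
    """Recompute headline counts from a cached report bundle (no re-analysis)."""
    out = Path(out_dir)
    summary = json.loads((out / "summary.json").read_text())
    refreshed = {"config_hash": summary.get("config_hash"), "seed": summary.get("seed")}
    for name in ("sharing", "associations", "diversity", "pgen_subsample"):
        path = out / f"{name}.tsv"
        if path.exists():
            df = pd.read_csv(path, sep="\t", comment="#")
            refreshed[f"n_rows_{name}"] = int(len(df))
    refreshed["summary"] = summary
    return refreshed
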