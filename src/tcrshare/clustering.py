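"""Specificity-group clustering of CDR3beta inner regions.

A deliberately simple, fully testable re-implementation of the GLIPH2 grouping
semantics:

* **global** groups: connected components of the graph joining equal-length
  inner sequences that differ at <= 1 position (found exactly with per-position
  wildcard hashing), named by a consensus pattern with ``%`` at variable
  positions;
* **local** groups: 3-/4-mers significantly enriched in the sample relative to
  a naive reference repertoire (one-sided Fisher, fold >= 10, p < 1e-3 by
  default), each defining a group of all sample sequences containing the k-mer;
* **scores**: Monte-Carlo p-values for V-gene bias, CDR3 length conservation
  and group size against the reference, using the randomised-tie rule so that
  p-values are exactly uniform under the null despite discrete statistics.

Discontinuous motifs and HLA scoring are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import CASE, CONTROL, PB, SG, StudyDataset, inner_region
from .pgen import PgenModel


@dataclass(frozen=True)
class MemberRecord:
    """One clonotype's participation in clustering."""

    seq: str            # inner amino-acid region
    junction_aa: str
    v_call: str
    j_call: str
    subject_id: str
    tissue: str
    cohort: str
    duplicate_count: int


@dataclass
class GroupScores:
    v_gene_bias_p: float | None
    length_conservation_p: float | None
    size_p: float | None

    def all_significant(self, alpha: float = 0.05) -> bool:
        ps = (self.v_gene_bias_p, self.length_conservation_p, self.size_p)
        return all(p is not None and p < alpha for p in ps)


@dataclass
class SpecificityGroup:
    pattern: str
    group_type: str                 # "global" | "local"
    members: list[MemberRecord]
    scores: GroupScores | None = None
    category: str | None = None     # sharing category, see classify_shared_groups
    expansion_flag: bool | None = None

    @property
    def unique_seqs(self) -> list[str]:
        return sorted({m.seq for m in self.members})

    @property
    def size(self) -> int:
        return len(self.unique_seqs)

    def subjects(self, tissue: str | None = None, cohort: str | None = None) -> set[str]:
        return {
            m.subject_id
            for m in self.members
            if (tissue is None or m.tissue == tissue) and (cohort is None or m.cohort == cohort)
        }

    def matches(self, seq: str) -> bool:
        """Does ``seq`` match the group's pattern (``%`` = single-char wildcard)?"""
        if self.group_type == "local":
            return self.pattern in seq
        if len(seq) != len(self.pattern):
            return False
        return all(p == "%" or p == s for p, s in zip(self.pattern, seq))


def clustering_records(dataset: StudyDataset, trim: tuple[int, int] = (3, 2)) -> list[MemberRecord]:
    """Flatten a study into clustering members; junctions too short to trim are excluded."""
    out = []
    th, tt = trim
    for rep in dataset.repertoires:
        for c in rep.clonotypes:
            if len(c.junction_aa) <= th + tt:
                continue
            out.append(
                MemberRecord(
                    seq=inner_region(c.junction_aa, th, tt),
                    junction_aa=c.junction_aa,
                    v_call=c.v_call,
                    j_call=c.j_call,
                    subject_id=c.subject_id,
                    tissue=c.tissue,
                    cohort=c.cohort,
                    duplicate_count=c.duplicate_count,
                )
            )
    return out


def name_pattern(member_seqs: list[str]) -> str:
    """Consensus pattern with ``%`` at every position where members differ."""
    if not member_seqs:
        raise ValueError("empty member set")
    L = len(member_seqs[0])
    if any(len(s) != L for s in member_seqs):
        raise ValueError("member sequences must have equal length")
    return "".join(
        member_seqs[0][i] if len({s[i] for s in member_seqs}) == 1 else "%" for i in range(L)
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def hamming1_components(seqs: list[str]) -> list[list[str]]:
    """Connected components under 'equal length and Hamming distance <= 1'.

    Exact: two equal-length sequences differ at <= 1 position iff they share a
    masked key (one position replaced by ``%``) or are identical, so a single
    hashing pass per position finds every edge.
    """
    uniq = sorted(set(seqs))
    uf = _UnionFind(len(uniq))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(uniq):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in by_len.items():
        for pos in range(L):
            buckets: dict[str, int] = {}
            for i in idxs:
                key = uniq[i][:pos] + "%" + uniq[i][pos + 1 :]
                if key in buckets:
                    uf.union(buckets[key], i)
                else:
                    buckets[key] = i
    comps: dict[int, list[str]] = {}
    for i, s in enumerate(uniq):
        comps.setdefault(uf.find(i), []).append(s)
    return sorted(comps.values())


def _brute_force_components(seqs: list[str], max_mismatch: int) -> list[list[str]]:
    uniq = sorted(set(seqs))
    uf = _UnionFind(len(uniq))
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            a, b = uniq[i], uniq[j]
            if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= max_mismatch:
                uf.union(i, j)
    comps: dict[int, list[str]] = {}
    for i, s in enumerate(uniq):
        comps.setdefault(uf.find(i), []).append(s)
    return sorted(comps.values())


def global_clusters(records: list[MemberRecord], max_mismatch: int = 1) -> list[SpecificityGroup]:
    """Global specificity groups; components with a single unique sequence are dropped."""
    seqs = [m.seq for m in records]
    if max_mismatch == 1:
        comps = hamming1_components(seqs)
    else:  # small inputs only
        comps = _brute_force_components(seqs, max_mismatch)
    by_seq: dict[str, list[MemberRecord]] = {}
    for m in records:
        by_seq.setdefault(m.seq, []).append(m)
    groups = []
    for comp in comps:
        if len(comp) < 2:
            continue
        members = [m for s in comp for m in by_seq[s]]
        groups.append(SpecificityGroup(pattern=name_pattern(comp), group_type="global", members=members))
    return groups


# ---------------------------------------------------------------------------
# reference repertoire and scoring
# ---------------------------------------------------------------------------

class ReferenceRepertoire:
    """Naive background sample used for enrichment and score nulls."""

    def __init__(self, inner_seqs: list[str], v_calls: list[str]) -> None:
        if not inner_seqs:
            raise ValueError("reference repertoire is empty")
        self.inner_seqs = list(inner_seqs)
        self.v_calls = list(v_calls)
        vs, vc = np.unique(self.v_calls, return_counts=True)
        self._v_levels = list(vs)
        self._v_probs = vc / vc.sum()
        ls, lc = np.unique([len(s) for s in self.inner_seqs], return_counts=True)
        self._l_levels = ls.astype(int)
        self._l_probs = lc / lc.sum()
        self._kmer_cache: dict[int, dict[str, int]] = {}
        self._null_sizes_cache: dict[tuple[int, int, int], np.ndarray] = {}

    @classmethod
    def from_model(cls, model: PgenModel, n: int = 10_000, seed: int = 12345) -> "ReferenceRepertoire":
        from .simulate import _draw_vj  # local import; simulate does not import this module

        rng = np.random.default_rng(seed)
        inner = model.sample_inner(rng, n)
        vs, _ = _draw_vj(rng, n)
        return cls(inner, vs)

    def v_usage(self, v_call: str) -> float:
        try:
            return float(self._v_probs[self._v_levels.index(v_call)])
        except ValueError:
            return 0.0

    def kmer_counts(self, k: int) -> dict[str, int]:
        """Number of reference sequences containing each k-mer (cached)."""
        if k not in self._kmer_cache:
            counts: dict[str, int] = {}
            for s in self.inner_seqs:
                for km in {s[i : i + k] for i in range(len(s) - k + 1)}:
                    counts[km] = counts.get(km, 0) + 1
            self._kmer_cache[k] = counts
        return self._kmer_cache[k]

    def null_component_sizes(self, sample_size: int, n_rep: int = 20, seed: int = 0) -> np.ndarray:
        """Pooled sizes (>= 2 unique sequences) of global components arising in
        random reference subsamples of ``sample_size`` — the size-score null."""
        key = (sample_size, n_rep, seed)
        if key not in self._null_sizes_cache:
            rng = np.random.default_rng(seed)
            sizes: list[int] = []
            n = len(self.inner_seqs)
            for _ in range(n_rep):
                idx = rng.choice(n, size=min(sample_size, n), replace=sample_size > n)
                comps = hamming1_components([self.inner_seqs[i] for i in idx])
                sizes.extend(len(c) for c in comps if len(c) >= 2)
            self._null_sizes_cache[key] = np.asarray(sizes if sizes else [2], dtype=np.int64)
        return self._null_sizes_cache[key]


def _randomized_tail_p(t_obs: float, t_null: np.ndarray, rng: np.random.Generator) -> float:
    """Upper-tail Monte-Carlo p with the randomised tie rule.

    p = (#{T > t} + U * (1 + #{T == t})) / (n + 1) is exactly Uniform(0, 1)
    when t is an independent draw from the null, even for discrete T.
    """
    greater = int(np.sum(t_null > t_obs))
    equal = int(np.sum(t_null == t_obs))
    return (greater + rng.random() * (1 + equal)) / (len(t_null) + 1)


def score_group(
    group: SpecificityGroup,
    reference: ReferenceRepertoire,
    n_null: int = 1000,
    seed: int = 0,
    null_component_sizes: np.ndarray | None = None,
) -> GroupScores:
    """Monte-Carlo enrichment scores for one group (deterministic given seed).

    * ``v_gene_bias_p``: is the modal V-gene count among members higher than the
      modal count among equally many draws from reference V usage?
    * ``length_conservation_p``: same construction on the modal inner length.
    * ``size_p``: is the group's unique-sequence count large relative to global
      components arising in reference subsamples (``null_component_sizes``)?

    Single-member groups are degenerate: all scores are ``None``.
    """
    if n_null < 100:
        import logging

        logging.getLogger(__name__).warning("n_null=%d is small; scores will be coarse", n_null)
    members = group.members
    m = len({(mm.seq, mm.subject_id) for mm in members})
    if m < 2:
        return GroupScores(None, None, None)
    rng = np.random.default_rng(seed)

    v_calls = [mm.v_call for mm in members]
    obs_v = max(np.unique(v_calls, return_counts=True)[1])
    draws = rng.choice(len(reference._v_levels), size=(n_null, len(v_calls)), p=reference._v_probs)
    null_v = np.zeros(n_null, dtype=np.int64)
    for g in range(len(reference._v_levels)):
        null_v = np.maximum(null_v, (draws == g).sum(axis=1))
    v_p = _randomized_tail_p(float(obs_v), null_v.astype(float), rng)

    lengths = [len(mm.seq) for mm in members]
    obs_l = max(np.unique(lengths, return_counts=True)[1])
    draws = rng.choice(len(reference._l_levels), size=(n_null, len(lengths)), p=reference._l_probs)
    null_l = np.zeros(n_null, dtype=np.int64)
    for g in range(len(reference._l_levels)):
        null_l = np.maximum(null_l, (draws == g).sum(axis=1))
    l_p = _randomized_tail_p(float(obs_l), null_l.astype(float), rng)

    sizes = (
        null_component_sizes
        if null_component_sizes is not None
        else reference.null_component_sizes(sample_size=2000, seed=seed)
    )
    s_p = _randomized_tail_p(float(group.size), sizes.astype(float), rng)
    return GroupScores(v_gene_bias_p=v_p, length_conservation_p=l_p, size_p=s_p)


def local_motifs(
    sample_records: list[MemberRecord],
    reference: ReferenceRepertoire,
    ks: tuple[int, ...] = (3, 4),
    p_threshold: float = 1e-3,
    min_fold: float = 10.0,
    min_sample_count: int = 2,
) -> list[SpecificityGroup]:
    """Locally enriched k-mer motifs versus the reference repertoire.

    For each k-mer, a one-sided Fisher exact test compares the number of sample
    sequences containing it with the reference; k-mers passing both the fold
    and p thresholds each define a local group.
    """
    sample_seqs = sorted({m.seq for m in sample_records})
    if not reference.inner_seqs:
        raise ValueError("empty reference")
    n_s = len(sample_seqs)
    n_r = len(reference.inner_seqs)
    groups: list[SpecificityGroup] = []
    by_seq: dict[str, list[MemberRecord]] = {}
    for m in sample_records:
        by_seq.setdefault(m.seq, []).append(m)
    for k in ks:
        ref_counts = reference.kmer_counts(k)
        counts: dict[str, int] = {}
        for s in sample_seqs:
            for km in {s[i : i + k] for i in range(len(s) - k + 1)}:
                counts[km] = counts.get(km, 0) + 1
        for km in sorted(counts):
            a = counts[km]
            if a < min_sample_count:
                continue
            b = ref_counts.get(km, 0)
            fold = (a / n_s) / (b / n_r) if b else float("inf")
            if fold < min_fold:
                continue
            p = float(stats.fisher_exact([[a, n_s - a], [b, n_r - b]], alternative="greater").pvalue)
            if p >= p_threshold:
                continue
            members = [m for s in sample_seqs if km in s for m in by_seq[s]]
            groups.append(SpecificityGroup(pattern=km, group_type="local", members=members))
    return groups


# ---------------------------------------------------------------------------
# sharing categories and filters
# ---------------------------------------------------------------------------

SG_ONLY = "SG-only"
SG_CASE_PB = "SG+casePB"
SG_HC_PB = "SG+hcPB"
SG_BOTH = "SG+both"
PB_ONLY = "PB-only"


def classify_shared_groups(groups: list[SpecificityGroup], min_cells: int = 2) -> dict[str, int]:
    """Annotate each group's sharing category and SG-expansion flag in place.

    Groups with >= 1 SG member are partitioned into {SG-only, SG+casePB,
    SG+hcPB, SG+both}; the rest are PB-only.  ``expansion_flag`` marks groups
    containing a clonally expanded SG clonotype (>= min_cells cells).
    """
    counts = {SG_ONLY: 0, SG_CASE_PB: 0, SG_HC_PB: 0, SG_BOTH: 0, PB_ONLY: 0}
    for g in groups:
        has_sg = any(m.tissue == SG for m in g.members)
        case_pb = any(m.tissue == PB and m.cohort == CASE for m in g.members)
        hc_pb = any(m.tissue == PB and m.cohort == CONTROL for m in g.members)
        if not has_sg:
            g.category = PB_ONLY
        elif case_pb and hc_pb:
            g.category = SG_BOTH
        elif case_pb:
            g.category = SG_CASE_PB
        elif hc_pb:
            g.category = SG_HC_PB
        else:
            g.category = SG_ONLY
        g.expansion_flag = any(
            m.tissue == SG and m.duplicate_count >= min_cells for m in g.members
        )
        counts[g.category] += 1
    return counts


def filter_shared_groups(
    groups: list[SpecificityGroup], alpha: float = 0.05, min_unique_members: int = 3
) -> list[SpecificityGroup]:
    """'Filter 1': groups whose three scores are all < alpha and that contain at
    least ``min_unique_members`` unique sequences."""
    out = []
    for g in groups:
        if g.scores is None:
            continue
        if g.size >= min_unique_members and g.scores.all_significant(alpha):
            out.append(g)
    return out


def write_gliph2_input(records: list[MemberRecord], path: str | Path) -> None:
    """Write a GLIPH2-compatible input TSV for cross-checking with the real tool."""
    rows = [
        {
            "CDR3b": m.junction_aa,
            "TRBV": m.v_call,
            "TRBJ": m.j_call,
            "CDR3a": "NA",
            "subject:condition": f"{m.subject_id}:{m.tissue}_{m.cohort}",
            "count": m.duplicate_count,
        }
        for m in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
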