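"""Core data types and I/O for CDR3beta repertoire studies.

A *clonotype* is a unique nucleotide junction (+ V/J call) within one subject's
repertoire, carrying a cDNA/UMI abundance (``duplicate_count``).  Repertoires come
from two compartments: salivary gland (``SG``, cases only in this study design,
one record per recovered cell aggregated to clonotypes) and peripheral blood
(``PB``, deep-sequenced).  Files follow the AIRR Rearrangement TSV convention
(MiAIRR column names); subject metadata and clinical features travel in sidecar
CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

log = logging.getLogger(__name__)

SG = "SG"
PB = "PB"
CASE = "CASE"
CONTROL = "CONTROL"

#: MiAIRR columns required from a rearrangement TSV.
AIRR_COLUMNS = ("junction", "junction_aa", "v_call", "j_call", "duplicate_count", "repertoire_id")

#: Synonymous codons per amino acid (standard table), used by the generator's
#: reverse translation and by nucleotide-level pGen factors.
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, tuple())
    CODONS_BY_AA[_aa] = CODONS_BY_AA[_aa] + (_codon,)
CODONS_BY_AA["*"] = tuple(standard_dna_table.stop_codons)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """Raised when an input table is missing required columns."""


def translate(junction_nt: str) -> str:
    """Translate a frame-complete nucleotide junction with the standard table.

    Stop codons are emitted as ``"*"``.  Raises ``ValueError`` on non-ACGT
    symbols or a length not divisible by 3.
    """
    nt = junction_nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"junction length {len(nt)} not divisible by 3")
    if set(nt) - set("ACGT"):
        raise ValueError(f"non-ACGT symbol in junction: {junction_nt!r}")
    return str(Seq(nt).translate())


def inner_region(junction_aa: str, trim_head: int = 3, trim_tail: int = 2) -> str:
    """Trim the junction to the high-probability antigen-contact inner region.

    By default the first three residues (canonical ``C`` plus two V-templated
    positions) and last two (J-templated) are removed; motif patterns are
    defined on this inner region.  Raises ``ValueError`` when the junction is
    too short to trim (callers exclude such sequences from clustering).
    """
    if len(junction_aa) <= trim_head + trim_tail:
        raise ValueError(f"junction {junction_aa!r} too short for ({trim_head},{trim_tail}) trim")
    return junction_aa[trim_head : len(junction_aa) - trim_tail]


@dataclass(frozen=True)
class Clonotype:
    junction_nt: str
    junction_aa: str
    v_call: str
    j_call: str
    duplicate_count: int
    subject_id: str
    tissue: str  # SG | PB
    cohort: str  # CASE | CONTROL

    def inner_aa(self, trim_head: int = 3, trim_tail: int = 2) -> str:
        return inner_region(self.junction_aa, trim_head, trim_tail)

    def key(self, level: str = "nt") -> tuple:
        """Clonotype identity key: ``nt`` (junction_nt, V, J) or ``aa`` (junction_aa)."""
        if level == "nt":
            return (self.junction_nt, self.v_call, self.j_call)
        if level == "aa":
            return (self.junction_aa,)
        raise ValueError(f"unknown identity level {level!r}")


@dataclass
class Repertoire:
    subject_id: str
    tissue: str
    cohort: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    n_cells: int | None = None  # SG only: number of sorted TCRbeta+ cells

    @property
    def total_count(self) -> int:
        return sum(c.duplicate_count for c in self.clonotypes)

    @property
    def n_unique(self) -> int:
        return len(self.clonotypes)

    def counts(self) -> np.ndarray:
        return np.asarray([c.duplicate_count for c in self.clonotypes], dtype=np.int64)

    def aa_set(self) -> set[str]:
        return {c.junction_aa for c in self.clonotypes}

    def nt_index(self) -> dict[tuple, Clonotype]:
        return {c.key("nt"): c for c in self.clonotypes}


@dataclass
class SubjectRecord:
    subject_id: str
    cohort: str
    age: float | None = None
    sex: str | None = None
    WUSF: float | None = None
    ESSDAI: float | None = None
    OSS: float | None = None
    schirmer: float | None = None
    serum_IgG: float | None = None
    focus_score: float | None = None
    acr_eular_weighted: float | None = None
    anti_Ro: bool | None = None
    anti_La: bool | None = None

CLINICAL_FEATURES = (
    "WUSF", "ESSDAI", "OSS", "schirmer", "serum_IgG", "focus_score", "acr_eular_weighted",
)


@dataclass
class SpecificityDbEntry:
    cdr3_aa: str
    pathogen_or_antigen: str
    v_call: str | None = None


@dataclass
class StudyDataset:
    """All repertoires of both cohorts plus the clinical table.

    ``min_pb_clonotypes`` / ``min_sg_cells`` are the adequate-sampling
    thresholds (strict ``>``) applied before any cohort-level statistic.
    """

    subjects: list[SubjectRecord]
    repertoires: list[Repertoire]
    min_pb_clonotypes: int = 25_000
    min_sg_cells: int = 40

    def __post_init__(self) -> None:
        known = {s.subject_id for s in self.subjects}
        for rep in self.repertoires:
            if rep.subject_id not in known:
                raise ValueError(f"repertoire subject {rep.subject_id!r} missing from clinical table")

    def subject(self, subject_id: str) -> SubjectRecord:
        return next(s for s in self.subjects if s.subject_id == subject_id)

    def repertoire(self, subject_id: str, tissue: str) -> Repertoire | None:
        for rep in self.repertoires:
            if rep.subject_id == subject_id and rep.tissue == tissue:
                return rep
        return None

    def cohort_subjects(self, cohort: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.cohort == cohort]

    def pb_adequate(self, subject_id: str) -> bool:
        rep = self.repertoire(subject_id, PB)
        return rep is not None and rep.n_unique > self.min_pb_clonotypes

    def sg_adequate(self, subject_id: str) -> bool:
        rep = self.repertoire(subject_id, SG)
        if rep is None:
            return False
        n_cells = rep.n_cells if rep.n_cells is not None else rep.total_count
        return n_cells > self.min_sg_cells

    def adequate_pb_subjects(self, cohort: str | None = None) -> list[str]:
        out = []
        for s in self.subjects:
            if cohort is not None and s.cohort != cohort:
                continue
            if self.pb_adequate(s.subject_id):
                out.append(s.subject_id)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _productive(junction_nt: str, junction_aa: str) -> bool:
    return len(junction_nt) % 3 == 0 and "*" not in junction_aa and len(junction_nt) > 0


def read_airr(
    path: str | Path,
    metadata: Mapping[str, tuple[str, str, str]] | pd.DataFrame | None = None,
) -> list[Repertoire]:
    """Read an AIRR Rearrangement TSV into aggregated :class:`Repertoire` objects.

    ``metadata`` maps ``repertoire_id`` to ``(subject_id, tissue, cohort)``;
    alternatively those three columns may be present in the TSV itself.  Rows
    sharing (junction, v_call, j_call) within a repertoire are merged with
    counts summed; unproductive rows (stop codon or out-of-frame junction) are
    dropped and the drop count logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        log.warning("empty rearrangement file %s", path)
        return []
    missing = [c for c in AIRR_COLUMNS if c not in df.columns and c != "junction_aa"]
    # junction_aa is recomputable; everything else is required
    if missing:
        raise FormatError(f"missing required AIRR columns: {missing}")
    if df.empty:
        log.warning("rearrangement file %s has no rows", path)
        return []

    if isinstance(metadata, pd.DataFrame):
        metadata = {
            str(r.repertoire_id): (str(r.subject_id), str(r.tissue), str(r.cohort))
            for r in metadata.itertuples()
        }

    df["duplicate_count"] = df["duplicate_count"].astype(int)
    keep = df["junction"].map(lambda nt: isinstance(nt, str) and len(nt) % 3 == 0 and len(nt) > 0)
    n_dropped = int((~keep).sum())
    df = df[keep].copy()
    df["junction_aa"] = df["junction"].map(translate)
    productive = ~df["junction_aa"].str.contains(r"\*", regex=True)
    n_dropped += int((~productive).sum())
    df = df[productive]
    if n_dropped:
        log.info("dropped %d unproductive rows from %s", n_dropped, path)

    reps: list[Repertoire] = []
    for rep_id, sub in df.groupby("repertoire_id", sort=True):
        if metadata is not None:
            subject_id, tissue, cohort = metadata[str(rep_id)]
        else:
            try:
                subject_id = str(sub["subject_id"].iloc[0])
                tissue = str(sub["tissue"].iloc[0])
                cohort = str(sub["cohort"].iloc[0])
            except KeyError as exc:
                raise FormatError(
                    "no metadata mapping given and subject_id/tissue/cohort columns absent"
                ) from exc
        agg = (
            sub.groupby(["junction", "v_call", "j_call"], sort=True)["duplicate_count"]
            .sum()
            .reset_index()
        )
        clonotypes = [
            Clonotype(
                junction_nt=row.junction,
                junction_aa=translate(row.junction),
                v_call=row.v_call,
                j_call=row.j_call,
                duplicate_count=int(row.duplicate_count),
                subject_id=subject_id,
                tissue=tissue,
                cohort=cohort,
            )
            for row in agg.itertuples()
        ]
        reps.append(Repertoire(subject_id=subject_id, tissue=tissue, cohort=cohort, clonotypes=clonotypes))
    return reps


def write_airr(repertoires: Iterable[Repertoire], path: str | Path) -> None:
    """Write repertoires as an AIRR Rearrangement TSV (one row per clonotype)."""
    rows = []
    for rep in repertoires:
        rep_id = f"{rep.subject_id}_{rep.tissue}"
        for c in rep.clonotypes:
            rows.append(
                {
                    "repertoire_id": rep_id,
                    "subject_id": rep.subject_id,
                    "tissue": rep.tissue,
                    "cohort": rep.cohort,
                    "junction": c.junction_nt,
                    "junction_aa": c.junction_aa,
                    "v_call": c.v_call,
                    "j_call": c.j_call,
                    "duplicate_count": c.duplicate_count,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _coerce(value, typ):
    if pd.isna(value):
        return None
    if typ is bool:
        return str(value).strip().lower() in {"1", "true", "yes", "y"}
    return typ(value)


def read_clinical(path: str | Path) -> list[SubjectRecord]:
    """Read the per-subject clinical CSV (any clinical field may be missing)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "cohort" not in df.columns:
        raise FormatError("clinical CSV requires subject_id and cohort columns")
    numeric = {f.name: float for f in dc_fields(SubjectRecord)}
    numeric.update({"subject_id": str, "cohort": str, "sex": str, "anti_Ro": bool, "anti_La": bool})
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for f in dc_fields(SubjectRecord):
            if hasattr(row, f.name):
                kwargs[f.name] = _coerce(getattr(row, f.name), numeric[f.name])
        records.append(SubjectRecord(**kwargs))
    if len({r.subject_id for r in records}) != len(records):
        raise FormatError("duplicate subject_id in clinical CSV")
    return records


def write_clinical(subjects: Iterable[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in subjects]).to_csv(path, index=False)


def read_specificity_db(path: str | Path) -> list[SpecificityDbEntry]:
    """Read a McPAS/VDJdb/TBAdb-style TSV of (cdr3_aa, pathogen/antigen, optional v_call)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        cdr3 = cols["cdr3_aa"]
    except KeyError as exc:
        raise FormatError("specificity DB requires a cdr3_aa column") from exc
    label = cols.get("pathogen") or cols.get("antigen") or cols.get("pathogen_or_antigen")
    if label is None:
        raise FormatError("specificity DB requires a pathogen/antigen column")
    vcol = cols.get("v_call")
    out = []
    for row in df.itertuples(index=False):
        aa = getattr(row, cdr3)
        if not isinstance(aa, str) or not aa:
            continue
        out.append(
            SpecificityDbEntry(
                cdr3_aa=aa,
                pathogen_or_antigen=str(getattr(row, label)),
                v_call=(getattr(row, vcol) if vcol and isinstance(getattr(row, vcol), str) else None),
            )
        )
    return out


def write_specificity_db(entries: Iterable[SpecificityDbEntry], path: str | Path) -> None:
    pd.DataFrame(
        [{"cdr3_aa": e.cdr3_aa, "pathogen": e.pathogen_or_antigen, "v_call": e.v_call} for e in entries]
    ).to_csv(path, sep="\t", index=False)
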