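"""SG clonal expansions, SG<->PB sharing classification, exact 2x2 tests and
convergent-recombination summaries.

A *clonal expansion* is >= 2 cells in an SG sample carrying a nucleotide-identical
CDR3beta.  Sharing between an SG clonotype set and pooled cohort PB repertoires
is classified into {SG-only, case-PB-only, HC-PB-only, both}; cohort asymmetry
is tested with a two-sided Fisher exact test on the table

    rows    = cohort PB (case, control)
    columns = SG clonotype detected / not detected in that cohort's PB

restricted to SG clonotypes found in any PB ("both" counts as detected in each
row).  Cross-subject comparison defaults to amino-acid identity; same-subject
overrepresentation uses nucleotide identity.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .model import Clonotype, Repertoire


@dataclass
class SharingTable:
    n_sg_only: int
    n_case_pb_only: int
    n_hc_pb_only: int
    n_both: int

    @property
    def n_total(self) -> int:
        return self.n_sg_only + self.n_case_pb_only + self.n_hc_pb_only + self.n_both

    @property
    def n_in_pb(self) -> int:
        return self.n_case_pb_only + self.n_hc_pb_only + self.n_both

    def pb_proportions(self) -> dict[str, float]:
        """Proportions over the in-PB subset (case-only, hc-only, both)."""
        n = self.n_in_pb
        if n == 0:
            return {"case_pb_only": 0.0, "hc_pb_only": 0.0, "both": 0.0}
        return {
            "case_pb_only": self.n_case_pb_only / n,
            "hc_pb_only": self.n_hc_pb_only / n,
            "both": self.n_both / n,
        }

    def fisher_table(self) -> list[list[int]]:
        """Cohort-detection 2x2 table (restricted to SG clonotypes found in any PB)."""
        case_detected = self.n_case_pb_only + self.n_both
        hc_detected = self.n_hc_pb_only + self.n_both
        return [[case_detected, self.n_hc_pb_only], [hc_detected, self.n_case_pb_only]]


@dataclass
class ExpansionRecord:
    clonotype: Clonotype
    n_cells: int
    pb_copies_same_subject: int | None = None
    overrepresented: bool | None = None


def detect_expansions(sg: Repertoire, min_cells: int = 2) -> tuple[list[ExpansionRecord], float]:
    """Return SG clonotypes carried by >= min_cells cells and the expanded cell fraction."""
    records = [
        ExpansionRecord(clonotype=c, n_cells=c.duplicate_count)
        for c in sg.clonotypes
        if c.duplicate_count >= min_cells
    ]
    total = sg.total_count
    expanded_cells = sum(r.n_cells for r in records)
    fraction = expanded_cells / total if total else 0.0
    return records, fraction


def _key(c: Clonotype, key: str) -> str:
    if key == "aa":
        return c.junction_aa
    if key == "nt":
        return c.junction_nt
    raise ValueError(f"unknown sharing key {key!r}")


def classify_sharing(
    sg_clonotypes: list[Clonotype] | set[str],
    case_pb_union: set[str],
    hc_pb_union: set[str],
    key: str = "aa",
) -> SharingTable:
    """Assign each SG clonotype to exactly one sharing category.

    ``sg_clonotypes`` may be Clonotype objects (keyed by ``key``) or a pre-keyed
    set of strings; the PB unions are keyed sets pooled over the adequately
    sampled subjects of each cohort.
    """
    if sg_clonotypes and isinstance(next(iter(sg_clonotypes)), Clonotype):
        sg_keys = {_key(c, key) for c in sg_clonotypes}
    else:
        sg_keys = set(sg_clonotypes)
    n_sg_only = n_case = n_hc = n_both = 0
    for k in sg_keys:
        in_case = k in case_pb_union
        in_hc = k in hc_pb_union
        if in_case and in_hc:
            n_both += 1
        elif in_case:
            n_case += 1
        elif in_hc:
            n_hc += 1
        else:
            n_sg_only += 1
    return SharingTable(n_sg_only=n_sg_only, n_case_pb_only=n_case, n_hc_pb_only=n_hc, n_both=n_both)


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(p, odds_ratio)``; the p-value sums hypergeometric outcomes with
    probability <= the observed table's, the mainstream two-sided convention.
    The odds ratio is the sample ratio ad/bc (``inf`` when bc == 0 with ad > 0,
    ``nan`` for 0/0).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 table entries must be non-negative")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return p, odds


def detect_overrepresented(
    expansions: list[ExpansionRecord],
    pb_same_subject: Repertoire | None,
    min_copies: int = 5,
) -> list[ExpansionRecord]:
    """Flag expansions whose nucleotide-identical clonotype has >= min_copies in the
    same subject's PB.  With no PB repertoire all flags stay ``None``."""
    if pb_same_subject is None:
        for r in expansions:
            r.pb_copies_same_subject = None
            r.overrepresented = None
        return expansions
    pb_counts: dict[str, int] = {}
    for c in pb_same_subject.clonotypes:
        pb_counts[c.junction_nt] = pb_counts.get(c.junction_nt, 0) + c.duplicate_count
    for r in expansions:
        copies = pb_counts.get(r.clonotype.junction_nt, 0)
        r.pb_copies_same_subject = copies
        r.overrepresented = copies >= min_copies
    return expansions


def convergence_summary(repertoire: Repertoire) -> tuple[dict[str, int], float]:
    """Count distinct nucleotide encodings per amino-acid clonotype.

    Returns the aa -> encoding-count map and the fraction of aa clonotypes with
    >= 2 encodings (convergent recombination).
    """
    encodings: dict[str, set[str]] = {}
    for c in repertoire.clonotypes:
        encodings.setdefault(c.junction_aa, set()).add(c.junction_nt)
    counts = {aa: len(nts) for aa, nts in encodings.items()}
    if not counts:
        return {}, 0.0
    frac = sum(1 for v in counts.values() if v >= 2) / len(counts)
    return counts, frac
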