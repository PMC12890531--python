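"""Generation probability (pGen) model and the abundance x cohort interaction regression.

The package uses a simplified, fully closed-form generative model for CDR3beta
amino-acid sequences: an inner-region length distribution ``P_L`` and a
position-independent residue distribution ``P_A``, so that

    pGen(a_1..a_L) = P_L(L) * prod_i P_A(a_i).

This replaces a full V(D)J recombination model: it preserves the analysis
semantics (every sequence has an exact, known generation probability and
high-abundance/high-pGen coupling can be planted and recovered) without
recombination machinery.  Externally computed per-clonotype pGen values (e.g.
OLGA output) can be supplied via TSV and used in place of the model.

The regression mirrors the "private repertoire" analysis: regress log10 pGen on
log10 mean clonotype abundance, a cohort indicator, and their interaction; a
positive interaction coefficient (beta3) means pGen rises faster with abundance
in controls than in cases, i.e. abundant case clonotypes are *not* explained by
recombination bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .model import AMINO_ACIDS, CODONS_BY_AA, CONTROL, PB, StudyDataset, inner_region

#: Default inner-region length distribution (lengths 7-13; junction lengths
#: 12-18, matching typical human CDR3beta repertoires).
DEFAULT_INNER_LENGTH_PROBS: dict[int, float] = {
    7: 0.10, 8: 0.16, 9: 0.22, 10: 0.20, 11: 0.14, 12: 0.10, 13: 0.08,
}

#: Default CDR3-like amino-acid frequencies (glycine/serine rich, cysteine rare).
DEFAULT_AA_PROBS: dict[str, float] = {
    "G": 0.11, "S": 0.10, "L": 0.10, "A": 0.07, "E": 0.06, "T": 0.06, "R": 0.06,
    "Q": 0.05, "P": 0.05, "V": 0.05, "D": 0.05, "N": 0.04, "Y": 0.04, "F": 0.04,
    "I": 0.03, "K": 0.03, "H": 0.02, "W": 0.02, "M": 0.015, "C": 0.005,
}


@dataclass
class PgenModel:
    """Closed-form amino-acid-level generation-probability model."""

    length_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_INNER_LENGTH_PROBS))
    aa_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_PROBS))

    def __post_init__(self) -> None:
        for name, probs in (("length", self.length_probs), ("amino-acid", self.aa_probs)):
            total = float(sum(probs.values()))
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"{name} distribution sums to {total}, expected 1")
        self._lengths = np.array(sorted(self.length_probs), dtype=np.int64)
        self._pl = np.array([self.length_probs[l] for l in self._lengths])
        self._alphabet = "".join(sorted(self.aa_probs))
        self._pa = np.array([self.aa_probs[a] for a in self._alphabet])
        self._aa_index = {a: i for i, a in enumerate(self._alphabet)}

    # -- probabilities ------------------------------------------------------

    def pgen(self, inner_aa: str) -> float:
        """Exact amino-acid-level generation probability of an inner sequence."""
        pl = self.length_probs.get(len(inner_aa), 0.0)
        p = pl
        for a in inner_aa:
            if a not in self.aa_probs:
                raise ValueError(f"residue {a!r} not in model alphabet")
            p *= self.aa_probs[a]
        return p

    def log10_pgen(self, inner_aa: str) -> float:
        return float(np.log10(self.pgen(inner_aa)))

    @staticmethod
    def nt_factor(junction_aa: str) -> float:
        """Probability of one particular synonymous encoding of ``junction_aa``.

        Codons are drawn uniformly per residue, so the factor is the product of
        1/(number of synonymous codons).  Multiplying the amino-acid pGen by this
        factor gives the probability of one specific nucleotide encoding, and
        summing over all encodings recovers the amino-acid pGen.
        """
        f = 1.0
        for a in junction_aa:
            f /= len(CODONS_BY_AA[a])
        return f

    # -- sampling (used by the synthetic-study generator) -------------------

    def sample_inner(self, rng: np.random.Generator, n: int) -> list[str]:
        """Vectorised draw of ``n`` inner amino-acid sequences."""
        lengths = rng.choice(self._lengths, size=n, p=self._pl)
        out = [""] * n
        order = np.argsort(lengths, kind="stable")
        pos = 0
        for L in np.unique(lengths):
            idx = order[pos : pos + int((lengths == L).sum())]
            pos += len(idx)
            mat = rng.choice(len(self._alphabet), size=(len(idx), int(L)), p=self._pa)
            for row, i in zip(mat, idx):
                out[i] = "".join(self._alphabet[j] for j in row)
        return out


def read_pgen_tsv(path: str | Path) -> dict[str, float]:
    """Read externally computed pGen values (columns: junction_aa, pgen)."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.junction_aa): float(r.pgen) for r in df.itertuples()}


@dataclass
class GlmFit:
    """Fit of log10 pGen ~ log10 abundance * cohort (g = 1 for controls)."""

    beta: np.ndarray  # (intercept, abundance slope, cohort offset, interaction)
    se: np.ndarray
    pvalues: np.ndarray
    n: int

    @property
    def beta3(self) -> float:
        return float(self.beta[3])

    @property
    def p_beta3(self) -> float:
        return float(self.pvalues[3])


def interaction_glm(
    log10_pgen: np.ndarray, log10_abundance: np.ndarray, is_control: np.ndarray
) -> GlmFit:
    """Least-squares fit of ``y = b0 + b1*x + b2*g + b3*x*g``.

    ``y`` is log10 pGen, ``x`` log10 mean abundance and ``g`` the control-cohort
    indicator, so ``b3 > 0`` means control pGen rises faster with abundance.
    """
    y = np.asarray(log10_pgen, dtype=float)
    x = np.asarray(log10_abundance, dtype=float)
    g = np.asarray(is_control, dtype=float)
    if y.shape != x.shape or y.shape != g.shape:
        raise ValueError("input arrays must have identical shapes")
    if len(y) < 5:
        raise ValueError("need more than 4 records to identify 4 coefficients")
    for val in (0.0, 1.0):
        if np.count_nonzero(g == val) < 2:
            raise ValueError("need at least 2 records per cohort")
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("collinear design (constant abundance within a cohort?)")
    res = sm.OLS(y, X).fit()
    return GlmFit(beta=np.asarray(res.params), se=np.asarray(res.bse),
                  pvalues=np.asarray(res.pvalues), n=len(y))


def _fast_ols_beta3(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS returning (beta3, two-sided t-test p for beta3).

    Used inside the subsampling loop; agrees with :func:`interaction_glm`
    (statsmodels) to numerical precision.
    """
    xtx = X.T @ X
    xty = X.T @ y
    beta = np.linalg.solve(xtx, xty)
    resid = y - X @ beta
    dof = len(y) - 4
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se3 = float(np.sqrt(cov[3, 3]))
    t3 = float(beta[3]) / se3
    p3 = 2.0 * float(stats.t.sf(abs(t3), dof))
    return float(beta[3]), p3


@dataclass
class SubsampleSummary:
    beta3: np.ndarray
    p: np.ndarray
    n_per_cohort: int
    iterations: int

    @property
    def frac_positive(self) -> float:
        return float(np.mean(self.beta3 > 0))

    @property
    def frac_positive_significant(self) -> float:
        return float(np.mean((self.beta3 > 0) & (self.p < 0.05)))

    @property
    def mean_beta3(self) -> float:
        return float(np.mean(self.beta3))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": np.arange(self.iterations), "beta3": self.beta3, "p": self.p})

    def to_dict(self) -> dict:
        return {
            "n_per_cohort": self.n_per_cohort,
            "iterations": self.iterations,
            "frac_beta3_positive": self.frac_positive,
            "frac_beta3_positive_significant": self.frac_positive_significant,
            "mean_beta3": self.mean_beta3,
        }


def subsample_interaction(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    n_per_cohort: int = 10_000,
    iterations: int = 10_000,
    seed: int = 0,
) -> SubsampleSummary:
    """Repeat the interaction fit on random per-cohort subsamples of clonotypes.

    ``*_records`` need columns ``log10_pgen`` and ``log10_abundance`` (one row
    per unique clonotype).  Pools smaller than ``n_per_cohort`` are sampled with
    replacement (logged via a flag in the summary frame is unnecessary; the
    paper-style use has much larger pools).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pools = []
    for df in (case_records, control_records):
        if len(df) == 0:
            raise ValueError("empty record pool")
        pools.append((df["log10_pgen"].to_numpy(float), df["log10_abundance"].to_numpy(float)))
    beta3 = np.empty(iterations)
    pvals = np.empty(iterations)
    n = n_per_cohort
    y = np.empty(2 * n)
    X = np.ones((2 * n, 4))
    X[:n, 2] = 0.0  # cases
    X[n:, 2] = 1.0  # controls
    for it in range(iterations):
        for j, (py, px) in enumerate(pools):
            replace = len(py) < n
            idx = rng.choice(len(py), size=n, replace=replace)
            sl = slice(0, n) if j == 0 else slice(n, 2 * n)
            y[sl] = py[idx]
            X[sl, 1] = px[idx]
        X[:, 3] = X[:, 1] * X[:, 2]
        beta3[it], pvals[it] = _fast_ols_beta3(X, y)
    return SubsampleSummary(beta3=beta3, p=pvals, n_per_cohort=n, iterations=iterations)


def mean_abundance_records(
    dataset: StudyDataset,
    cohort: str,
    model: PgenModel | None = None,
    pgen_values: dict[str, float] | None = None,
    trim: tuple[int, int] = (3, 2),
) -> pd.DataFrame:
    """Per-unique-PB-clonotype regression records for one cohort.

    A clonotype is keyed by its amino-acid junction; its abundance is the mean
    ``duplicate_count`` over the adequately sampled subjects of the cohort in
    which it is detected (a declared aggregation choice), log10-transformed.
    pGen comes from ``pgen_values`` (external, keyed by junction_aa) or from the
    closed-form ``model`` applied to the inner region.
    """
    if (model is None) == (pgen_values is None):
        raise ValueError("supply exactly one of model / pgen_values")
    adequate = set(dataset.adequate_pb_subjects(cohort))
    totals: dict[str, list[int]] = {}
    for rep in dataset.repertoires:
        if rep.tissue != PB or rep.cohort != cohort or rep.subject_id not in adequate:
            continue
        per_subject: dict[str, int] = {}
        for c in rep.clonotypes:
            per_subject[c.junction_aa] = per_subject.get(c.junction_aa, 0) + c.duplicate_count
        for aa, cnt in per_subject.items():
            totals.setdefault(aa, []).append(cnt)
    rows = []
    for aa in sorted(totals):
        if pgen_values is not None:
            p = pgen_values.get(aa)
            if p is None or p <= 0:
                continue
        else:
            p = model.pgen(inner_region(aa, *trim))
            if p <= 0:
                continue
        rows.append(
            {
                "junction_aa": aa,
                "log10_pgen": float(np.log10(p)),
                "log10_abundance": float(np.log10(np.mean(totals[aa]))),
                "n_subjects_detected": len(totals[aa]),
            }
        )
    return pd.DataFrame(rows)
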