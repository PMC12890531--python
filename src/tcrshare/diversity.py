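"""Per-subject repertoire richness, diversity, rarefaction and abundance structure.

All estimators operate on an :class:`AbundanceSpectrum` — the clonotype count
vector with its frequency-of-frequencies representation (f_x = number of
clonotypes seen exactly x times).  Four indices mirror common repertoire
practice: chao1 (bias-corrected), the Efron-Thisted unseen-species estimate,
D50, and Shannon entropy (natural log).  Rarefaction is the exact hypergeometric
expectation; extrapolation uses the standard Chao-style f0-hat formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import PB, Repertoire, StudyDataset

#: Abundance-class boundaries as repertoire fractions.  The printed intervals
#: are open at both ends; a value equal to a boundary joins the larger class
#: (left-closed convention, declared).
ABUNDANCE_CLASSES = (
    ("rare", 0.0, 1e-5),        # 0 < x < 0.001 %
    ("small", 1e-5, 2.5e-4),    # 0.001 % <= x < 0.025 %
    ("moderate", 2.5e-4, 2.5e-3),
    ("large", 2.5e-3, float("inf")),
)


@dataclass
class AbundanceSpectrum:
    counts: np.ndarray

    def __init__(self, counts) -> None:
        c = np.asarray(list(counts), dtype=np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c[c > 0]

    @classmethod
    def from_repertoire(cls, rep: Repertoire) -> "AbundanceSpectrum":
        return cls(rep.counts())

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(len(self.counts))

    def freq_of_freq(self) -> dict[int, int]:
        vals, cnts = np.unique(self.counts, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnts)}


def chao1(spectrum: AbundanceSpectrum) -> float:
    """Bias-corrected chao1 richness: S_obs + f1(f1-1) / (2(f2+1))."""
    if spectrum.s_obs == 0:
        return 0.0
    ff = spectrum.freq_of_freq()
    f1, f2 = ff.get(1, 0), ff.get(2, 0)
    return spectrum.s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _euler_alternating_sum(terms: np.ndarray, rtol: float = 1e-12, max_k: int = 500) -> float:
    """Euler-transformed sum of sum_k (-1)^k terms[k] (terms >= 0).

    For the finite sequences arising here the transform converges to the exact
    alternating sum; it stays stable when a t > 1 argument inflates the terms.
    """
    c = np.zeros(max_k, dtype=float)
    c[: len(terms)] = terms
    total = 0.0
    diff = c.copy()
    for k in range(max_k):
        term = diff[0] / 2.0 ** (k + 1)
        total += term
        if k > len(terms) and abs(term) <= rtol * max(abs(total), 1e-300):
            break
        diff = diff[:-1] - diff[1:]
        if diff.size == 0:
            break
    return total


def efron_thisted(spectrum: AbundanceSpectrum, t: float = 1.0, x_max: int = 10) -> float:
    """Efron-Thisted unseen-species richness: S_obs + sum_x (-1)^(x+1) t^x f_x.

    The alternating series is truncated at ``x_max`` and evaluated with an Euler
    transform; the estimate is clamped at S_obs (a negative correction is not a
    meaningful richness deficit).
    """
    if spectrum.s_obs == 0:
        return 0.0
    ff = spectrum.freq_of_freq()
    terms = np.array([t**x * ff.get(x, 0) for x in range(1, x_max + 1)], dtype=float)
    delta = _euler_alternating_sum(terms)
    return float(max(spectrum.s_obs + delta, spectrum.s_obs))


def d50(spectrum: AbundanceSpectrum) -> int:
    """Smallest number of top clonotypes whose cumulative frequency reaches 50%."""
    if spectrum.n_total == 0:
        return 0
    c = np.sort(spectrum.counts)[::-1]
    cum = np.cumsum(c) / spectrum.n_total
    return int(np.searchsorted(cum, 0.5, side="left") + 1)


def shannon(spectrum: AbundanceSpectrum) -> float:
    """Shannon-Weiner index H = -sum p_i ln p_i (natural log, unnormalised)."""
    if spectrum.n_total == 0:
        return 0.0
    p = spectrum.counts / spectrum.n_total
    return float(-(p * np.log(p)).sum())


def rarefy(spectrum: AbundanceSpectrum, m: int) -> float:
    """Exact expected richness in a subsample of m cDNA molecules (no replacement).

    E[S_m] = sum_i [1 - C(N - n_i, m) / C(N, m)].
    """
    N = spectrum.n_total
    if not 0 < m <= N:
        raise ValueError(f"subsample size m={m} must satisfy 0 < m <= N={N}")
    n = spectrum.counts
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(N - n + 1) - gammaln(N - n - m + 1) - (gammaln(N + 1) - gammaln(N - m + 1))
        )
    ratio = np.where(N - n >= m, np.exp(log_ratio), 0.0)
    return float(np.sum(1.0 - ratio))


def extrapolate(spectrum: AbundanceSpectrum, m_extra: int) -> float:
    """Chao-style extrapolated richness at N + m_extra molecules.

    S_obs + f0_hat * [1 - (1 - f1 / (N f0_hat + f1))^m_extra], f0_hat = chao1 - S_obs;
    with no singletons the curve is flat at S_obs.
    """
    if m_extra < 0:
        raise ValueError("m_extra must be non-negative")
    ff = spectrum.freq_of_freq()
    f1 = ff.get(1, 0)
    f0 = chao1(spectrum) - spectrum.s_obs
    if f0 <= 0 or f1 == 0:
        return float(spectrum.s_obs)
    N = spectrum.n_total
    return float(spectrum.s_obs + f0 * (1.0 - (1.0 - f1 / (N * f0 + f1)) ** m_extra))


def abundance_classes(spectrum: AbundanceSpectrum) -> dict[str, float]:
    """Repertoire-space occupancy of rare/small/moderate/large clonotypes.

    Each clonotype's relative frequency is assigned to a class; occupancy is the
    summed frequency per class, so occupancies sum to 1.
    """
    if spectrum.n_total == 0:
        return {name: 0.0 for name, *_ in ABUNDANCE_CLASSES}
    freq = spectrum.counts / spectrum.n_total
    out = {}
    for name, lo, hi in ABUNDANCE_CLASSES:
        mask = (freq >= lo) & (freq < hi) if lo > 0 else (freq > 0) & (freq < hi)
        out[name] = float(freq[mask].sum())
    return out


@dataclass
class DiversityProfile:
    subject_id: str
    cohort: str
    s_obs: int
    n_total: int
    chao1: float
    efron_thisted: float
    d50: int
    shannon: float
    occupancy: dict[str, float]
    v_usage: dict[str, float] = field(default_factory=dict)


def diversity_profile(rep: Repertoire) -> DiversityProfile:
    spec = AbundanceSpectrum.from_repertoire(rep)
    usage: dict[str, float] = {}
    total = rep.total_count
    for c in rep.clonotypes:
        usage[c.v_call] = usage.get(c.v_call, 0.0) + c.duplicate_count / total
    return DiversityProfile(
        subject_id=rep.subject_id,
        cohort=rep.cohort,
        s_obs=spec.s_obs,
        n_total=spec.n_total,
        chao1=chao1(spec),
        efron_thisted=efron_thisted(spec),
        d50=d50(spec),
        shannon=shannon(spec),
        occupancy=abundance_classes(spec),
    )


def study_profiles(dataset: StudyDataset, adequate_only: bool = True) -> list[DiversityProfile]:
    """PB diversity profiles, restricted by default to adequately sampled subjects."""
    out = []
    for rep in dataset.repertoires:
        if rep.tissue != PB:
            continue
        if adequate_only and not dataset.pb_adequate(rep.subject_id):
            continue
        out.append(diversity_profile(rep))
    return out


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples, tie-corrected
    normal approximation otherwise.  Returns (U for the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "asymptotic" if (ties or len(x) + len(y) > 30) else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohort_compare(
    profiles_case: list[DiversityProfile],
    profiles_hc: list[DiversityProfile],
    metric: str,
) -> dict:
    """Compare one diversity metric between cohorts (two-sided Mann-Whitney)."""

    def values(profiles):
        if metric in ("rare", "small", "moderate", "large"):
            return np.array([p.occupancy[metric] for p in profiles], dtype=float)
        return np.array([getattr(p, metric) for p in profiles], dtype=float)

    x, y = values(profiles_case), values(profiles_hc)
    if np.array_equal(np.sort(x), np.sort(y)):
        p = 1.0
        u = float(len(x) * len(y) / 2)
    else:
        u, p = mann_whitney(x, y)
    return {
        "metric": metric,
        "case_mean": float(x.mean()),
        "case_sd": float(x.std(ddof=1)),
        "hc_mean": float(y.mean()),
        "hc_sd": float(y.std(ddof=1)),
        "U": u,
        "p": p,
        "n_case": len(x),
        "n_hc": len(y),
    }


def profiles_frame(profiles: list[DiversityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id, "cohort": p.cohort, "s_obs": p.s_obs,
            "n_total": p.n_total, "chao1": p.chao1, "efron_thisted": p.efron_thisted,
            "d50": p.d50, "shannon": p.shannon,
        }
        row.update({f"occ_{k}": v for k, v in p.occupancy.items()})
        rows.append(row)
    return pd.DataFrame(rows)
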