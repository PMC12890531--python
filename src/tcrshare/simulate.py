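"""Synthetic two-cohort CDR3beta study generator with planted ground truth.

Emulates the study design the analysis modules target: cases carry a small
salivary-gland (SG) sample of sorted memory T cells (4-256 cells) plus a deep
peripheral-blood (PB) repertoire; controls are PB-only.  The generator plants,
with recorded truth:

* disease-associated specificity-group motifs (case-exclusive, or present in
  both cohorts with a case abundance multiplier),
* SG clonal expansions whose nucleotide-identical clonotypes are seeded into
  the same subject's PB at >= 5 cDNA copies,
* convergent recombination (one amino-acid clonotype, several encodings),
* a cohort diversity deficit (cases have fewer unique PB clonotypes),
* a pGen x abundance rank coupling in controls only (the interaction effect),
* clinical features linearly coupled to the latent shared-motif burden
  (salivary flow decreases with burden), and
* "public" specificity-database clonotypes more abundant in controls.

Everything is deterministic given the config seed, and problem sizes are desk
scale (PB ~2,000 clonotypes/subject) so the full pipeline runs in seconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    CASE,
    CODONS_BY_AA,
    CONTROL,
    PB,
    SG,
    Clonotype,
    Repertoire,
    SpecificityDbEntry,
    StudyDataset,
    SubjectRecord,
    translate,
)
from .pgen import PgenModel

#: Fixed junction flanks; the inner region is junction_aa[3:-2].
FLANK_N = "CAS"
FLANK_C = "YF"

#: Skewed V usage (TRBV5-1 and TRBV20-1 dominant, as in human memory repertoires).
V_GENES = (
    "TRBV5-1", "TRBV20-1", "TRBV19", "TRBV28", "TRBV12-3", "TRBV7-9",
    "TRBV9", "TRBV6-5", "TRBV27", "TRBV18", "TRBV29-1", "TRBV4-1",
)
V_USAGE = np.array([0.16, 0.14, 0.10, 0.09, 0.08, 0.08, 0.07, 0.07, 0.06, 0.05, 0.05, 0.05])
J_GENES = ("TRBJ2-1", "TRBJ2-7", "TRBJ1-1", "TRBJ2-3", "TRBJ1-2")
J_USAGE = np.array([0.28, 0.24, 0.18, 0.16, 0.14])

PATHOGENS = ("CMV", "EBV", "InfluenzaA", "SARS-CoV-2", "M.tuberculosis", "HSV-1")


@dataclass
class GeneratorConfig:
    n_cases: int = 19
    n_controls: int = 19
    # PB repertoire sizes (negative binomial); the case mean is lower when the
    # cohort diversity deficit is on.
    pb_mean_control: float = 2000.0
    pb_mean_case: float = 1400.0
    pb_dispersion: float = 30.0
    n_inadequate_pb_per_cohort: int = 2  # subjects with ~15% of the cohort mean
    sg_cells_range: tuple[int, int] = (4, 256)
    sg_clone_size_exponent: float = 2.5
    # clonotype cDNA abundance power law P(x) ~ x^-a
    abundance_exponent: float = 2.2
    abundance_max: int = 10_000
    # planted specificity-group motifs
    n_planted_exclusive: int = 3
    n_planted_enriched: int = 2
    exclusive_prevalence: int = 5       # cases carrying an exclusive motif
    enriched_prevalence_cases: int = 15
    enriched_prevalence_controls: int = 15
    enriched_sg_cases: int = 6          # enriched-motif cases with SG members
    enriched_multiplier: float = 4.0    # case abundance multiplier
    motif_n_variants: int = 4           # member sequences per motif (1 wildcard position)
    # SG <-> PB sharing
    sg_pb_seed_fraction: float = 0.35   # SG clones seeded into own PB at >= min copies
    sg_seed_min_copies: int = 5
    seed_neighbor_variant: bool = True  # seeded clones also leave a 1-mismatch PB variant
    sg_public_fraction: float = 0.10    # SG clones drawn from the public pool
    # cross-subject sharing
    n_public_pool: int = 800
    public_presence_range: tuple[float, float] = (0.2, 0.6)
    convergence_rate: float = 0.25      # P(an aa clonotype gets a 2nd nt encoding)
    # interaction effect: pGen-abundance rank coupling in controls only,
    # calibrated so the subsampled interaction is recovered with >95% power
    pgen_abundance_coupling: float = 0.20
    # clinical couplings on the z-scored latent shared-motif burden
    wusf_coupling: float = -0.8
    essdai_coupling: float = 0.6
    # public-specificity database planting
    n_db_per_pathogen: int = 5
    db_presence_prob: float = 0.8
    db_control_multiplier: float = 4.0
    db_abundance_cap: int = 50          # public clones are modestly expanded
    # adequacy thresholds stamped on the emitted dataset (desk scale)
    min_pb_clonotypes: int = 500
    min_sg_cells: int = 40
    inner_length_probs: dict[int, float] | None = None
    aa_probs: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        adequate_cases = self.n_cases - self.n_inadequate_pb_per_cohort
        if self.n_planted_exclusive and self.exclusive_prevalence > adequate_cases:
            raise ValueError("exclusive motif prevalence exceeds adequately sampled cases")
        if self.n_planted_enriched and self.enriched_prevalence_cases > adequate_cases:
            raise ValueError("enriched motif case prevalence exceeds adequately sampled cases")
        for p in (self.sg_pb_seed_fraction, self.sg_public_fraction, self.convergence_rate,
                  self.db_presence_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.pgen_abundance_coupling) >= 1.0:
            raise ValueError("pgen_abundance_coupling must lie in (-1, 1)")


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A configuration with no planted structure (for calibration tests)."""
    cfg = GeneratorConfig(
        n_planted_exclusive=0,
        n_planted_enriched=0,
        pb_mean_case=2000.0,
        pgen_abundance_coupling=0.0,
        wusf_coupling=0.0,
        essdai_coupling=0.0,
        db_control_multiplier=1.0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class PlantedMotif:
    pattern: str
    inner_seqs: list[str]
    v_call: str
    j_call: str
    mode: str                      # "exclusive" | "enriched"
    case_subjects: list[str]
    control_subjects: list[str]
    sg_subjects: list[str]
    multiplier: float


@dataclass
class SyntheticTruth:
    motifs: list[PlantedMotif]
    model: PgenModel
    pgen: dict[str, float]                 # inner_aa -> exact amino-acid pGen
    burdens: dict[str, int]                # case subject -> latent shared-clonotype burden
    sg_seeded: dict[str, list[str]]        # case subject -> seeded SG aa junctions
    specificity_db: list[SpecificityDbEntry]
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "motifs": [asdict(m) for m in self.motifs],
            "pgen": self.pgen,
            "burdens": self.burdens,
            "sg_seeded": self.sg_seeded,
            "specificity_db": [asdict(e) for e in self.specificity_db],
            "config": {k: v for k, v in asdict(self.config).items()
                       if not isinstance(v, dict) or v is None},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def encode_nt(rng: np.random.Generator, junction_aa: str) -> str:
    """Draw one nucleotide encoding, uniform over synonymous codons per residue."""
    parts = []
    for a in junction_aa:
        codons = CODONS_BY_AA[a]
        parts.append(codons[int(rng.integers(len(codons)))])
    return "".join(parts)


def sample_sequence(model: PgenModel, rng: np.random.Generator) -> tuple[str, str, float]:
    """Draw one (inner_aa, junction_nt, exact amino-acid pGen) triple."""
    inner = model.sample_inner(rng, 1)[0]
    junction_aa = FLANK_N + inner + FLANK_C
    return inner, encode_nt(rng, junction_aa), model.pgen(inner)


def _zipf(rng: np.random.Generator, a: float, size: int, cap: int) -> np.ndarray:
    return np.minimum(rng.zipf(a, size=size), cap).astype(np.int64)


class _RepBuilder:
    """Accumulates (junction_nt, v, j) -> count entries for one repertoire."""

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str, str], int] = {}

    def add(self, nt: str, v: str, j: str, count: int) -> None:
        key = (nt, v, j)
        self.entries[key] = self.entries.get(key, 0) + int(count)

    def to_repertoire(self, subject_id: str, tissue: str, cohort: str,
                      n_cells: int | None = None) -> Repertoire:
        clonotypes = [
            Clonotype(
                junction_nt=nt, junction_aa=translate(nt), v_call=v, j_call=j,
                duplicate_count=count, subject_id=subject_id, tissue=tissue, cohort=cohort,
            )
            for (nt, v, j), count in self.entries.items()
        ]
        return Repertoire(subject_id=subject_id, tissue=tissue, cohort=cohort,
                          clonotypes=clonotypes, n_cells=n_cells)


def _draw_vj(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    vi = rng.choice(len(V_GENES), size=n, p=V_USAGE)
    ji = rng.choice(len(J_GENES), size=n, p=J_USAGE)
    return [V_GENES[i] for i in vi], [J_GENES[i] for i in ji]


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def generate_study(config: GeneratorConfig) -> tuple[StudyDataset, SyntheticTruth]:
    """Generate a full two-cohort study with recorded ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    defaults = PgenModel()
    model = PgenModel(
        length_probs=dict(config.inner_length_probs or defaults.length_probs),
        aa_probs=dict(config.aa_probs or defaults.aa_probs),
    )
    alphabet = sorted(model.aa_probs)

    case_ids = [f"P{i + 1}" for i in range(config.n_cases)]
    control_ids = [f"H{i + 1}" for i in range(config.n_controls)]

    # public cross-subject pool (cohort-symmetric presence probabilities)
    pool_inner = model.sample_inner(rng, config.n_public_pool)
    pool_q = rng.uniform(*config.public_presence_range, size=config.n_public_pool)
    pool_v, pool_j = _draw_vj(rng, config.n_public_pool)

    # public specificity database (planted more abundant in controls)
    db_entries: list[SpecificityDbEntry] = []
    for pathogen in PATHOGENS:
        seqs = model.sample_inner(rng, config.n_db_per_pathogen)
        vs, _ = _draw_vj(rng, config.n_db_per_pathogen)
        for s, v in zip(seqs, vs):
            db_entries.append(SpecificityDbEntry(cdr3_aa=FLANK_N + s + FLANK_C,
                                                 pathogen_or_antigen=pathogen, v_call=v))

    # subjects with deliberately shallow PB sampling (excluded from planting)
    inad_cases = [case_ids[i] for i in rng.choice(config.n_cases,
                  size=config.n_inadequate_pb_per_cohort, replace=False)]
    inad_controls = [control_ids[i] for i in rng.choice(config.n_controls,
                     size=config.n_inadequate_pb_per_cohort, replace=False)]
    adequate_cases = [s for s in case_ids if s not in inad_cases]
    adequate_controls = [s for s in control_ids if s not in inad_controls]

    # planted motifs: Hamming-1 families at one wildcard position, shared V
    motifs: list[PlantedMotif] = []
    n_motifs = config.n_planted_exclusive + config.n_planted_enriched
    for m in range(n_motifs):
        L = int(rng.choice([7, 8, 9]))
        # sample the base sequence directly at the chosen length
        base = [alphabet[int(i)] for i in
                rng.choice(len(alphabet), size=L, p=np.array([model.aa_probs[a] for a in alphabet]))]
        w = int(rng.integers(L))
        variants = [a for a in rng.permutation(alphabet) if a != base[w]][: config.motif_n_variants - 1]
        members = ["".join(base)]
        for a in variants:
            s = base.copy()
            s[w] = a
            members.append("".join(s))
        pattern = "".join("%" if i == w else base[i] for i in range(L))
        v_call = V_GENES[int(rng.choice(len(V_GENES), p=V_USAGE))]
        j_call = J_GENES[int(rng.choice(len(J_GENES), p=J_USAGE))]
        if m < config.n_planted_exclusive:
            subs = [adequate_cases[i] for i in rng.choice(len(adequate_cases),
                    size=config.exclusive_prevalence, replace=False)]
            motifs.append(PlantedMotif(pattern, members, v_call, j_call, "exclusive",
                                       sorted(subs), [], sorted(subs), 1.0))
        else:
            cs = [adequate_cases[i] for i in rng.choice(len(adequate_cases),
                  size=config.enriched_prevalence_cases, replace=False)]
            hs = [adequate_controls[i] for i in rng.choice(len(adequate_controls),
                  size=min(config.enriched_prevalence_controls, len(adequate_controls)),
                  replace=False)]
            sg = [cs[i] for i in rng.choice(len(cs),
                  size=min(config.enriched_sg_cases, len(cs)), replace=False)]
            motifs.append(PlantedMotif(pattern, members, v_call, j_call, "enriched",
                                       sorted(cs), sorted(hs), sorted(sg), config.enriched_multiplier))

    repertoires: list[Repertoire] = []
    burdens: dict[str, int] = {}
    sg_seeded: dict[str, list[str]] = {}
    all_inner: set[str] = set(pool_inner)

    def build_pb(subject_id: str, cohort: str, mean: float, depth: float = 1.0) -> _RepBuilder:
        r = config.pb_dispersion
        n_base = max(30, int(rng.negative_binomial(r, r / (r + mean))))
        inner = model.sample_inner(rng, n_base)
        vs, js = _draw_vj(rng, n_base)
        # public-pool membership; shallow sampling detects fewer public clones
        mask = rng.random(config.n_public_pool) < pool_q * depth
        for i in np.flatnonzero(mask):
            inner.append(pool_inner[i])
            vs.append(pool_v[i])
            js.append(pool_j[i])
        n = len(inner)
        counts = _zipf(rng, config.abundance_exponent, n, config.abundance_max)
        if cohort == CONTROL and config.pgen_abundance_coupling != 0.0:
            # rank-couple abundance to pGen; the abundance marginal is preserved
            rho = config.pgen_abundance_coupling
            logp = np.array([math.log10(model.pgen(s)) for s in inner])
            z = (logp - logp.mean()) / (logp.std() + 1e-12)
            target = rho * z + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
            order = np.argsort(target, kind="stable")
            sorted_counts = np.sort(counts)
            new = np.empty_like(counts)
            new[order] = sorted_counts
            counts = new
        builder = _RepBuilder()
        for s, v, j, c in zip(inner, vs, js, counts):
            aa = FLANK_N + s + FLANK_C
            builder.add(encode_nt(rng, aa), v, j, int(c))
            all_inner.add(s)
        # planted motif members
        for motif in motifs:
            targets = motif.case_subjects if cohort == CASE else motif.control_subjects
            if subject_id not in targets:
                continue
            k = 1 + int(rng.integers(min(3, len(motif.inner_seqs))))
            picks = rng.choice(len(motif.inner_seqs), size=k, replace=False)
            for i in picks:
                s = motif.inner_seqs[int(i)]
                c = int(_zipf(rng, config.abundance_exponent, 1, config.abundance_max)[0]) + 1
                if cohort == CASE and motif.mode == "enriched":
                    c = int(math.ceil(c * motif.multiplier))
                builder.add(encode_nt(rng, FLANK_N + s + FLANK_C), motif.v_call, motif.j_call, c)
                all_inner.add(s)
        # public specificity-database clonotypes
        for e in db_entries:
            if rng.random() < config.db_presence_prob * depth:
                c = int(_zipf(rng, config.abundance_exponent, 1, config.db_abundance_cap)[0])
                if cohort == CONTROL:
                    c = int(math.ceil(c * config.db_control_multiplier))
                builder.add(encode_nt(rng, e.cdr3_aa), e.v_call or "TRBV5-1", "TRBJ2-1", c)
                all_inner.add(e.cdr3_aa[3:-2])
        return builder

    def apply_convergence(builder: _RepBuilder) -> None:
        # with prob `convergence_rate`, give an aa clonotype a 2nd distinct encoding
        for (nt, v, j) in list(builder.entries):
            if rng.random() >= config.convergence_rate:
                continue
            aa = translate(nt)
            for _ in range(8):
                nt2 = encode_nt(rng, aa)
                if nt2 != nt:
                    c = int(_zipf(rng, config.abundance_exponent, 1, config.abundance_max)[0])
                    builder.add(nt2, v, j, c)
                    break

    # cases: PB + SG
    for subject_id in case_ids:
        depth = 0.15 if subject_id in inad_cases else 1.0
        pb = build_pb(subject_id, CASE, config.pb_mean_case * depth, depth)

        lo, hi = config.sg_cells_range
        n_cells = int(rng.integers(lo, hi + 1))
        sg = _RepBuilder()
        seeded_aa: list[str] = []
        planted_here: list[tuple[str, str, str, int]] = []
        for motif in motifs:
            if subject_id not in motif.sg_subjects:
                continue
            s = motif.inner_seqs[int(rng.integers(len(motif.inner_seqs)))]
            cells = int(rng.integers(2, 5))  # expanded SG clone
            planted_here.append((FLANK_N + s + FLANK_C, motif.v_call, motif.j_call, cells))
            all_inner.add(s)
        cells_left = max(n_cells - sum(p[3] for p in planted_here), 0)
        fill: list[tuple[str, str, str, int]] = []
        while cells_left > 0:
            size = int(min(rng.zipf(config.sg_clone_size_exponent), 40, cells_left))
            if rng.random() < config.sg_public_fraction:
                i = int(rng.integers(config.n_public_pool))
                aa, v, j = FLANK_N + pool_inner[i] + FLANK_C, pool_v[i], pool_j[i]
            else:
                s = model.sample_inner(rng, 1)[0]
                v, j = _draw_vj(rng, 1)
                aa, v, j = FLANK_N + s + FLANK_C, v[0], j[0]
                all_inner.add(s)
            fill.append((aa, v, j, size))
            cells_left -= size
        total_cells = sum(p[3] for p in planted_here) + sum(f[3] for f in fill)
        for aa, v, j, cells in planted_here + fill:
            nt = encode_nt(rng, aa)
            sg.add(nt, v, j, cells)
            planted = any(aa == p[0] for p in planted_here)
            if planted or rng.random() < config.sg_pb_seed_fraction:
                copies = config.sg_seed_min_copies + int(
                    _zipf(rng, config.abundance_exponent, 1, config.abundance_max)[0]) - 1
                pb.add(nt, v, j, copies)  # same nucleotide encoding: nt-identical sharing
                seeded_aa.append(aa)
                if config.seed_neighbor_variant:
                    # a sequence-similar sister clone in the same subject's PB,
                    # so the seeded clone sits inside a specificity group
                    inner_seq = list(aa[len(FLANK_N):-len(FLANK_C)])
                    pos = int(rng.integers(len(inner_seq)))
                    alt = alphabet[int(rng.integers(len(alphabet)))]
                    while alt == inner_seq[pos]:
                        alt = alphabet[int(rng.integers(len(alphabet)))]
                    inner_seq[pos] = alt
                    var_aa = FLANK_N + "".join(inner_seq) + FLANK_C
                    pb.add(encode_nt(rng, var_aa), v, j,
                           int(_zipf(rng, config.abundance_exponent, 1, config.abundance_max)[0]))
                    all_inner.add("".join(inner_seq))

        apply_convergence(pb)
        repertoires.append(pb.to_repertoire(subject_id, PB, CASE))
        repertoires.append(sg.to_repertoire(subject_id, SG, CASE, n_cells=total_cells))
        seeded_aa = sorted(set(seeded_aa))
        sg_seeded[subject_id] = seeded_aa
        burdens[subject_id] = len(seeded_aa)

    # controls: PB only
    for subject_id in control_ids:
        depth = 0.15 if subject_id in inad_controls else 1.0
        pb = build_pb(subject_id, CONTROL, config.pb_mean_control * depth, depth)
        apply_convergence(pb)
        repertoires.append(pb.to_repertoire(subject_id, PB, CONTROL))

    # clinical features coupled to the z-scored latent burden
    b = np.array([burdens[s] for s in case_ids], dtype=float)
    bz = (b - b.mean()) / (b.std() + 1e-12)

    def coupled(coef: float, loc: float, scale: float, size: int, z: np.ndarray) -> np.ndarray:
        noise = math.sqrt(max(1.0 - coef * coef, 0.0)) * rng.standard_normal(size)
        return loc + scale * (coef * z + noise)

    subjects: list[SubjectRecord] = []
    wusf = np.clip(coupled(config.wusf_coupling, 0.30, 0.15, config.n_cases, bz), 0.01, None)
    essdai = np.clip(np.round(coupled(config.essdai_coupling, 6.0, 3.5, config.n_cases, bz)), 0, None)
    focus = np.clip(coupled(0.4 if config.wusf_coupling else 0.0, 2.0, 1.0, config.n_cases, bz), 0.2, None)
    igg = np.clip(coupled(0.3 if config.essdai_coupling else 0.0, 1400.0, 350.0, config.n_cases, bz), 400, None)
    for i, sid in enumerate(case_ids):
        subjects.append(SubjectRecord(
            subject_id=sid, cohort=CASE,
            age=float(np.round(rng.normal(55, 11), 1)), sex=("F" if rng.random() < 0.9 else "M"),
            WUSF=float(np.round(wusf[i], 3)), ESSDAI=float(essdai[i]),
            OSS=float(rng.integers(0, 10)), schirmer=float(rng.integers(0, 16)),
            serum_IgG=float(np.round(igg[i], 1)), focus_score=float(np.round(focus[i], 2)),
            acr_eular_weighted=float(rng.integers(4, 10)),
            anti_Ro=bool(rng.random() < 0.8), anti_La=bool(rng.random() < 0.45),
        ))
    for sid in control_ids:
        subjects.append(SubjectRecord(
            subject_id=sid, cohort=CONTROL,
            age=float(np.round(rng.normal(55, 11), 1)), sex=("F" if rng.random() < 0.9 else "M"),
            WUSF=float(np.round(np.clip(rng.normal(0.45, 0.12), 0.05, None), 3)),
            schirmer=float(rng.integers(5, 25)),
            serum_IgG=float(np.round(rng.normal(1050, 250), 1)),
            anti_Ro=False, anti_La=False,
        ))

    dataset = StudyDataset(
        subjects=subjects, repertoires=repertoires,
        min_pb_clonotypes=config.min_pb_clonotypes, min_sg_cells=config.min_sg_cells,
    )
    truth = SyntheticTruth(
        motifs=motifs, model=model,
        pgen={s: model.pgen(s) for s in sorted(all_inner) if len(s) in model.length_probs},
        burdens=burdens, sg_seeded=sg_seeded, specificity_db=db_entries, config=config,
    )
    return dataset, truth


def reference_repertoire_seqs(model: PgenModel, n: int, seed: int) -> tuple[list[str], list[str]]:
    """Draw a naive background sample (inner sequences + V calls) for enrichment scoring."""
    rng = np.random.default_rng(seed)
    inner = model.sample_inner(rng, n)
    vs, _ = _draw_vj(rng, n)
    return inner, vs
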