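# tcrshare

Analysis of T-cell receptor (TCR) CDR3β repertoires for paired tissue/blood
study designs, built for studies of autoimmune exocrinopathy (Sjögren's
disease-style cohorts): a small set of T cells sorted from salivary-gland (SG)
biopsies of cases, deep-sequenced peripheral-blood (PB) repertoires of the same
cases and of matched healthy controls, and a per-subject clinical table.  The
package asks where gland-infiltrating clones reappear, which CDR3β motifs are
disease-associated, and whether the blood repertoire of cases is restricted and
"private".

It is a library first (`import tcrshare`), with an `examples/` directory of
narrative scripts and a thin `tcrshare` command-line wrapper.

## What it computes

**Clonal expansion and sharing.** An SG clonal expansion is ≥ 2 cells carrying a
nucleotide-identical CDR3β; an expansion is *overrepresented* when the same
nucleotide clonotype has ≥ 5 cDNA copies in the same subject's blood.  Each SG
sequence is classified as SG-only / case-PB-only / HC-PB-only / both against
the pooled blood repertoires of adequately sampled subjects, and the cohort
asymmetry is tested with a two-sided Fisher exact test on
rows = cohort PB, columns = detected / not detected.

**Specificity groups.** A deliberately simple GLIPH2-style clustering of the
CDR3β *inner region* (junction minus 3 N-terminal and 2 C-terminal residues):
global groups are connected components under "equal length, Hamming distance
≤ 1", named by a consensus pattern with `%` at variable positions (e.g.
`SST%GNT`); local groups are 3-/4-mers enriched against a naive reference
repertoire (one-sided Fisher, fold ≥ 10, p < 10⁻³).  Groups are scored by
Monte-Carlo p-values for V-gene bias, length conservation and size.

**Disease-associated motifs.** SG–PB shared groups with ≥ 3 distinct sequences
whose blood members occur in ≥ 3 adequately sampled cases pass the score
filter, then are called when *exclusive* (0 controls) or significantly more
abundant in cases (two-sided Mann-Whitney on per-subject summed cDNA counts,
absent subjects contributing zeros).  The per-subject count of groups shared
between a subject's own SG and PB (the *shared-motif burden*) is correlated
with clinical features (tie-corrected Spearman, exact permutation p for n ≤ 9).

**Diversity.** Per-subject richness and diversity:
chao1 `S_obs + f₁(f₁−1)/(2(f₂+1))`, Efron–Thisted
`S_obs + Σₓ (−1)^(x+1) tˣ fₓ` (Euler-transformed, clamped at `S_obs`), D50,
Shannon `H = −Σ pᵢ ln pᵢ`, exact hypergeometric rarefaction
`E[S_m] = Σᵢ [1 − C(N−nᵢ, m)/C(N, m)]` with Chao-style extrapolation, and
rare/small/moderate/large abundance-class occupancies, compared between
cohorts with two-sided Mann-Whitney tests.

**Generation probability.** A closed-form amino-acid model
`pGen(a₁..a_L) = P_L(L)·Π P_A(aᵢ)` (external per-clonotype pGen values, e.g.
OLGA output, can be supplied instead).  For each unique blood clonotype the
regression `log₁₀ pGen = β₀ + β₁·log₁₀(mean abundance) + β₂·g + β₃·x·g`
(g = 1 for controls) is fitted on repeated equal-size subsamples per cohort;
β₃ > 0 in most subsamples means abundant case clonotypes have systematically
low pGen — antigen-driven selection rather than recombination bias.

**Synthetic study generator.** `tcrshare.generate_study` emits a full two-cohort
study with recorded ground truth (planted motifs, expansions seeded into the
same subject's blood, convergent nucleotide encodings, a cohort diversity
deficit, the pGen×abundance coupling, clinical couplings, and public
specificity-database clones), so every stage is testable without any download.

## Worked example

```bash
python examples/04_disease_associated_motifs.py
```

prints (seed 1):

```
shared groups: 609, candidates: 6, score-filtered: 1, called: 5
  %%%K%K%%: 15 cases / 15 controls, abundance (MW p=0.013)
  AR%%SY%%: 5 cases / 0 controls, exclusive
  E%Y%%%%%F: 15 cases / 15 controls, abundance (MW p=0.008)
  %%%%%G%: 5 cases / 0 controls, exclusive
  SD%L%%N%: 5 cases / 0 controls, exclusive
recovery vs truth: 5/5 planted motifs found, 0 false calls (FDR 0.00)
shared-motif burden vs salivary flow: Spearman rho = -0.70, p = 0.00248 over 16 cases
```

All five planted motifs (three case-exclusive, two case-enriched at a 4×
abundance multiplier) are recovered with no false calls, and the planted
negative coupling between shared-motif burden and unstimulated salivary flow is
detected.  `examples/06_pgen_interaction.py` shows the interaction regression:
with the planted control-only coupling, 100% of 1,000 subsamples of 5,000
clonotypes per cohort give β₃ > 0 with p < 0.05.

The other examples cover simulation (`01`), expansion/sharing statistics
(`02`), clustering and scores (`03`), diversity (`05`) and the full stamped
pipeline bundle (`07`).  The same stages are available from the shell:

```bash
tcrshare simulate --seed 1 --out study/
tcrshare run --airr study/repertoires.airr.tsv --clinical study/clinical.csv \
             --db study/specificity_db.tsv --seed 1 --out report/
```

## Layout

```
src/tcrshare/        model, simulate, overlap, clustering, diversity,
                     association, pgen, pipeline, cli
tests/               unit, property and acceptance tests (pytest + hypothesis)
examples/            one narrative script per capability
docs/methods.md      models, assumptions, parameter choices, limitations
scripts/acceptance.py
```
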