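# Methods

This note documents the models, conventions and numerical choices behind
`tcrshare`, what the synthetic study generator does and does not emulate, and
the problem sizes used by the test suite and the acceptance script.

## Data model and identity conventions

A clonotype is keyed within a subject by (nucleotide junction, V call, J call);
amino-acid junction identity is a separate view used for cross-subject
comparison, so that convergent recombination (distinct rearrangements encoding
one peptide) is observable.  Rows of an AIRR Rearrangement TSV sharing the
nucleotide key are merged at read time with cDNA counts summed; unproductive
rows (out-of-frame junction or stop codon) are dropped with a logged count
rather than raised, to tolerate real files.

Sharing analyses default to amino-acid identity across subjects and nucleotide
identity within a subject (expansion overrepresentation asks for the *same
rearrangement* recirculating).  Both keys are exposed.

The inner region used for motif clustering removes 3 N-terminal residues
(canonical C plus two V-templated positions) and 2 C-terminal (J-templated)
residues of the amino-acid junction.  This is configurable; the default
reproduces length-7 patterns from 12-mer junctions.

Adequate-sampling thresholds are strict inequalities on the study object
(`min_pb_clonotypes`, `min_sg_cells`) and every cohort-level statistic is
restricted to adequately sampled subjects.  For deep-sequenced human data the
conventional thresholds are 25,000 unique PB clonotypes and 40 SG cells; the
synthetic generator stamps desk-scaled values (500 / 40) on the datasets it
emits, because its repertoires are ~30× shallower than real deep sequencing.

## Contingency and rank statistics

* `fisher_2x2` is the two-sided Fisher exact test with the mainstream
  convention (sum of hypergeometric outcomes no more probable than the observed
  table); the odds ratio is the sample ratio ad/bc with ∞ for bc = 0 and NaN
  for 0/0.  The cohort-asymmetry table for SG sharing puts cohorts in rows and
  detected/not-detected in columns, restricted to SG items found in any PB
  ("both" counts as detected in each row).
* Mann-Whitney U is exact for small tie-free samples (≤ 30 pooled) and the
  tie-corrected normal approximation otherwise.  The volcano effect size is the
  mean pooled rank of cases minus controls.
* Spearman correlation is Pearson on (tie-corrected) ranks; for n ≤ 9 the
  two-tailed p is an exact permutation enumeration, above that the asymptotic
  value.  Clinical features are dropped pairwise when missing; fewer than 5
  pairs or a constant vector is an error surfaced as NaN in batch tables.

Implementation of these standard tests is delegated to scipy/statsmodels; the
test suite checks them against independent full-enumeration oracles (all 2×2
tables with cells ≤ 4 plus random tables up to N = 40; all Mann-Whitney group
sizes up to 7).

## Specificity-group clustering and scores

Global groups are connected components of the graph joining equal-length inner
sequences at Hamming distance ≤ 1, found exactly by per-position wildcard
hashing (two equal-length sequences differ at ≤ 1 position iff they share a
masked key).  Components with a single distinct sequence are not groups.
Patterns print `%` at positions where members differ.  Local groups are
exhaustive 3-/4-mers tested for enrichment against a reference repertoire with
a one-sided Fisher test (defaults: fold ≥ 10, p < 10⁻³, ≥ 2 sample sequences).
Discontinuous motifs and HLA scoring are out of scope.  A GLIPH2-compatible
input writer allows cross-checking with the published tool.

Group scores are upper-tail Monte-Carlo p-values against the reference
repertoire: V-gene bias (modal V-gene count among members vs. equally many
multinomial draws from reference V usage), length conservation (same
construction on inner length), and size (distinct-sequence count vs. component
sizes arising in random reference subsamples, pooled over replicates).  All
three use the randomised tie rule

    p = (#{T > T_obs} + U·(1 + #{T == T_obs})) / (n_null + 1),  U ~ Uniform(0,1)

which is *exactly* uniform under the null despite the discreteness of the
statistics — this is what makes the null-calibration tests sharp.  Draws are
deterministic given the seed.  Single-member groups get undefined scores.

The "filter 1" used before association calls requires all three score
p-values < 0.05 and ≥ 3 distinct member sequences.  Candidacy for association
additionally requires blood detection in ≥ 3 adequately sampled cases; groups
carrying an expanded SG clonotype are retained alongside the score-filtered
set.  The ≥ 3-distinct-sequence floor applies to both routes: two-sequence
components are weak motif evidence and admit chance case-enriched calls.

## Diversity estimators

chao1 uses the bias-corrected form `S_obs + f₁(f₁−1)/(2(f₂+1))`.  The
Efron–Thisted correction `Δ(t) = Σₓ (−1)^(x+1) tˣ fₓ` is truncated at
x_max = 10 and evaluated through an Euler transform (stable when t > 1
inflates the terms; for the finite default series it reproduces the exact
alternating sum), and the estimate is clamped at `S_obs`.  D50 is the smallest
number of top clonotypes reaching half of the repertoire, count-identical
clones being interchangeable.  Shannon entropy uses the natural log,
unnormalised.  Rarefaction is the exact without-replacement expectation
computed with log-gamma binomials; extrapolation uses `f̂₀ = chao1 − S_obs`
and is flat when there are no singletons.  Abundance classes (rare < 0.001 %,
small < 0.025 %, moderate < 0.25 %, large above) are left-closed: a frequency
equal to a boundary joins the larger class.  Note that class occupancy depends
on total sampling depth: at the generator's desk scale (~10⁴ cDNA per subject)
no clonotype can fall below 0.001 %, so the "rare" class is empty there by
construction — a property of the scale, not a defect of the estimator.

## Generation-probability model and interaction regression

The pGen model is a closed form over the inner region:
`pGen = P_L(L)·Π P_A(aᵢ)` with a length distribution over 7–13 (junction
12–18, matching human CDR3β) and a glycine/serine-rich residue distribution.
It deliberately replaces a full V(D)J recombination model: every sequence has
an exact, enumerable probability, nucleotide encodings are uniform over
synonymous codons (so encoding probabilities sum to the amino-acid pGen), and
planted pGen–abundance structure is recoverable.  Users with real OLGA output
can inject per-clonotype values via TSV.

The interaction regression is ordinary least squares of log₁₀ pGen on log₁₀
mean abundance, a control-cohort indicator and their product.  "Mean
abundance" of a clonotype is the mean cDNA count over the cohort subjects in
which it is detected (a declared aggregation choice).  Gaussian least squares
on the log scale was chosen for stability; only the sign convention of the
interaction (positive = control pGen rises faster with abundance) is fixed by
the analysis semantics.  The subsampling wrapper refits on equal-size random
subsamples per cohort (with replacement only when a pool is smaller than the
subsample) and reports the fraction of iterations with β₃ > 0 and p < 0.05;
the in-loop closed-form OLS is tested to agree with statsmodels to numerical
precision.  Note that subsamples of one study share that study's realised
coefficient, so under the null the significant-positive fraction is 0.025 only
in expectation *across* studies; calibration checks therefore average over
independent null studies.

## Synthetic study generator

The generator emulates the study design end to end: 19 cases with an SG sample
of 4–256 sorted cells plus a PB repertoire, 19 controls PB-only, two subjects
per cohort deliberately under-sampled.  Its defaults are the study conditions:

* PB repertoires: negative-binomial unique-clonotype counts (means 2,000
  control / 1,400 case — the case deficit is the planted diversity effect),
  zipf(2.2) cDNA counts capped at 10⁴.  These are ~30× smaller than real deep
  sequencing so that the full pipeline runs in seconds; statistical structure,
  not scale, is what the downstream stages consume.
* Cross-subject sharing: an 800-sequence public pool with per-sequence
  presence probabilities uniform on 0.2–0.6, identical in both cohorts.
* Planted motifs: five Hamming-1 families (4 member sequences, one wildcard
  position, shared V gene) — three case-exclusive in 5 cases, two present in
  15 cases and 15 controls with a 4× case abundance multiplier.
* SG structure: clone sizes from zipf(2.5); planted members enter SG as
  expanded clones (2–4 cells); 35 % of SG clones (and every planted member)
  are seeded into the same subject's PB with the *same nucleotide encoding* at
  ≥ 5 copies, and each seeded clone leaves a 1-mismatch sister sequence in the
  same subject's PB so that it sits inside a specificity group.
* Convergent recombination: each amino-acid clonotype acquires a second
  distinct nucleotide encoding with probability 0.25.
* Interaction effect: control repertoires rank-couple cDNA counts to log pGen
  with coupling 0.20 (a Gaussian-copula reordering, which preserves the
  abundance marginal exactly); the magnitude is calibrated so the subsampled
  regression detects the effect in > 95 % of iterations at 5,000 clonotypes
  per cohort.
* Clinical features: linear couplings plus Gaussian noise on the z-scored
  latent burden (the number of a subject's SG clonotypes seeded into its own
  PB, which is what the measured shared-motif burden approximates): −0.8 for
  unstimulated salivary flow, +0.6 for the systemic activity index; age and
  the remaining measures are uncoupled.
* Public specificities: 6 pathogen labels × 5 sequences planted in most
  subjects, 4× more abundant in controls, counts capped at 50 so the planted
  asymmetry is not swamped by single heavy-tailed draws.

`null_config()` switches off every planted effect for calibration tests.
Everything is drawn from a single seeded generator; identical seeds give
byte-identical datasets and pipeline bundles.

What the generator does **not** emulate: realistic V(D)J recombination
(insertions/deletions, gene-dependent junction composition), position-dependent
residue usage, HLA structure, sequencing error, or cross-cohort asymmetric
public clones (every unplanted sharing process is cohort-symmetric).  Passing
recovery tests therefore demonstrate that the pipeline's inference is correct
under its stated model, not that real repertoires satisfy that model.

## Problem sizes

Unit and property tests run on small constructed inputs plus one default-scale
study fixture.  The recovery acceptance aggregates 20 generator seeds
(~5 s/seed); the interaction acceptance uses 5,000 clonotypes per cohort ×
1,000 iterations, with the null averaged over three independent studies; the
score-uniformity check scores 300 null groups with 400 Monte-Carlo draws each.
The acceptance script completes in about two minutes on one CPU.

## Known limitations

* The clustering is a simplified re-implementation of the GLIPH2 semantics;
  it does not reproduce the published tool's discontinuous motifs, reference
  panels or HLA scoring, and group counts are not comparable across tools.
* Local-motif enrichment at desk scale has limited power for motifs carried by
  a handful of sequences; the global route is the primary discovery path.
* Exact Mann-Whitney p-values are only available for tie-free small samples;
  zero-inflated abundance vectors always use the tie-corrected approximation.
* The Efron–Thisted estimator is reported at t = 1 with x_max = 10; other
  truncations change the estimate and no universally agreed convention exists.
* `report` recomputes headline counts from cached TSVs; it does not detect
  hand-edited bundles beyond the stored config hash.
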