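"""Call disease-associated motifs and compare the calls with the planted truth.

Candidates are SG-PB shared groups with >= 3 distinct sequences whose blood
members appear in >= 3 adequately sampled cases.  After the score filter, a
motif is called when it is case-exclusive or significantly more abundant in
cases (two-sided Mann-Whitney on per-subject cDNA counts, zeros included).
"""

from tcrshare import GeneratorConfig, generate_study
from tcrshare.pipeline import PipelineConfig, discover_associated_motifs, evaluate_recovery

dataset, truth = generate_study(GeneratorConfig(seed=1))
disc = discover_associated_motifs(dataset, PipelineConfig(seed=1), model=truth.model)

print(f"shared groups: {disc['summary']['n_shared_groups']}, "
      f"candidates: {disc['summary']['n_candidates']}, "
      f"score-filtered: {disc['summary']['n_filtered']}, "
      f"called: {disc['summary']['n_called']}")
for g, r in zip(disc["tested_groups"], disc["results"]):
    if r.called:
        route = "exclusive" if r.exclusive else f"abundance (MW p={r.mw_p:.2g})"
        print(f"  {g.pattern}: {r.n_cases_detected} cases / {r.n_hcs_detected} controls, {route}")

rec = evaluate_recovery(disc["called_groups"], truth)
print(f"recovery vs truth: {rec['n_recovered']}/{rec['n_planted']} planted motifs found, "
      f"{rec['n_false']} false calls (FDR {rec['fdr']:.2f})")

wusf = disc["clinical"][disc["clinical"].feature == "WUSF"].iloc[0]
print(f"shared-motif burden vs salivary flow: Spearman rho = {wusf.spearman_rho:.2f}, "
      f"p = {wusf.p:.3g} over {wusf.n} cases")
# The negative rho reproduces the planted coupling: patients whose gland
# clones recirculate more broadly have lower unstimulated salivary flow.
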