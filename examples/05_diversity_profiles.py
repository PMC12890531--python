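"""Per-subject blood repertoire diversity and the cohort comparison.

Four indices summarise each repertoire: chao1 and Efron-Thisted richness
(unseen-species corrected), D50 (dominant clonotypes covering half the
repertoire) and Shannon entropy; abundance classes report the repertoire
fraction held by rare/small/moderate/large clones.
"""

from tcrshare import GeneratorConfig, generate_study
from tcrshare.diversity import cohort_compare, study_profiles

dataset, _ = generate_study(GeneratorConfig(seed=1))
profiles = study_profiles(dataset)
cases = [p for p in profiles if p.cohort == "CASE"]
controls = [p for p in profiles if p.cohort == "CONTROL"]

p0 = cases[0]
print(f"{p0.subject_id}: S_obs={p0.s_obs}, chao1={p0.chao1:.0f}, "
      f"Efron-Thisted={p0.efron_thisted:.0f}, D50={p0.d50}, H={p0.shannon:.2f}")
print(f"  occupancy: " + ", ".join(f"{k}={v:.3f}" for k, v in p0.occupancy.items()))

for metric in ("s_obs", "chao1", "d50", "shannon"):
    res = cohort_compare(cases, controls, metric)
    print(f"{metric}: cases {res['case_mean']:.1f}+/-{res['case_sd']:.1f} vs "
          f"controls {res['hc_mean']:.1f}+/-{res['hc_sd']:.1f}, "
          f"Mann-Whitney p = {res['p']:.3g}")
# The planted diversity deficit shows up as significantly lower richness in
# cases; Shannon entropy moves the same way but with less power, as expected
# for an index dominated by the abundant clones.
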