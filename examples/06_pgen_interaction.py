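"""The subsampled pGen x abundance x cohort interaction regression.

For each unique blood clonotype we regress log10 pGen on log10 mean abundance,
a cohort indicator and their interaction.  A positive interaction coefficient
(beta3) means pGen rises faster with abundance in controls - i.e. abundant
case clonotypes are *not* explained by recombination bias ('private'
repertoire).  Subsampling equal numbers of clonotypes per cohort removes the
sequencing-depth asymmetry.
"""

from tcrshare import GeneratorConfig, generate_study
from tcrshare.pgen import mean_abundance_records, subsample_interaction

dataset, truth = generate_study(GeneratorConfig(seed=1))
case = mean_abundance_records(dataset, "CASE", model=truth.model)
control = mean_abundance_records(dataset, "CONTROL", model=truth.model)
print(f"record pools: {len(case)} case clonotypes, {len(control)} control clonotypes")

summary = subsample_interaction(case, control, n_per_cohort=5000, iterations=1000, seed=1)
print(f"mean beta3 = {summary.mean_beta3:.3f}")
print(f"fraction of subsamples with beta3 > 0: {summary.frac_positive:.1%}")
print(f"fraction with beta3 > 0 and p < 0.05: {summary.frac_positive_significant:.1%}")
# With the planted control-only pGen-abundance coupling, essentially every
# subsample detects a significantly positive interaction; under a null
# configuration the significant-positive fraction falls to ~2.5% (half of a
# two-sided 5% rate).
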