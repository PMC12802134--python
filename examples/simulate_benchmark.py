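"""Generate a semi-synthetic benchmark dataset with known ground truth.

Fabricates a fully synthetic baseline cohort (67 subjects, 120 taxa on a
random coalescent tree, 200 metabolites with sub-class structure), then
injects scenario-5 perturbations: one taxonomic clade and one metabolite
group, with control subgroups receiving one perturbation each and cases
both.
"""

from mmrules.simulate import ScenarioConfig, fabricate_baseline, generate_scenario

baseline = fabricate_baseline(seed=1)
ds = generate_scenario(baseline, ScenarioConfig(scenario=5, n_subjects=64, seed=42))

print(f"taxa counts:        {ds.taxa.values.shape} (subjects x taxa)")
print(f"metabolite levels:  {ds.metab.values.shape} (subjects x metabolites)")
print(f"cases / controls:   {ds.labels.array.sum()} / {(1 - ds.labels.array).sum()}")
print(f"perturbed clade:    {len(ds.truth['taxa_clades'][0])} taxa")
print(f"perturbed group:    {len(ds.truth['metab_groups'][0])} metabolites")
print(f"first clade members: {ds.truth['taxa_clades'][0][:4]} ...")

# The truth sets are what a detection method should recover: the clade's
# relative abundance and the group's standardized levels differ between
# the synthetic case and control populations by the calibrated effects.
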