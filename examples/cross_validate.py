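"""Cross-validated prediction on a small semi-synthetic dataset.

Runs stratified 5-fold cross-validation of the rule network on a
48-subject scenario-1 dataset (scaled-down fit: 3000 epochs, 2 restart
seeds per fold).  Metabolite standardization is re-fit on each training
fold, so held-out subjects never leak into the transform.
"""

import numpy as np

from mmrules.fit import FitConfig, cross_validate
from mmrules.model import HyperParams
from mmrules.pipeline import prepare_synthetic
from mmrules.simulate import ScenarioConfig, fabricate_baseline, generate_scenario

baseline = fabricate_baseline(seed=1)
ds = generate_scenario(baseline, ScenarioConfig(scenario=1, n_subjects=48, seed=8))
prep = prepare_synthetic(ds)

cv = cross_validate(
    prep.taxa_rel, prep.metab_raw, prep.emb_T, prep.emb_M, ds.labels,
    prep.prior_T, prep.prior_M, HyperParams(),
    FitConfig(epochs=3000, seeds=2), base_seed=0,
)
print("per-fold held-out AUC:", np.round(cv.fold_aucs, 2))
print(f"mean fold AUC: {cv.mean_auc:.3f}   pooled AUC: {cv.pooled_auc:.3f}")
print(cv.predictions.head().to_string(index=False))
# An AUC well above 0.5 means the learned rules generalize to held-out
# subjects; at this small n, individual folds are noisy.
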