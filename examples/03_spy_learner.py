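"""Train the two-step spy learner and audit its threshold.

Seeds 10% of the labeled positives into the unlabeled pool, repeats the
first step 25 times, and averages the minimum spy probability into the
reliable-negative threshold. Prints the threshold, the reliable-negative
count and purity (checkable here because the generator records the latent
class), and the step-2 training label mean that later serves as the
classification threshold.
"""

import pandas as pd

from pucase import GeneratorConfig, SpyConfig, generate_pu_dataset, spy_fit, spy_predict
from pucase.datagen import strong_shift_cost_features

dataset = generate_pu_dataset(
    GeneratorConfig(
        n_cases=1500,
        class_prior=0.2,
        label_frequency=0.5,
        cost_features=strong_shift_cost_features(),
        seed=3,
    )
)
config = SpyConfig(spy_fraction=0.10, n_repeats=25, seed=0)
fit = spy_fit(dataset, config)

f = dataset.frame
y = pd.Series(f["y"].to_numpy(), index=f["case_id"].to_numpy())
rn = list(fit.reliable_negative_ids)
purity = (y.loc[rn] == 0).mean()
print(f"averaged spy threshold t:    {fit.threshold_t:.4f}")
print(f"spread of per-repeat minima: {fit.per_repeat_min.std():.4f}")
print(f"reliable negatives:          {len(rn)} (share truly negative: {purity:.3f})")
print(f"step-2 training label mean:  {fit.step2_train_label_mean:.4f}")

preds = spy_predict(fit, dataset)
pos_ids = f.loc[f["s"] == 1, "case_id"]
recall = (preds.loc[pos_ids] >= fit.step2_train_label_mean).mean()
print(f"recall on labeled positives at that threshold: {recall:.3f}")
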