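# pucase

Positive-unlabeled (PU) learning for case ascertainment in hospital
administrative cost data.

Conditions like sepsis are systematically under-coded in administrative
data: a case with an explicit diagnosis code is reliably positive, but an
uncoded case may simply have been missed. Treating coded cases as the only
positives and everything else as *unlabeled* — never as negative — turns
case finding into a PU learning problem. `pucase` implements that analysis
end to end for researchers in health services research and hospital
management who want to quantify and repair under-coding:

- a **synthetic case-table generator** with known class prior α = p(y=1)
  and label frequency c = p(s=1|y=1) under the SCAR labeling mechanism
  (zero-inflated log-normal cost features, procedure counts, coding flags,
  cohort fields), so algorithm behavior can be tested against ground truth
  that real data never provides;
- **cohort filters and undersampling** (keep all labeled positives + a
  random unlabeled subsample);
- the two-step **spy learner**: seed 10% of labeled positives into the
  unlabeled pool, fit positives vs. unlabeled, repeat with fresh spy draws
  and average the minimum spy probability into a reliable-negative
  threshold t; train a supervised step-2 model on positives vs. reliable
  negatives;
- the **adaptive-resampling ensemble**: iteratively estimate each
  instance's mislabel probability, resample each putative class weighted
  against mislabeling, and ensemble 20 radial-kernel SVM fits on
  low-mislabel resamples;
- **PU-estimable evaluation**: recall r = TP/(TP+FN), recall@k and
  precision@k over the top k% of probability-ranked cases, five-fold
  cross-validated, across five coding-strategy truth scenarios
  (A explicit, B explicit∧implicit, C implicit, D explicit∨implicit,
  E implicit-only), plus prediction-CDF diagnostics;
- the **external validity check**: transfer a relabel count r from the
  learning sample to the initial population,
  s_i = l_i + u_i · r / u_t, new rate s = s_i / n_i, and benchmark the
  ratio s / (l_i/n_i) against the 2.4–4.1 range that medical record
  review studies report for sepsis.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
from pucase import (AdaConfig, GeneratorConfig, ada_fit, ada_predict,
                    generate_pu_dataset)
from pucase.datagen import strong_shift_cost_features
import pandas as pd

ds = generate_pu_dataset(GeneratorConfig(
    n_cases=1500, class_prior=0.2, label_frequency=0.5,
    cost_features=strong_shift_cost_features(), seed=3))
fit = ada_fit(ds, AdaConfig(seed=0))
preds = ada_predict(fit, ds)

f = ds.frame
s = pd.Series(f["s"].to_numpy(), index=f["case_id"].to_numpy())
y = pd.Series(f["y"].to_numpy(), index=f["case_id"].to_numpy())
ml = fit.per_case_mislabel_probability
print(f"mislabel prob, hidden positives: {ml[(s==0)&(y==1)].mean():.3f}")
print(f"mislabel prob, true negatives:   {ml[(s==0)&(y==0)].mean():.3f}")
print(f"recall at label-mean threshold:  "
      f"{(preds[s==1] >= fit.train_label_mean).mean():.3f}")
```

prints

```
mislabel prob, hidden positives: 0.520
mislabel prob, true negatives:   0.004
recall at label-mean threshold:  0.993
```

The hidden positives — latent positives the labeling process missed — are
flagged as likely mislabeled (0.52 vs. 0.004 for true negatives), and at
the class-label-mean classification threshold the ensemble recovers 99.3%
of the labeled positives. The `examples/` directory walks through each
capability: generation, filtering, both learners, scenario evaluation,
external validity and the full persisted pipeline.

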