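"""Apply inclusion filters and undersample the unlabeled pool.

Plants known cohort violations (underage cases, missing DRG, zero length
of stay) in a generated table, filters them out, and then builds a
balanced learning sample that keeps every labeled positive plus a random
unlabeled subsample — printing the exclusion tally and the resulting
positive class label mean.
"""

from pucase import (
    GeneratorConfig,
    apply_cohort_filters,
    compute_class_label_mean,
    generate_pu_dataset,
    inject_cohort_noise,
    undersample,
)

dataset = generate_pu_dataset(GeneratorConfig(n_cases=3000, seed=4))
noisy, log = inject_cohort_noise(
    dataset,
    {"underage": 0.05, "missing_drg": 0.03, "zero_length_of_stay": 0.02},
    seed=0,
)
print(f"planted violations: {log['violation'].value_counts().to_dict()}")

filtered, report = apply_cohort_filters(noisy)
print(f"excluded per rule:  {report.n_excluded_by_rule}")
print(f"survivors:          {report.n_output} of {report.n_input}")

learning = undersample(filtered, n_unlabeled=800, seed=0)
mean = compute_class_label_mean(learning)
print(f"learning sample:    {learning.n_cases} cases, label mean {mean:.4f}")
print("every labeled positive was retained; only the unlabeled pool was thinned")
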