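"""Generate a synthetic PU case table and inspect its structure.

Draws 2,000 hospital-style inpatient cases with latent sepsis class prior
alpha = 0.2 and SCAR label frequency c = 0.5, then prints the observed
label share (which targets alpha * c = 0.10), the empirical label
frequency among latent positives (recovering c), and the cost shift that
separates coded cases from the rest.
"""

from pucase import GeneratorConfig, generate_pu_dataset, write_case_table

config = GeneratorConfig(n_cases=2000, class_prior=0.2, label_frequency=0.5, seed=1)
dataset = generate_pu_dataset(config)
f = dataset.frame

labeled = f["s"] == 1
latent_pos = f["y"] == 1
print(f"cases generated:            {dataset.n_cases}")
print(f"observed label share:       {dataset.labeled_fraction:.3f}  (alpha*c = 0.100)")
print(f"c recovered among latents:  {f.loc[latent_pos, 's'].mean():.3f}  (c = 0.500)")
ratio = f.loc[labeled, "total_costs"].mean() / f.loc[~labeled, "total_costs"].mean()
print(f"labeled/unlabeled cost ratio: {ratio:.2f}")
print(f"feature columns: {dataset.feature_columns}")

path = write_case_table(dataset, "scratch_cases.csv")
print(f"case table written to {path}")
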