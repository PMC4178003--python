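"""Fit the class-weighted 1-norm linear SVM on the three-marker panel.

The classifier minimizes ||w||_1 plus class-weighted slack, solved exactly
as a linear program. The L1 penalty drives unused weights to exactly zero;
the class penalties up-weight the minority (severe) class by the
negative/positive count ratio.
"""

from sepsipanel import (GeneratorConfig, class_penalties, fit_l1_svm,
                        normalize, sample_cohort)

cohort = sample_cohort(GeneratorConfig(seed=42, dropout_prob=0.0))
panel = ["Ang-2", "Ang-1", "HCO3"]
X_norm, params = normalize(cohort.features().loc[:, panel])
y = cohort.labels()

penalties = class_penalties(y)
model, diag = fit_l1_svm(X_norm, y, penalties=penalties, norm_params=params)

print(f"class penalties (C_pos, C_neg): ({penalties[0]:.3f}, {penalties[1]:.3f})")
for name, w in zip(model.feature_names, model.weights):
    print(f"  weight[{name:>5s}] = {w:+.4f}")
print(f"  bias            = {model.bias:+.4f}")
print(f"LP objective: {diag.objective_value:.4f}; "
      f"nonzero weights: {diag.n_nonzero_weights}/3")
print("\nSigns match the clinical picture: severe sepsis shows high Ang-2")
print("with depressed Ang-1 and bicarbonate.")
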