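"""Generate a synthetic PICU sepsis cohort and inspect its structure.

The generator emulates the statistical skeleton of a 45-patient two-group
observational study: up to 10 blood draws per patient over 7 days, a
strongly correlated electrolyte block in the non-severe group, an
angiopoietin pair that couples in the severe group, and planted severe-group
shifts (Ang-2 up, Ang-1 down, HCO3 down) that fade after day 2 for the
treatment-responsive marker.
"""

from sepsipanel import GeneratorConfig, group_correlations, sample_cohort

cohort = sample_cohort(GeneratorConfig(seed=42))
f = cohort.frame

print(f"cohort: {cohort.n_samples} blood draws from "
      f"{f['patient_id'].nunique()} patients")
print(f"severe patients: {f.groupby('patient_id')['label'].first().sum()}")
print(f"draws per day:\n{f['day'].value_counts().sort_index().to_string()}")

corr = group_correlations(cohort.features(), cohort.labels())
print("\nNa-Cl correlation      non-severe: "
      f"{corr[0].loc['Na', 'Cl']:.3f}   severe: {corr[1].loc['Na', 'Cl']:.3f}")
print("Ang-1-Ang-2 correlation non-severe: "
      f"{corr[0].loc['Ang-1', 'Ang-2']:.3f}   severe: {corr[1].loc['Ang-1', 'Ang-2']:.3f}")
print("\nThe electrolytes de-correlate in the severe group while the")
print("angiopoietins couple — the group contrast the selection step exploits.")
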