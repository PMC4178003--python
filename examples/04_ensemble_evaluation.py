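"""Repeated-split bagged-ensemble evaluation of the panel.

A random third of the draws is held out; 50 bootstrap resamples of the rest
each train one L1 SVM whose mean is the ensemble decision function; the
four diagnostic measures are computed on the held-out third. Averaging over
repeated splits gives the reported means and standard errors. (R is reduced
here so the example runs in seconds; the full protocol uses R=100.)
"""

from sepsipanel import GeneratorConfig, repeated_evaluation, sample_cohort

cohort = sample_cohort(GeneratorConfig(seed=42))
res = repeated_evaluation(cohort.features(), cohort.labels(),
                          ("Ang-2", "Ang-1", "HCO3"), B=50, R=20, seed=0)

print(f"bagged L1-SVM ensemble, B={res.B}, repeats R={res.R}")
for m in ("TPR", "TNR", "PPV", "NPV"):
    print(f"  {m}: {res.mean(m):.3f} +/- {res.se(m):.3f}")
print("\nTPR/TNR are sensitivity and specificity; PPV/NPV the predictive")
print("values. On this synthetic cohort the panel separates the groups")
print("far more cleanly than any single biomarker.")
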