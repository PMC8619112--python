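"""Classification comparison: in-sample sensitivity/specificity of both models.

Each replicate draws a fresh true model (coefficients uniform on (−2.5, 2.5),
absolute effect uniform on (0, 2), relative effect uniform on (−0.7, −0.3),
sum-to-zero coding), simulates n=1000 subjects, fits both models and
classifies at probability threshold 0.5.  Uses 100 replicates here (the
full comparison uses 1000).
"""

from abrelates import classification_study

out = classification_study(reps=100, delta_range=(-0.7, -0.3), n=1000, seed=3)

print(out.describe().loc[["25%", "50%", "75%"]].round(3).to_string())
print(
    f"\nmedian sensitivity: enhanced {out.sensitivity_abrelates.median():.3f} "
    f"vs logistic {out.sensitivity_logistic.median():.3f}\n"
    f"median specificity: enhanced {out.specificity_abrelates.median():.3f} "
    f"vs logistic {out.specificity_logistic.median():.3f}\n"
    "When relative effects exist, the enhanced model separates the classes\n"
    "at least as well as ordinary logistic regression."
)
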