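"""Within-arm and between-arm effect measures from published coefficient tables.

Builds parameter vectors from printed trial coefficients (sepsis/synbiotic,
influenza vaccination, COVID-19 hydroxychloroquine) and prints the effect
measures a trialist would report: per-covariate log-odds changes inside each
arm, and individualized odds ratios between arms over a covariate grid.
"""

from abrelates import CodingScheme, Theta, effects_report, odds_ratio_ranges, within_group_effect
from abrelates.model import InteractionTerm

# Sepsis trial: no intercept, no absolute effect; covariates 1/weight and sex.
sepsis = Theta(0.0, [0.0], [-6.755, 0.225], [0.240])
print("Sepsis (synbiotic vs placebo)")
print(f"  weight effect, synbiotic arm (log-odds): "
      f"{within_group_effect(sepsis, 0, 1):.3f}")
print(f"  weight effect, control arm  (log-odds): "
      f"{within_group_effect(sepsis, 0, 2):.3f}")
print(f"  male-vs-female odds multiplier, synbiotic arm: "
      f"{within_group_effect(sepsis, 1, 1, scale='odds'):.3f}\n")

# Influenza vaccination: HAI titer level in the vaccinated arm.
flu = Theta(0.0, [-1.596], [-0.280, -0.590], [-0.242])
print("Influenza (vaccinated vs control)")
print(f"  HAI titer effect, vaccinated arm (log-odds): "
      f"{within_group_effect(flu, 1, 1):.3f}\n")

# COVID-19 hydroxychloroquine trial: sum-to-zero coding, symptoms interaction.
covid = Theta(0.0, [-3.279], [-0.099, -0.947, 0.833, 0.463], [-0.513])
sz = CodingScheme("sum_zero")
terms = (InteractionTerm(column=3, treatment=1, base_column=2),)
print("COVID-19 (hydroxychloroquine vs placebo)")
print(f"  per-symptom effect, treatment arm (log-odds): "
      f"{within_group_effect(covid, 2, 1, coding=sz, interactions=terms):.3f}")
print(f"  per-symptom effect, placebo arm  (log-odds): "
      f"{within_group_effect(covid, 2, 2, coding=sz, interactions=terms):.3f}\n")

table = effects_report(
    covid,
    {"age": [25, 30, 40], "weight": [139, 200, 385], "symptoms": [0]},
    1, 2,
    covariate_names=("age", "weight", "symptoms", "symptoms_x_t1"),
    coding=sz,
    interactions=terms,
    transforms={"weight": lambda w: 500.0 / w},
)
print("Individualized odds ratios, treatment vs placebo (0 symptoms):")
print(table.to_string(index=False))
print("\nOdds-ratio range per age as weight sweeps 139-385 lb:")
print(odds_ratio_ranges(table, over="weight").to_string(index=False))
print("\nAn odds ratio below 1 means the treatment lowers the infection odds"
      "\nfor that covariate profile - the individualized treatment effect.")
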