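"""Fit the enhanced model and ordinary logistic regression to one synthetic trial.

Simulates a two-arm trial (n=1000) in which the treatment both shifts the
log-odds (absolute effect τ1 = −1) and scales it (relative effect
δ1 = −0.3), fits both models, and prints the coefficient tables.
"""

from abrelates import FitOptions, benchmark_design, fit, fit_logistic, generate_dataset

design = benchmark_design(n=1000, delta1=-0.3, seed=42)
data = generate_dataset(design)

res = fit(data, FitOptions(grid_points=41))
res_log = fit_logistic(data)

print("Enhanced model (absolute + relative treatment effects)")
print(res.summary().to_string(index=False))
print(f"log-likelihood: {res.loglik:.3f}\n")

print("Ordinary logistic regression (relative effect forced to zero)")
print(res_log.summary().to_string(index=False))
print(f"log-likelihood: {res_log.loglik:.3f}\n")

print(
    "tau1 is the additive treatment effect on the log-odds; delta1 scales the\n"
    "whole linear predictor of the treated arm by (1 + delta1). The logistic\n"
    "fit cannot represent the scaling, so its treatment coefficient is biased\n"
    f"toward zero ({res_log.estimate('tau1'):.3f} vs a generative -1), while "
    f"the enhanced fit recovers both\n"
    f"tau1 = {res.estimate('tau1'):.3f} and delta1 = {res.estimate('delta1'):.3f}."
)
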