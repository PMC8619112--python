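"""Synthetic randomized trials from the AbRelaTEs generative model, and the
Monte-Carlo machinery that measures estimation quality and the coverage
collapse of ordinary logistic regression when relative effects exist.

A replicate draws covariates per the design (i.i.d. standard normal or
Bernoulli columns), expands declared treatment×covariate interaction
columns under the coding in force, computes the success probability

    π_i = φ( (μ0 + τ_{j(i),0} + x_i'β0)(1 + δ_{j(i),0}) )

and samples Bernoulli outcomes.  ``mc_study`` fits both the AbRelaTEs model
and ordinary logistic regression to every replicate and tabulates, per
parameter and model, the mean estimate, the SD of the estimates, the mean
model-based SE, and the empirical coverage of nominal 95% Wald intervals —
for the logistic fit the coverage target for the treatment coefficient is
the generative τ1,0, which is exactly the misspecification being measured.

Two reference two-arm designs used throughout the package (equal
allocation, μ0 = 0):

* ``benchmark_design`` — four standard-normal covariates,
  β0 = (−0.5, 0.5, −0.5, 0.5), τ1,0 = −1, baseline coding;
* ``benchmark_interaction_design`` — two standard-normal covariates plus
  interactions t₁x₁ and t₁x₂ with the same β0 and τ1,0, sum-to-zero coding
  (τ2,0 = −τ1,0, δ2,0 = −δ1,0, ±1 indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fit import FitOptions, FitResult, fit, fit_logistic
from .model import (
    SUM_ZERO,
    CodingScheme,
    InteractionTerm,
    ModelSpecError,
    Theta,
    TrialData,
    indicator_matrix,
    predict_prob,
)

__all__ = [
    "CovariateSpec",
    "SimDesign",
    "MCReport",
    "benchmark_design",
    "benchmark_interaction_design",
    "generate_dataset",
    "mc_study",
    "classification_study",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column law: ``std_normal`` or ``bernoulli`` (prob)."""

    kind: str = "std_normal"
    prob: float = 0.5

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "std_normal":
            return rng.standard_normal(n)
        if self.kind == "bernoulli":
            return rng.binomial(1, self.prob, size=n).astype(float)
        raise ModelSpecError(f"unknown covariate law {self.kind!r}")


@dataclass
class SimDesign:
    """Generative specification of a two-or-more-arm trial.

    interactions are pairs (treatment index, base covariate index); each
    adds a column equal to the coded indicator of that treatment times the
    base covariate, appended after the base covariates in the given order.
    beta0 covers base covariates then interaction columns.
    """

    n: int
    tau0: tuple | float
    beta0: tuple
    delta0: tuple | float
    mu0: float = 0.0
    g: int = 2
    coding: CodingScheme = field(default_factory=CodingScheme)
    covariates: tuple[CovariateSpec, ...] = ()
    interactions: tuple[tuple[int, int], ...] = ()
    allocation: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self):
        self.tau0 = np.atleast_1d(np.asarray(self.tau0, dtype=float))
        self.delta0 = np.atleast_1d(np.asarray(self.delta0, dtype=float))
        self.beta0 = np.asarray(self.beta0, dtype=float)
        if np.any(np.abs(self.delta0) >= 1):
            raise ModelSpecError("true relative effects must lie in (-1, 1)")
        if self.allocation is None:
            self.allocation = tuple([1.0 / self.g] * self.g)
        if abs(sum(self.allocation) - 1.0) > 1e-9:
            raise ModelSpecError("allocation fractions must sum to 1")
        if self.beta0.size != len(self.covariates) + len(self.interactions):
            raise ModelSpecError(
                "beta0 must cover base covariates plus interaction columns"
            )

    def true_theta(self) -> Theta:
        return Theta(self.mu0, self.tau0, self.beta0, self.delta0)

    def interaction_terms(self) -> tuple[InteractionTerm, ...]:
        base = len(self.covariates)
        return tuple(
            InteractionTerm(column=base + k, treatment=tj, base_column=cj)
            for k, (tj, cj) in enumerate(self.interactions)
        )

    def echo(self) -> dict:
        d = asdict(self)
        d["tau0"] = list(np.atleast_1d(self.tau0))
        d["delta0"] = list(np.atleast_1d(self.delta0))
        d["beta0"] = list(self.beta0)
        d["coding"] = self.coding.kind
        return d


def benchmark_design(n: int, delta1: float = -0.3, seed: int | None = None) -> SimDesign:
    """Two-arm design with four standard-normal covariates and no interactions."""
    return SimDesign(
        n=n,
        tau0=-1.0,
        beta0=(-0.5, 0.5, -0.5, 0.5),
        delta0=delta1,
        covariates=tuple(CovariateSpec() for _ in range(4)),
        seed=seed,
    )


def benchmark_interaction_design(
    n: int, delta1: float = -0.5, seed: int | None = None
) -> SimDesign:
    """Two-arm sum-to-zero design: two covariates plus t₁x₁ and t₁x₂ interactions."""
    return SimDesign(
        n=n,
        tau0=-1.0,
        beta0=(-0.5, 0.5, -0.5, 0.5),
        delta0=delta1,
        coding=CodingScheme(SUM_ZERO),
        covariates=(CovariateSpec(), CovariateSpec()),
        interactions=((1, 0), (1, 1)),
        seed=seed,
    )


def generate_dataset(design: SimDesign, rng: np.random.Generator | None = None) -> TrialData:
    """Draw one trial: deterministic given the design seed (or supplied rng)."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    counts = [int(round(design.n * f)) for f in design.allocation]
    counts[-1] = design.n - sum(counts[:-1])
    group = np.repeat(np.arange(1, design.g + 1), counts)
    Xbase = np.column_stack([c.draw(design.n, rng) for c in design.covariates]) \
        if design.covariates else np.empty((design.n, 0))
    cols = [Xbase]
    ind = indicator_matrix(group, design.g, design.coding)
    for tj, cj in design.interactions:
        cols.append((ind[:, tj - 1] * Xbase[:, cj])[:, None])
    X = np.hstack(cols)
    names = tuple(f"x{k + 1}" for k in range(len(design.covariates))) + tuple(
        f"t{tj}_x{cj + 1}" for tj, cj in design.interactions
    )
    data = TrialData(
        y=np.zeros(design.n),
        group=group,
        X=X,
        coding=design.coding,
        g=design.g,
        interactions=design.interaction_terms(),
        covariate_names=names,
    )
    pi = predict_prob(design.true_theta(), data)
    data.y = rng.binomial(1, pi).astype(float)
    return data


@dataclass
class MCReport:
    """Per-parameter, per-model Monte-Carlo summary.

    table columns: model, parameter, truth, estimate (mean over replicates),
    sd (SD of estimates), se (mean model-based SE), cp (empirical coverage
    of nominal 95% Wald intervals).
    """

    table: pd.DataFrame
    reps_requested: int
    reps_completed: dict
    design: dict
    warnings: list[str] = field(default_factory=list)

    def value(self, model: str, parameter: str, column: str) -> float:
        t = self.table
        row = t[(t.model == model) & (t.parameter == parameter)]
        if row.empty:
            raise KeyError((model, parameter))
        return float(row[column].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        payload = {
            "design": self.design,
            "reps_requested": self.reps_requested,
            "reps_completed": self.reps_completed,
            "warnings": self.warnings,
            "table": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _truths(design: SimDesign, names: list[str]) -> dict:
    truth = {"mu": design.mu0}
    for j, t in enumerate(np.atleast_1d(design.tau0), start=1):
        truth[f"tau{j}"] = float(t)
    for j, d in enumerate(np.atleast_1d(design.delta0), start=1):
        truth[f"delta{j}"] = float(d)
    # covariate names as generated
    nb = len(design.covariates)
    gen_names = [f"x{k + 1}" for k in range(nb)] + [
        f"t{tj}_x{cj + 1}" for tj, cj in design.interactions
    ]
    for nm, b in zip(gen_names, design.beta0):
        truth[nm] = float(b)
    return {k: truth[k] for k in names if k in truth}


def _usable(res: FitResult) -> bool:
    return res.converged and res.cov is not None and np.all(np.isfinite(res.se))


def mc_study(
    design: SimDesign,
    reps: int,
    options: FitOptions | None = None,
    seed: int | None = None,
    level: float = 0.95,
) -> MCReport:
    """Repeatedly simulate and fit both models; tabulate estimate/SD/SE/CP.

    Non-converged replicates (or replicates whose observed information is
    not invertible) are dropped from the summaries of the affected model
    and counted in ``reps_completed``.
    """
    if reps < 1:
        raise ModelSpecError("reps must be at least 1")
    options = options or FitOptions()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    collected = {"abrelates": [], "logistic": []}
    for _ in range(reps):
        data = generate_dataset(design, rng)
        try:
            res_a = fit(data, options)
        except Exception:
            res_a = None
        try:
            res_l = fit_logistic(data, options)
        except Exception:
            res_l = None
        if res_a is not None and _usable(res_a):
            collected["abrelates"].append(res_a)
        if res_l is not None and _usable(res_l):
            collected["logistic"].append(res_l)
    rows = []
    completed = {}
    warnings = []
    for model, results in collected.items():
        completed[model] = len(results)
        if not results:
            continue
        names = results[0].param_names
        truth = _truths(design, names)
        est = np.array([r.estimates for r in results])
        se = np.array([r.se for r in results])
        lo = np.array([r.ci_low for r in results])
        hi = np.array([r.ci_high for r in results])
        for k, nm in enumerate(names):
            row = {
                "model": model,
                "parameter": nm,
                "truth": truth.get(nm, np.nan),
                "estimate": est[:, k].mean(),
                "sd": est[:, k].std(ddof=1),
                "se": se[:, k].mean(),
                "cp": np.nan,
            }
            if nm in truth:
                row["cp"] = float(
                    np.mean((lo[:, k] <= truth[nm]) & (truth[nm] <= hi[:, k]))
                )
            rows.append(row)
        if len(results) < 0.9 * reps:
            warnings.append(
                f"{model}: only {len(results)}/{reps} replicates converged"
            )
    return MCReport(
        table=pd.DataFrame(rows),
        reps_requested=reps,
        reps_completed=completed,
        design=design.echo(),
        warnings=warnings,
    )


def _sens_spec(y: np.ndarray, prob: np.ndarray, threshold: float = 0.5):
    pred = prob >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    return sens, spec


def classification_study(
    reps: int,
    delta_range: tuple[float, float] = (-0.7, -0.3),
    n: int = 1000,
    seed: int | None = None,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """In-sample sensitivity/specificity comparison over random true models.

    Each replicate draws β_{j,0} ~ U(−2.5, 2.5) for the three covariates
    and the t₁x₁ interaction, τ1,0 ~ U(0, 2) and δ1,0 ~ U(delta_range)
    under sum-to-zero coding; covariates are x₁, x₂ standard normal and
    x₃ Bernoulli(0.5).  Both models are fitted and classified at
    probability threshold 0.5.  Degenerate replicates (all-0 or all-1
    outcomes) are redrawn.  Returns one row per replicate with paired
    metrics.
    """
    options = options or FitOptions(grid_points=41, fix_mu_zero=True)
    rng = np.random.default_rng(seed)
    rows = []
    redrawn = 0
    while len(rows) < reps:
        beta = rng.uniform(-2.5, 2.5, size=4)
        tau1 = rng.uniform(0.0, 2.0)
        lo, hi = delta_range
        delta1 = rng.uniform(lo, hi) if hi > lo else float(lo)
        design = SimDesign(
            n=n,
            tau0=tau1,
            beta0=tuple(beta),
            delta0=delta1,
            coding=CodingScheme(SUM_ZERO),
            covariates=(CovariateSpec(), CovariateSpec(), CovariateSpec("bernoulli")),
            interactions=((1, 0),),
        )
        data = generate_dataset(design, rng)
        if data.y.min() == data.y.max():
            redrawn += 1
            continue
        try:
            res_a = fit(data, options)
            res_l = fit_logistic(data, options)
        except Exception:
            redrawn += 1
            continue
        sens_a, spec_a = _sens_spec(data.y, predict_prob(res_a.theta, data))
        sens_l, spec_l = _sens_spec(data.y, predict_prob(res_l.theta, data))
        rows.append(
            {
                "replicate": len(rows),
                "delta1_true": delta1,
                "tau1_true": tau1,
                "sensitivity_abrelates": sens_a,
                "specificity_abrelates": spec_a,
                "sensitivity_logistic": sens_l,
                "specificity_logistic": spec_l,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["redrawn"] = redrawn
    return out
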