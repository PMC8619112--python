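"""Core model objects for the AbRelaTEs enhanced logistic regression.

The model extends classical logistic regression for a randomized trial
with ``g`` arms (arm ``g`` is the control) by multiplying the whole linear
predictor of arm ``j`` with a *relative treatment effect* factor ``1 + δ_j``::

    logit P(Y=1 | x, arm j) = (μ + τ_j + x'β) (1 + δ_j)

``τ_j`` is the familiar additive ("absolute") treatment effect on the
log-odds; ``δ_j ∈ (−1, 1)`` scales the entire log-odds proportionally, so
the effect of treatment varies with the covariate profile x — an
individualized effect.  With δ = 0 the model is exactly ordinary logistic
regression.

Two codings of the arm indicators are supported:

* ``baseline`` — the control arm carries τ = δ = 0 and 0/1 indicators;
* ``sum_zero`` — two arms only, τ₂ = −τ₁ and δ₂ = −δ₁ with ±1 indicators.

Interaction columns (treatment indicator × base covariate) are pre-expanded
into the covariate matrix and flagged so that effect measures can fold the
interaction coefficient in with the arm-appropriate sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CodingScheme",
    "InteractionTerm",
    "Theta",
    "TrialData",
    "coded_indicator",
    "indicator_matrix",
    "linear_predictor",
    "log_likelihood",
    "predict_prob",
]

BASELINE = "baseline"
SUM_ZERO = "sum_zero"


class ModelSpecError(ValueError):
    """Inconsistent parameter/data specification (dimension or domain)."""


@dataclass(frozen=True)
class CodingScheme:
    """How treatment-arm indicators are coded.

    kind
        ``"baseline"``: the control arm (internal index g) has τ = δ = 0 and
        indicator columns are 0/1.
        ``"sum_zero"``: valid for two arms only; τ₂ = −τ₁, δ₂ = −δ₁, and the
        single indicator is +1 for the treatment arm and −1 for control.
    """

    kind: str = BASELINE

    def __post_init__(self):
        if self.kind not in (BASELINE, SUM_ZERO):
            raise ModelSpecError(f"unknown coding kind {self.kind!r}")


@dataclass(frozen=True)
class InteractionTerm:
    """Flags column ``column`` of X as (indicator of treatment ``treatment``) × (column ``base_column``).

    ``treatment`` is the 1-based treatment index (never the control arm).
    ``base_column`` may be None when the base covariate is not itself a
    column of X; effect measures that must recompute the interaction per arm
    then require it.
    """

    column: int
    treatment: int = 1
    base_column: int | None = None


def coded_indicator(group: int, treatment: int, g: int, coding: CodingScheme) -> float:
    """Coded indicator of treatment ``treatment`` for a subject in arm ``group``."""
    if coding.kind == SUM_ZERO:
        if g != 2 or treatment != 1:
            raise ModelSpecError("sum_zero coding requires exactly two arms")
        return 1.0 if group == 1 else -1.0
    return 1.0 if group == treatment else 0.0


def indicator_matrix(group: np.ndarray, g: int, coding: CodingScheme) -> np.ndarray:
    """n × (g−1) matrix of coded treatment indicators (one column per treatment)."""
    group = np.asarray(group)
    if coding.kind == SUM_ZERO:
        if g != 2:
            raise ModelSpecError("sum_zero coding requires exactly two arms")
        return np.where(group[:, None] == 1, 1.0, -1.0)
    return (group[:, None] == np.arange(1, g)[None, :]).astype(float)


@dataclass
class Theta:
    """Full parameter vector (μ, τ₁..τ_{g−1}, β₁..β_p, δ₁..δ_{g−1}).

    The control-arm constraint (τ_g = δ_g = 0 under baseline coding, the
    sum-to-zero identities under sum_zero) is resolved through the coding
    scheme at evaluation time, so only the g−1 free treatment parameters are
    stored.  Every δ_j must lie strictly inside (−1, 1).
    """

    mu: float
    tau: np.ndarray
    beta: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if self.tau.shape != self.delta.shape:
            raise ModelSpecError(
                f"tau has length {self.tau.size} but delta has length "
                f"{self.delta.size}; both must be g-1"
            )
        if np.any(np.abs(self.delta) >= 1.0):
            raise ModelSpecError(
                f"relative effects must lie strictly in (-1, 1); got {self.delta}"
            )

    @property
    def g(self) -> int:
        return self.tau.size + 1

    @property
    def p(self) -> int:
        return self.beta.size

    def beta_star(self) -> np.ndarray:
        """(μ, τ', β')' — the coefficient block multiplying the scaled design."""
        return np.concatenate(([self.mu], self.tau, self.beta))

    def as_vector(self) -> np.ndarray:
        """(μ, τ', β', δ')' in one flat array of length 2g + p − 1."""
        return np.concatenate(([self.mu], self.tau, self.beta, self.delta))

    @classmethod
    def from_vector(cls, vec: np.ndarray, g: int, p: int) -> "Theta":
        vec = np.asarray(vec, dtype=float)
        if vec.size != 2 * g + p - 1:
            raise ModelSpecError(
                f"parameter vector has length {vec.size}, expected {2 * g + p - 1}"
            )
        return cls(
            mu=float(vec[0]),
            tau=vec[1:g],
            beta=vec[g : g + p],
            delta=vec[g + p :],
        )

    @classmethod
    def zeros(cls, g: int, p: int) -> "Theta":
        return cls(0.0, np.zeros(g - 1), np.zeros(p), np.zeros(g - 1))


@dataclass
class TrialData:
    """One trial: binary outcomes, arm assignment, covariates, coding.

    group holds internal arm indices 1..g with the control arm mapped to g;
    ``group_labels`` remembers the original labels for reporting.  X already
    contains any expanded interaction columns, flagged in ``interactions``.
    """

    y: np.ndarray
    group: np.ndarray
    X: np.ndarray
    coding: CodingScheme = field(default_factory=CodingScheme)
    g: int = 2
    interactions: tuple[InteractionTerm, ...] = ()
    covariate_names: tuple[str, ...] | None = None
    group_labels: tuple | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        self.group = np.asarray(self.group, dtype=int).reshape(-1)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        n = self.y.size
        if self.group.size != n or self.X.shape[0] != n:
            raise ModelSpecError(
                f"outcome has {n} rows but group has {self.group.size} "
                f"and X has {self.X.shape[0]}"
            )
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ModelSpecError("outcome vector must be binary 0/1")
        if not np.all(np.isfinite(self.X)):
            raise ModelSpecError("covariate matrix contains non-finite values")
        present = np.unique(self.group)
        if present.min() < 1 or present.max() > self.g or present.size != self.g:
            raise ModelSpecError(
                f"group indices must cover 1..{self.g} with every arm non-empty; "
                f"found {present}"
            )
        if self.covariate_names is not None and len(self.covariate_names) != self.p:
            raise ModelSpecError("covariate_names length does not match X")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def treat_indicators(self) -> np.ndarray:
        """Coded indicator matrix T (n × g−1) for the absolute effects."""
        return indicator_matrix(self.group, self.g, self.coding)

    def rel_indicators(self) -> np.ndarray:
        """Coded indicator matrix R for the relative effects (same coding as T)."""
        return indicator_matrix(self.group, self.g, self.coding)

    def design(self) -> np.ndarray:
        """V = [1 | T | X], the n × (g + p) unscaled design matrix."""
        return np.column_stack(
            [np.ones(self.n), self.treat_indicators(), self.X]
        )


def _check_dims(theta: Theta, data: TrialData) -> None:
    if theta.g != data.g:
        raise ModelSpecError(
            f"theta encodes {theta.g} arms but data has {data.g}"
        )
    if theta.p != data.p:
        raise ModelSpecError(
            f"theta has {theta.p} covariate coefficients but X has {data.p} columns"
        )


def linear_predictor(theta: Theta, data: TrialData) -> np.ndarray:
    """Per-subject log-odds (μ + τ_{j(i)} + x_i'β)(1 + δ_{j(i)}).

    τ and δ are resolved through the coding scheme, so under sum_zero the
    control arm receives −τ₁ and multiplier 1 − δ₁.
    """
    _check_dims(theta, data)
    m = 1.0 + data.rel_indicators() @ theta.delta
    base = theta.mu + data.treat_indicators() @ theta.tau + data.X @ theta.beta
    return base * m


def predict_prob(theta: Theta, data: TrialData) -> np.ndarray:
    """Success probabilities φ(linear predictor), φ(u) = e^u / (1 + e^u)."""
    from scipy.special import expit

    return expit(linear_predictor(theta, data))


def log_likelihood(theta: Theta, data: TrialData) -> float:
    """Bernoulli log-likelihood Σ y·lp − log(1 + e^lp), computed stably."""
    lp = linear_predictor(theta, data)
    return float(np.sum(data.y * lp - np.logaddexp(0.0, lp)))
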