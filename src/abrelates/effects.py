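"""Effect measures: within-arm covariate effects and between-arm odds ratios.

Within-arm ("within-group") effects interpret one covariate inside one arm:
per unit increase of covariate k in arm j, the log-odds change by
``(β_k + c_j γ_k)(1 + δ_j)`` where γ_k is the coefficient of an interaction
column flagged to covariate k (0 if none) and c_j is the coded treatment
indicator of arm j (so the sign flips with arm under sum-to-zero coding).

Between-arm ("between-group") effects compare two arms at one fixed
covariate profile — the individualized treatment effect.  Under baseline
coding, against the control arm, the log-odds ratio reduces to
``τ_j + (μ + τ_j + x'β) δ_j``.
"""

from __future__ import annotations

import math

import numpy as np

from .model import (
    CodingScheme,
    InteractionTerm,
    ModelSpecError,
    Theta,
    coded_indicator,
)

__all__ = [
    "within_group_effect",
    "log_odds_ratio",
    "odds_ratio",
    "constrained_relative_change",
]


def _delta_multiplier(theta: Theta, group: int, coding: CodingScheme) -> float:
    """1 + R(group)'δ for a subject in arm ``group``."""
    r = np.array(
        [coded_indicator(group, j, theta.g, coding) for j in range(1, theta.g)]
    )
    return 1.0 + float(r @ theta.delta)


def _tau_term(theta: Theta, group: int, coding: CodingScheme) -> float:
    t = np.array(
        [coded_indicator(group, j, theta.g, coding) for j in range(1, theta.g)]
    )
    return float(t @ theta.tau)


def _check_group(theta: Theta, group: int) -> None:
    if not 1 <= group <= theta.g:
        raise ModelSpecError(f"unknown arm {group}; model has arms 1..{theta.g}")


def within_group_effect(
    theta: Theta,
    covariate_index: int,
    group: int,
    scale: str = "log_odds",
    *,
    coding: CodingScheme | None = None,
    interactions: tuple[InteractionTerm, ...] = (),
) -> float:
    """Per-unit effect of one covariate on the log-odds (or odds) inside one arm.

    Returns ``(β_k + c γ_k)(1 + δ_j)`` on the log-odds scale, where γ_k is
    the coefficient of the interaction column whose ``base_column`` is
    ``covariate_index`` (zero when there is none) and c is the coded
    indicator of that interaction's treatment for arm ``group``.  On the
    odds scale the exponential is returned.
    """
    coding = coding or CodingScheme()
    _check_group(theta, group)
    if not 0 <= covariate_index < theta.p:
        raise ModelSpecError(
            f"covariate index {covariate_index} outside 0..{theta.p - 1}"
        )
    effect = theta.beta[covariate_index]
    for term in interactions:
        if term.base_column == covariate_index:
            c = coded_indicator(group, term.treatment, theta.g, coding)
            effect += c * theta.beta[term.column]
    effect *= _delta_multiplier(theta, group, coding)
    if scale == "log_odds":
        return float(effect)
    if scale == "odds":
        return float(math.exp(effect))
    raise ModelSpecError(f"unknown scale {scale!r}; use 'log_odds' or 'odds'")


def _arm_row(
    x: np.ndarray,
    group: int,
    theta: Theta,
    coding: CodingScheme,
    interactions: tuple[InteractionTerm, ...],
) -> np.ndarray:
    """Covariate row for one arm: interaction columns re-coded for that arm."""
    row = np.array(x, dtype=float).copy()
    for term in interactions:
        if term.base_column is None:
            raise ModelSpecError(
                "interaction term needs base_column to recompute per arm"
            )
        c = coded_indicator(group, term.treatment, theta.g, coding)
        row[term.column] = c * row[term.base_column]
    return row


def log_odds_ratio(
    theta: Theta,
    x,
    group_a: int,
    group_b: int,
    *,
    coding: CodingScheme | None = None,
    interactions: tuple[InteractionTerm, ...] = (),
) -> float:
    """Log-odds difference between arm a and arm b at covariate profile x.

    x has one entry per model column; entries of interaction columns are
    recomputed per arm from their base covariate, so the caller may leave
    them at any placeholder value.
    """
    coding = coding or CodingScheme()
    _check_group(theta, group_a)
    _check_group(theta, group_b)
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != theta.p:
        raise ModelSpecError(f"profile has {x.size} entries, model expects {theta.p}")

    def lp(group: int) -> float:
        row = _arm_row(x, group, theta, coding, interactions)
        base = theta.mu + _tau_term(theta, group, coding) + float(row @ theta.beta)
        return base * _delta_multiplier(theta, group, coding)

    return lp(group_a) - lp(group_b)


def odds_ratio(
    theta: Theta,
    x,
    group_a: int,
    group_b: int,
    *,
    coding: CodingScheme | None = None,
    interactions: tuple[InteractionTerm, ...] = (),
) -> float:
    """Odds(arm a) / Odds(arm b) at covariate profile x; strictly positive."""
    return float(
        math.exp(
            log_odds_ratio(
                theta, x, group_a, group_b, coding=coding, interactions=interactions
            )
        )
    )


def constrained_relative_change(delta: float) -> float:
    """Relative log-odds change 2δ/(1−δ) under the two-arm sum-to-zero coding.

    With τ₂ = −τ₁ and δ₂ = −δ₁ the relative change of the log-odds between
    arms (no absolute effect) is 2δ₁/(1−δ₁), not δ₁ itself.
    """
    if abs(delta) >= 1.0:
        raise ModelSpecError(f"relative effect must lie in (-1, 1); got {delta}")
    return 2.0 * delta / (1.0 - delta)
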