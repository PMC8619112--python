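"""CSV ingestion, result serialization and odds-ratio report tables."""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import odds_ratio
from .fit import FitResult
from .model import (
    CodingScheme,
    InteractionTerm,
    ModelSpecError,
    Theta,
    TrialData,
)

__all__ = [
    "RunConfig",
    "read_trial_csv",
    "effects_report",
    "odds_ratio_ranges",
    "fit_result_to_dict",
    "save_fit_json",
    "load_theta_json",
]

logger = logging.getLogger("abrelates")


@dataclass
class RunConfig:
    """Column roles and options for reading one trial CSV.

    interactions: covariate names to expand as treatment×covariate columns;
    entries may be a bare name (interacted with treatment 1) or a
    (name, treatment_index) pair.
    """

    outcome: str
    group: str
    covariates: tuple[str, ...]
    control: object
    coding: str = "baseline"
    interactions: tuple = ()
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def read_trial_csv(path, config: RunConfig) -> TrialData:
    """Read a trial table: drop incomplete rows, map the control arm to index g.

    Rows with missing values in any used column are dropped (the count is
    logged).  The outcome must be binary; interaction columns are
    synthesized from the coded treatment indicator.
    """
    df = pd.read_csv(path)
    used = [config.outcome, config.group, *config.covariates]
    for col in used:
        if col not in df.columns:
            raise ModelSpecError(f"column {col!r} not found in {path}")
    before = len(df)
    df = df.dropna(subset=used)
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values in used columns", dropped)
    y = df[config.outcome].to_numpy()
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0, 1))):
        raise ModelSpecError(
            f"outcome column {config.outcome!r} is not binary 0/1; found {vals}"
        )
    labels = list(pd.unique(df[config.group]))
    if config.control not in labels:
        raise ModelSpecError(
            f"control label {config.control!r} not present in column "
            f"{config.group!r}; found {labels}"
        )
    treat_labels = sorted((l for l in labels if l != config.control), key=str)
    ordered = treat_labels + [config.control]  # control -> internal index g
    g = len(ordered)
    index_of = {lab: j + 1 for j, lab in enumerate(ordered)}
    group = df[config.group].map(index_of).to_numpy()
    coding = CodingScheme(config.coding)

    Xbase = df[list(config.covariates)].to_numpy(dtype=float)
    names = list(config.covariates)
    from .model import indicator_matrix

    ind = indicator_matrix(group, g, coding)
    terms = []
    cols = [Xbase]
    for item in config.interactions:
        name, tj = (item, 1) if isinstance(item, str) else item
        if name not in config.covariates:
            raise ModelSpecError(f"interaction base covariate {name!r} unknown")
        base_col = names.index(name)
        cols.append((ind[:, tj - 1] * Xbase[:, base_col])[:, None])
        terms.append(
            InteractionTerm(
                column=len(names), treatment=tj, base_column=base_col
            )
        )
        names.append(f"{name}_x_t{tj}")
    X = np.hstack(cols)
    return TrialData(
        y=y.astype(float),
        group=group,
        X=X,
        coding=coding,
        g=g,
        interactions=tuple(terms),
        covariate_names=tuple(names),
        group_labels=tuple(ordered),
    )


def effects_report(
    theta: Theta,
    grid: dict,
    group_a: int,
    group_b: int,
    *,
    covariate_names: tuple[str, ...],
    coding: CodingScheme | None = None,
    interactions: tuple[InteractionTerm, ...] = (),
    transforms: dict | None = None,
) -> pd.DataFrame:
    """Odds-ratio table over the Cartesian product of a covariate grid.

    grid maps covariate names to value lists (original scale); covariates
    absent from the grid are held at 0.  ``transforms`` optionally maps a
    name to a callable applied before model evaluation (the table keeps the
    original value), e.g. a reciprocal rescaling of weight.
    """
    coding = coding or CodingScheme()
    transforms = transforms or {}
    for name in grid:
        if name not in covariate_names:
            raise ModelSpecError(f"grid covariate {name!r} unknown")
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        x = np.zeros(len(covariate_names))
        for k, v in zip(keys, combo):
            f = transforms.get(k)
            x[covariate_names.index(k)] = f(v) if f else v
        orr = odds_ratio(
            theta, x, group_a, group_b, coding=coding, interactions=interactions
        )
        rows.append(dict(zip(keys, combo), odds_ratio=orr))
    return pd.DataFrame(rows)


def odds_ratio_ranges(table: pd.DataFrame, over: str) -> pd.DataFrame:
    """Collapse an effects table to min–max odds-ratio ranges per stratum.

    ``over`` is the grid covariate whose values are swept within each
    stratum of the remaining covariates.
    """
    strata = [c for c in table.columns if c not in (over, "odds_ratio")]
    def _agg(gr):
        return pd.Series(
            {
                f"{over}_min": gr[over].min(),
                f"{over}_max": gr[over].max(),
                "or_min": gr["odds_ratio"].min(),
                "or_max": gr["odds_ratio"].max(),
            }
        )
    if strata:
        return table.groupby(strata, as_index=False).apply(_agg, include_groups=False)
    return _agg(table).to_frame().T


def fit_result_to_dict(res: FitResult, data: TrialData | None = None) -> dict:
    out = {
        "loglik": res.loglik,
        "converged": res.converged,
        "n_iter": res.n_iter,
        "n_obs": res.n_obs,
        "level": res.level,
        "warnings": res.warnings,
        "theta": {
            "mu": res.theta.mu,
            "tau": list(res.theta.tau),
            "beta": list(res.theta.beta),
            "delta": list(res.theta.delta),
        },
        "parameters": [
            {
                "name": nm,
                "coefficient": float(res.estimates[k]),
                "standard_error": float(res.se[k]),
                "p_value": float(res.p_value[k]),
                "ci_low": float(res.ci_low[k]),
                "ci_high": float(res.ci_high[k]),
            }
            for k, nm in enumerate(res.param_names)
        ],
    }
    if res.selected_grid_delta is not None:
        out["selected_grid_delta"] = res.selected_grid_delta
    if data is not None:
        out["coding"] = data.coding.kind
        out["covariate_names"] = list(data.covariate_names or ())
        out["interactions"] = [
            {"column": t.column, "treatment": t.treatment, "base_column": t.base_column}
            for t in data.interactions
        ]
        if data.group_labels is not None:
            out["group_labels"] = [
                lab.item() if hasattr(lab, "item") else lab
                for lab in data.group_labels
            ]
    return out


def save_fit_json(res: FitResult, path, data: TrialData | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(res, data), fh, indent=2)


def load_theta_json(path):
    """Recover (Theta, CodingScheme, interaction terms) from a saved fit."""
    with open(path) as fh:
        d = json.load(fh)
    t = d["theta"]
    theta = Theta(t["mu"], np.array(t["tau"]), np.array(t["beta"]), np.array(t["delta"]))
    coding = CodingScheme(d.get("coding", "baseline"))
    terms = tuple(
        InteractionTerm(e["column"], e["treatment"], e.get("base_column"))
        for e in d.get("interactions", [])
    )
    names = tuple(d.get("covariate_names", ()))
    return theta, coding, terms, names
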