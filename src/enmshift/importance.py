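"""Variable-importance analysis: percent contribution, jackknife gains,
and iterative contribution/correlation-based variable screening.

Percent contribution attributes the solver's per-coordinate objective
improvements (the gain ledger accumulated along the coordinate-ascent path)
to source variables — product features split evenly between their two
variables — floors negatives at zero and normalizes to 100%. The jackknife
refits with-only-one and without-one variable models and compares training
gains. The screen alternates dropping minor contributors and the weaker
member of highly correlated pairs until the variable set is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import FitDiagnostics, MaxEntFitter, expand_features, training_gain
from .features import FeatureSpec

__all__ = [
    "ContributionTable",
    "JackknifeResult",
    "percent_contribution",
    "jackknife",
    "iterative_variable_screen",
    "cumulative_topk",
]


@dataclass
class ContributionTable:
    """Per-variable percent contributions, descending, summing to 100."""

    contributions: pd.Series  # index: variable, values: percent

    def __post_init__(self) -> None:
        s = self.contributions.astype(float)
        if (s < 0).any():
            raise ValueError("contributions must be non-negative")
        total = float(s.sum())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"contributions must sum to 100, got {total}")
        self.contributions = s.sort_values(ascending=False, kind="stable")

    def __getitem__(self, variable: str) -> float:
        return float(self.contributions[variable])

    def to_frame(self) -> pd.DataFrame:
        return self.contributions.rename("contribution_pct").reset_index(
            names="variable"
        )


@dataclass
class JackknifeResult:
    gain_with_only: pd.Series
    gain_without: pd.Series
    full_gain: float


def percent_contribution(diag: FitDiagnostics, columns: list) -> ContributionTable:
    """Attribute ledger improvements to source variables, normalized to 100%."""
    if len(diag.gain_ledger) != len(columns):
        raise ValueError("ledger length must match feature columns")
    per_var: dict[str, float] = {}
    for col, gain in zip(columns, diag.gain_ledger):
        share = max(float(gain), 0.0)
        vars_ = col.variables
        for v in vars_:
            per_var[v] = per_var.get(v, 0.0) + share / len(vars_)
    total = sum(per_var.values())
    if total <= 0:
        warnings.warn("zero total objective improvement; attributing uniformly")
        n = len(per_var) if per_var else 1
        series = pd.Series({v: 100.0 / n for v in per_var} or {"<none>": 100.0})
    else:
        series = pd.Series({v: 100.0 * g / total for v, g in per_var.items()})
    return ContributionTable(series)


def cumulative_topk(table: ContributionTable, k: int) -> float:
    """Sum of the k largest per-variable contributions (percent)."""
    n = len(table.contributions)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    return float(table.contributions.iloc[:k].sum())


def jackknife(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    spec: FeatureSpec,
    rm: float = 1.0,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> JackknifeResult:
    """With-only and without-one training gains for every variable."""
    variables = list(background_values.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")

    def _gain(vars_: list[str]) -> float:
        fitter = MaxEntFitter(spec, rm=rm, max_iter=max_iter, tol=tol)
        model, _ = fitter.fit(presence_values, background_values, vars_)
        fm_p = expand_features(presence_values[vars_], model.spec, model.stats)
        return training_gain(model, fm_p)

    full = _gain(variables)
    with_only = {v: _gain([v]) for v in variables}
    without = {v: _gain([u for u in variables if u != v]) for v in variables}
    return JackknifeResult(
        gain_with_only=pd.Series(with_only),
        gain_without=pd.Series(without),
        full_gain=full,
    )


def iterative_variable_screen(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    spec: FeatureSpec,
    rm: float = 1.0,
    min_contrib: float = 1.0,
    max_abs_corr: float = 0.8,
    max_iter: int = 2000,
) -> list[str]:
    """Iteratively drop minor-contribution and redundant-correlated variables.

    Each round fits a model on the surviving variables, removes those whose
    percent contribution falls below ``min_contrib``, then for every
    remaining pair with |Pearson r| > ``max_abs_corr`` on the background
    sample removes the lower-contribution member; repeats until stable.
    Deterministic, and terminates in at most v rounds since the variable set
    strictly shrinks or the loop stops.
    """
    variables = sorted(background_values.columns)
    if len(variables) < 2:
        raise ValueError("screening needs at least 2 variables")

    while True:
        fitter = MaxEntFitter(spec, rm=rm, max_iter=max_iter)
        model, diag = fitter.fit(presence_values, background_values, variables)
        fm_cols = expand_features(
            background_values[variables].head(1), model.spec, model.stats
        ).columns
        contrib = percent_contribution(diag, fm_cols).contributions
        contrib = contrib.reindex(variables).fillna(0.0)

        survivors = [v for v in variables if contrib[v] >= min_contrib]
        if not survivors:
            # keep the single best variable rather than emptying the set
            survivors = [contrib.idxmax()]

        corr = background_values[survivors].corr().abs()
        dropped: set[str] = set()
        # deterministic pair order: by descending correlation then names
        pairs = [
            (corr.loc[a, b], a, b)
            for i, a in enumerate(survivors)
            for b in survivors[i + 1 :]
        ]
        for r, a, b in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
            if r > max_abs_corr and a not in dropped and b not in dropped:
                loser = a if contrib[a] < contrib[b] else b
                if contrib[a] == contrib[b]:
                    loser = max(a, b)  # deterministic tie-break
                dropped.add(loser)
        survivors = [v for v in survivors if v not in dropped]

        if not survivors:
            raise ValueError("screening removed every variable")
        if survivors == variables:
            return survivors
        variables = survivors
        if len(variables) == 1:
            return variables
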