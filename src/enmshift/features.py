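"""Maxent feature classes and per-feature L1 regularization weights.

Raw environmental variables are first min-max scaled to ``z = (x - min) /
(max - min)`` using the background range, then expanded into the classic
maxent feature classes:

=====  ==========================================================
L      linear, ``z``
Q      quadratic, ``z**2``
P      product, ``z_i * z_j`` for all unordered variable pairs
H      forward hinge ``max(0, z - k)/(1 - k)`` and reverse hinge
       ``max(0, k - z)/k`` at equally spaced knots ``k`` in (0, 1)
T      threshold, indicator ``z > k`` at equally spaced knots
=====  ==========================================================

Working on the scaled variable makes every feature invariant to positive
affine transforms of the raw data and keeps all training features in
``[0, 1]``. Categorical variables contribute one 0/1 indicator per observed
class instead (linear class only).

The per-feature penalty is the standard maxent schedule: ``beta_j =
RM * r_class(m) * max(s_j, eps * s_bg_j) / sqrt(m)`` where ``m`` is the
presence sample size, ``s_j`` the presence-sample standard deviation of
feature ``j``, ``s_bg_j`` the background sd used as a floor
(``eps = 0.001``), and ``r_class`` a per-class factor interpolated
piecewise-linearly in ``m`` and clamped at the schedule ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "FeatureColumn",
    "FeatureMatrix",
    "TrainingStats",
    "RegularizationWeights",
    "expand_features",
    "regularization_weights",
]

_CLASS_ORDER = "LQPHT"

# (m, r) anchors of the published default regularization schedule per class.
_SCHEDULES: dict[str, list[tuple[float, float]]] = {
    "L": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "Q": [(10, 1.3), (17, 0.8), (30, 0.5), (100, 0.05)],
    "P": [(10, 2.6), (17, 1.6), (30, 0.9), (100, 0.05)],
    "H": [(0, 0.5), (1, 0.5)],  # constant 0.5
    "T": [(0, 2.0), (100, 1.0)],
}


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to build and how many knots to use."""

    classes: frozenset = frozenset("LQ")
    hinge_knots: int = 30
    threshold_knots: int = 20
    categorical: frozenset = frozenset()

    def __post_init__(self) -> None:
        cls = frozenset(str(c).upper() for c in self.classes)
        object.__setattr__(self, "classes", cls)
        object.__setattr__(self, "categorical", frozenset(self.categorical))
        if not cls:
            raise ValueError("at least one feature class is required")
        bad = cls - set(_CLASS_ORDER)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        if "H" in cls and self.hinge_knots < 2:
            raise ValueError("hinge_knots must be >= 2")
        if "T" in cls and self.threshold_knots < 2:
            raise ValueError("threshold_knots must be >= 2")

    @classmethod
    def from_label(cls, label: str, **kw) -> "FeatureSpec":
        """Build from an FC combination label such as ``"LQH"`` or ``"Q"``."""
        return cls(classes=frozenset(label.upper()), **kw)

    @property
    def label(self) -> str:
        return "".join(c for c in _CLASS_ORDER if c in self.classes)


@dataclass(frozen=True)
class FeatureColumn:
    """Metadata for one expanded feature."""

    cls: str                 # feature class label (L/Q/P/H/T)
    variables: tuple         # source variable name(s); two names for products
    knot: float | None = None
    direction: str = ""      # "fwd"/"rev" for hinges, category code for cats

    @property
    def feature_id(self) -> str:
        var = "*".join(self.variables)
        parts = [self.cls, var]
        if self.direction:
            parts.append(self.direction)
        if self.knot is not None:
            parts.append(f"{self.knot:g}")
        return ":".join(parts)


@dataclass
class FeatureMatrix:
    """Expanded samples: ``X`` (n_samples x n_features) plus column metadata."""

    X: np.ndarray
    columns: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("column metadata length must equal matrix width")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [c.feature_id for c in self.columns],
                "class": [c.cls for c in self.columns],
                "variables": ["*".join(c.variables) for c in self.columns],
                "knot": [c.knot for c in self.columns],
            }
        )


class TrainingStats:
    """Background/presence summary statistics that fix scaling and penalties.

    Built once from the background sample (plus the presence sample for the
    penalty sds) and then shared by every expansion, projection and clamping
    step so that train and projection features are on identical scales.
    """

    def __init__(
        self,
        variables: list[str],
        var_min: dict,
        var_max: dict,
        var_mean: dict,
        var_sd: dict,
        categories: dict | None = None,
    ):
        self.variables = list(variables)
        self.var_min = dict(var_min)
        self.var_max = dict(var_max)
        self.var_mean = dict(var_mean)
        self.var_sd = dict(var_sd)
        self.categories = dict(categories or {})
        # per-feature stats filled by finalize()
        self.feat_mean_bg: np.ndarray | None = None
        self.feat_sd_bg: np.ndarray | None = None
        self.feat_sd_presence: np.ndarray | None = None

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        spec: FeatureSpec,
        variables: list[str] | None = None,
    ) -> "TrainingStats":
        names = list(variables) if variables is not None else list(background.columns)
        var_min, var_max, var_mean, var_sd, cats = {}, {}, {}, {}, {}
        for name in names:
            col = np.asarray(background[name], dtype=float)
            if name in spec.categorical:
                cats[name] = sorted(set(col.tolist()))
            var_min[name] = float(np.min(col))
            var_max[name] = float(np.max(col))
            var_mean[name] = float(np.mean(col))
            var_sd[name] = float(np.std(col))
            if name not in spec.categorical and var_max[name] == var_min[name]:
                warnings.warn(
                    f"variable {name!r} is constant over the background; "
                    "it contributes only zero features"
                )
        return cls(names, var_min, var_max, var_mean, var_sd, cats)

    def finalize(
        self, spec: FeatureSpec, background: pd.DataFrame, presence: pd.DataFrame
    ) -> None:
        """Compute per-feature background mean/sd and presence sd."""
        fm_bg = expand_features(background, spec, self)
        fm_p = expand_features(presence, spec, self)
        self.feat_mean_bg = fm_bg.X.mean(axis=0)
        self.feat_sd_bg = fm_bg.X.std(axis=0)
        self.feat_sd_presence = fm_p.X.std(axis=0)

    def scale(self, name: str, x: np.ndarray, clamp: bool = False) -> np.ndarray:
        lo, hi = self.var_min[name], self.var_max[name]
        if hi == lo:
            return np.zeros_like(np.asarray(x, dtype=float))
        x = np.asarray(x, dtype=float)
        if clamp:
            x = np.clip(x, lo, hi)
        return (x - lo) / (hi - lo)


@dataclass
class RegularizationWeights:
    """Per-feature non-negative L1 penalties; linear in the global RM."""

    beta: np.ndarray
    rm: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.beta < 0):
            raise ValueError("penalties must be non-negative")
        if not self.rm > 0:
            raise ValueError("regularization multiplier must be positive")


def schedule_factor(cls: str, m: int) -> float:
    """Class schedule r_class(m): piecewise-linear in m, clamped at the ends."""
    anchors = _SCHEDULES[cls]
    ms = np.array([a[0] for a in anchors], dtype=float)
    rs = np.array([a[1] for a in anchors], dtype=float)
    return float(np.interp(float(m), ms, rs))


def expand_features(
    values: pd.DataFrame, spec: FeatureSpec, stats: TrainingStats
) -> FeatureMatrix:
    """Expand a per-sample variable table into the feature matrix.

    Column order is deterministic: classes in L, Q, P, H, T order; within a
    class, variables in ``stats.variables`` order; within a variable, knots
    ascending (forward hinges before reverse hinges).
    """
    missing = [v for v in stats.variables if v not in values.columns]
    if missing:
        raise KeyError(f"variables missing from table: {missing}")
    n = len(values)
    continuous = [v for v in stats.variables if v not in spec.categorical]
    z = {v: stats.scale(v, np.asarray(values[v], dtype=float)) for v in continuous}

    cols: list[FeatureColumn] = []
    mats: list[np.ndarray] = []

    if "L" in spec.classes:
        for v in continuous:
            cols.append(FeatureColumn("L", (v,)))
            mats.append(z[v])
        for v in stats.variables:
            if v in spec.categorical:
                raw = np.asarray(values[v], dtype=float)
                for cat in stats.categories.get(v, []):
                    cols.append(FeatureColumn("L", (v,), direction=f"cat={cat:g}"))
                    mats.append((raw == cat).astype(float))
    if "Q" in spec.classes:
        for v in continuous:
            cols.append(FeatureColumn("Q", (v,)))
            mats.append(z[v] ** 2)
    if "P" in spec.classes:
        for a, b in combinations(continuous, 2):
            cols.append(FeatureColumn("P", (a, b)))
            mats.append(z[a] * z[b])
    if "H" in spec.classes:
        knots = np.linspace(0.0, 1.0, spec.hinge_knots + 2)[1:-1]
        for v in continuous:
            for k in knots:
                cols.append(FeatureColumn("H", (v,), knot=float(k), direction="fwd"))
                mats.append(np.maximum(0.0, z[v] - k) / (1.0 - k))
            for k in knots:
                cols.append(FeatureColumn("H", (v,), knot=float(k), direction="rev"))
                mats.append(np.maximum(0.0, k - z[v]) / k)
    if "T" in spec.classes:
        knots = np.linspace(0.0, 1.0, spec.threshold_knots + 2)[1:-1]
        for v in continuous:
            for k in knots:
                cols.append(FeatureColumn("T", (v,), knot=float(k)))
                mats.append((z[v] > k).astype(float))

    X = np.column_stack(mats) if mats else np.empty((n, 0))
    return FeatureMatrix(X, cols)


def regularization_weights(
    fm: FeatureMatrix, stats: TrainingStats, m: int, rm: float, eps: float = 1e-3
) -> RegularizationWeights:
    """Per-feature penalties ``beta_j = rm * r_class(m) * max(s_j, eps*s_bg_j) / sqrt(m)``."""
    if m < 1:
        raise ValueError("presence sample size must be >= 1")
    if not rm > 0:
        raise ValueError("rm must be positive")
    if stats.feat_sd_presence is None or stats.feat_sd_bg is None:
        raise ValueError("stats.finalize() must be called before computing weights")
    if len(stats.feat_sd_presence) != fm.n_features:
        raise ValueError("feature matrix does not match the stats' feature layout")
    s = np.maximum(stats.feat_sd_presence, eps * stats.feat_sd_bg)
    r = np.array([schedule_factor(c.cls, m) for c in fm.columns])
    beta = rm * r * s / np.sqrt(m)
    return RegularizationWeights(beta=beta, rm=rm)
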