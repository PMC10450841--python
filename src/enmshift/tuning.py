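"""Candidate-model calibration: (feature classes x regularization multiplier)
grid, evaluation metrics, and optimal-model selection.

Each candidate is one (FC, RM) setting. Candidates are scored with training
and test AUC (and their difference, an overfitting signal), omission rates
at the 5% and 10% training thresholds, partial-ROC significance against a
null of random prediction, and sample-size-corrected AIC computed from raw
probabilities at the presence cells. Selection keeps statistically
significant candidates with low omission and returns the minimum-AICc
member (delta AICc = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .engine import MaxEntModel
from .features import FeatureMatrix

__all__ = [
    "CandidateSpec",
    "CandidateMetrics",
    "make_candidate_grid",
    "default_fc_combinations",
    "auc",
    "auc_band",
    "omission_rate",
    "partial_roc",
    "aicc",
    "select_best",
]

_CLASS_ORDER = "LQPHT"


def default_fc_combinations() -> list[str]:
    """The 29 feature-class combinations used for calibration by default.

    All 31 nonempty subsets of {L, Q, P, H, T} minus the two degenerate
    singletons {P} and {T} (product-only and threshold-only models).
    """
    from itertools import combinations

    labels = []
    for r in range(1, 6):
        for combo in combinations(_CLASS_ORDER, r):
            labels.append("".join(combo))
    return [lab for lab in labels if lab not in ("P", "T")]


@dataclass(frozen=True)
class CandidateSpec:
    fc: str
    rm: float

    def __post_init__(self) -> None:
        if not self.rm > 0:
            raise ValueError("rm must be positive")
        if not self.fc or set(self.fc) - set(_CLASS_ORDER):
            raise ValueError(f"invalid feature-class label {self.fc!r}")


@dataclass
class CandidateMetrics:
    auc_train: float = math.nan
    auc_test: float = math.nan
    auc_diff: float = math.nan
    or5: float = math.nan
    or10: float = math.nan
    proc_p: float = math.nan
    proc_auc_ratio: float = math.nan
    aicc: float | None = None
    delta_aicc: float = math.nan
    k_params: int = 0


def make_candidate_grid(
    rm_values: list[float], fc_combos: list[str]
) -> list[CandidateSpec]:
    """Full Cartesian product, fc-major then rm-minor, deterministic order."""
    if not rm_values or not fc_combos:
        raise ValueError("rm_values and fc_combos must be nonempty")
    if len(set(rm_values)) != len(rm_values):
        raise ValueError("duplicate rm values")
    if len(set(fc_combos)) != len(fc_combos):
        raise ValueError("duplicate fc combinations")
    return [CandidateSpec(fc=fc, rm=float(rm)) for fc in fc_combos for rm in rm_values]


def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) with ties counted one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_band(value: float) -> str:
    """Conventional qualitative AUC banding for model-accuracy reporting."""
    if value < 0.6:
        return "Failing"
    if value < 0.7:
        return "Poor"
    if value < 0.8:
        return "Good"
    if value < 0.9:
        return "Good-Excellent (unspecified in source)"
    return "Excellent"


def omission_rate(test_scores, train_scores, q: float = 0.10) -> float:
    """Fraction of test scores below the q-training-omission threshold.

    The threshold is the lowest training score retained when the
    lowest-scoring fraction ``q`` of training points is dropped, i.e. the
    score of rank ``n - ceil((1-q) n) + 1`` from the bottom; test points
    strictly below it count as omitted.
    """
    test = np.asarray(test_scores, dtype=float)
    train = np.sort(np.asarray(train_scores, dtype=float))
    if test.size == 0 or train.size == 0:
        raise ValueError("score lists must be nonempty")
    if not 0.0 <= q < 1.0:
        raise ValueError("q must be in [0, 1)")
    n = train.size
    keep = math.ceil((1.0 - q) * n)
    threshold = train[n - keep]
    return float(np.mean(test < threshold))


def partial_roc(
    test_scores,
    projection_scores,
    e: float = 0.05,
    n_boot: int = 500,
    boot_frac: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial-ROC significance restricted to sensitivity >= 1 - e.

    The ROC here plots sensitivity of the test points against the
    proportion of the projected landscape predicted suitable, over all score
    thresholds. Bootstrap resamples (fraction ``boot_frac`` of the test
    points, with replacement) each yield the ratio of the model's partial
    AUC to the null (diagonal) partial AUC over the same region; the p-value
    is the proportion of ratios <= 1. Returns ``(p_value, mean_ratio)``;
    a degenerate constant projection yields ``(nan, nan)``.
    """
    test = np.asarray(test_scores, dtype=float)
    proj = np.asarray(projection_scores, dtype=float)
    proj = proj[np.isfinite(proj)]
    if test.size == 0:
        raise ValueError("test scores must be nonempty")
    if proj.size == 0 or np.all(proj == proj[0]):
        return math.nan, math.nan
    rng = np.random.default_rng(seed)
    # x-axis: fraction of landscape at or above each threshold
    thresholds = np.quantile(proj, np.linspace(0.0, 1.0, 101))
    thresholds = np.unique(thresholds)
    frac_area = np.array([np.mean(proj >= t) for t in thresholds])
    order = np.argsort(frac_area)
    thresholds, frac_area = thresholds[order], frac_area[order]

    n_take = max(1, int(round(boot_frac * test.size)))
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = test[rng.integers(0, test.size, n_take)]
        sens = np.array([np.mean(sample >= t) for t in thresholds])
        keep = sens >= 1.0 - e
        if keep.sum() < 2:
            ratios[b] = math.nan
            continue
        x, y = frac_area[keep], sens[keep]
        p_auc = np.trapezoid(y, x)
        null_auc = np.trapezoid(x, x)
        ratios[b] = p_auc / null_auc if null_auc > 0 else math.nan
    valid = ratios[np.isfinite(ratios)]
    if valid.size == 0:
        return math.nan, math.nan
    p_value = float(np.mean(valid <= 1.0))
    return p_value, float(valid.mean())


def aicc(
    model: MaxEntModel, presence_fm: FeatureMatrix, landscape_fm: FeatureMatrix
) -> float | None:
    """Sample-size-corrected AIC from landscape-standardized raw output.

    Raw probabilities are renormalized to sum to one over the landscape
    cells; the log-likelihood is their log at the presence cells; K is the
    nonzero-coefficient count. Undefined (None) when K >= n - 1.
    """
    n = presence_fm.n_samples
    k = model.k_params
    if k >= n - 1:
        return None
    z_land = model.linear_predictor(landscape_fm)
    z_pres = model.linear_predictor(presence_fm)
    from scipy.special import logsumexp

    log_norm = logsumexp(z_land)
    lnL = float(np.sum(z_pres - log_norm))
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)


def select_best(
    metrics: list[tuple[CandidateSpec, CandidateMetrics]],
    alpha: float = 0.05,
    or_cap: float = 0.05,
) -> CandidateSpec:
    """Filter to significant, low-omission candidates; return minimum AICc.

    Filter: partial-ROC p < alpha and OR5 <= or_cap. If no candidate
    passes, fall back (with a warning) to all candidates with defined AICc.
    Ties on AICc break by (lower rm, shorter fc label, lexicographic fc).
    """
    if not metrics:
        raise ValueError("no candidates to select from")
    passing = [
        (spec, met)
        for spec, met in metrics
        if met.aicc is not None
        and np.isfinite(met.proc_p)
        and met.proc_p < alpha
        and met.or5 <= or_cap
    ]
    if not passing:
        warnings.warn(
            "no candidate passed the significance/omission filter; "
            "falling back to all candidates with defined AICc"
        )
        passing = [(s, m) for s, m in metrics if m.aicc is not None]
        if not passing:
            raise ValueError("AICc undefined for every candidate")
    best = min(passing, key=lambda sm: (sm[1].aicc, sm[0].rm, len(sm[0].fc), sm[0].fc))
    return best[0]


def metrics_table(
    metrics: list[tuple[CandidateSpec, CandidateMetrics]]
) -> pd.DataFrame:
    """Calibration results as a flat table (one row per candidate)."""
    rows = []
    defined = [m.aicc for _, m in metrics if m.aicc is not None]
    aicc_min = min(defined) if defined else math.nan
    for spec, met in metrics:
        delta = met.aicc - aicc_min if met.aicc is not None else math.nan
        rows.append(
            {
                "fc": spec.fc,
                "rm": spec.rm,
                "k_params": met.k_params,
                "auc_train": met.auc_train,
                "auc_test": met.auc_test,
                "auc_diff": met.auc_diff,
                "or5": met.or5,
                "or10": met.or10,
                "proc_p": met.proc_p,
                "proc_auc_ratio": met.proc_auc_ratio,
                "aicc": met.aicc,
                "delta_aicc": delta,
            }
        )
    return pd.DataFrame(rows)
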