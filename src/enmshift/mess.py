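"""Multivariate environmental similarity surface (MESS) and the
most-dissimilar variable (MoD) map.

Each scenario cell is compared with a reference envelope — the environmental
values at the species' occurrence points under the current climate. For a
value ``p`` of variable ``i`` with reference minimum/maximum ``min_i`` /
``max_i`` and ``F_i`` the percentage of reference values strictly below
``p``, the per-variable similarity is

    F_i = 0          ->  S_i = 100 (p - min_i) / (max_i - min_i)
    0 < F_i <= 50    ->  S_i = 2 F_i
    50 < F_i < 100   ->  S_i = 2 (100 - F_i)
    F_i = 100        ->  S_i = 100 (max_i - p) / (max_i - min_i)

The cell's MESS is the minimum S_i over variables; it is negative exactly
when some variable leaves its reference range, flagging novel (extrapolated)
climate. The MoD map records which variable attains the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import EnvStack, Raster

__all__ = [
    "ReferenceEnvelope",
    "MessResult",
    "build_envelope",
    "similarity_component",
    "mess_surface",
]


@dataclass
class ReferenceEnvelope:
    """Sorted reference values per variable with empirical percentile lookup."""

    variables: list
    sorted_values: dict   # variable -> ascending ndarray
    min_: dict
    max_: dict

    def percentile(self, name: str, p) -> np.ndarray:
        """F_i(p): percent of reference values strictly less than p."""
        ref = self.sorted_values[name]
        p = np.asarray(p, dtype=float)
        return 100.0 * np.searchsorted(ref, p, side="left") / ref.size


def build_envelope(reference_points: pd.DataFrame) -> ReferenceEnvelope:
    """Build the envelope from per-point variable values (>= 2 points)."""
    if len(reference_points) < 2:
        raise ValueError("need at least 2 reference points")
    bad = [c for c in reference_points.columns if reference_points[c].isna().any()]
    if bad:
        raise ValueError(f"missing values in reference variables: {bad}")
    names = list(reference_points.columns)
    sorted_values = {
        c: np.sort(np.asarray(reference_points[c], dtype=float)) for c in names
    }
    return ReferenceEnvelope(
        variables=names,
        sorted_values=sorted_values,
        min_={c: float(v[0]) for c, v in sorted_values.items()},
        max_={c: float(v[-1]) for c, v in sorted_values.items()},
    )


def similarity_component(p, envelope: ReferenceEnvelope, name: str) -> np.ndarray:
    """Per-variable similarity S_i at value(s) p (vectorized)."""
    p = np.asarray(p, dtype=float)
    lo, hi = envelope.min_[name], envelope.max_[name]
    if hi == lo:
        # degenerate envelope: inside iff exactly at the single value
        return np.where(p == lo, 100.0, -np.inf)
    f = envelope.percentile(name, p)
    span = hi - lo
    s = np.empty_like(p, dtype=float)
    low = f == 0.0
    high = f == 100.0
    mid_lo = (f > 0.0) & (f <= 50.0)
    mid_hi = (f > 50.0) & (f < 100.0)
    s[low] = 100.0 * (p[low] - lo) / span
    s[mid_lo] = 2.0 * f[mid_lo]
    s[mid_hi] = 2.0 * (100.0 - f[mid_hi])
    s[high] = 100.0 * (hi - p[high]) / span
    return s


@dataclass
class MessResult:
    mess: Raster
    mod: Raster                # 1-based index into `variables` of the minimizer
    variables: list
    mean_mess_cells: float
    mean_mess_points: float | None = None


def mess_surface(
    scenario: EnvStack,
    envelope: ReferenceEnvelope,
    points: list | None = None,
) -> MessResult:
    """MESS and MoD rasters for a scenario stack.

    MoD ties go to the first variable in envelope order. If ``points``
    (lon/lat pairs) are given, the mean MESS at those cells is reported too.
    """
    missing = [v for v in envelope.variables if v not in scenario]
    if missing:
        raise KeyError(f"scenario lacks envelope variables: {missing}")
    sub = scenario.subset(envelope.variables)
    mask = sub.joint_mask()
    hdr = scenario.header

    n_valid = int(mask.sum())
    s_all = np.empty((len(envelope.variables), n_valid))
    for i, name in enumerate(envelope.variables):
        s_all[i] = similarity_component(scenario[name].values[mask], envelope, name)
    min_idx = np.argmin(s_all, axis=0)          # first minimizer on ties
    mess_vals = s_all[min_idx, np.arange(n_valid)]

    mess_grid = np.full(mask.shape, hdr.nodata)
    mod_grid = np.full(mask.shape, hdr.nodata)
    mess_grid[mask] = mess_vals
    mod_grid[mask] = min_idx + 1.0
    mess_raster = Raster(hdr, mess_grid, mask.copy())
    mod_raster = Raster(hdr, mod_grid, mask.copy())

    mean_points = None
    if points is not None:
        from .geodata import cell_index_arrays

        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        rows, cols, ok = cell_index_arrays(pts[:, 0], pts[:, 1], hdr)
        sel = ok & mask[np.clip(rows, 0, hdr.nrows - 1), np.clip(cols, 0, hdr.ncols - 1)]
        if sel.any():
            mean_points = float(mess_grid[rows[sel], cols[sel]].mean())

    return MessResult(
        mess=mess_raster,
        mod=mod_raster,
        variables=list(envelope.variables),
        mean_mess_cells=float(mess_vals.mean()),
        mean_mess_points=mean_points,
    )
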