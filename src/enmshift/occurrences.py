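"""Occurrence record cleaning, grid thinning and train/test splitting.

Raw occurrence sets mix database downloads, literature records and field
surveys, so they carry out-of-bounds coordinates, points on invalid cells
(water, missing layers), points in excluded land-cover classes (plantations,
built-up areas) and exact duplicates. Cleaning removes those in a fixed
order and accounts for every record. Spatial thinning then keeps a single
record per occupied grid cell (per species) to blunt spatial autocorrelation
and sampling bias, the standard preparation for presence/background models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geodata import EnvStack, GridHeader, cell_index_arrays

__all__ = [
    "OccurrenceRecord",
    "CleaningReport",
    "clean_occurrences",
    "thin_to_grid",
    "split_train_test",
    "read_occurrences_csv",
    "write_occurrences_csv",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")


@dataclass
class CleaningReport:
    """Stage-by-stage accounting: input count equals retained + removals."""

    n_input: int = 0
    n_out_of_bounds: int = 0
    n_nodata: int = 0
    n_landcover_excluded: int = 0
    n_duplicates: int = 0
    n_thinned: int = 0
    n_retained: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.n_out_of_bounds
            + self.n_nodata
            + self.n_landcover_excluded
            + self.n_duplicates
            + self.n_thinned
        )
        return self.n_input == self.n_retained + removed

    def to_dict(self) -> dict:
        return asdict(self)


def read_occurrences_csv(path) -> list[OccurrenceRecord]:
    """Read `species,longitude,latitude[,source]` CSV (decimal degrees)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("species", "longitude", "latitude"):
        if needed not in cols:
            raise ValueError(f"occurrence CSV missing column {needed!r}")
    src = cols.get("source")
    return [
        OccurrenceRecord(
            species=str(r[cols["species"]]),
            lon=float(r[cols["longitude"]]),
            lat=float(r[cols["latitude"]]),
            source="" if src is None else str(r[src]),
        )
        for _, r in df.iterrows()
    ]


def write_occurrences_csv(records: list[OccurrenceRecord], path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "longitude": [r.lon for r in records],
            "latitude": [r.lat for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, index=False)


def clean_occurrences(
    records: list[OccurrenceRecord],
    stack: EnvStack,
    exclude_landcover: set | frozenset = frozenset(),
    landcover_layer: str = "LC",
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Remove unusable records in order: out-of-bounds, invalid-cell,
    excluded land cover, exact duplicates.

    Each stage counts only records that survived the previous stages, so the
    report reconciles exactly with the input size. Cleaning is idempotent.
    """
    report = CleaningReport(n_input=len(records))
    if exclude_landcover and landcover_layer not in stack:
        raise KeyError(
            f"land-cover exclusion requested but layer {landcover_layer!r} "
            "is not in the stack"
        )
    hdr = stack.header
    joint = stack.joint_mask()

    kept: list[OccurrenceRecord] = []
    if records:
        lons = np.array([r.lon for r in records])
        lats = np.array([r.lat for r in records])
        rows, cols, ok = cell_index_arrays(lons, lats, hdr)
        for i, rec in enumerate(records):
            if not ok[i]:
                report.n_out_of_bounds += 1
                continue
            if not joint[rows[i], cols[i]]:
                report.n_nodata += 1
                continue
            if exclude_landcover:
                lc = stack[landcover_layer].values[rows[i], cols[i]]
                if lc in exclude_landcover or int(lc) in exclude_landcover:
                    report.n_landcover_excluded += 1
                    continue
            kept.append(rec)

    seen: set[tuple[str, float, float]] = set()
    out: list[OccurrenceRecord] = []
    for rec in kept:
        key = (rec.species, rec.lon, rec.lat)
        if key in seen:
            report.n_duplicates += 1
        else:
            seen.add(key)
            out.append(rec)
    report.n_retained = len(out)
    return out, report


def thin_to_grid(
    records: list[OccurrenceRecord], header: GridHeader, seed: int
) -> tuple[list[OccurrenceRecord], int]:
    """Keep exactly one record per occupied grid cell per species.

    The survivor within each cell is chosen uniformly at random (seeded);
    output order is deterministic — sorted by (species, row, col).
    """
    rng = np.random.default_rng(seed)
    cells: dict[tuple[str, int, int], list[OccurrenceRecord]] = {}
    if records:
        lons = np.array([r.lon for r in records])
        lats = np.array([r.lat for r in records])
        rows, cols, ok = cell_index_arrays(lons, lats, header)
        if not ok.all():
            raise IndexError("thin_to_grid requires in-bounds records")
        for i, rec in enumerate(records):
            cells.setdefault((rec.species, int(rows[i]), int(cols[i])), []).append(rec)
    out: list[OccurrenceRecord] = []
    for key in sorted(cells):
        bucket = cells[key]
        out.append(bucket[int(rng.integers(len(bucket)))])
    return out, len(records) - len(out)


def split_train_test(
    records: list[OccurrenceRecord], fraction_train: float, seed: int
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Seeded random partition with |train| = round(fraction_train * n)."""
    if not (0.0 < fraction_train < 1.0):
        raise ValueError("fraction_train must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # round-half-even would under-fill 75% of 2; use standard rounding
    n_train = int(np.floor(fraction_train * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return [records[i] for i in train_idx], [records[i] for i in test_idx]
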