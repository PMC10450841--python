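"""Synthetic environmental worlds with a known Gaussian niche.

The generator builds spatially smooth, partially correlated environmental
layers on a lon/lat grid, defines a ground-truth niche as a product of
Gaussians in environment space, samples presence records proportional to
true suitability, and derives "future" scenario stacks by additive
per-variable climate shifts. Every stage of the modelling pipeline —
thinning, fitting, calibration, thresholding, change maps, centroids,
MESS — can therefore be exercised offline against a known truth.

The default regime mirrors the data shape of a typical regional
presence-only study: a 100x100 grid of 0.05-degree cells at mid-latitudes,
five variables (a temperature-like layer with a north-south gradient, a
precipitation-like layer with an east-west gradient, one nuisance layer
correlated with temperature, two smooth-noise layers) and 150 presence
records, with the niche defined on temperature and precipitation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geodata import EnvStack, GridHeader, Raster
from .occurrences import OccurrenceRecord

__all__ = [
    "VariableRecipe",
    "TrueNiche",
    "WorldConfig",
    "make_world",
    "sample_presences",
    "default_config",
]


@dataclass(frozen=True)
class VariableRecipe:
    """How one synthetic layer is composed.

    The layer is ``offset + gradient + noise_amplitude * smooth_noise``, with
    an optional step that mixes in a previously generated layer to hit a
    target Pearson correlation.
    """

    name: str
    offset: float = 0.0
    gradient: str = "none"           # "ns" (value increases southward), "ew", "none"
    gradient_amplitude: float = 0.0  # total range of the gradient over the grid
    noise_amplitude: float = 1.0
    noise_scale: float = 5.0         # gaussian-filter sigma in cells
    correlate_with: str | None = None
    correlation: float = 0.0


@dataclass(frozen=True)
class TrueNiche:
    """Ground truth: suitability s(x) = exp(-sum_k (x_k - mu_k)^2 / (2 sigma_k^2))."""

    optima: dict      # variable -> mu_k
    breadths: dict    # variable -> sigma_k > 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.breadths.values()):
            raise ValueError("niche breadths must be positive")
        if set(self.optima) != set(self.breadths):
            raise ValueError("optima and breadths must cover the same variables")

    def suitability(self, values: dict) -> np.ndarray:
        """True suitability in (0, 1] given per-variable arrays."""
        expo = 0.0
        for k, mu in self.optima.items():
            expo = expo + (np.asarray(values[k], dtype=float) - mu) ** 2 / (
                2.0 * self.breadths[k] ** 2
            )
        return np.exp(-expo)


@dataclass
class WorldConfig:
    nrows: int = 100
    ncols: int = 100
    cellsize: float = 0.05
    xll: float = 110.0
    yll: float = 35.0
    recipes: list = field(default_factory=list)
    niche: TrueNiche | None = None
    scenario_deltas: dict = field(default_factory=dict)  # name -> {var: delta}
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.recipes) < 2:
            raise ValueError("world needs at least 2 variables")
        names = [r.name for r in self.recipes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")


def default_config(seed: int = 0, warming: float = 3.0) -> WorldConfig:
    """Desk-scale default world: 2 informative, 1 correlated, 2 noise layers.

    ``temp`` decreases northward (colder toward the pole), so a uniform
    ``+warming`` scenario pushes the niche's optimal isotherm poleward.
    """
    recipes = [
        VariableRecipe(
            "temp", offset=12.0, gradient="ns", gradient_amplitude=10.0,
            noise_amplitude=1.0, noise_scale=6.0,
        ),
        VariableRecipe(
            "precip", offset=800.0, gradient="ew", gradient_amplitude=400.0,
            noise_amplitude=60.0, noise_scale=6.0,
        ),
        VariableRecipe(
            "tcorr", offset=5.0, noise_amplitude=2.0, noise_scale=6.0,
            correlate_with="temp", correlation=0.7,
        ),
        VariableRecipe("noise1", offset=0.0, noise_amplitude=1.0, noise_scale=6.0),
        VariableRecipe("noise2", offset=50.0, noise_amplitude=10.0, noise_scale=4.0),
    ]
    # optima sit mid-grid (temp spans 12-22 northward-decreasing, precip
    # 800-1200 eastward-increasing) so a +warming shift moves, rather than
    # truncates, the suitable band
    # breadths model a habitat specialist (narrow climatic tolerance), the
    # regime in which presence-background models attain high discrimination
    niche = TrueNiche(
        optima={"temp": 17.0, "precip": 1000.0},
        breadths={"temp": 1.0, "precip": 60.0},
    )
    scenarios = {
        "warm": {"temp": warming, "tcorr": warming * 0.6},
    }
    return WorldConfig(recipes=recipes, niche=niche,
                       scenario_deltas=scenarios, seed=seed)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized gaussian-filtered white noise (mean 0, sd 1)."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def make_world(config: WorldConfig) -> tuple[EnvStack, dict, TrueNiche | None]:
    """Build the current stack and the additive-shift scenario stacks.

    Identical configs (including seed) yield bit-identical worlds; a
    scenario with all-zero deltas equals the current stack exactly.
    """
    hdr = GridHeader(
        ncols=config.ncols, nrows=config.nrows,
        xll=config.xll, yll=config.yll, cellsize=config.cellsize,
    )
    rng = np.random.default_rng(config.seed)
    shape = (config.nrows, config.ncols)
    rows = np.arange(config.nrows)[:, None]
    cols = np.arange(config.ncols)[None, :]

    fields: dict[str, np.ndarray] = {}
    for rec in config.recipes:
        grad = np.zeros(shape)
        if rec.gradient == "ns":
            # row 0 is north; value increases toward the south (low row -> low value)
            grad = rec.gradient_amplitude * (rows / max(config.nrows - 1, 1)) * np.ones(shape)
        elif rec.gradient == "ew":
            grad = rec.gradient_amplitude * (cols / max(config.ncols - 1, 1)) * np.ones(shape)
        elif rec.gradient != "none":
            raise ValueError(f"unknown gradient {rec.gradient!r}")
        noise = _smooth_field(rng, shape, rec.noise_scale)
        raw = grad + rec.noise_amplitude * noise
        if rec.correlate_with is not None:
            base = fields[rec.correlate_with]
            zb = (base - base.mean()) / base.std()
            zr = (raw - raw.mean()) / raw.std()
            rho = rec.correlation
            mixed = rho * zb + np.sqrt(1.0 - rho**2) * zr
            raw = rec.noise_amplitude * mixed
        fields[rec.name] = rec.offset + raw

    current = EnvStack({n: Raster(hdr, v.copy()) for n, v in fields.items()})
    scenarios: dict[str, EnvStack] = {}
    for scen_name, deltas in config.scenario_deltas.items():
        shifted = {
            n: Raster(hdr, v + float(deltas.get(n, 0.0)))
            for n, v in fields.items()
        }
        scenarios[scen_name] = EnvStack(shifted)
    return current, scenarios, config.niche


def sample_presences(
    stack: EnvStack,
    niche: TrueNiche,
    n: int,
    seed: int,
    species: str = "synthetic",
) -> list[OccurrenceRecord]:
    """Draw presence cells without replacement, probability proportional to
    true suitability; records are placed at cell centers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = stack.joint_mask()
    rows, cols = np.nonzero(mask)
    if n > rows.size:
        raise ValueError(f"n={n} exceeds {rows.size} valid cells")
    values = {k: stack[k].values[rows, cols] for k in niche.optima}
    s = niche.suitability(values)
    p = s / s.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(rows.size, size=n, replace=False, p=p)
    records = []
    for i in chosen:
        lon, lat = stack.header.cell_center(int(rows[i]), int(cols[i]))
        records.append(OccurrenceRecord(species=species, lon=lon, lat=lat,
                                        source="synthworld"))
    return records
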