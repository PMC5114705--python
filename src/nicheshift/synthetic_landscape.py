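"""Seeded synthetic landscapes with a known suitability truth.

Replaces downloaded climate and occurrence data with a generator that
emulates their structure: spatially smooth, mutually correlated
bioclim-like layers plus an elevation surface on a lon/lat grid; a known
Gibbs suitability surface driven by a quadratic niche in designated
driver layers; presence points sampled proportionally to that truth; and
future stacks built as current + scenario-dependent shift + per-pseudo-GCM
smooth noise (11 members × 4 RCPs × 2 horizons by default).

Smooth random fields use low-order spectral synthesis: a seeded sum of
the first few 2-D Fourier modes with squared-exponential amplitude decay,
normalized to unit standard deviation.  Cheap, differentiable in the
config, and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .occurrence_prep import OccurrenceSet
from .projection_ensemble import RCPS, HORIZONS, SuitabilityGrid
from .raster_stack import GridSpec, Layer, RasterStack

__all__ = [
    "LayerRecipe",
    "TruthConfig",
    "SyntheticTruth",
    "make_layers",
    "true_suitability",
    "sample_presences",
    "make_future",
    "make_truth",
    "default_grid",
    "recovery_config",
]


def default_grid(cell_size: float = 0.5) -> GridSpec:
    """Test-scale grid: lon [−120, −80] × lat [10, 50] at 0.5° (80 × 80)."""
    n_cols = int(round(40.0 / cell_size))
    n_rows = int(round(40.0 / cell_size))
    return GridSpec(
        lon_min=-120.0,
        lon_max=-80.0,
        lat_min=10.0,
        lat_max=50.0,
        cell_size=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
    )


@dataclass(frozen=True)
class LayerRecipe:
    """How one environmental layer is synthesized.

    value = offset + lat_coef · latnorm + elev_coef · elevnorm
            + noise_amp · smooth_field,
    optionally re-mixed against another layer to hit a target correlation
    (shared-component mixing), to exercise the collinearity filter.
    """

    name: str
    offset: float = 0.0
    lat_coef: float = 0.0
    elev_coef: float = 0.0
    noise_amp: float = 1.0
    correlate_with: str | None = None
    rho: float = 0.0


def _bioclim_recipes() -> tuple[LayerRecipe, ...]:
    """ELEV + 19 bioclim-like layers, temperature-like ones cooling poleward."""
    recipes = [LayerRecipe("ELEV", offset=800.0, noise_amp=600.0)]
    rng = np.random.default_rng(20_16)  # fixed structural choices, not data noise
    for i in range(1, 20):
        name = f"BIO{i}"
        if i <= 11:  # temperature-like
            lat_coef = -float(rng.uniform(8.0, 15.0))
            elev_coef = -float(rng.uniform(2.0, 5.0))
            offset = 25.0
        else:  # precipitation-like
            lat_coef = float(rng.uniform(-5.0, 5.0))
            elev_coef = float(rng.uniform(-2.0, 2.0))
            offset = 100.0
        recipes.append(
            LayerRecipe(name, offset=offset, lat_coef=lat_coef, elev_coef=elev_coef, noise_amp=2.0)
        )
    # a pair of near-duplicates to exercise the |r| > 0.8 filter
    recipes[7] = LayerRecipe(
        "BIO7", offset=25.0, lat_coef=-10.0, elev_coef=-3.0, noise_amp=2.0,
        correlate_with="BIO1", rho=0.9,
    )
    return tuple(recipes)


@dataclass(frozen=True)
class TruthConfig:
    """Study conditions for one synthetic experiment."""

    grid: GridSpec = field(default_factory=default_grid)
    recipes: tuple[LayerRecipe, ...] = field(default_factory=_bioclim_recipes)
    # quadratic niche: eta = c0 + sum_v (lin_v * z + quad_v * z^2), z scaled to [0,1]
    # peak at mid-range; curvature 60 puts ~95% of the truth mass inside a
    # band roughly 1/5 of the scaled variable's range (a few degrees of
    # latitude on the default grid) — a regional-scale climatic envelope
    niche_linear: Mapping[str, float] = field(default_factory=lambda: {"BIO1": 60.0})
    niche_quadratic: Mapping[str, float] = field(default_factory=lambda: {"BIO1": -60.0})
    niche_intercept: float = 0.0
    m_presences: int = 300
    # temperature-like shift per scenario: delta = warming[rcp] * horizon_frac[year]
    warming_by_rcp: Mapping[float, float] = field(
        default_factory=lambda: {2.6: 1.0, 4.5: 1.8, 6.0: 2.2, 8.5: 3.7}
    )
    horizon_frac: Mapping[int, float] = field(default_factory=lambda: {2050: 0.6, 2070: 1.0})
    shifted_layers: tuple[str, ...] = ("BIO1",)
    gcm_noise_sd: float = 0.3
    n_members: int = 11

    def deltas(self, year: int, rcp: float) -> dict[str, float]:
        d = self.warming_by_rcp[rcp] * self.horizon_frac[year]
        return {name: d for name in self.shifted_layers}


def recovery_config(
    n_decoys: int = 3, m: int = 300, grid: GridSpec | None = None
) -> TruthConfig:
    """Small driver-recovery setup: one true temperature driver, pure-noise decoys."""
    recipes = [
        LayerRecipe("ELEV", offset=500.0, noise_amp=400.0),
        LayerRecipe("BIO1", offset=25.0, lat_coef=-12.0, elev_coef=-3.0, noise_amp=1.5),
        LayerRecipe("BIO12", offset=100.0, lat_coef=-20.0, elev_coef=10.0, noise_amp=15.0),
    ]
    for i in range(n_decoys):
        recipes.append(LayerRecipe(f"NOISE{i + 1}", offset=0.0, noise_amp=1.0))
    return TruthConfig(
        grid=grid if grid is not None else default_grid(),
        recipes=tuple(recipes),
        niche_linear={"BIO1": 60.0, "BIO12": 30.0},
        niche_quadratic={"BIO1": -60.0, "BIO12": -30.0},
        m_presences=m,
    )


def smooth_field(grid: GridSpec, rng: np.random.Generator, n_modes: int = 4, length: float = 2.0) -> np.ndarray:
    """Unit-variance smooth Gaussian random field by low-order spectral synthesis.

    Sum of cos(2π(kx·x + ky·y) + φ) over the first ``n_modes``² wavenumber
    pairs with squared-exponential amplitude decay exp(−|k|²/(2·length²)).
    """
    x = (np.arange(grid.n_cols) + 0.5) / grid.n_cols
    y = (np.arange(grid.n_rows) + 0.5) / grid.n_rows
    X, Y = np.meshgrid(x, y)
    f = np.zeros_like(X)
    for kx in range(n_modes + 1):
        for ky in range(n_modes + 1):
            if kx == 0 and ky == 0:
                continue
            amp = np.exp(-(kx * kx + ky * ky) / (2.0 * length * length))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            coeff = rng.normal(0.0, 1.0)
            f += amp * coeff * np.cos(2 * np.pi * (kx * X + ky * Y) + phase)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_layers(config: TruthConfig, seed: int) -> RasterStack:
    """Synthesize the current environmental stack from the layer recipes."""
    grid = config.grid
    rng = np.random.default_rng(seed)
    latnorm = (grid.lat_centers()[:, None] - grid.lat_min) / (grid.lat_max - grid.lat_min)
    latnorm = np.broadcast_to(latnorm, (grid.n_rows, grid.n_cols))
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)

    layers: dict[str, np.ndarray] = {}
    elevnorm = np.zeros_like(latnorm)
    for recipe in config.recipes:
        base = (
            recipe.offset
            + recipe.lat_coef * latnorm
            + recipe.elev_coef * elevnorm
            + recipe.noise_amp * smooth_field(grid, rng)
        )
        if recipe.correlate_with is not None:
            partner = layers[recipe.correlate_with]
            zp = (partner - partner.mean()) / partner.std()
            zb = (base - base.mean()) / base.std()
            mixed = recipe.rho * zp + np.sqrt(max(0.0, 1.0 - recipe.rho**2)) * zb
            base = base.mean() + base.std() * mixed
        layers[recipe.name] = base
        if recipe.name == "ELEV":
            lo, hi = base.min(), base.max()
            elevnorm = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
    return RasterStack(grid, [Layer(n, v, mask.copy()) for n, v in layers.items()])


def true_suitability(stack: RasterStack, config: TruthConfig) -> SuitabilityGrid:
    """Known Gibbs truth: mass ∝ exp(eta), eta the quadratic niche polynomial.

    Stored values are the probability masses (summing to 1 over unmasked
    cells), i.e. the raw-scale truth the fitted raw output estimates.
    """
    grid = stack.grid
    mask = stack.mask
    eta = np.full((grid.n_rows, grid.n_cols), config.niche_intercept, dtype=float)
    for name, coef in config.niche_linear.items():
        v = stack.layer(name).values
        z = (v - v.min()) / (v.max() - v.min())
        eta += coef * z
    for name, coef in config.niche_quadratic.items():
        v = stack.layer(name).values
        z = (v - v.min()) / (v.max() - v.min())
        eta += coef * z**2
    w = np.exp(eta - eta[~mask].max())
    w[mask] = 0.0
    mass = w / w.sum()
    return SuitabilityGrid(grid=grid, values=mass, mask=mask, scenario="current", model_id="truth")


def sample_presences(
    truth: SuitabilityGrid, m: int, seed: int, species: str = "synthetic"
) -> OccurrenceSet:
    """Draw m presence points ∝ the truth mass, jittered within their cells."""
    if m < 1:
        raise ValueError("need m >= 1")
    mass = np.where(truth.mask, 0.0, truth.values).ravel()
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero suitability: nothing to sample")
    rng = np.random.default_rng(seed)
    cells = rng.choice(mass.size, size=m, replace=True, p=mass / total)
    rows, cols = np.unravel_index(cells, (truth.grid.n_rows, truth.grid.n_cols))
    cs = truth.grid.cell_size
    # uniform jitter strictly inside the cell, so edge tie-breaking is exercised
    u = rng.uniform(0.02, 0.98, size=m)
    v = rng.uniform(0.02, 0.98, size=m)
    lon = truth.grid.lon_min + (cols + u) * cs
    lat = truth.grid.lat_max - (rows + v) * cs
    df = pd.DataFrame(
        {
            "species": species,
            "lon": lon,
            "lat": lat,
            "source_id": [f"sim-{i:05d}" for i in range(m)],
        }
    )
    return OccurrenceSet(species=species, records=df, n_raw=m, n_after_clean=m)


def make_future(
    stack: RasterStack,
    deltas: Mapping[str, float],
    sigma_g: float,
    members: int,
    seed: int,
) -> list[RasterStack]:
    """Pseudo-GCM member stacks: current + delta + seeded smooth noise × sigma_g."""
    if members < 1:
        raise ValueError("need at least one member")
    out = []
    for g in range(members):
        rng = np.random.default_rng(np.random.SeedSequence([seed, g]))
        layers = []
        for l in stack.layers:
            v = l.values + deltas.get(l.name, 0.0)
            if sigma_g > 0:
                v = v + sigma_g * smooth_field(stack.grid, rng)
            layers.append(Layer(l.name, v, l.mask.copy()))
        out.append(RasterStack(stack.grid, layers))
    return out


@dataclass
class SyntheticTruth:
    """One generated experiment: inputs, truth surface and presence sample."""

    config: TruthConfig
    seed: int
    current: RasterStack
    truth: SuitabilityGrid
    presences: OccurrenceSet
    futures: dict[tuple[int, float], list[RasterStack]] = field(default_factory=dict)

    def config_echo(self) -> str:
        cfg = self.config
        doc = {
            "seed": self.seed,
            "grid": {
                "lon_min": cfg.grid.lon_min,
                "lat_min": cfg.grid.lat_min,
                "cell_size": cfg.grid.cell_size,
                "n_rows": cfg.grid.n_rows,
                "n_cols": cfg.grid.n_cols,
            },
            "layers": [r.name for r in cfg.recipes],
            "niche_linear": dict(cfg.niche_linear),
            "niche_quadratic": dict(cfg.niche_quadratic),
            "m_presences": cfg.m_presences,
            "warming_by_rcp": {str(k): v for k, v in cfg.warming_by_rcp.items()},
            "horizon_frac": {str(k): v for k, v in cfg.horizon_frac.items()},
            "gcm_noise_sd": cfg.gcm_noise_sd,
            "n_members": cfg.n_members,
        }
        return json.dumps(doc, indent=1)


def make_truth(
    config: TruthConfig,
    seed: int,
    scenarios: Sequence[tuple[int, float]] | None = None,
) -> SyntheticTruth:
    """Full synthetic bundle: layers, truth, presences and future members.

    ``scenarios`` defaults to every horizon × RCP combination; pass an
    explicit subset to keep small experiments fast.
    """
    ss = np.random.SeedSequence(seed)
    seed_layers, seed_pres, seed_fut = (int(s) for s in ss.generate_state(3) % (2**31))
    current = make_layers(config, seed_layers)
    truth = true_suitability(current, config)
    presences = sample_presences(truth, config.m_presences, seed_pres)
    if scenarios is None:
        scenarios = [(y, r) for y in HORIZONS for r in RCPS]
    futures = {}
    for i, (year, rcp) in enumerate(scenarios):
        futures[(year, rcp)] = make_future(
            current,
            config.deltas(year, rcp),
            config.gcm_noise_sd,
            config.n_members,
            seed=seed_fut + i,
        )
    return SyntheticTruth(
        config=config,
        seed=seed,
        current=current,
        truth=truth,
        presences=presences,
        futures=futures,
    )
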