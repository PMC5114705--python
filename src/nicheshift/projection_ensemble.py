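"""Projection of fitted models onto climate stacks and GCM ensemble averaging.

A fitted model is projected onto any stack providing its variables: raw
Gibbs mass is recomputed with training scaling bounds (clamped to the
training range by default) and renormalized over the projection landscape,
then mapped through the logistic transform with the training entropy
frozen.  Per-scenario ensembles are cell-wise means of the member
suitability maps (equal GCM weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .maxent_core import MaxentModel
from .raster_stack import GridSpec, RasterStack, read_raster, write_raster

__all__ = ["ScenarioSpec", "SuitabilityGrid", "project", "ensemble_mean"]

HORIZONS = (2050, 2070)
RCPS = (2.6, 4.5, 6.0, 8.5)
DEFAULT_GCMS = tuple(f"gcm{i:02d}" for i in range(1, 12))


@dataclass(frozen=True)
class ScenarioSpec:
    """One future-climate member: horizon year × RCP × GCM."""

    year: int
    rcp: float
    gcm: str = ""

    def __post_init__(self) -> None:
        if self.year not in HORIZONS:
            raise ValueError(f"year must be one of {HORIZONS}")
        if self.rcp not in RCPS:
            raise ValueError(f"rcp must be one of {RCPS}")

    @property
    def label(self) -> str:
        tag = f"{self.year}-rcp{self.rcp}"
        return f"{tag}-{self.gcm}" if self.gcm else tag


@dataclass
class SuitabilityGrid:
    """Logistic suitability in [0, 1] per cell, with provenance."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray
    scenario: ScenarioSpec | str = "current"
    model_id: str = ""
    ensemble: bool = False
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        ok = self.values[~self.mask]
        if ok.size and (ok.min() < -1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def scenario_label(self) -> str:
        return self.scenario if isinstance(self.scenario, str) else self.scenario.label

    def write(self, path: str | Path) -> None:
        path = Path(path)
        write_raster(path, self.grid, self.values, self.mask)
        sidecar = {
            "scenario": self.scenario_label,
            "model_id": self.model_id,
            "ensemble": self.ensemble,
            "members": list(self.members),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def project(
    model: MaxentModel,
    stack: RasterStack,
    clamp: bool = True,
    scenario: ScenarioSpec | str = "current",
    model_id: str = "",
) -> SuitabilityGrid:
    """Project a fitted model onto a (current or future) stack.

    Raw mass is renormalized over the projection landscape's unmasked
    cells; the logistic transform reuses the training entropy, so a cell
    resembling a typical training cell still scores ~0.5.
    """
    missing = [v for v in model.expansion.variables if v not in stack.names]
    if missing:
        raise ValueError(f"projection stack is missing variables: {missing}")
    env, idx = stack.env_matrix(model.expansion.variables)
    F = model.expansion.transform(env, clamp=clamp)
    eta = F @ model.lam
    log_q = eta - logsumexp(eta)
    suit = model.logistic_from_raw(np.exp(log_q))
    mask = stack.mask
    values = np.zeros(mask.shape)
    values.flat[idx] = suit
    return SuitabilityGrid(
        grid=stack.grid,
        values=values,
        mask=mask,
        scenario=scenario,
        model_id=model_id,
    )


def ensemble_mean(grids: Sequence[SuitabilityGrid]) -> SuitabilityGrid:
    """Cell-wise mean suitability over GCM members of one (year, RCP)."""
    if not grids:
        raise ValueError("need at least one member grid")
    first = grids[0]
    key = _scenario_key(first)
    for g in grids[1:]:
        if not g.grid.approx_equal(first.grid):
            raise ValueError("ensemble members must share one grid")
        if _scenario_key(g) != key:
            raise ValueError(
                f"mixed scenarios in ensemble: {key} vs {_scenario_key(g)}"
            )
    mask = np.zeros_like(first.mask)
    for g in grids:
        mask |= g.mask
    mean = np.mean([g.values for g in grids], axis=0)
    mean[mask] = 0.0
    scenario = first.scenario
    if isinstance(scenario, ScenarioSpec):
        scenario = ScenarioSpec(scenario.year, scenario.rcp, gcm="")
    members = tuple(
        g.scenario.gcm if isinstance(g.scenario, ScenarioSpec) else g.scenario_label
        for g in grids
    )
    return SuitabilityGrid(
        grid=first.grid,
        values=mean,
        mask=mask,
        scenario=scenario,
        model_id=first.model_id,
        ensemble=True,
        members=members,
    )


def _scenario_key(g: SuitabilityGrid):
    if isinstance(g.scenario, ScenarioSpec):
        return (g.scenario.year, g.scenario.rcp)
    return g.scenario


def read_suitability(path: str | Path) -> SuitabilityGrid:
    path = Path(path)
    grid, values, mask = read_raster(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SuitabilityGrid(
        grid=grid,
        values=np.where(mask, 0.0, values),
        mask=mask,
        scenario=meta.get("scenario", "current"),
        model_id=meta.get("model_id", ""),
        ensemble=bool(meta.get("ensemble", False)),
        members=tuple(meta.get("members", ())),
    )
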