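"""Membrane-mechanics feasibility of clathrin-driven vesicle budding.

The per-area cost of curving a membrane into a sphere of radius ``r`` is
the Helfrich bending density ``G_bending = 8*pi*kappa / (4*pi*r^2) =
2*kappa/r^2`` plus the membrane tension ``gamma``.  For an n-membraned
vesicle the default convention applies both terms to each membrane,
``n * (2*kappa/r^2 + gamma)``; comparing against the area density of
energy released by clathrin assembly (~0.08 k_BT/nm^2) decides whether
coat polymerisation alone can pay for budding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "MembraneParams",
    "EnergyBudget",
    "CLATHRIN_BUDGET_KBT_NM2",
    "bending_energy_density",
    "vesicle_formation_cost",
    "feasibility_report",
    "feasibility_sweep",
    "endpoint_to_pit_curvature_ratio",
]

#: area density of energy released by clathrin assembly, k_BT nm^-2
CLATHRIN_BUDGET_KBT_NM2 = 0.08


class MembraneParams(BaseModel):
    """Mechanical parameters of the budding membrane(s).

    Defaults are the outer-mitochondrial-membrane values (kappa = 15 k_BT,
    gamma = 0.0025 k_BT/nm^2) at the ~60 nm vesicle radius seen by EM,
    with two membranes for a double-membraned vesicle.
    """

    model_config = ConfigDict(extra="forbid")

    kappa: float = Field(default=15.0, gt=0)  # bending rigidity, k_BT
    gamma: float = Field(default=0.0025, ge=0)  # tension, k_BT nm^-2
    radius_nm: float = Field(default=60.0, gt=0)
    n_membranes: int = Field(default=2, ge=1)


@dataclass
class EnergyBudget:
    bending_density: float  # per membrane, k_BT nm^-2
    tension_density: float  # per membrane, k_BT nm^-2
    total_cost: float  # all membranes, k_BT nm^-2
    coat_budget: float
    feasible: bool
    margin: float


def bending_energy_density(kappa: float, radius_nm: float) -> float:
    """Helfrich bending density 2*kappa/r^2 (k_BT nm^-2)."""
    if kappa <= 0 or radius_nm <= 0:
        raise ValueError("kappa and radius must be positive")
    return 2.0 * kappa / radius_nm**2


def vesicle_formation_cost(params: MembraneParams,
                           coat_budget: float = CLATHRIN_BUDGET_KBT_NM2,
                           extra_density: float = 0.0,
                           tension_per_membrane: bool = True) -> EnergyBudget:
    """Per-area cost of forming an n-membraned vesicle, vs the coat budget.

    Default convention: ``n * (2*kappa/r^2 + gamma)``.  With
    ``tension_per_membrane=False`` the tension is charged once:
    ``n * 2*kappa/r^2 + gamma``.  ``extra_density`` is an optional additive
    term (e.g. cargo crowding or inter-membrane interactions), default 0.
    """
    bend = bending_energy_density(params.kappa, params.radius_nm)
    if tension_per_membrane:
        total = params.n_membranes * (bend + params.gamma)
    else:
        total = params.n_membranes * bend + params.gamma
    total += extra_density
    return EnergyBudget(
        bending_density=bend,
        tension_density=params.gamma,
        total_cost=total,
        coat_budget=coat_budget,
        feasible=coat_budget >= total,
        margin=coat_budget - total,
    )


def feasibility_report(budget: EnergyBudget) -> dict:
    """Verdict record for one energy budget."""
    return {
        "bending_density_kbt_nm2": budget.bending_density,
        "tension_density_kbt_nm2": budget.tension_density,
        "total_cost_kbt_nm2": budget.total_cost,
        "coat_budget_kbt_nm2": budget.coat_budget,
        "feasible": bool(budget.feasible),
        "margin_kbt_nm2": budget.margin,
    }


def feasibility_sweep(kappas: Iterable[float], gammas: Iterable[float],
                      radii_nm: Iterable[float],
                      n_membranes: Iterable[int] = (1, 2),
                      coat_budget: float = CLATHRIN_BUDGET_KBT_NM2,
                      ) -> pd.DataFrame:
    """Feasibility over a grid of (kappa, gamma, r, n)."""
    rows = []
    for k, g, r, n in product(kappas, gammas, radii_nm, n_membranes):
        b = vesicle_formation_cost(
            MembraneParams(kappa=k, gamma=g, radius_nm=r, n_membranes=n),
            coat_budget=coat_budget)
        rows.append({"kappa": k, "gamma": g, "radius_nm": r,
                     "n_membranes": n, **feasibility_report(b)})
    return pd.DataFrame(rows)


def endpoint_to_pit_curvature_ratio(endpoint_radius_nm: float = 250.0,
                                    pit_radius_nm: float = 60.0) -> float:
    """How much tighter a coated pit curves than a tube endpoint (~4x)."""
    if endpoint_radius_nm <= 0 or pit_radius_nm <= 0:
        raise ValueError("radii must be positive")
    return endpoint_radius_nm / pit_radius_nm
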