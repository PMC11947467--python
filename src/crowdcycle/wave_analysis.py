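"""Traveling-wave analytics for the two-compartment model.

Low-density initial conditions in one spatial dimension develop pulled
invasion fronts whose minimum speed is set by the linearisation about the
empty state:

    c_min = 2 sqrt(D * lambda(0)),
    lambda(0) = (-k1 - k2 + sqrt(k1^2 + k2^2 + 6 k1 k2)) / 2,

independent of the crowding thresholds K1, K2 and of the crowding-function
shapes.  When 4 r / (k1 + k2) << 1 with r = k1 k2/(k1 + k2), the two-stage
structure becomes irrelevant and c_min is approximated by the single-rate
Fisher-KPP-style expression sqrt(2 D r).

A reduced model with Heaviside crowding (f = H(K1 - rho), g = H(K2 - rho))
admits closed-form predictions for the S/G2/M composition of the invaded
tissue: the bulk density rho2_bulk and the excess of the edge peak over the
bulk, which on the supercritical branch (K1/K2 > alpha_kappa) reduces to
K2 - K1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

import numpy as np

from .model_core import (
    EXPONENTIAL_CROWDING,
    ModelParameters,
    growth_eigenvalue,
    intrinsic_rate,
)
from .pde_solver import SimulationResult, edge_position, expansion_speed

__all__ = [
    "BulkEdgePrediction",
    "WaveSpeedMeasurement",
    "cmin",
    "fkpp_cmin",
    "alpha_kappa",
    "reduced_model_bulk_edge",
    "measure_wave_speed",
    "wave_report",
]


def cmin(params: ModelParameters) -> float:
    """Minimum traveling-wave (invasion) speed, um/h.

    ``2 sqrt(D lambda(0))``; a pure function of D, k1, k2 — the crowding
    thresholds do not enter because pulled fronts are governed by the
    zero-density linearisation.
    """
    lam0 = growth_eigenvalue(params, EXPONENTIAL_CROWDING, 0.0)
    return 2.0 * math.sqrt(params.D * lam0)


def fkpp_cmin(params: ModelParameters) -> float:
    """Single-rate low-rate approximation to the wave speed, um/h.

    ``sqrt(2 D r)`` with r = k1 k2/(k1+k2); accurate when 4r/(k1+k2) << 1,
    i.e. when one cell-cycle stage is rate-limiting.
    """
    return math.sqrt(2.0 * params.D * intrinsic_rate(params))


def alpha_kappa(kappa: float) -> float:
    """Critical threshold ratio alpha(kappa) separating the bulk branches.

    ``alpha = 2 / (sqrt(kappa^2 + 6 kappa + 1) - kappa + 1)`` with
    kappa = k1/k2.  Lies in (1/2, 1), decreasing in kappa, with limits 1 as
    kappa -> 0 and 1/2 as kappa -> infinity.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    return 2.0 / (math.sqrt(kappa * kappa + 6.0 * kappa + 1.0) - kappa + 1.0)


@dataclass(frozen=True)
class BulkEdgePrediction:
    """Reduced-model (Heaviside crowding) composition of an invaded tissue.

    On the supercritical branch (K1/K2 > alpha_kappa) the S/G2/M bulk
    density is positive and the edge-minus-bulk excess equals K2 - K1; on
    the subcritical branch the bulk is empty of S/G2/M cells.
    """

    alpha_kappa: float
    rho2_bulk: float
    rho2_edge: float
    edge_minus_bulk: float
    branch: Literal["supercritical", "subcritical"]


def reduced_model_bulk_edge(params: ModelParameters) -> BulkEdgePrediction:
    """Closed-form bulk/edge S/G2/M densities of the Heaviside reduced model.

    With kappa = k1/k2 and a = alpha_kappa(kappa):

    - supercritical (K1/K2 > a): rho2_bulk/K2 = (K1/K2)/a - 1 and
      rho2_edge/K2 = (K1/K2)(1 - a)/a, hence edge - bulk = K2 - K1;
    - subcritical: rho2_bulk = 0 and the excess is the edge value itself.
    """
    kappa = params.k1 / params.k2
    a = alpha_kappa(kappa)
    ratio = params.K1 / params.K2
    rho2_edge = params.K2 * ratio * (1.0 - a) / a
    if ratio > a:
        rho2_bulk = params.K2 * (ratio / a - 1.0)
        branch: Literal["supercritical", "subcritical"] = "supercritical"
    else:
        rho2_bulk = 0.0
        branch = "subcritical"
    return BulkEdgePrediction(
        alpha_kappa=a,
        rho2_bulk=rho2_bulk,
        rho2_edge=rho2_edge,
        edge_minus_bulk=rho2_edge - rho2_bulk,
        branch=branch,
    )


class WaveSpeedMeasurement(NamedTuple):
    """Numerically measured front speed and plateau composition."""

    speed: float            # um/h
    bulk_rho2: float        # mean rho2 over the trailing 20% of the invaded region
    bulk_rho_total: float   # mean total density over the same region


def measure_wave_speed(
    result: SimulationResult,
    threshold: float,
    window: tuple[float, float],
) -> WaveSpeedMeasurement:
    """Measure the front speed of a 1-D simulation and its bulk composition.

    Speed is the least-squares slope of the edge trajectory (see
    ``pde_solver.expansion_speed``).  The plateau composition is averaged
    over the trailing 20% of the invaded region (positions below the final
    edge) at the final output time, for comparison with
    ``reduced_model_bulk_edge``.
    """
    if result.grid.geometry != "cartesian1d":
        raise ValueError("wave-speed measurement expects a 1-D Cartesian result")
    speed = expansion_speed(result, threshold, window)
    x_edge: Optional[float] = edge_position(
        result.grid.nodes, result.rho_total[-1], threshold
    )
    if x_edge is None:
        raise ValueError("no front present at the final output time")
    nodes = result.grid.nodes
    invaded = nodes <= x_edge
    # trailing 20% of the invaded region, i.e. the bulk far behind the front
    bulk = invaded & (nodes <= 0.2 * x_edge)
    if not np.any(bulk):
        bulk = invaded
    return WaveSpeedMeasurement(
        speed=speed,
        bulk_rho2=float(np.mean(result.rho2[-1][bulk])),
        bulk_rho_total=float(np.mean(result.rho_total[-1][bulk])),
    )


def wave_report(params: ModelParameters) -> dict:
    """All closed-form wave quantities as a JSON-ready mapping."""
    r = intrinsic_rate(params)
    pred = reduced_model_bulk_edge(params)
    return {
        "cmin_um_per_h": cmin(params),
        "fkpp_cmin_um_per_h": fkpp_cmin(params),
        "intrinsic_rate_per_h": r,
        "regime_4r_over_k1_plus_k2": 4.0 * r / (params.k1 + params.k2),
        "alpha_kappa": pred.alpha_kappa,
        "branch": pred.branch,
        "rho2_bulk": pred.rho2_bulk,
        "rho2_edge": pred.rho2_edge,
        "edge_minus_bulk": pred.edge_minus_bulk,
    }
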