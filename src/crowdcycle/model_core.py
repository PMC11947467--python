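"""Core model objects: parameters, crowding functions and local growth kinetics.

The model tracks two cell-cycle compartments of an epithelial tissue,
``rho1`` (cells in G0/G1 together with freshly divided, post-mitotic cells)
and ``rho2`` (cells in S/G2/M).  Cells progress G1 -> S at intrinsic rate
``k1`` and divide (S/G2/M -> two G1 daughters) at intrinsic rate ``k2``.
Both transitions are slowed by tissue crowding through nonincreasing
"crowding functions" ``f`` and ``g`` of the total density ``rho = rho1 +
rho2``, normalised so that ``f(0) = g(0) = 1``.  The local (well-mixed)
kinetics are linear in the compartment densities with a 2x2 growth matrix
whose dominant eigenvalue ``lambda(rho)`` is the net population growth rate.

Units used throughout the package: densities and crowding thresholds in
cells/mm^2, space in micrometres, time in hours, diffusivity in um^2/h.
Densities only ever enter through the ratios ``rho/K``, so no mm^2 <-> um^2
conversion is applied to them anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "ModelParameters",
    "CrowdingSpec",
    "PhaseDurations",
    "POSTERIOR_MODES",
    "crowding_value",
    "growth_matrix",
    "growth_eigenvalue",
    "phase_durations",
    "doubling_time",
    "intrinsic_rate",
]

CrowdingKind = Literal["linear", "heaviside", "constant"]

_VALID_KINDS = ("linear", "heaviside", "constant")


@dataclass(frozen=True)
class ModelParameters:
    """The parameter vector theta = (D, k1, k2, K1, K2).

    Attributes
    ----------
    D : float
        Cell diffusivity, um^2/h.  Both compartments share it.
    k1 : float
        Intrinsic G1 -> S transition rate, 1/h.
    k2 : float
        Intrinsic division rate (S/G2/M -> G1), 1/h.
    K1 : float
        Crowding threshold of the G1 -> S transition, cells/mm^2.
    K2 : float
        Crowding threshold of division, cells/mm^2.  ``K1 < K2`` is a
        biological finding for MDCK tissue, not an enforced constraint.
    """

    D: float
    k1: float
    k2: float
    K1: float
    K2: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"D must be nonnegative, got {self.D}")
        for name in ("k1", "k2", "K1", "K2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)


#: Marginal posterior modes of the calibration to the MDCK tissue-expansion
#: data (large circular tissues, 46 h of free expansion).  Used throughout
#: as the reference parameter set.
POSTERIOR_MODES = ModelParameters(D=1300.0, k1=0.612, k2=0.457, K1=4965.0, K2=5435.0)


@dataclass(frozen=True)
class CrowdingSpec:
    """Declarative choice of the two crowding functions.

    ``kind_f`` governs the G1 -> S transition (threshold ``K1``), ``kind_g``
    the division step (threshold ``K2``).  Supported kinds:

    - ``linear``: ``(1 - rho/K)+``, the default calibrated form;
    - ``heaviside``: ``H(K - rho)`` with the convention ``H(0) = 0`` so the
      transition shuts off exactly at the threshold;
    - ``constant``: 1 everywhere (no density dependence; both constant
      recovers the exponential-growth submodel).
    """

    kind_f: CrowdingKind = "linear"
    kind_g: CrowdingKind = "linear"

    def __post_init__(self) -> None:
        for name in ("kind_f", "kind_g"):
            kind = getattr(self, name)
            if kind not in _VALID_KINDS:
                raise ValueError(f"{name} must be one of {_VALID_KINDS}, got {kind!r}")

    def f(self, rho, params: ModelParameters):
        return crowding_value(self.kind_f, rho, params.K1)

    def g(self, rho, params: ModelParameters):
        return crowding_value(self.kind_g, rho, params.K2)


EXPONENTIAL_CROWDING = CrowdingSpec("constant", "constant")
LINEAR_CROWDING = CrowdingSpec("linear", "linear")
HEAVISIDE_CROWDING = CrowdingSpec("heaviside", "heaviside")


def crowding_value(kind: CrowdingKind, rho, K: float):
    """Evaluate one crowding function at total density ``rho``.

    Parameters
    ----------
    kind : {"linear", "heaviside", "constant"}
    rho : float or ndarray
        Total cell density, cells/mm^2; must be nonnegative.
    K : float
        Crowding threshold, cells/mm^2; must be positive.

    Returns
    -------
    float or ndarray in [0, 1], nonincreasing in ``rho`` and equal to 1 at
    ``rho = 0``.
    """
    if K <= 0:
        raise ValueError(f"crowding threshold K must be positive, got K={K}")
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError(f"density rho must be nonnegative, got rho={rho}")
    if kind == "linear":
        out = np.maximum(1.0 - rho_arr / K, 0.0)
    elif kind == "heaviside":
        # H(0) = 0: the threshold density is absorbing.
        out = np.where(rho_arr < K, 1.0, 0.0)
    elif kind == "constant":
        out = np.ones_like(rho_arr)
    else:
        raise ValueError(f"unknown crowding kind {kind!r}")
    return out if out.ndim else float(out)


def growth_matrix(
    params: ModelParameters, spec: CrowdingSpec, rho: float
) -> np.ndarray:
    """The 2x2 local reaction matrix at total density ``rho``, 1/h.

    Ordering is (rho1, rho2).  With a = k1 f(rho) and b = k2 g(rho) the
    matrix is ``[[-a, 2b], [a, -b]]``: division removes one S/G2/M cell and
    produces two G1 daughters, so the column sums (net cell production) are
    0 for the first compartment and b for the second — total-density growth
    comes only from division.
    """
    a = params.k1 * spec.f(rho, params)
    b = params.k2 * spec.g(rho, params)
    return np.array([[-a, 2.0 * b], [a, -b]])


def growth_eigenvalue(params: ModelParameters, spec: CrowdingSpec, rho: float) -> float:
    """Dominant eigenvalue lambda(rho) of the growth matrix, 1/h.

    Closed form ``(-(a+b) + sqrt((a+b)^2 + 4ab)) / 2`` with a = k1 f(rho),
    b = k2 g(rho); always real, positive iff both a and b are positive, and
    zero as soon as either crowding factor vanishes.  At ``rho = 0`` (where
    f = g = 1) it reduces to ``(-k1 - k2 + sqrt(k1^2 + k2^2 + 6 k1 k2))/2``.
    """
    a = params.k1 * spec.f(rho, params)
    b = params.k2 * spec.g(rho, params)
    if a == 0.0 or b == 0.0:
        return 0.0
    s = a + b
    return 0.5 * (-s + math.sqrt(s * s + 4.0 * a * b))


class PhaseDurations(NamedTuple):
    """Density-dependent cell-cycle stage duration estimates, hours.

    ``math.inf`` marks a stage whose crowding factor is zero (the stage
    never completes at that density).
    """

    t_g1_postm: float
    t_sg2m: float
    t_total: float


def phase_durations(params: ModelParameters, rho: float) -> PhaseDurations:
    """Mean stage durations at fixed density under linear crowding.

    The combined G1/post-M stage lasts ``1 / (k1 (1 - rho/K1)+)`` on
    average and S/G2/M lasts ``1 / (k2 (1 - rho/K2)+)``; the total is their
    sum.  These are timescale estimates of the exponential stage clocks,
    not tracked single-cell durations.
    """
    f = crowding_value("linear", rho, params.K1)
    g = crowding_value("linear", rho, params.K2)
    t1 = 1.0 / (params.k1 * f) if f > 0 else math.inf
    t2 = 1.0 / (params.k2 * g) if g > 0 else math.inf
    return PhaseDurations(t1, t2, t1 + t2)


def doubling_time(params: ModelParameters, spec: CrowdingSpec, rho: float) -> float:
    """Population doubling time ln(2)/lambda(rho) in hours.

    Doubling of the dominant growth mode at fixed density; ``math.inf``
    where the net growth rate is zero.
    """
    lam = growth_eigenvalue(params, spec, rho)
    return math.log(2.0) / lam if lam > 0 else math.inf


def intrinsic_rate(params: ModelParameters) -> float:
    """Effective single-population intrinsic growth rate r, 1/h.

    Defined through the harmonic composition of the stage rates,
    ``1/r = 1/k1 + 1/k2``, i.e. ``r = k1 k2 / (k1 + k2)`` — the rate of the
    one-population logistic reduction of the two-stage model.
    """
    return params.k1 * params.k2 / (params.k1 + params.k2)
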