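"""Synthetic FUCCI-style density-profile datasets for every study scenario.

Each generator forward-simulates the model from a scenario-specific initial
condition with known "truth" parameters, samples the solution on the
observation schedule, and corrupts it with additive Gaussian measurement
noise (constant scale, truncated at zero, iid across replicates, positions,
times and compartments).  Three scenarios are provided:

- ``expansion``: a radially symmetric circular tissue (default initial
  radius 1700 um, i.e. ~3.4 mm diameter; plateau density 3500 cells/mm^2)
  freely expanding for 46 h, observed at regular intervals by 11 noisy
  replicates.  The first 10 h are treated as a seeding transient: the
  observation clock starts at the first retained profile, which plays the
  role of the experimental initial condition.
- ``colonization``: a 1-D barrier-release geometry (domain 3000 um, a
  4800 cells/mm^2 G1 block for x < 850 um, no S/G2/M cells), matching the
  high-density colonization simulations.
- ``scratch``: a low-density (400 cells/mm^2) 1-D monolayer with a central
  cell-free gap, observed every 16 h over two days, with density-independent
  (constant-crowding) truth kinetics — the regime where the crowding
  thresholds are invisible to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional

import numpy as np

from .model_core import (
    EXPONENTIAL_CROWDING,
    LINEAR_CROWDING,
    CrowdingSpec,
    ModelParameters,
    POSTERIOR_MODES,
)
from .bayesian_inference import ObservationSet
from .pde_solver import (
    Grid,
    InitialCondition,
    SimulationResult,
    SolverSettings,
    simulate,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "expansion_spec",
    "colonization_spec",
    "scratch_spec",
    "expansion_scenario",
    "colonization_scenario",
    "scratch_scenario",
    "replicate_average",
    "SCRATCH_TRUTH",
]

#: Truth kinetics of the low-density scratch scenario (melanoma-like cells:
#: slower cycling than epithelium, mean cycle 1/k1 + 1/k2 = 37.5 h so the
#: population completes one to two cycles in 48 h).  The thresholds are the
#: epithelial posterior modes but are inert under constant crowding.
SCRATCH_TRUTH = ModelParameters(D=400.0, k1=0.08, k2=0.04, K1=4965.0, K2=5435.0)

#: densities below one cell per mm^2 are treated as empty space by the
#: simulated measurement (no nuclei to count, hence no measurement noise)
_DETECTION_FLOOR = 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic experiment.

    ``observation_times`` are absolute simulation hours; the returned
    observation sets re-zero their clock at the first observation, mirroring
    the discarding of the post-seeding transient.  ``extent`` is the radius
    (radial) or block width (Cartesian) of the seeded region; the scratch
    scenario instead seeds everything outside a central gap of half-width
    ``gap_halfwidth``.

    The noise scale is constant in the tissue bulk and tapers linearly with
    density below ``noise_taper_frac`` of the dataset's peak total density:
    counting fluctuations shrink where there are few cells to count, and a
    constant scale clipped at zero would otherwise paint a spurious,
    systematically positive density floor over the near-empty front tail.
    """

    kind: Literal["expansion", "colonization", "scratch"]
    geometry: Literal["radial", "cartesian1d"]
    L: float
    grid_n: int
    extent: float
    rho1_plateau: float
    rho2_plateau: float
    smoothing_width: float
    observation_times: np.ndarray
    replicates: int
    noise: float
    seed: int
    params: ModelParameters
    crowding: CrowdingSpec
    gap_halfwidth: float = 0.0
    noise_taper_frac: float = 0.1
    #: noise on the earliest observed profile.  The calibration conditions
    #: on that profile as the exact initial state, so its measurement noise
    #: is a model-misspecification term: disable it to study the inference
    #: machinery in the regime where the conditioning is exact.
    noise_on_first: bool = True
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        t = np.asarray(self.observation_times, dtype=float)
        object.__setattr__(self, "observation_times", t)
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.noise < 0:
            raise ValueError(f"noise scale must be >= 0, got {self.noise}")
        if t.size < 1 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("observation_times must be strictly increasing, >= 0")
        if self.rho1_plateau < 0 or self.rho2_plateau < 0:
            raise ValueError("plateau densities must be nonnegative")

    def replace(self, **changes) -> "ScenarioSpec":
        return replace(self, **changes)


class ScenarioResult(NamedTuple):
    """Everything a recovery experiment needs: the spec, the grid, the exact
    initial condition, the noise-free truth fields at the observation times,
    the replicated noisy observations, and their replicate average."""

    spec: ScenarioSpec
    grid: Grid
    initial_condition: InitialCondition
    truth: SimulationResult
    observations: ObservationSet
    averaged: ObservationSet


def expansion_spec(**overrides) -> ScenarioSpec:
    """Defaults of the circular tissue-expansion experiment."""
    base = ScenarioSpec(
        kind="expansion",
        geometry="radial",
        L=5000.0,
        grid_n=500,
        extent=1700.0,                 # initial radius, um (~3.4 mm diameter)
        rho1_plateau=2450.0,           # 70/30 split of the 3500 cells/mm^2 plateau
        rho2_plateau=1050.0,
        smoothing_width=100.0,         # half-cosine edge ramp
        observation_times=np.array([10.0, 19.0, 28.0, 37.0, 46.0]),
        replicates=11,
        noise=150.0,
        seed=0,
        params=POSTERIOR_MODES,
        crowding=LINEAR_CROWDING,
    )
    return base.replace(**overrides) if overrides else base


def colonization_spec(**overrides) -> ScenarioSpec:
    """Defaults of the 1-D barrier-release colonization simulation."""
    base = ScenarioSpec(
        kind="colonization",
        geometry="cartesian1d",
        L=3000.0,
        grid_n=300,
        extent=850.0,                  # block width, um
        rho1_plateau=4800.0,
        rho2_plateau=0.0,
        smoothing_width=0.0,           # sharp step, as in the source setup
        observation_times=np.array([0.0, 6.0, 12.0, 18.0, 24.0]),
        replicates=1,
        noise=0.0,
        seed=0,
        params=POSTERIOR_MODES,
        crowding=LINEAR_CROWDING,
    )
    return base.replace(**overrides) if overrides else base


def scratch_spec(**overrides) -> ScenarioSpec:
    """Defaults of the low-density scratch (wound-healing) experiment."""
    base = ScenarioSpec(
        kind="scratch",
        geometry="cartesian1d",
        L=2000.0,
        grid_n=200,
        extent=0.0,                    # unused: blocks fill everything but the gap
        rho1_plateau=300.0,            # total 400 cells/mm^2, ~5% of close packing
        rho2_plateau=100.0,
        smoothing_width=0.0,
        observation_times=np.array([0.0, 16.0, 32.0, 48.0]),
        replicates=3,
        noise=20.0,
        seed=0,
        params=SCRATCH_TRUTH,
        crowding=EXPONENTIAL_CROWDING,
        gap_halfwidth=250.0,
    )
    return base.replace(**overrides) if overrides else base


def _ramp(x: np.ndarray, edge: float, width: float) -> np.ndarray:
    """1 inside, 0 outside, half-cosine ramp of the given width ending at
    ``edge``."""
    if width <= 0:
        return (x < edge).astype(float)
    out = np.zeros_like(x)
    out[x <= edge - width] = 1.0
    on_ramp = (x > edge - width) & (x < edge)
    out[on_ramp] = 0.5 * (1.0 + np.cos(np.pi * (x[on_ramp] - (edge - width)) / width))
    return out


def build_initial_condition(spec: ScenarioSpec, grid: Grid) -> InitialCondition:
    x = grid.nodes
    if spec.kind == "scratch":
        centre = spec.L / 2.0
        mask = (np.abs(x - centre) > spec.gap_halfwidth).astype(float)
        return InitialCondition(
            rho1=spec.rho1_plateau * mask, rho2=spec.rho2_plateau * mask
        )
    shape = _ramp(x, spec.extent, spec.smoothing_width)
    return InitialCondition(
        rho1=spec.rho1_plateau * shape, rho2=spec.rho2_plateau * shape
    )


def _generate(spec: ScenarioSpec) -> ScenarioResult:
    grid = Grid(geometry=spec.geometry, L=spec.L, N=spec.grid_n)
    ic = build_initial_condition(spec, grid)
    obs_times = spec.observation_times
    sim_times = obs_times if obs_times[0] == 0.0 else np.concatenate(([0.0], obs_times))
    if obs_times[-1] > 0 and sim_times[0] == sim_times[-1]:
        raise ValueError("observation times collapse to a single instant")
    solver = replace(spec.solver, output_times=sim_times)
    sim = simulate(spec.params, spec.crowding, ic, grid, solver)
    keep = slice(1, None) if sim_times.size > obs_times.size else slice(None)
    truth = SimulationResult(
        grid=grid,
        times=sim.times[keep] - sim.times[keep][0],
        rho1=sim.rho1[keep],
        rho2=sim.rho2[keep],
    )
    rng = np.random.default_rng(spec.seed)
    shape = (spec.replicates,) + truth.rho1.shape
    # measurement noise only where cells are detectable (counting nuclei in
    # empty space yields exactly zero), with the scale tapering linearly
    # below noise_taper_frac of the peak total density so that clipping at
    # zero cannot paint a positive density floor over the front tail
    taper_at = spec.noise_taper_frac * float((truth.rho1 + truth.rho2).max())
    sd1 = spec.noise * (truth.rho1 > _DETECTION_FLOOR)
    sd2 = spec.noise * (truth.rho2 > _DETECTION_FLOOR)
    if taper_at > 0:
        sd1 = sd1 * np.minimum(1.0, truth.rho1 / taper_at)
        sd2 = sd2 * np.minimum(1.0, truth.rho2 / taper_at)
    if not spec.noise_on_first:
        sd1[0] = 0.0
        sd2[0] = 0.0
    rho1_obs = truth.rho1[None] + sd1[None] * rng.standard_normal(shape)
    rho2_obs = truth.rho2[None] + sd2[None] * rng.standard_normal(shape)
    observations = ObservationSet(
        geometry=spec.geometry,
        times=truth.times,
        positions=grid.nodes,
        rho1=np.maximum(rho1_obs, 0.0),
        rho2=np.maximum(rho2_obs, 0.0),
    )
    return ScenarioResult(
        spec=spec,
        grid=grid,
        initial_condition=ic,
        truth=truth,
        observations=observations,
        averaged=observations.averaged(),
    )


def expansion_scenario(spec: Optional[ScenarioSpec] = None) -> ScenarioResult:
    """Generate the radial tissue-expansion dataset.

    The simulation runs from the smoothed plateau at t = 0; the profile at
    the first observation time (default 10 h) becomes "time zero" of the
    returned observation set, and the remaining times are re-zeroed
    accordingly.
    """
    spec = spec or expansion_spec()
    if spec.geometry != "radial":
        raise ValueError("expansion scenario requires radial geometry")
    return _generate(spec)


def colonization_scenario(spec: Optional[ScenarioSpec] = None) -> ScenarioResult:
    """Generate the 1-D colonization dataset (barrier-release block)."""
    spec = spec or colonization_spec()
    if spec.geometry != "cartesian1d":
        raise ValueError("colonization scenario requires cartesian geometry")
    return _generate(spec)


def scratch_scenario(spec: Optional[ScenarioSpec] = None) -> ScenarioResult:
    """Generate the low-density scratch dataset (central gap closing)."""
    spec = spec or scratch_spec()
    if spec.geometry != "cartesian1d":
        raise ValueError("scratch scenario requires cartesian geometry")
    return _generate(spec)


def replicate_average(obs: ObservationSet) -> ObservationSet:
    """Pointwise replicate mean with per-point sample sd (ddof 1; sd = 0
    for a single replicate).  Invariant to replicate ordering."""
    return obs.averaged()
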