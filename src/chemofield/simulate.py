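"""Synthetic point fields and an agent-based chemotaxis simulator.

Two families of generators:

* Poisson point fields on the unit interval — homogeneous, and inhomogeneous
  via thinning (simulate at a dominating constant rate ``lambda_max``, retain
  a candidate at ``x`` with probability ``fn(x)/lambda_max``).  These are the
  exact null and alternative models of the dispersion test.

* A biased-random-walk simulator of the three-band microfluidic chemotaxis
  assay.  It is the agent-level analog of the drift–diffusion (Keller–Segel)
  description: per time step each agent's cross-axis position advances by
  ``chi * dc/dx * dt`` plus a mean-zero Gaussian increment of variance
  ``2 D dt``; the long-axis position diffuses without drift; both axes
  reflect off the channel walls at 0 and 1.  The chemical concentration ``c``
  is a static smoothed indicator of the loaded central band; the population
  density itself is never represented — the simulator emits point fields,
  which is what the analysis consumes.

Parameter defaults (unit-interval lengths, seconds) are calibrated so the
three scenario presets reproduce the qualitative structure of the assay:
a control population released in the middle third homogenizes over tens of
seconds, an attractant run clusters into the central band well within a
two-minute horizon, and a repellent run empties it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.special import erf

from .point_field import FrameSeries, PointField
from .stats import BandGeometry

__all__ = [
    "IntensityFunction",
    "ChemicalProfile",
    "AgentSimConfig",
    "SCENARIOS",
    "simulate_homogeneous_poisson",
    "simulate_inhomogeneous_poisson",
    "chemical_profile_value",
    "simulate_chemotaxis_frames",
    "scenario",
]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class IntensityFunction:
    """A nonnegative intensity ``fn`` on [0,1] with a known upper bound."""

    fn: Callable[[np.ndarray], np.ndarray]
    lambda_max: float

    def __post_init__(self) -> None:
        if self.lambda_max < 0:
            raise ValueError("lambda_max must be nonnegative")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        vals = np.asarray(self.fn(np.asarray(x, dtype=float)), dtype=float)
        if np.any(vals < 0):
            raise ValueError("intensity function returned a negative value")
        if np.any(vals > self.lambda_max * (1.0 + 1e-12)):
            raise ValueError("intensity function exceeds lambda_max")
        return vals


@dataclass(frozen=True)
class ChemicalProfile:
    """Static concentration profile of the test chemical across the channel.

    A smoothed indicator of the loaded band with error-function edges of
    width ``sigma`` (unit-interval units), scaled so the band-center
    concentration equals ``amplitude``.  ``sigma = 0`` degenerates to a sharp
    indicator whose gradient is defined as 0 everywhere (including edges).
    The smoothing stands in for the lateral diffusion of the chemical after
    flow stops.
    """

    band: BandGeometry = field(default_factory=BandGeometry)
    sigma: float = 0.1
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def _raw(self, x: np.ndarray, sigma: float) -> np.ndarray:
        a, b = self.band.low, self.band.high
        s = sigma * _SQRT2
        return 0.5 * (erf((x - a) / s) - erf((x - b) / s))

    def value(self, x, sigma: float | None = None) -> np.ndarray:
        """Concentration at ``x`` (vectorized); ``x`` must lie in [0,1]."""
        xa = np.asarray(x, dtype=float)
        if np.any((xa < 0) | (xa > 1)):
            raise ValueError("x must lie in [0,1]")
        s = self.sigma if sigma is None else sigma
        a, b = self.band.low, self.band.high
        if s == 0:
            return self.amplitude * ((xa >= a) & (xa < b)).astype(float)
        norm = float(self._raw(np.array(self.band.center), s))
        return self.amplitude * self._raw(xa, s) / norm

    def gradient(self, x, sigma: float | None = None) -> np.ndarray:
        """Analytic spatial derivative of :meth:`value`."""
        xa = np.asarray(x, dtype=float)
        if np.any((xa < 0) | (xa > 1)):
            raise ValueError("x must lie in [0,1]")
        s = self.sigma if sigma is None else sigma
        if s == 0:
            return np.zeros_like(xa)
        a, b = self.band.low, self.band.high
        norm = float(self._raw(np.array(self.band.center), s))
        g = (
            np.exp(-((xa - a) ** 2) / (2.0 * s * s))
            - np.exp(-((xa - b) ** 2) / (2.0 * s * s))
        ) * (_INV_SQRT_2PI / s)
        return self.amplitude * g / norm


def chemical_profile_value(profile: ChemicalProfile, x: float) -> tuple[float, float]:
    """Concentration and gradient of the profile at a single position."""
    return float(profile.value(x)), float(profile.gradient(x))


InitScheme = Literal["uniform", "middle_third", "lateral_bands"]


@dataclass(frozen=True)
class AgentSimConfig:
    """Full parameterization of the biased-random-walk simulator.

    Parameters
    ----------
    n_agents
        Population size; constant across frames (reflecting walls conserve
        agents).  Default 200, the per-frame head count of the assay.
    diffusion
        Random-motility coefficient D in unit^2/s.  The default 5e-3 gives a
        cross-axis relaxation time 1/(D pi^2) of about 20 s, so a population
        released in the middle third homogenizes over tens of seconds.
    sensitivity
        Chemotactic sensitivity chi in unit^2/s per concentration unit:
        positive for an attractant, negative for a repellent, zero for a
        control.  The scenario presets use |chi| = 3 D, for which the
        stationary density is proportional to exp(3 c) — about 80% of the
        population inside the loaded band — strong enough aggregation for
        clustered verdicts well within the two-minute horizon.
    dt, n_steps, frame_stride
        Euler–Maruyama step (s), number of steps, and steps per emitted
        frame.  Defaults: 0.05 s steps over 120 s, one frame per second.
    profile
        Chemical concentration profile across the channel.
    init
        Initial placement: ``uniform`` over the channel, ``middle_third`` of
        the cross axis, or ``lateral_bands`` (outer thirds).  The long axis
        is always uniform.
    seed
        Master seed; expanded into independent per-agent streams, so results
        do not depend on agent iteration order.
    sigma_growth
        Optional linear growth rate of the profile's edge width (unit/s),
        emulating continued lateral diffusion of the chemical.  Default off.
    wall_attraction
        Optional short-range drift (unit/s) toward a wall for agents within
        ``wall_range`` of it, a phenomenological knob for wall-accumulation
        peaks.  Default off.
    """

    n_agents: int = 200
    diffusion: float = 5e-3
    sensitivity: float = 0.0
    dt: float = 0.05
    n_steps: int = 2400
    frame_stride: int = 20
    profile: ChemicalProfile = field(default_factory=ChemicalProfile)
    init: InitScheme = "uniform"
    seed: int = 0
    sigma_growth: float = 0.0
    wall_attraction: float = 0.0
    wall_range: float = 0.05

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if self.diffusion <= 0:
            raise ValueError("diffusion must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if not 0 < self.frame_stride <= self.n_steps:
            raise ValueError("frame_stride must satisfy 0 < frame_stride <= n_steps")
        if self.init not in ("uniform", "middle_third", "lateral_bands"):
            raise ValueError(f"unknown init scheme {self.init!r}")
        if self.sigma_growth < 0 or self.wall_attraction < 0:
            raise ValueError("sigma_growth and wall_attraction must be nonnegative")

    @property
    def total_time(self) -> float:
        return self.dt * self.n_steps


def simulate_homogeneous_poisson(intensity: float, seed=None) -> PointField:
    """Homogeneous Poisson point field on [0,1].

    The point count is Poisson(intensity); positions are independent
    uniforms.  Deterministic given a seed.
    """
    if intensity < 0:
        raise ValueError("intensity must be nonnegative")
    rng = _rng(seed)
    n = rng.poisson(intensity)
    return PointField(rng.uniform(0.0, 1.0, size=n))


def simulate_inhomogeneous_poisson(intensity_fn: IntensityFunction, seed=None) -> PointField:
    """Inhomogeneous Poisson field on [0,1] by thinning.

    Candidates from a homogeneous process of rate ``lambda_max`` are retained
    at ``x`` with probability ``fn(x)/lambda_max``.  Raises if ``fn`` returns
    a negative value or exceeds ``lambda_max`` at any sampled point.
    """
    rng = _rng(seed)
    if intensity_fn.lambda_max == 0:
        return PointField(np.empty(0))
    n_cand = rng.poisson(intensity_fn.lambda_max)
    x = rng.uniform(0.0, 1.0, size=n_cand)
    vals = intensity_fn(x)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < vals / intensity_fn.lambda_max
    return PointField(x[keep])


def _initial_positions(config: AgentSimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_agents
    pos = np.empty((n, 2))
    pos[:, 1] = rng.uniform(0.0, 1.0, size=n)  # long axis always uniform
    if config.init == "uniform":
        pos[:, 0] = rng.uniform(0.0, 1.0, size=n)
    elif config.init == "middle_third":
        pos[:, 0] = rng.uniform(1.0 / 3.0, 2.0 / 3.0, size=n)
    else:  # lateral_bands: outer thirds, half the agents each side
        side = rng.uniform(0.0, 1.0, size=n) < 0.5
        u = rng.uniform(0.0, 1.0 / 3.0, size=n)
        pos[:, 0] = np.where(side, u, u + 2.0 / 3.0)
    return pos


def _reflect(x: np.ndarray) -> np.ndarray:
    """Fold positions back into [0,1] by reflection at both walls."""
    y = np.remainder(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def simulate_chemotaxis_frames(config: AgentSimConfig) -> FrameSeries:
    """Run the biased random walk and emit a 2-D point field per frame.

    Frames are emitted at step 0 and every ``frame_stride`` steps thereafter,
    with timestamps ``step * dt``.  Agent count is constant, all positions
    stay in the unit square, and the output is deterministic given the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_agents + 1)
    init_rng = np.random.default_rng(children[0])
    pos = _initial_positions(config, init_rng)

    # independent per-agent noise streams; assembled as (n_steps, n_agents, 2)
    noise = np.empty((config.n_steps, config.n_agents, 2))
    for i in range(config.n_agents):
        noise[:, i, :] = np.random.default_rng(children[i + 1]).standard_normal(
            (config.n_steps, 2)
        )

    sigma_step = math.sqrt(2.0 * config.diffusion * config.dt)
    chi_dt = config.sensitivity * config.dt
    profile = config.profile

    times = [0.0]
    frames = [PointField(pos.copy())]
    for step in range(1, config.n_steps + 1):
        t = step * config.dt
        if chi_dt != 0.0:
            sig = profile.sigma + config.sigma_growth * (t - config.dt)
            drift = chi_dt * profile.gradient(pos[:, 0], sigma=sig)
        else:
            drift = 0.0
        if config.wall_attraction > 0.0:
            x = pos[:, 0]
            wall_drift = np.where(
                x < config.wall_range,
                -config.wall_attraction,
                np.where(x > 1.0 - config.wall_range, config.wall_attraction, 0.0),
            )
            drift = drift + wall_drift * config.dt
        pos[:, 0] = _reflect(pos[:, 0] + drift + sigma_step * noise[step - 1, :, 0])
        pos[:, 1] = _reflect(pos[:, 1] + sigma_step * noise[step - 1, :, 1])
        if step % config.frame_stride == 0:
            times.append(t)
            frames.append(PointField(pos.copy()))
    return FrameSeries(times, frames)


#: scenario presets mirroring the three assay experiments
SCENARIOS: dict[str, dict] = {
    # no chemical; organisms released in the middle third and left to disperse
    "control": {"init": "middle_third", "sensitivity": 0.0},
    # central band loaded with an attractant; organisms injected everywhere
    "attractant": {"init": "uniform", "sensitivity": 1.5e-2},
    # central band loaded with a repellent; organisms injected everywhere
    "repellent": {"init": "uniform", "sensitivity": -1.5e-2},
}


def scenario(name: str, **overrides) -> AgentSimConfig:
    """Fully populated simulator config for a named assay scenario.

    ``control`` releases 200 agents in the middle third with no chemical
    drift; ``attractant``/``repellent`` start uniform with positive/negative
    sensitivity.  All runs default to a two-minute horizon sampled at one
    frame per second.  Keyword overrides are merged on top of the preset.
    """
    try:
        preset = dict(SCENARIOS[name])
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None
    preset.update(overrides)
    return AgentSimConfig(**preset)
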