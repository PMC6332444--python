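"""Self-adaptive pulling-direction optimization (SA-SMD).

A candidate pulling direction is parameterized by a nutation angle theta in
[0, pi/2] and a precession angle phi in [-pi, pi] about the initial
direction n0, so candidates cover the hemisphere around n0.  The quality of
a candidate is the average scalar pulling force over a short trial segment
of length T simulated forward from a checkpoint of the running simulation;
the multi-population entropy GA minimizes that objective over (phi, theta).

Trial segments for all candidates restore the checkpoint's generator
state, so every candidate is scored on the identical noise realization
(common random numbers); the winning direction is then adopted and the main
trajectory continues from the checkpoint on the main stream, which by
construction replays the winner's noise.  Trial trajectories themselves are
discarded.

An optimization is triggered at time t when both (t - t_last_opt) > t0 and
the average pulling force over the trailing window of length T exceeds the
cut-off force f0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .engine import EngineParams, Snapshot, clone_rng, noise_scale
from .ga import GAConfig, GAHistory, evolve
from .landscape import FunnelLandscape, _perp_axes, _unit
from .steering import PullSpec, RuptureResult, _pull_run, extension
from .units import from_pN, to_pN

__all__ = ["DirectionAngles", "ControllerConfig", "OptimizationRecord",
           "direction_from_angles", "angles_from_direction",
           "trial_average_force", "should_optimize", "optimize_direction",
           "run_sasmd", "default_run_ga_config"]

#: GA budget used inside SA-SMD runs: 16 populations x 4 members x 3
#: generations = 192 trial segments per direction optimization.
def default_run_ga_config() -> GAConfig:
    return GAConfig(m=16, pop_size=4, n_generations=3)


@dataclass(frozen=True)
class DirectionAngles:
    """Spherical parameterization of a pulling direction about n0."""

    theta: float  # nutation, rad, [0, pi/2]
    phi: float  # precession, rad, [-pi, pi]
    n0: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not 0.0 <= self.theta <= math.pi / 2:
            raise ValueError("theta must lie in [0, pi/2]")
        if not -math.pi <= self.phi <= math.pi:
            raise ValueError("phi must lie in [-pi, pi]")
        object.__setattr__(self, "n0", tuple(float(x) for x in self.n0))


@dataclass(frozen=True)
class ControllerConfig:
    """Controller for a pulling run (C-SMD ignores the trigger fields).

    Forces are internal units (kJ/mol/nm); ``f0`` defaults to 250 pN.
    ``max_time`` counts from the start of pulling (after equilibration).
    """

    k: float = 200.0  # spring constant, kJ/mol/nm^2
    v: float = 0.002  # pulling speed, nm/ps
    T: float = 1.0  # force-averaging window, ps
    t0: float = 5.0  # minimal interval between optimizations, ps
    f0: float = from_pN(250.0)  # trigger cut-off force, kJ/mol/nm
    cutoff_separation: float = 0.6  # termination separation, nm
    max_time: float = 6000.0  # ps
    n0: tuple = (0.0, 0.0, 1.0)  # initial pulling direction
    engine: EngineParams = field(default_factory=EngineParams)
    equil_time: float = 100.0  # unrestrained pre-pull relaxation, ps
    traj_stride: int = 50  # steps between recorded trajectory frames
    recenter_hemisphere: bool = False  # optimize about the current direction

    def __post_init__(self):
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.f0 < 0:
            raise ValueError("f0 must be non-negative")
        if self.T <= 0:
            raise ValueError("T must be positive")
        n0 = np.asarray(self.n0, dtype=float)
        if abs(np.linalg.norm(n0) - 1.0) > 1e-9:
            raise ValueError("n0 must be a unit vector")
        object.__setattr__(self, "n0", tuple(float(x) for x in n0))

    @property
    def f0_pN(self) -> float:
        return to_pN(self.f0)

    def with_f0_pN(self, f0_pn: float) -> "ControllerConfig":
        return replace(self, f0=from_pN(f0_pn))


@dataclass
class OptimizationRecord:
    """One executed direction optimization."""

    t_opt: float  # ps
    chosen: DirectionAngles
    objective_value: float  # trial mean force of the chosen direction
    n_evaluations: int
    ga_history: GAHistory
    warning: bool = False  # True if no finite trial evaluation was seen
    trigger_force: float = float("nan")  # trailing-window force that fired


def direction_from_angles(a: DirectionAngles) -> np.ndarray:
    """Unit vector at nutation theta / precession phi about a.n0.

    The phi = 0 axis is the component of the world x axis orthogonal to n0
    (y axis if n0 is parallel to x), making runs reproducible.
    """
    n0 = _unit(a.n0)
    e1, e2 = _perp_axes(n0)
    st = math.sin(a.theta)
    return (math.cos(a.theta) * n0
            + st * (math.cos(a.phi) * e1 + math.sin(a.phi) * e2))


def angles_from_direction(d, n0) -> DirectionAngles:
    """Inverse of :func:`direction_from_angles` (d must lie in n0's
    hemisphere)."""
    n0 = _unit(n0)
    d = _unit(d)
    ct = float(np.clip(d @ n0, -1.0, 1.0))
    if ct < 0:
        raise ValueError("direction lies outside the n0 hemisphere")
    e1, e2 = _perp_axes(n0)
    theta = math.acos(ct)
    phi = math.atan2(float(d @ e2), float(d @ e1)) if theta > 1e-12 else 0.0
    return DirectionAngles(min(theta, math.pi / 2), phi, tuple(n0))


def should_optimize(t: float, t_last_opt: float, f_recent: float,
                    cfg: ControllerConfig) -> bool:
    """Trigger rule: elapsed time strictly exceeds t0 AND the trailing
    windowed force strictly exceeds f0."""
    if t < t_last_opt:
        raise ValueError("t must not precede t_last_opt")
    return (t - t_last_opt) > cfg.t0 and f_recent > cfg.f0


def _trial_batch(snap: Snapshot, dirs: np.ndarray, cfg: ControllerConfig,
                 l: FunnelLandscape, spec: PullSpec | None) -> np.ndarray:
    """Mean trial force for each candidate direction (common random
    numbers: one cloned stream, shared draws)."""
    p = cfg.engine
    n_steps = int(round(cfg.T / p.dt))
    x_off = extension(spec, snap.r, snap.t) if spec is not None else 0.0
    ncand = dirs.shape[0]
    pos = np.tile(snap.r, (ncand, 1))
    f_mean = np.empty(ncand)
    _kernels.trial_batch(pos, np.ascontiguousarray(dirs, dtype=float),
                         clone_rng(snap), *l.kernel_args,
                         cfg.k, cfg.v, x_off, n_steps, p.dt, p.friction,
                         noise_scale(p), f_mean)
    return f_mean


def trial_average_force(snap: Snapshot, a: DirectionAngles,
                        cfg: ControllerConfig, l: FunnelLandscape,
                        spec: PullSpec | None = None) -> float:
    """Average pulling force over a trial segment of length T started from
    the checkpoint along the candidate direction.

    ``spec`` is the live pulling spec at the checkpoint; the candidate
    segment continues its accumulated extension (force continuity).  With
    ``spec=None`` the trial starts an unloaded pull.  The caller's state is
    untouched: the trial runs on a cloned generator.
    """
    return float(_trial_batch(snap, direction_from_angles(a)[None, :],
                              cfg, l, spec)[0])


def optimize_direction(snap: Snapshot, cfg: ControllerConfig,
                       ga_cfg: GAConfig, l: FunnelLandscape,
                       rng: np.random.Generator,
                       spec: PullSpec | None = None,
                       n0=None):
    """Minimize the trial average force over the (phi, theta) hemisphere.

    Returns ``(DirectionAngles, OptimizationRecord)``.  Two reference
    candidates are always evaluated in addition to the GA's: the hemisphere
    axis n0 itself (theta = 0) and the current pulling direction, so the
    reported optimum is never worse than keeping either.
    """
    n0 = np.asarray(cfg.n0 if n0 is None else n0, dtype=float)

    def fitness(X):
        dirs = np.empty((len(X), 3))
        for i, (phi, theta) in enumerate(X):
            dirs[i] = direction_from_angles(DirectionAngles(theta, phi, tuple(n0)))
        return _trial_batch(snap, dirs, cfg, l, spec)

    bounds = [(-math.pi, math.pi), (0.0, math.pi / 2)]
    best_x, best_f, hist = evolve(fitness, bounds, ga_cfg, rng, vectorized=True)
    n_evals = hist.n_evaluations
    warning = best_x is None

    # reference candidates: keep n0 / keep the current direction
    refs = [DirectionAngles(0.0, 0.0, tuple(n0))]
    if spec is not None:
        try:
            refs.append(angles_from_direction(spec.n, n0))
        except ValueError:
            pass  # current direction outside the hemisphere (recentering off)
    ref_x = np.array([[a.phi, a.theta] for a in refs])
    ref_f = fitness(ref_x)
    n_evals += len(refs)
    j = int(np.argmin(ref_f))
    if warning or ref_f[j] < best_f:
        chosen = refs[j]
        best_f = float(ref_f[j])
    else:
        chosen = DirectionAngles(float(best_x[1]), float(best_x[0]), tuple(n0))
    record = OptimizationRecord(
        t_opt=snap.t, chosen=chosen, objective_value=float(best_f),
        n_evaluations=n_evals, ga_history=hist, warning=warning)
    return chosen, record


def run_sasmd(l: FunnelLandscape, cfg: ControllerConfig,
              ga_cfg: GAConfig | None = None, seed: int = 0):
    """Full self-adaptive run: equilibrate, pull, re-optimize the direction
    whenever the (t0, f0) trigger fires, until unbinding or max_time.

    Returns ``(RuptureResult, list[OptimizationRecord])``.  With an
    unreachable trigger (f0 = inf) the control flow and random stream are
    identical to :func:`sasmd.steering.run_csmd`, so results agree bit for
    bit at equal seeds.
    """
    if ga_cfg is None:
        ga_cfg = default_run_ga_config()
    ga_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    def optimize_cb(snap, spec, records, f_recent):
        n0 = spec.n if cfg.recenter_hemisphere else None
        chosen, record = optimize_direction(snap, cfg, ga_cfg, l, ga_rng,
                                            spec=spec, n0=n0)
        record.trigger_force = float(f_recent)
        records.append(record)
        return direction_from_angles(chosen)

    return _pull_run(l, cfg, seed, optimize=optimize_cb)
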