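"""Overdamped Langevin dynamics with exact checkpoint/restore.

The surrogate ligand is a single point particle with isotropic friction
``gamma`` moving on a landscape under an optional external force:

    dr = (f_ext - grad U) / gamma * dt + sqrt(2 kB T dt / gamma) * xi

with ``xi`` a standard-normal 3-vector (Euler-Maruyama).  Exactly one such
vector is drawn per step from the state's ``numpy.random.Generator``, so a
snapshot of ``(r, t, generator state)`` reproduces a trajectory bit for
bit.  That property is what lets the direction optimizer evaluate many
candidate pulling directions from identical starting conditions.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .landscape import FunnelLandscape, Landscape
from .units import KB

__all__ = ["EngineParams", "SimState", "Snapshot", "step", "checkpoint",
           "restore", "equilibrate", "noise_scale"]


@dataclass(frozen=True)
class EngineParams:
    """Integrator parameters.

    dt : time step, ps (default 0.002 ps = 2 fs)
    friction : drag coefficient gamma, kJ/mol/nm^2*ps.  The default 50
        gives a well relaxation time gamma/k_well of a fraction of a ps for
        typical well stiffnesses here, well below the 5 ps optimization
        interval, so the ligand is diffusively equilibrated between
        direction updates.
    temperature : K
    """

    dt: float = 0.002
    friction: float = 50.0
    temperature: float = 300.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


def noise_scale(p: EngineParams) -> float:
    """Per-step displacement noise amplitude sqrt(2 kB T dt / gamma), nm."""
    return float(np.sqrt(2.0 * KB * p.temperature * p.dt / p.friction))


class SimState:
    """Mutable simulation state: position (nm), time (ps), RNG stream."""

    __slots__ = ("r", "t", "rng")

    def __init__(self, r, t: float = 0.0, rng=None, seed: int | None = None):
        self.r = np.array(r, dtype=float)
        if self.r.shape != (3,):
            raise ValueError("r must be a 3-vector")
        self.t = float(t)
        if rng is None:
            rng = np.random.default_rng(seed)
        self.rng = rng

    def __eq__(self, other):
        if not isinstance(other, SimState):
            return NotImplemented
        return (
            bool(np.all(self.r == other.r))
            and self.t == other.t
            and self.rng.bit_generator.state == other.rng.bit_generator.state
        )

    def __repr__(self):
        return f"SimState(r={self.r.tolist()}, t={self.t})"


class Snapshot:
    """Deep, immutable copy of a SimState, serializable to JSON."""

    __slots__ = ("_r", "_t", "_rng_state")

    def __init__(self, r, t, rng_state):
        self._r = tuple(float(x) for x in r)
        self._t = float(t)
        self._rng_state = copy.deepcopy(rng_state)

    @property
    def r(self):
        return np.array(self._r)

    @property
    def t(self):
        return self._t

    @property
    def rng_state(self):
        return copy.deepcopy(self._rng_state)

    def to_json(self) -> str:
        return json.dumps({"r": self._r, "t": self._t, "rng_state": self._rng_state})

    @classmethod
    def from_json(cls, text: str) -> "Snapshot":
        d = json.loads(text)
        if set(d) != {"r", "t", "rng_state"}:
            raise ValueError("corrupted snapshot")
        return cls(d["r"], d["t"], d["rng_state"])


def checkpoint(s: SimState) -> Snapshot:
    """Capture position, time and the full RNG stream state."""
    return Snapshot(s.r, s.t, s.rng.bit_generator.state)


def restore(snap: Snapshot) -> SimState:
    """Reconstruct the exact state (including the RNG stream) of a snapshot."""
    state = snap.rng_state
    try:
        bg_name = state["bit_generator"]
    except (TypeError, KeyError) as err:
        raise ValueError("corrupted snapshot: missing bit generator state") from err
    bg = getattr(np.random, bg_name)()
    bg.state = state
    return SimState(snap.r, snap.t, rng=np.random.Generator(bg))


def clone_rng(snap: Snapshot) -> np.random.Generator:
    """A fresh generator positioned at the snapshot's stream state."""
    return restore(snap).rng


def step(s: SimState, l: Landscape, f_ext, p: EngineParams) -> SimState:
    """Advance the state by one Euler-Maruyama step (in place; returns s)."""
    f_ext = np.asarray(f_ext, dtype=float)
    if not np.all(np.isfinite(f_ext)):
        raise ValueError("external force must be finite")
    f_total = f_ext - l.grad(s.r)
    xi = s.rng.standard_normal(3)
    s.r += f_total * (p.dt / p.friction) + noise_scale(p) * xi
    s.t += p.dt
    return s


def equilibrate(s: SimState, l: Landscape, duration: float, p: EngineParams) -> SimState:
    """Unrestrained dynamics (f_ext = 0) for ``duration`` ps (in place)."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = int(round(duration / p.dt))
    if n == 0:
        return s
    if isinstance(l, FunnelLandscape):
        _kernels.free_run(s.r, s.rng, n, *l.kernel_args, p.dt, p.friction,
                          noise_scale(p))
        s.t += n * p.dt
        return s
    zero = np.zeros(3)
    for _ in range(n):
        step(s, l, zero, p)
    return s
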