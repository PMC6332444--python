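"""Constant-velocity harmonic steering (SMD) and rupture-force analysis.

The steering potential is the standard moving-spring form

    U_s = 1/2 k [ v t - (R(t) - R(0)) . n ]^2

so the force on the ligand is ``k x n`` with scalar extension
``x = v (t - t_start) + x_offset - (R - R_ref) . n``.  The logged per-step
"pulling force" is the signed scalar ``k x`` (the projection along the
current pulling direction; negative if the ligand overtakes the
constraint), not the vector norm.

When the pulling direction changes mid-run, the new spec resets the
reference position and segment clock to the switch point and carries the
accumulated extension in ``x_offset``, which makes the force magnitude
continuous across the switch; artificial force spikes would otherwise
corrupt both the optimization trigger and the optimizer's objective.

The rupture force of a run is the maximum of the force profile averaged
over non-overlapping windows of length T (1 ps by default), windows aligned
to the start of each pulling segment; ties break to the earliest window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .engine import SimState, checkpoint, equilibrate, noise_scale
from .landscape import FunnelLandscape
from .units import to_pN

__all__ = ["PullSpec", "ForceProfile", "RuptureResult", "steering_force",
           "extension", "windowed_average", "rupture_force",
           "switch_direction", "run_csmd"]


@dataclass(frozen=True)
class PullSpec:
    """Parameters of one harmonic pulling segment."""

    k: float  # spring constant, kJ/mol/nm^2
    v: float  # pulling speed, nm/ps
    n: np.ndarray  # unit pulling direction
    r_ref: np.ndarray  # reference position R_ref, nm
    t_start: float = 0.0  # segment time origin, ps
    x_offset: float = 0.0  # extension carried across direction switches, nm

    def __post_init__(self):
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        object.__setattr__(self, "r_ref", np.asarray(self.r_ref, dtype=float))
        if self.k <= 0:
            raise ValueError("spring constant must be positive")
        if self.v < 0:
            raise ValueError("pulling speed must be non-negative")
        if abs(np.linalg.norm(self.n) - 1.0) > 1e-12:
            raise ValueError("pulling direction must be a unit vector")


@dataclass(frozen=True)
class ForceProfile:
    """Windowed average pulling forces: (t_mid, f_avg) pairs."""

    t_mid: np.ndarray  # ps
    f_avg: np.ndarray  # kJ/mol/nm
    window_length: float  # ps

    def __post_init__(self):
        object.__setattr__(self, "t_mid", np.asarray(self.t_mid, dtype=float))
        object.__setattr__(self, "f_avg", np.asarray(self.f_avg, dtype=float))
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if np.any(np.diff(self.t_mid) <= 0):
            raise ValueError("window times must be strictly increasing")

    def __len__(self):
        return len(self.t_mid)


@dataclass
class RuptureResult:
    """Outcome of one pulling run."""

    rupture_force: float  # kJ/mol/nm (max windowed force)
    rupture_time: float  # ps, window midpoint of the maximum
    end_time: float  # ps
    n_direction_switches: int
    profile: ForceProfile
    unbound: bool  # False = "did not unbind" before max_time
    mode: str  # "csmd" | "sasmd"
    seed: int
    trajectory: np.ndarray = field(repr=False, default=None)  # (n, 4): t, x, y, z
    raw_forces: np.ndarray = field(repr=False, default=None)  # per-step k*x
    raw_dt: float = 0.0
    trajectory_path: Optional[str] = None

    @property
    def rupture_force_pN(self) -> float:
        return to_pN(self.rupture_force)


def extension(p: PullSpec, r, t: float) -> float:
    """Scalar spring extension x at position r, time t."""
    r = np.asarray(r, dtype=float)
    return float(p.v * (t - p.t_start) + p.x_offset - (r - p.r_ref) @ p.n)


def steering_force(p: PullSpec, s: SimState) -> np.ndarray:
    """Steering force k*x*n on the ligand (kJ/mol/nm)."""
    return p.k * extension(p, s.r, s.t) * p.n


def switch_direction(p: PullSpec, n_new, s: SimState) -> PullSpec:
    """Re-point the spring along ``n_new`` from the current state.

    The reference position and segment clock reset to the switch point and
    the current extension is carried over, so |force| is continuous.
    """
    n_new = np.asarray(n_new, dtype=float)
    if abs(np.linalg.norm(n_new) - 1.0) > 1e-12:
        raise ValueError("new pulling direction must be a unit vector")
    x_now = extension(p, s.r, s.t)
    return replace(p, n=n_new, r_ref=s.r.copy(), t_start=s.t, x_offset=x_now)


def windowed_average(t: np.ndarray, f: np.ndarray, T: float) -> ForceProfile:
    """Average uniformly sampled forces over consecutive windows of length T.

    ``t`` are sample times (uniform spacing dt), ``f`` the scalar pulling
    forces.  T must be an integer multiple of dt; a trailing partial window
    is dropped.  Window midpoints are ``t[0] + (i + 1/2) T``.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=0, atol=1e-9):
        raise ValueError("samples must be uniformly spaced")
    if T < dt - 1e-12:
        raise ValueError("window length T is smaller than the sample interval")
    n_win = int(round(T / dt))
    if abs(n_win * dt - T) > 1e-9:
        raise ValueError("T must be an integer multiple of the sample interval")
    m = len(f) // n_win
    f_avg = f[: m * n_win].reshape(m, n_win).mean(axis=1)
    t_mid = t[0] + (np.arange(m) + 0.5) * T
    return ForceProfile(t_mid, f_avg, T)


def rupture_force(fp: ForceProfile):
    """(max windowed force, its window midpoint); earliest window on ties."""
    if len(fp) == 0:
        raise ValueError("empty force profile")
    i = int(np.argmax(fp.f_avg))
    return float(fp.f_avg[i]), float(fp.t_mid[i])


def _segment_profile(segments, T: float) -> ForceProfile:
    """Concatenate per-segment windowed profiles (trailing partials dropped).

    ``segments``: list of (seg_start_time, forces, dt).
    """
    mids, avgs = [], []
    for t0, f, dt in segments:
        n_win = int(round(T / dt))
        m = len(f) // n_win
        if m == 0:
            continue
        avgs.append(f[: m * n_win].reshape(m, n_win).mean(axis=1))
        mids.append(t0 + (np.arange(m) + 0.5) * T)
    if not mids:
        return ForceProfile(np.empty(0), np.empty(0), T)
    return ForceProfile(np.concatenate(mids), np.concatenate(avgs), T)


def _pull_run(l: FunnelLandscape, cfg, seed: int, optimize=None):
    """Shared pulling driver for C-SMD and SA-SMD.

    ``cfg`` is a ControllerConfig (see :mod:`sasmd.optimizer`).  If
    ``optimize`` is None the run is conventional SMD (fixed direction, no
    trigger checks that alter control flow).  Otherwise ``optimize`` is
    called as ``optimize(snapshot, spec, records, f_recent)`` at each trigger and must
    return the new unit pulling direction; the main trajectory then
    continues from the checkpoint state on the main random stream (trial
    segments inside ``optimize`` use cloned streams and are never reused).

    Returns (RuptureResult, records) where ``records`` is whatever the
    optimize callback appended (empty for C-SMD).
    """
    if not isinstance(l, FunnelLandscape):
        raise TypeError("pulling drivers require a FunnelLandscape")
    p = cfg.engine
    dt = p.dt
    ss = np.random.SeedSequence(seed)
    eng_ss, _ga_ss = ss.spawn(2)
    state = SimState(l.well_center.copy(), 0.0, rng=np.random.default_rng(eng_ss))
    equilibrate(state, l, cfg.equil_time, p)

    t_pull0 = state.t
    n0 = np.asarray(cfg.n0, dtype=float)
    spec = PullSpec(cfg.k, cfg.v, n0, state.r.copy(), t_start=state.t)
    win_n = int(round(cfg.T / dt))
    max_t_abs = t_pull0 + cfg.max_time
    cap = int(np.ceil(cfg.max_time / dt)) + win_n + 8
    f_buf = np.empty(cap)
    stride = int(cfg.traj_stride)
    traj_cap = cap // max(stride, 1) + int(cfg.max_time / cfg.t0) + 16
    traj_buf = np.empty((traj_cap, 4))
    win = np.zeros(win_n)
    win_state = np.zeros(3)
    f_count = 0
    traj_count = 0
    t_last_opt = t_pull0
    trigger_on = optimize is not None
    segments = []  # (seg_start_time, slice into f_buf)
    seg_start_idx = 0
    seg_start_t = state.t
    records = []
    n_switches = 0

    while True:
        status, t_end, nf, ntr = _kernels.pull_loop(
            state.r, state.t, state.rng, *l.kernel_args,
            spec.k, spec.v, spec.n, spec.r_ref, spec.t_start, spec.x_offset,
            dt, p.friction, noise_scale(p),
            trigger_on, t_last_opt, cfg.t0, cfg.f0, win, win_state,
            l.envelope_radius, cfg.cutoff_separation, max_t_abs,
            f_buf, f_count, traj_buf, traj_count, stride)
        state.t = t_end
        f_count += nf
        traj_count += ntr
        if status != _kernels.STATUS_TRIGGER:
            break
        snap = checkpoint(state)
        f_recent = win_state[0] / win_n  # trailing T-window mean at the trigger
        n_new = optimize(snap, spec, records, f_recent)
        spec = switch_direction(spec, n_new, state)
        t_last_opt = state.t
        n_switches += 1
        segments.append((seg_start_t, slice(seg_start_idx, f_count)))
        seg_start_idx = f_count
        seg_start_t = state.t
    segments.append((seg_start_t, slice(seg_start_idx, f_count)))

    profile = _segment_profile(
        [(t0, f_buf[sl], dt) for t0, sl in segments], cfg.T)
    if len(profile):
        f_rup, t_rup = rupture_force(profile)
    else:
        f_rup, t_rup = float("nan"), float("nan")
    result = RuptureResult(
        rupture_force=f_rup,
        rupture_time=t_rup,
        end_time=state.t,
        n_direction_switches=n_switches,
        profile=profile,
        unbound=(status == _kernels.STATUS_UNBOUND),
        mode="csmd" if optimize is None else "sasmd",
        seed=seed,
        trajectory=traj_buf[:traj_count].copy(),
        raw_forces=f_buf[:f_count].copy(),
        raw_dt=dt,
    )
    return result, records


def run_csmd(l: FunnelLandscape, cfg, seed: int) -> RuptureResult:
    """Conventional SMD: pull along the fixed initial direction ``cfg.n0``
    until the ligand separates by ``cfg.cutoff_separation`` or ``max_time``
    elapses (the result is then flagged as not unbound)."""
    result, _ = _pull_run(l, cfg, seed, optimize=None)
    return result
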