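"""Synthetic anisotropic binding-funnel energy landscapes.

A funnel landscape stands in for a solvated protein--ligand complex: a
bound-state minimum of tunable depth (the analogue of the binding free
energy magnitude), surrounded by a spherical barrier shell whose height is
angularly modulated by "escape channels" -- directions in which the barrier
is depressed.  The easiest escape direction can therefore be placed at an
arbitrary angle from the initial pulling direction, which is the structural
fact a direction-optimizing steered-MD method exploits.

Closed form, for ligand displacement ``w = r - well_center``, ``d = |w|``::

    U(r) = -D exp(-d^2 / 2 s_w^2)                      (binding well)
         + B(u) S(d)                                   (barrier shell)
         + A G(d) prod_{i open} (1 - g_i(u))           (guide wall)
         + 1/2 k_bg d^2                                (optional confinement)

    S(d)   = exp(-(d - d_b)^2 / 2 s_b^2) (1 - exp(-d^2 / 2 r_0^2))

    B(u)   = B_bg - sum_i (B_bg - B_i) g_i(u)
    g_i(u) = exp(kappa_i (cos a_i - 1))
    G(d)   = (1 - exp(-d^2 / 2 a_on^2)) exp(-(d / a_off)^4)

where ``cos a_i = (w . e_i) / sqrt(d^2 + eps^2)`` is a softened cosine of
the angle between ``w`` and channel direction ``e_i`` (the softening
``eps`` keeps the form smooth at the well centre), ``kappa_i = 1/width_i^2``
sets the angular channel width, and ``B_i < B_bg`` is the barrier height
along channel ``i``.  The fixed ``r_0 = 0.05`` nm factor switches the
angular modulation off at the well centre so the minimum sits exactly at
``well_center``.  Along a channel direction the directional energy
maximum of the shell is ``B_i`` up to small cross terms; between channels
it is ``B_bg``.

The guide wall (amplitude ``A = guide_amp``) models the steric walls of
the binding cleft: it confines the ligand angularly onto channels flagged
``guide_open`` at *all* radii between ``a_on`` and ``a_off``, not just at
the barrier shell.  A channel that is *not* flagged open is a cryptic
exit: its depressed shell barrier is hidden behind the wall, so a
thermally fluctuating ligand cannot drift into it from the bound state,
while a pull directed at it can push through (provided
``guide_amp + B_i < B_open``, the wall plus the cryptic barrier is still
the cheaper exit).  With ``guide_amp = 0`` the form reduces to the plain
well + modulated shell.  Everything is analytic, so the gradient is exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "Channel",
    "FunnelParams",
    "FamilySpec",
    "Landscape",
    "FunnelLandscape",
    "HarmonicLandscape",
    "make_funnel_landscape",
    "make_family",
    "energy",
    "grad",
    "separation",
]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class Channel:
    """One escape channel: a direction of depressed barrier height."""

    direction: tuple  # unit 3-vector
    barrier_height: float  # kJ/mol, must be < background barrier
    width: float = 0.2  # angular width, rad
    guide_open: bool = False  # True: the guide wall is notched here


@dataclass(frozen=True)
class FunnelParams:
    """Closed-form parameter set of a funnel landscape (the descriptor)."""

    well_depth: float = 30.0  # kJ/mol, proxy for |binding free energy|
    well_width: float = 0.3  # nm, Gaussian width of the bound well
    well_center: tuple = (0.0, 0.0, 0.0)
    background_barrier: float = 68.0  # kJ/mol, barrier away from channels
    barrier_radius: float = 0.8  # nm, radius of the barrier shell
    barrier_width: float = 0.15  # nm, radial width of the shell
    channels: tuple = ()
    envelope_radius: float = None  # binding-site envelope; default shell radius
    background_stiffness: float = 0.0  # kJ/mol/nm^2, optional confinement
    core_softening: float = 0.01  # nm, smoothing of the angular term at d=0
    guide_amp: float = 0.0  # kJ/mol, cleft-wall amplitude (0 = no wall)
    guide_on: float = 0.25  # nm, radius where the wall turns on
    guide_off: float = 1.1  # nm, radius where the wall dies off
    direction_jitter: float = 0.0  # rad, seeded perturbation of channel axes
    barrier_jitter: float = 0.0  # relative, seeded perturbation of heights


@dataclass(frozen=True)
class FamilySpec:
    """A family of funnels sharing geometry, differing in well depth.

    The well depth is the single controlled analogue of the experimental
    binding free energy; ``reference_energy = -well_depth``.
    """

    n_members: int
    depth_range: tuple  # (min, max) kJ/mol
    shared_geometry: FunnelParams = field(default_factory=FunnelParams)
    seed: int = 0
    spacing: str = "even"  # "even" | "random"


class Landscape:
    """Interface: analytic potential energy surface with exact gradient."""

    well_center: np.ndarray

    def energy(self, r) -> float:
        raise NotImplementedError

    def grad(self, r) -> np.ndarray:
        raise NotImplementedError

    def separation(self, r) -> float:
        """Distance from the binding-site envelope (0 inside it)."""
        raise NotImplementedError


class FunnelLandscape(Landscape):
    """Anisotropic binding funnel; see the module docstring for the form."""

    def __init__(self, params: FunnelParams):
        if params.well_depth <= 0:
            raise ValueError("well_depth must be positive")
        if len(params.channels) == 0:
            raise ValueError("at least one escape channel is required")
        dirs = []
        for ch in params.channels:
            d = np.asarray(ch.direction, dtype=float)
            if abs(np.linalg.norm(d) - 1.0) > 1e-8:
                raise ValueError(f"channel direction {ch.direction} is not a unit vector")
            if not (0 < ch.barrier_height < params.background_barrier):
                raise ValueError("channel barrier_height must lie in (0, background_barrier)")
            if ch.width <= 0:
                raise ValueError("channel width must be positive")
            dirs.append(d)
        self.descriptor = params
        self.well_center = np.asarray(params.well_center, dtype=float)
        self.well_depth = float(params.well_depth)
        self.channels = tuple(params.channels)
        self.background_stiffness = float(params.background_stiffness)
        self.envelope_radius = (
            float(params.envelope_radius)
            if params.envelope_radius is not None
            else float(params.barrier_radius)
        )
        # packed arrays for the numba kernels
        self._dirs = np.array(dirs, dtype=float)
        self._kappa = np.array([1.0 / ch.width**2 for ch in params.channels])
        self._amp = np.array(
            [params.background_barrier - ch.barrier_height for ch in params.channels]
        )
        self._opened = np.array(
            [1.0 if ch.guide_open else 0.0 for ch in params.channels]
        )
        self._scal = np.array(
            [
                params.well_depth,
                params.well_width,
                params.background_barrier,
                params.barrier_radius,
                params.barrier_width,
                params.core_softening,
                params.background_stiffness,
                params.guide_amp,
                params.guide_on,
                params.guide_off,
            ]
        )

    @property
    def kernel_args(self):
        """(center, dirs, kappa, amp, opened, scal) consumed by the kernels."""
        return (self.well_center, self._dirs, self._kappa, self._amp,
                self._opened, self._scal)

    def energy(self, r) -> float:
        r = np.asarray(r, dtype=float)
        return float(_kernels.funnel_energy_one(r, *self.kernel_args))

    def grad(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.empty(3)
        _kernels.funnel_grad_one(r, *self.kernel_args, out)
        return out

    def energy_batch(self, pos: np.ndarray) -> np.ndarray:
        pos = np.ascontiguousarray(pos, dtype=float)
        out = np.empty(pos.shape[0])
        _kernels.funnel_energy_batch(pos, *self.kernel_args, out)
        return out

    def separation(self, r) -> float:
        d = float(np.linalg.norm(np.asarray(r, dtype=float) - self.well_center))
        return max(0.0, d - self.envelope_radius)


class HarmonicLandscape(Landscape):
    """Isotropic harmonic well U = 1/2 kappa |r - c|^2.

    A minimal landscape with exactly known statistical mechanics, used to
    validate the dynamics engine (equipartition, Boltzmann statistics).
    """

    def __init__(self, stiffness: float, center=(0.0, 0.0, 0.0), envelope_radius=0.0):
        if stiffness <= 0:
            raise ValueError("stiffness must be positive")
        self.stiffness = float(stiffness)
        self.well_center = np.asarray(center, dtype=float)
        self.envelope_radius = float(envelope_radius)

    def energy(self, r) -> float:
        w = np.asarray(r, dtype=float) - self.well_center
        return 0.5 * self.stiffness * float(w @ w)

    def grad(self, r) -> np.ndarray:
        return self.stiffness * (np.asarray(r, dtype=float) - self.well_center)

    def separation(self, r) -> float:
        d = float(np.linalg.norm(np.asarray(r, dtype=float) - self.well_center))
        return max(0.0, d - self.envelope_radius)


def _perp_axes(n: np.ndarray):
    """A deterministic orthonormal pair spanning the plane normal to n."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 1.0 - 1e-8:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - (ref @ n) * n)
    e2 = np.cross(n, e1)
    return e1, e2


def make_funnel_landscape(params: FunnelParams, seed: int = 0) -> FunnelLandscape:
    """Build a funnel landscape, applying seeded jitter if configured.

    Jitter (``direction_jitter`` rad on channel axes, relative
    ``barrier_jitter`` on channel heights) models member-to-member structural
    variability inside a family.  With both at 0 the landscape is a pure
    function of ``params``; either way the result is deterministic in
    ``(params, seed)``.
    """

    if params.direction_jitter > 0 or params.barrier_jitter > 0:
        rng = np.random.default_rng(seed)
        new_channels = []
        for ch in params.channels:
            d = _unit(ch.direction)
            if params.direction_jitter > 0:
                e1, e2 = _perp_axes(d)
                a = rng.normal(0.0, params.direction_jitter)
                phi = rng.uniform(-np.pi, np.pi)
                d = _unit(
                    np.cos(a) * d + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2)
                )
            h = ch.barrier_height
            if params.barrier_jitter > 0:
                h = h * (1.0 + rng.normal(0.0, params.barrier_jitter))
                h = float(np.clip(h, 0.05 * ch.barrier_height, 0.99 * params.background_barrier))
            new_channels.append(Channel(tuple(d), h, ch.width, ch.guide_open))
        params = dataclasses.replace(params, channels=tuple(new_channels))
    return FunnelLandscape(params)


def make_family(spec: FamilySpec):
    """Generate a family of landscapes differing (mainly) in well depth.

    Returns a list of ``(member_id, FunnelLandscape, reference_energy)``
    where ``reference_energy = -well_depth`` (kJ/mol) plays the role of the
    experimental binding free energy.  Depths are evenly spaced across
    ``depth_range`` (or seeded-random with ``spacing="random"``); geometric
    jitter configured on ``shared_geometry`` is applied per member with a
    member-specific seed, so members are structurally similar but not
    identical.  Deterministic per ``spec``.
    """

    if spec.n_members < 2:
        raise ValueError("a family needs at least 2 members")
    lo, hi = spec.depth_range
    if not (0 < lo <= hi):
        raise ValueError("depth_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(spec.seed)
    if spec.spacing == "even":
        depths = np.linspace(lo, hi, spec.n_members)
    elif spec.spacing == "random":
        depths = np.sort(rng.uniform(lo, hi, spec.n_members))
    else:
        raise ValueError(f"unknown spacing {spec.spacing!r}")
    members = []
    for i, depth in enumerate(depths):
        params = dataclasses.replace(spec.shared_geometry, well_depth=float(depth))
        member_seed = int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0] % 2**31)
        land = make_funnel_landscape(params, seed=member_seed)
        members.append((f"m{i:02d}", land, -float(depth)))
    return members


# -- thin functional surface -------------------------------------------------

def energy(l: Landscape, r) -> float:
    """Potential energy, kJ/mol."""
    return l.energy(r)


def grad(l: Landscape, r) -> np.ndarray:
    """Analytic gradient of the energy, kJ/mol/nm."""
    return l.grad(r)


def separation(l: Landscape, r) -> float:
    """Distance beyond the binding-site envelope, nm (0 inside)."""
    return l.separation(r)
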