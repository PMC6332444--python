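"""Standard study systems and structured (YAML) configuration.

The package's reference systems:

``standard_funnel``  -- the two-channel anisotropic landscape used in the
    mode-comparison and sweep experiments.  The initial pulling direction
    n0 = +z points into a moderately hard channel (a local angular minimum
    of the barrier, so a fixed-direction pull stays on it), while the
    easiest escape channel lies 45 degrees off n0.  A conventional pull
    must climb the hard barrier; a direction-optimized pull can find the
    soft channel.

``family_funnel``  -- the geometry shared by members of a synthetic
    complex family.  A narrower well makes the well-escape force (which
    scales with well depth, the binding-energy analogue) the dominant,
    depth-graded contribution to the rupture force; small seeded jitters
    make members structurally similar but not identical.

Config files are YAML with sections [landscape], [controller], [ga],
[experiment]; forces in files are given in pN (key ``f0_pN``), everything
else in internal units (kJ/mol, nm, ps).
"""

from __future__ import annotations

import dataclasses
import math

import yaml

from .engine import EngineParams
from .ga import GAConfig
from .landscape import Channel, FamilySpec, FunnelLandscape, FunnelParams, make_funnel_landscape
from .optimizer import ControllerConfig
from .units import from_pN, to_pN

__all__ = ["standard_funnel", "standard_landscape", "family_funnel",
           "standard_family_spec", "standard_controller", "aligned_funnel",
           "rate_study_system", "load_config",
           "save_config"]

_SQ2 = 1.0 / math.sqrt(2.0)


def standard_funnel() -> FunnelParams:
    """Two-channel anisotropic funnel; soft cryptic channel 45 degrees off
    n0 = +z.

    The approach channel along +z (the direction a practitioner would pull,
    into the open face of the cleft) carries a high exit barrier; the easy
    exit is a cryptic notch in the barrier shell 45 degrees away, hidden
    behind the cleft's guide wall so only a re-directed pull can reach it.
    """
    return FunnelParams(
        well_depth=30.0,
        well_width=0.3,
        background_barrier=100.0,
        barrier_radius=0.8,
        barrier_width=0.15,
        guide_amp=35.0,
        channels=(
            Channel(direction=(0.0, 0.0, 1.0), barrier_height=70.0,
                    width=0.3, guide_open=True),
            Channel(direction=(_SQ2, 0.0, _SQ2), barrier_height=8.0,
                    width=0.2, guide_open=False),
        ),
    )


def standard_landscape(seed: int = 0) -> FunnelLandscape:
    return make_funnel_landscape(standard_funnel(), seed=seed)


def aligned_funnel() -> FunnelParams:
    """Control landscape: the single easy exit lies exactly along n0, so
    direction optimization has no advantage to find."""
    return FunnelParams(
        well_depth=30.0,
        well_width=0.3,
        background_barrier=100.0,
        barrier_radius=0.8,
        barrier_width=0.15,
        guide_amp=35.0,
        channels=(
            Channel(direction=(0.0, 0.0, 1.0), barrier_height=8.0,
                    width=0.3, guide_open=True),
        ),
    )


def family_funnel() -> FunnelParams:
    """Family geometry: depth-dominated rupture, small member jitter.

    A narrow well (0.10 nm) makes the well-escape force -- which scales
    with well depth, the binding-energy analogue -- the dominant,
    depth-graded contribution to the rupture force, while a single open
    low-barrier exit channel keeps the post-escape transit cheap and
    direction-independent.  Small seeded jitters on the channel axis and
    barrier make members structurally similar but not identical.
    """
    return FunnelParams(
        well_depth=40.0,
        well_width=0.10,
        background_barrier=60.0,
        barrier_radius=0.8,
        barrier_width=0.15,
        guide_amp=20.0,
        channels=(
            Channel(direction=(0.0, 0.0, 1.0), barrier_height=10.0,
                    width=0.4, guide_open=True),
        ),
        direction_jitter=0.03,
        barrier_jitter=0.03,
    )


def standard_family_spec(n_members: int = 8, depth_range=(20.0, 60.0),
                         seed: int = 0) -> FamilySpec:
    return FamilySpec(n_members=n_members, depth_range=tuple(depth_range),
                      shared_geometry=family_funnel(), seed=seed)


def standard_controller(**overrides) -> ControllerConfig:
    """The default pulling controller: k = 200 kJ/mol/nm^2, v = 0.002
    nm/ps, T = 1 ps, t0 = 5 ps, f0 = 250 pN, 0.6 nm cut-off separation."""
    return dataclasses.replace(ControllerConfig(), **overrides)


def rate_study_system(depth: float = 45.0):
    """Landscape + controller for the pulling-rate experiment.

    At the default friction the surrogate ligand is quasi-static at both
    standard pulling speeds, so rupture forces barely depend on v.  The
    rate study therefore runs a depth-dominated family-style funnel with a
    high-friction engine (gamma = 2000 kJ/mol/nm^2*ps), placing the pulled
    transport in the drag-sensitive regime where -- as in solvated
    all-atom systems -- faster pulling measurably raises the rupture
    force.  Returns ``(FunnelLandscape, ControllerConfig)``.
    """
    params = dataclasses.replace(family_funnel(), well_depth=depth,
                                 direction_jitter=0.0, barrier_jitter=0.0)
    cfg = standard_controller(engine=EngineParams(friction=2000.0))
    return make_funnel_landscape(params), cfg


# -- YAML serialization ------------------------------------------------------

def _landscape_to_dict(p: FunnelParams) -> dict:
    d = dataclasses.asdict(p)
    d["channels"] = [dataclasses.asdict(c) for c in p.channels]
    for c in d["channels"]:
        c["direction"] = list(c["direction"])
    d["well_center"] = list(p.well_center)
    return d


def _landscape_from_dict(d: dict) -> FunnelParams:
    d = dict(d)
    d["channels"] = tuple(
        Channel(tuple(c["direction"]), c["barrier_height"], c.get("width", 0.2),
                c.get("guide_open", False))
        for c in d.get("channels", ())
    )
    if "well_center" in d:
        d["well_center"] = tuple(d["well_center"])
    return FunnelParams(**d)


def _controller_to_dict(c: ControllerConfig) -> dict:
    d = dataclasses.asdict(c)
    d.pop("f0")
    d["f0_pN"] = to_pN(c.f0)
    d["n0"] = list(c.n0)
    d["engine"] = dataclasses.asdict(c.engine)
    return d


def _controller_from_dict(d: dict) -> ControllerConfig:
    d = dict(d)
    if "f0_pN" in d:
        d["f0"] = from_pN(d.pop("f0_pN"))
    if "engine" in d:
        d["engine"] = EngineParams(**d["engine"])
    if "n0" in d:
        d["n0"] = tuple(d["n0"])
    return ControllerConfig(**d)


def load_config(path):
    """Read a YAML config; returns a dict with keys ``landscape``
    (FunnelParams), ``controller`` (ControllerConfig), ``ga`` (GAConfig)
    and ``experiment`` (plain dict).  Missing sections fall back to the
    package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {
        "landscape": _landscape_from_dict(raw["landscape"])
        if "landscape" in raw else standard_funnel(),
        "controller": _controller_from_dict(raw.get("controller", {})),
        "ga": GAConfig(**{k: tuple(v) if k == "entropy_weights" else v
                          for k, v in raw.get("ga", {}).items()}),
        "experiment": raw.get("experiment", {}),
    }
    return out


def save_config(path, landscape: FunnelParams = None,
                controller: ControllerConfig = None,
                ga: GAConfig = None, experiment: dict = None):
    doc = {}
    if landscape is not None:
        doc["landscape"] = _landscape_to_dict(landscape)
    if controller is not None:
        doc["controller"] = _controller_to_dict(controller)
    if ga is not None:
        d = dataclasses.asdict(ga)
        d["entropy_weights"] = list(ga.entropy_weights)
        doc["ga"] = d
    if experiment is not None:
        doc["experiment"] = experiment
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
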