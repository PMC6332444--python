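"""Experiment orchestration: sweeps, family runs, correlation analysis.

These functions reproduce, on synthetic funnel systems, the experimental
designs used to characterize direction-optimized pulling: sweeping the
trigger cut-off force f0, sweeping the pulling rate v, pairing
conventional against self-adaptive runs, and correlating mean rupture
forces against the members' reference binding energies across a landscape
family.

Every experiment is deterministic given its spec/seed arguments: per-run
seeds are derived with ``numpy.random.SeedSequence`` from the experiment
seed and the run's indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .ga import GAConfig
from .landscape import FamilySpec, FunnelLandscape, make_family
from .optimizer import ControllerConfig, run_sasmd
from .steering import run_csmd

__all__ = ["SweepSpec", "FamilyRunResult", "CorrelationReport",
           "ModeComparison", "run_sweep", "run_family", "pearson",
           "correlation_report", "compare_modes", "derive_seed"]


def derive_seed(*keys) -> int:
    """Stable 31-bit seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class SweepSpec:
    """One-variable sweep over SA-SMD runs.

    ``variable``: "cutoff_force" (values in pN) or "pulling_rate"
    (values in nm/ps).  Each value is run with ``n_seeds`` independent
    seeds derived from ``base_seed``.
    """

    variable: str
    values: tuple
    n_seeds: int = 5
    base_config: ControllerConfig = field(default_factory=ControllerConfig)
    base_seed: int = 0

    def __post_init__(self):
        if self.variable not in ("cutoff_force", "pulling_rate"):
            raise ValueError("variable must be 'cutoff_force' or 'pulling_rate'")
        if len(self.values) < 2:
            raise ValueError("a sweep needs at least 2 values")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        object.__setattr__(self, "values", tuple(self.values))


@dataclass
class FamilyRunResult:
    """Per-member rupture-force statistics over repeated SA-SMD runs."""

    table: pd.DataFrame  # member_id, reference_energy, mean/-sem rupture, n_runs
    runs: pd.DataFrame  # every individual run


@dataclass
class CorrelationReport:
    r: float
    slope: float  # pN per (kJ/mol of reference energy)
    intercept: float
    n: int
    table: pd.DataFrame
    summary: str

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


@dataclass
class ModeComparison:
    table: pd.DataFrame  # one row per seed: paired C-SMD / SA-SMD results
    mean_csmd_pN: float
    mean_sasmd_pN: float
    results: dict  # seed -> (csmd RuptureResult, sasmd RuptureResult, records)


def _config_for(spec: SweepSpec, value):
    if spec.variable == "cutoff_force":
        return spec.base_config.with_f0_pN(float(value))
    import dataclasses
    return dataclasses.replace(spec.base_config, v=float(value))


def run_sweep(spec: SweepSpec, l: FunnelLandscape,
              ga_cfg: GAConfig | None = None) -> pd.DataFrame:
    """SA-SMD runs over each (value, seed) pair, plus -- for cut-off-force
    sweeps -- conventional-SMD reference rows labelled value ``inf`` (the
    no-optimization limit of the trigger).

    Individual run failures are recorded (``error`` column) and the sweep
    continues.
    """
    rows = []
    values = list(spec.values)
    if spec.variable == "cutoff_force":
        values = values + [math.inf]
    for vi, value in enumerate(values):
        cfg = _config_for(spec, value) if math.isfinite(value) else spec.base_config
        for si in range(spec.n_seeds):
            seed = derive_seed(spec.base_seed, vi if math.isfinite(value) else 10**6, si)
            row = {"variable": spec.variable, "value": value, "seed": seed,
                   "mode": "sasmd" if math.isfinite(value) else "csmd"}
            try:
                if math.isfinite(value):
                    result, records = run_sasmd(l, cfg, ga_cfg, seed)
                else:
                    result = run_csmd(l, cfg, seed)
                row.update(rupture_force_pN=result.rupture_force_pN,
                           rupture_time_ps=result.rupture_time,
                           end_time_ps=result.end_time,
                           n_switches=result.n_direction_switches,
                           unbound=result.unbound, error="")
            except Exception as err:  # keep sweeping past individual failures
                row.update(rupture_force_pN=np.nan, rupture_time_ps=np.nan,
                           end_time_ps=np.nan, n_switches=-1, unbound=False,
                           error=str(err))
            rows.append(row)
    return pd.DataFrame(rows)


def run_family(fam: FamilySpec, cfg: ControllerConfig, n_repeats: int = 4,
               seeds=None, ga_cfg: GAConfig | None = None) -> FamilyRunResult:
    """``n_repeats`` independent SA-SMD runs per family member.

    ``seeds`` (one per repeat, defaults to ``0..n_repeats-1``) combine with
    the member index into per-run seeds, so the whole experiment is
    deterministic per seed list.  The standard error of the mean rupture
    force uses the n-1 sample standard deviation and is reported as NaN for
    a single repeat.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    family = make_family(fam)
    run_rows, member_rows = [], []
    for mi, (member_id, land, ref_energy) in enumerate(family):
        forces = []
        for rep, rep_seed in enumerate(seeds):
            run_seed = derive_seed(rep_seed, mi)
            try:
                result, _ = run_sasmd(land, cfg, ga_cfg, run_seed)
                forces.append(result.rupture_force_pN)
                run_rows.append({"member_id": member_id, "repeat": rep,
                                 "seed": run_seed,
                                 "rupture_force_pN": result.rupture_force_pN,
                                 "end_time_ps": result.end_time,
                                 "n_switches": result.n_direction_switches,
                                 "unbound": result.unbound, "error": ""})
            except Exception as err:
                run_rows.append({"member_id": member_id, "repeat": rep,
                                 "seed": run_seed, "rupture_force_pN": np.nan,
                                 "end_time_ps": np.nan, "n_switches": -1,
                                 "unbound": False, "error": str(err)})
        forces = np.asarray(forces, dtype=float)
        n_ok = len(forces)
        sem = (forces.std(ddof=1) / math.sqrt(n_ok)) if n_ok >= 2 else np.nan
        member_rows.append({
            "member_id": member_id,
            "well_depth": land.well_depth,
            "reference_energy": ref_energy,
            "mean_rupture_force_pN": forces.mean() if n_ok else np.nan,
            "std_error_pN": sem,
            "n_runs": n_ok,
        })
    return FamilyRunResult(pd.DataFrame(member_rows), pd.DataFrame(run_rows))


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def correlation_report(fr: FamilyRunResult) -> CorrelationReport:
    """Correlation of mean rupture force against reference binding energy.

    Reference energies are negative (more negative = stronger binding), so
    a family in which deeper wells give larger rupture forces shows a
    negative slope against reference energy.
    """
    t = fr.table
    if len(t) < 3:
        raise ValueError("need at least 3 family members")
    x = t["reference_energy"].to_numpy()
    y = t["mean_rupture_force_pN"].to_numpy()
    r = pearson(x, y)
    fit = scipy.stats.linregress(x, y)
    summary = (
        f"family of {len(t)} members: Pearson r = {r:.4f} between mean "
        f"rupture force (pN) and reference binding energy (kJ/mol, negative "
        f"= stronger); fit slope {fit.slope:.3f} pN/(kJ/mol), intercept "
        f"{fit.intercept:.1f} pN. Stronger binders rupture harder when the "
        f"slope is negative."
    )
    return CorrelationReport(r=r, slope=float(fit.slope),
                             intercept=float(fit.intercept), n=len(t),
                             table=t.copy(), summary=summary)


def compare_modes(l: FunnelLandscape, cfg: ControllerConfig, seeds,
                  ga_cfg: GAConfig | None = None) -> ModeComparison:
    """Paired conventional vs self-adaptive runs at identical seeds."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    rows, results = [], {}
    for seed in seeds:
        c = run_csmd(l, cfg, seed)
        s, records = run_sasmd(l, cfg, ga_cfg, seed)
        results[seed] = (c, s, records)
        rows.append({
            "seed": seed,
            "csmd_rupture_pN": c.rupture_force_pN,
            "sasmd_rupture_pN": s.rupture_force_pN,
            "csmd_end_ps": c.end_time,
            "sasmd_end_ps": s.end_time,
            "n_switches": s.n_direction_switches,
            "csmd_unbound": c.unbound,
            "sasmd_unbound": s.unbound,
        })
    table = pd.DataFrame(rows)
    return ModeComparison(
        table=table,
        mean_csmd_pN=float(table["csmd_rupture_pN"].mean()),
        mean_sasmd_pN=float(table["sasmd_rupture_pN"].mean()),
        results=results,
    )
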