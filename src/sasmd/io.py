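"""File output: XYZ trajectories, force-profile / run-ledger / log CSVs."""

from __future__ import annotations

import csv
import os

import numpy as np
import pandas as pd

from .steering import ForceProfile, RuptureResult
from .units import to_pN

__all__ = ["write_xyz", "write_trajectory_csv", "write_force_profile_csv",
           "append_run_ledger", "write_optimization_log",
           "write_family_manifest"]


def write_xyz(path, trajectory: np.ndarray, label: str = "L"):
    """One pseudo-atom per frame; the comment line carries the time in ps."""
    with open(path, "w") as fh:
        for t, x, y, z in trajectory:
            fh.write(f"1\nt= {t:.4f} ps\n{label} {x:.6f} {y:.6f} {z:.6f}\n")


def write_trajectory_csv(path, trajectory: np.ndarray):
    pd.DataFrame(trajectory, columns=["t", "x", "y", "z"]).to_csv(path, index=False)


def write_force_profile_csv(path, profile: ForceProfile):
    df = pd.DataFrame({
        "t_mid_ps": profile.t_mid,
        "f_avg_kJ_mol_nm": profile.f_avg,
        "f_avg_pN": to_pN(1.0) * profile.f_avg,
    })
    df.to_csv(path, index=False)


_LEDGER_FIELDS = ["run_id", "mode", "seed", "v", "f0_pN", "rupture_force_pN",
                  "rupture_time_ps", "end_time_ps", "n_switches", "unbound"]


def append_run_ledger(path, run_id: str, result: RuptureResult, cfg):
    """Append one summary line per run to a runs.csv ledger."""
    new = not os.path.exists(path)
    with open(path, "a", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_LEDGER_FIELDS)
        if new:
            w.writeheader()
        w.writerow({
            "run_id": run_id,
            "mode": result.mode,
            "seed": result.seed,
            "v": cfg.v,
            "f0_pN": cfg.f0_pN,
            "rupture_force_pN": f"{result.rupture_force_pN:.3f}",
            "rupture_time_ps": f"{result.rupture_time:.3f}",
            "end_time_ps": f"{result.end_time:.3f}",
            "n_switches": result.n_direction_switches,
            "unbound": result.unbound,
        })


def write_optimization_log(path, records):
    rows = [{
        "t_opt_ps": r.t_opt,
        "theta_rad": r.chosen.theta,
        "phi_rad": r.chosen.phi,
        "objective_pN": to_pN(r.objective_value),
        "n_evals": r.n_evaluations,
    } for r in records]
    pd.DataFrame(rows, columns=["t_opt_ps", "theta_rad", "phi_rad",
                                "objective_pN", "n_evals"]).to_csv(path, index=False)


def write_family_manifest(path, family):
    """CSV manifest of a landscape family: member_id, well_depth,
    reference_energy."""
    rows = [{"member_id": mid, "well_depth": land.well_depth,
             "reference_energy": ref} for mid, land, ref in family]
    pd.DataFrame(rows).to_csv(path, index=False)
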