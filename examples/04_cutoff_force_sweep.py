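"""Sweep the trigger cut-off force f0.

Lower f0 means optimizations fire more readily: the switch count grows and
the rupture force falls, flattening once the trigger threshold itself
limits the measured maximum.  The 'inf' row is the conventional-pull
reference (the trigger never fires).
"""
import numpy as np
import sasmd
from sasmd.analysis import SweepSpec, run_sweep

spec = SweepSpec("cutoff_force", (350.0, 300.0, 250.0), n_seeds=2,
                 base_config=sasmd.standard_controller(), base_seed=0)
table = run_sweep(spec, sasmd.standard_landscape())
summary = table.groupby("value")[["rupture_force_pN", "n_switches"]].mean()
print(summary.to_string())
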