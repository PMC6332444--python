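"""Rupture force vs binding depth across a synthetic complex family.

Family members share geometry and differ in well depth (the stand-in for
experimental binding free energy).  Four self-adaptive pulls per member;
the mean rupture force should rank the members by depth.
"""
import sasmd
from sasmd.analysis import correlation_report, run_family

fam = sasmd.standard_family_spec(n_members=5, seed=0)
fr = run_family(fam, sasmd.standard_controller(), n_repeats=2)
rep = correlation_report(fr)
print(fr.table.to_string(index=False))
print()
print(rep.summary)
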