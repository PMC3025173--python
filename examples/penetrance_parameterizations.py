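"""Penetrance tables and the algebra between parameterization dialects.

Builds the worked child+maternal penetrance table, solves it under both
baseline conventions, and shows that an incompatibility-style (MFG)
parameterization induces exactly the same table as the default
interaction-style one.
"""

from famlik import (DialectParameters, RiskParameters,
                    build_penetrance_table, to_default_dialect, to_dialect)
from famlik.params import solve_child_maternal

params = RiskParameters(r1=2, r2=4, s1=3, s2=4, baseline_alpha=0.05)
table = build_penetrance_table(params, weight_maternal=0.7)

print("7-cell penetrance table (rows: mother genotype, cols: child genotype)")
for (gm, gc), pen in table.collapsed_view.items():
    print(f"  mother {gm}, child {gc}: {pen:.2f}")

for baseline in ("11", "22"):
    alpha, r1, r2, s1, s2 = solve_child_maternal(table.collapsed_view,
                                                 baseline)
    print(f"baseline ({baseline},{baseline}): alpha={alpha:.2f} R1={r1} "
          f"R2={r2} S1={s1} S2={s2}")
# The same table admits both solutions: effects > 1 relative to the low-risk
# baseline become effects < 1 relative to the high-risk baseline.

mfg = DialectParameters("mfg_1b", {"rho1": 1, "rho2": 1, "eta1": 1,
                                   "eta2": 1, "mu0": 4, "mu2": 1})
default, notes = to_default_dialect(mfg)
print(f"\nMFG incompatibility mu0=4 in default dialect: "
      f"R1={default.r1}, gamma11={default.g11} ({notes[0]})")
round_trip = to_dialect(default, "mfg_1b")
print(f"round trip recovers mu0 = {round_trip.values['mu0']:.1f}")
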