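"""A small replicated simulation study comparing analysis methods.

Compares the logistic-regression comparator (method 0) with the multinomial
model using parents of controls (method 4) on a scenario with child and
maternal effects: bias of the log relative-risk estimates, power of the
joint test, and the total estimated standard error.
"""

from famlik.evaluate import run_study
from famlik.simulate import scenario_table

scenario = scenario_table()["C"]

for method in ("0", "4"):
    res = run_study(scenario, method, n_per_structure=500, n_reps=50,
                    base_seed=2026)
    print(f"\nmethod {method}: {res.n_reps} replicates "
          f"({res.n_failed} flagged)")
    print(res.params[["parameter", "true_log", "mean_log_est",
                      "mean_est_se"]].to_string(index=False))
    rej = res.rejection("joint", 0.05)
    print(f"joint-test power at 0.05: {rej:.2f}; "
          f"mean total SE: {float(res.total_se.mean_total_se.iloc[0]):.3f}")
# The multinomial model exploits Mendelian inheritance and the control
# mating-type information, so its total SE is smaller and its power higher
# than logistic regression on the same data.
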