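"""Why case-control patterns are ambiguous: apparent genotype relative risks.

Several distinct mechanisms (a maternal genotype effect, maternal or paternal
imprinting, or the child's own genotype) can produce the same apparent
(RR12, RR22) = (1.5, 2) pattern in cases vs. controls.  Comparing mothers of
cases vs. mothers of controls separates them.
"""

from famlik import RiskParameters, apparent_grr
from famlik.grr import grr_power, population_prevalence

models = {
    "child genotype (R1=1.5, R2=2)": RiskParameters(r1=1.5, r2=2.0,
                                                    baseline_alpha=0.05),
    "maternal genotype (S1=2, S2=4)": RiskParameters(s1=2, s2=4,
                                                     baseline_alpha=0.05),
    "maternal imprinting (Im=2)": RiskParameters(im=2, baseline_alpha=0.05),
    "paternal imprinting (Ip=2)": RiskParameters(ip=2, baseline_alpha=0.05),
}

print(f"{'model':36s} {'cases vs controls':>20s} {'mothers vs mothers':>20s}")
for name, params in models.items():
    cc = apparent_grr(params, 0.3, "cases_vs_controls")
    mm = apparent_grr(params, 0.3, "mothers_vs_mothers")
    print(f"{name:36s} ({cc[0]:.2f}, {cc[1]:.2f})".ljust(60)
          + f"({mm[0]:.2f}, {mm[1]:.2f})")
# All four mechanisms give (1.50, 2.00) in the children; only the mothers'
# comparison distinguishes them (maternal effect: amplified; maternal
# imprinting: identical; paternal imprinting: flat at 1).

p = models["maternal genotype (S1=2, S2=4)"]
k = population_prevalence(p, 0.3)
power_cc = grr_power(*apparent_grr(p, 0.3), 0.3, k, 500, 500, 0.05)
power_mm = grr_power(*apparent_grr(p, 0.3, "mothers_vs_mothers"),
                     0.3, k, 500, 500, 0.05)
print(f"\n2-df genotype-test power, 500 vs 500 at alpha 0.05:")
print(f"  analyzing children: {power_cc:.2f}; analyzing mothers: {power_mm:.2f}")
# Testing the individuals in whom the effect actually operates (here the
# mothers) is substantially more powerful.
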