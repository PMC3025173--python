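"""Apparent genotype relative risks and a case-control power approximation.

Under a generating model with maternal, imprinting or interaction effects, a
naive case-control comparison of child (or maternal) genotypes estimates
"apparent" genotype relative risks that are composites of the true factors.
These are computed here by exact enumeration of the joint distribution of
(g_m, g_f, ordered g_c) under HWE and random mating — never from transcribed
closed forms.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from .params import RiskParameters

__all__ = ["apparent_grr", "joint_genotype_disease", "grr_power", "population_prevalence"]


def _hwe_geno(a2: float) -> dict[int, float]:
    q = 1.0 - a2
    return {0: q * q, 1: 2 * a2 * q, 2: a2 * a2}


def joint_genotype_disease(params: RiskParameters, a2: float):
    """Enumerate the joint family-configuration/disease distribution.

    Yields ``(g_m, g_f, child_mat, child_pat, p_config, penetrance)`` over all
    parental genotypes (HWE + random mating) and Mendelian child outcomes;
    ``child_mat``/``child_pat`` are risk-allele indicators per origin.
    """
    yield from _enumerate(params, a2)


def _enumerate(params: RiskParameters, a2: float):
    alpha = params.require_alpha()
    geno = _hwe_geno(a2)
    for g_m, g_f in itertools.product((0, 1, 2), repeat=2):
        p_par = geno[g_m] * geno[g_f]
        for c_mat in (0, 1):
            p_mat = (g_m / 2) if c_mat else (1 - g_m / 2)
            if p_mat == 0:
                continue
            for c_pat in (0, 1):
                p_pat = (g_f / 2) if c_pat else (1 - g_f / 2)
                if p_pat == 0:
                    continue
                gm_s = ("11", "12", "22")[g_m]
                gc_s = ("2" if c_mat else "1") + ("2" if c_pat else "1")
                pen = alpha * params.risk_product(gm_s, gc_s)
                if pen > 1.0 + 1e-12:
                    from .params import PenetranceOverflowError
                    raise PenetranceOverflowError(
                        f"penetrance {pen:.4g} > 1 in cell (g_m={gm_s}, g_c={gc_s})")
                yield g_m, g_f, c_mat, c_pat, p_par * p_mat * p_pat, pen


def population_prevalence(params: RiskParameters, a2: float) -> float:
    """Disease prevalence K under HWE and random mating, by enumeration."""
    return sum(p * pen for *_, p, pen in _enumerate(params, a2))


def apparent_grr(params: RiskParameters, a2: float,
                 analysis: str = "cases_vs_controls") -> tuple[float, float]:
    """Apparent (RR12, RR22) from a naive genotype comparison.

    ``cases_vs_controls`` conditions on the child's unordered genotype;
    ``mothers_vs_mothers`` on the mother's genotype (mothers of cases vs.
    mothers of controls).  Ratios are relative to the homozygous low-risk
    genotype.
    """
    if analysis not in ("cases_vs_controls", "mothers_vs_mothers"):
        raise ValueError(f"unknown analysis {analysis!r}")
    if params.baseline_alpha is None:
        params = RiskParameters(baseline_alpha=0.01, **params.factors())
    p_dis = np.zeros(3)   # joint P(genotype, dis)
    p_g = np.zeros(3)
    for g_m, g_f, c_mat, c_pat, p, pen in _enumerate(params, a2):
        g = g_m if analysis == "mothers_vs_mothers" else c_mat + c_pat
        p_dis[g] += p * pen
        p_g[g] += p
    risk = p_dis / p_g   # P(dis | genotype)
    return float(risk[1] / risk[0]), float(risk[2] / risk[0])


def grr_power(rr12: float, rr22: float, a2: float, prevalence: float,
              n_case: int, n_control: int, alpha_level: float = 0.05) -> float:
    """Power of the 2-df Pearson genotype test in a case-control sample.

    Controls are population based (of unknown disease status).  The
    noncentrality is the Pearson statistic evaluated at the expected genotype
    frequencies; this approximates dedicated genetic power calculators.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    q = 1.0 - a2
    f = np.array([q * q, 2 * a2 * q, a2 * a2])
    rr = np.array([1.0, rr12, rr22])
    baseline = prevalence / float(f @ rr)
    pen = baseline * rr
    if (pen <= 0).any() or (pen > 1).any():
        raise ValueError("implied penetrances outside (0, 1]")
    p_case = f * pen / prevalence
    p_ctrl = f
    # expected 2x3 table and its Pearson statistic = noncentrality
    n = n_case + n_control
    exp_case = n_case * p_case
    exp_ctrl = n_control * p_ctrl
    col = exp_case + exp_ctrl
    lam = 0.0
    for j in range(3):
        e_case = n_case * col[j] / n
        e_ctrl = n_control * col[j] / n
        lam += (exp_case[j] - e_case) ** 2 / e_case
        lam += (exp_ctrl[j] - e_ctrl) ** 2 / e_ctrl
    crit = stats.chi2.ppf(1.0 - alpha_level, df=2)
    return float(stats.ncx2.sf(crit, df=2, nc=lam))
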