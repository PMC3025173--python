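"""Synthetic family data under the multiplicative penetrance model.

Families are drawn under HWE and random mating (or a mixture of
subpopulations), the child's alleles by Mendelian transmission with recorded
parental origin, and case-side structures are ascertained by rejection
sampling: a family enters the sample with probability equal to the child's
ordered-origin penetrance.  Control-side structures are population samples
without disease conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import RiskParameters
from .tables import (CASE_STRUCTURES, CONTROL_STRUCTURES, StructureCounts,
                     _ORDERED, collapse_matrix)

__all__ = ["Scenario", "Subpopulation", "scenario_table", "simulate_structure",
           "simulate_stratified", "SCENARIO_NAMES"]


@dataclass(frozen=True)
class Subpopulation:
    proportion: float
    a2: float
    baseline_alpha: float


@dataclass(frozen=True)
class Scenario:
    """Generating conditions: allele frequency, baseline risk, risk factors."""

    name: str
    a2: float
    baseline_alpha: float
    params: RiskParameters
    stratification: tuple[Subpopulation, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "params",
                           replace(self.params, baseline_alpha=self.baseline_alpha))
        if not 0 < self.a2 < 1:
            raise ValueError("a2 must lie in (0, 1)")
        if self.stratification is not None:
            tot = sum(s.proportion for s in self.stratification)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("stratification proportions must sum to 1")
            for s in self.stratification:
                p = replace(self.params, baseline_alpha=s.baseline_alpha)
                _max_penetrance(p)  # validates <= 1
        _max_penetrance(self.params)


def _max_penetrance(params: RiskParameters) -> float:
    from .params import ORDERED_CELLS
    alpha = params.require_alpha()
    mx = max(alpha * params.risk_product(gm, gc) for gm, gc in ORDERED_CELLS)
    if mx > 1.0 + 1e-12:
        raise ValueError(f"maximum cell penetrance {mx:.4g} exceeds 1")
    return mx


# The ten standard simulation scenarios: a2 = 0.3 and baseline risk 0.1
# throughout; (R1, R2) = (1.5, 2.25) multiplicative child effects, matching
# maternal effects, imprinting factor 1.8, interactions 0.5 where present.
_SCENARIO_FACTORS = {
    "A": dict(r1=1.5, r2=2.25),
    "B": dict(s1=1.5, s2=2.25),
    "C": dict(r1=1.5, r2=2.25, s1=1.5, s2=2.25),
    "D": dict(r1=1.5, r2=2.25, im=1.8),
    "E": dict(r1=1.5, r2=2.25, ip=1.8),
    "F": dict(r1=1.5, r2=2.25, s1=1.5, s2=2.25, im=1.8),
    "G": dict(r1=1.5, r2=2.25, s1=1.5, s2=2.25, ip=1.8),
    "H": dict(r1=1.5, r2=2.25, s1=1.5, s2=2.25, g11=0.5, g22=0.5),
    "I": dict(r1=1.5, r2=2.25, s1=1.5, s2=2.25, im=1.8, g11=0.5),
    "J": dict(r1=1.5, r2=2.25, s1=1.5, s2=2.25, ip=1.8, g11=0.5),
}

SCENARIO_NAMES = tuple(_SCENARIO_FACTORS) + ("null",)


def scenario_table() -> dict[str, Scenario]:
    """The built-in simulation scenarios A-J (plus the global null)."""
    out = {}
    for name, factors in _SCENARIO_FACTORS.items():
        out[name] = Scenario(name=name, a2=0.3, baseline_alpha=0.1,
                             params=RiskParameters(**factors))
    out["null"] = Scenario(name="null", a2=0.3, baseline_alpha=0.1,
                           params=RiskParameters())
    return out


def _draw_families(n: int, a2: float, rng: np.random.Generator):
    """Draw n families; returns (g_m, g_f, c_mat, c_pat) risk-allele arrays."""
    g_m = rng.binomial(2, a2, size=n)
    g_f = rng.binomial(2, a2, size=n)
    c_mat = rng.random(n) < g_m / 2.0
    c_pat = rng.random(n) < g_f / 2.0
    return g_m, g_f, c_mat.astype(np.int8), c_pat.astype(np.int8)


# lookup (g_m, g_f, c_mat, c_pat) -> ordered-cell index; Mendelian-impossible
# combinations keep -1 and can never be produced by the sampler
_CELL_LUT = np.full((3, 3, 2, 2), -1, dtype=np.int64)
for _k, _c in enumerate(_ORDERED):
    _CELL_LUT[_c[1], _c[2], _c[3], _c[4]] = _k


def _ordered_cell_index(g_m, g_f, c_mat, c_pat) -> np.ndarray:
    return _CELL_LUT[g_m, g_f, c_mat, c_pat]


def _penetrances_by_cell(params: RiskParameters) -> np.ndarray:
    alpha = params.require_alpha()
    out = np.empty(16)
    for k, (_lab, gm, _gf, cm, cp, _mt) in enumerate(_ORDERED):
        gm_s = ("11", "12", "22")[gm]
        gc_s = ("2" if cm else "1") + ("2" if cp else "1")
        out[k] = alpha * params.risk_product(gm_s, gc_s)
    return out


def _sample_case_cells(scenario: Scenario, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Ordered-cell counts (length 16) for n ascertained case families."""
    pen = _penetrances_by_cell(scenario.params)
    counts16 = np.zeros(16, dtype=np.int64)
    remaining = n
    while remaining > 0:
        batch = max(256, int(remaining / max(pen.mean(), 1e-3)))
        g_m, g_f, c_mat, c_pat = _draw_families(batch, scenario.a2, rng)
        cells = _ordered_cell_index(g_m, g_f, c_mat, c_pat)
        accept = rng.random(batch) < pen[cells]
        kept = cells[accept][:remaining]
        counts16 += np.bincount(kept, minlength=16)
        remaining = n - int(counts16.sum())
    return counts16


def _sample_control_cells(a2: float, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    g_m, g_f, c_mat, c_pat = _draw_families(n, a2, rng)
    cells = _ordered_cell_index(g_m, g_f, c_mat, c_pat)
    return np.bincount(cells, minlength=16)


def simulate_structure(structure_kind: str, scenario: Scenario, n: int,
                       rng: np.random.Generator,
                       snp_id: str = "snp") -> StructureCounts:
    """Simulate observed counts for one data structure.

    Case-side structures are conditioned on an affected child by rejection
    sampling; control-side structures are unconditioned population draws.
    Counts follow the structure's frozen cell ordering.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scenario.stratification is not None:
        return simulate_stratified(scenario, structure_kind, n, rng, snp_id)
    if structure_kind in CASE_STRUCTURES:
        counts16 = _sample_case_cells(scenario, n, rng)
    elif structure_kind in CONTROL_STRUCTURES:
        counts16 = _sample_control_cells(scenario.a2, n, rng)
    else:
        raise ValueError(f"unknown structure_kind {structure_kind!r}")
    mat = collapse_matrix(structure_kind)
    counts = (mat @ counts16).astype(np.int64)
    return StructureCounts(structure_kind=structure_kind, counts=counts,
                           snp_id=snp_id)


def simulate_stratified(scenario: Scenario, structure_kind: str, n: int,
                        rng: np.random.Generator,
                        snp_id: str = "snp") -> StructureCounts:
    """Simulate from a mixture of subpopulations (no labels in the output).

    Each family's subpopulation is drawn by the mixing proportions; within a
    subpopulation, sampling proceeds exactly as in :func:`simulate_structure`
    with that stratum's allele frequency and baseline risk.
    """
    if scenario.stratification is None:
        raise ValueError("scenario has no stratification")
    strata = scenario.stratification
    props = np.array([s.proportion for s in strata])
    a2s = np.array([s.a2 for s in strata])
    # per-stratum ordered-cell penetrances (baseline differs by stratum)
    pens = np.vstack([
        _penetrances_by_cell(replace(scenario.params,
                                     baseline_alpha=s.baseline_alpha))
        for s in strata])
    is_case = structure_kind in CASE_STRUCTURES
    if not is_case and structure_kind not in CONTROL_STRUCTURES:
        raise ValueError(f"unknown structure_kind {structure_kind!r}")
    counts16 = np.zeros(16, dtype=np.int64)
    remaining = n
    while remaining > 0:
        batch = (max(256, int(remaining / max(pens.mean(), 1e-3)))
                 if is_case else remaining)
        k = rng.choice(len(strata), p=props, size=batch)
        a2 = a2s[k]
        g_m = rng.binomial(2, a2)
        g_f = rng.binomial(2, a2)
        c_mat = (rng.random(batch) < g_m / 2.0).astype(np.int8)
        c_pat = (rng.random(batch) < g_f / 2.0).astype(np.int8)
        cells = _ordered_cell_index(g_m, g_f, c_mat, c_pat)
        if is_case:
            # ascertainment across strata happens jointly: higher-risk
            # strata are over-represented among accepted case families
            accept = rng.random(batch) < pens[k, cells]
            cells = cells[accept]
        kept = cells[:remaining]
        counts16 += np.bincount(kept, minlength=16)
        remaining = n - int(counts16.sum())
    mat = collapse_matrix(structure_kind)
    counts = (mat @ counts16).astype(np.int64)
    return StructureCounts(structure_kind=structure_kind, counts=counts,
                           snp_id=snp_id)
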