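"""Multinomial cell-probability tables for family data structures.

A case/parent trio with an affected child has 15 observable genotype
combinations (16 ordered-origin cells; the double-heterozygote trio cell is
the sum of the two parental-origin possibilities).  Conditional on the child
being affected, the probability of ordered cell ``k`` is

    P(cell k | dis) = risk_k * mu_{mt(k)} / Sigma

where ``risk_k`` is the product of relative-risk factors for the cell (the
baseline penetrance alpha cancels), ``mt(k)`` indexes the six exchangeable
parental mating types, and ``Sigma`` is the sum of the 16 raw weights.  The
``mu`` parameters absorb both the ordered parental-pair frequency and the
(constant within a mating type) Mendelian transmission factor; under HWE and
random mating they reduce to ``(p^4, p^3 q, p^2 q^2, p^2 q^2, p q^3, q^4)``
with ``p`` the risk-allele frequency and ``q = 1 - p``.

Every thinner observable structure (case/mother duo, case only, parents of
case, and the control-side structures, which use the null table) is a margin
of this 16-cell table, obtained by summing cells that share the observed
information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import RiskParameters

__all__ = [
    "NuisanceModel",
    "CellTable",
    "StructureCounts",
    "trio_cell_table",
    "duo_cell_table",
    "collapse_structure",
    "control_cell_table",
    "joint_loglik",
    "cell_labels",
    "prevalence",
    "hwe_mu",
    "STRUCTURE_KINDS",
    "CASE_STRUCTURES",
    "CONTROL_STRUCTURES",
    "REGIMES",
]

REGIMES = ("hwe_rm_fixed_af", "hwe_rm_free_af", "pae", "mating_symmetry")

# ---------------------------------------------------------------------------
# the 16 ordered trio cells, in the frozen row order of the trio table
# (label, g_m copies, g_f copies, child maternal-origin 2, paternal-origin 2,
#  mating type 1..6)
# ---------------------------------------------------------------------------
_ORDERED = (
    ("1", 2, 2, 1, 1, 1),
    ("2", 2, 1, 1, 1, 2),
    ("3", 2, 1, 1, 0, 2),
    ("4", 1, 2, 1, 1, 2),
    ("5", 1, 2, 0, 1, 2),
    ("6", 2, 0, 1, 0, 3),
    ("7", 0, 2, 0, 1, 3),
    ("8", 1, 1, 1, 1, 4),
    ("9a", 1, 1, 0, 1, 4),
    ("9b", 1, 1, 1, 0, 4),
    ("10", 1, 1, 0, 0, 4),
    ("11", 1, 0, 1, 0, 5),
    ("12", 1, 0, 0, 0, 5),
    ("13", 0, 1, 0, 1, 5),
    ("14", 0, 1, 0, 0, 5),
    ("15", 0, 0, 0, 0, 6),
)

_MT_INDEX = np.array([c[5] - 1 for c in _ORDERED])
#: number of ordered cells mapping to each mating type (parents-of-X weights)
_MT_MULTIPLICITY = np.bincount(_MT_INDEX, minlength=6).astype(float)

# exponent matrix: ordered-cell risk product = exp(E @ log(theta)),
# theta = (r1, r2, s1, s2, im, ip, g11, g12, g21, g22)
_E = np.zeros((16, 10))
for _k, (_lab, _gm, _gf, _cm, _cp, _mt) in enumerate(_ORDERED):
    _j = _cm + _cp
    if _j == 1:
        _E[_k, 0] = 1
    elif _j == 2:
        _E[_k, 1] = 1
    if _gm == 1:
        _E[_k, 2] = 1
    elif _gm == 2:
        _E[_k, 3] = 1
    _E[_k, 4] = _cm
    _E[_k, 5] = _cp
    if _gm and _j:
        _E[_k, 6 + 2 * (_gm - 1) + (_j - 1)] = 1

_GENO = ("11", "12", "22")
_MT_LABELS = ("22x22", "22x12", "22x11", "12x12", "12x11", "11x11")


def _margins():
    """Build label lists and collapse matrices (cells x 16) per structure."""
    out: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}

    def build(labels, keyfun):
        mat = np.zeros((len(labels), 16))
        index = {lab: i for i, lab in enumerate(labels)}
        for k, cell in enumerate(_ORDERED):
            mat[index[keyfun(cell)], k] = 1.0
        return tuple(labels), mat

    # trio: Table row order, double-het merged
    trio_labels = [str(i) for i in range(1, 16)]
    out["case_parent_trio"] = build(
        trio_labels, lambda c: c[0].rstrip("ab"))
    # duos: frozen order (22,22),(22,12),(12,22),(12,12),(12,11),(11,12),(11,11)
    duo_order = ["m22_c22", "m22_c12", "m12_c22", "m12_c12",
                 "m12_c11", "m11_c12", "m11_c11"]
    out["case_mother_duo"] = build(
        duo_order, lambda c: f"m{_GENO[c[1]]}_c{_GENO[c[3] + c[4]]}")
    duo_order_f = [lab.replace("m", "f") for lab in duo_order]
    out["case_father_duo"] = build(
        duo_order_f, lambda c: f"f{_GENO[c[2]]}_c{_GENO[c[3] + c[4]]}")
    out["case_only"] = build(
        [f"c{g}" for g in _GENO], lambda c: f"c{_GENO[c[3] + c[4]]}")
    out["mother_of_case"] = build(
        [f"m{g}" for g in _GENO], lambda c: f"m{_GENO[c[1]]}")
    out["father_of_case"] = build(
        [f"f{g}" for g in _GENO], lambda c: f"f{_GENO[c[2]]}")
    out["parents_of_case"] = build(list(_MT_LABELS), lambda c: _MT_LABELS[c[5] - 1])
    return out


_CASE_MARGINS = _margins()

#: control-side structures and the case-side margin they share (applied to
#: the null table, i.e. the population distribution)
_CONTROL_TO_MARGIN = {
    "control": "case_only",
    "mother_of_control": "mother_of_case",
    "father_of_control": "father_of_case",
    "parents_of_control": "parents_of_case",
    "control_mother_duo": "case_mother_duo",
    "control_father_duo": "case_father_duo",
}

CASE_STRUCTURES = tuple(_CASE_MARGINS)
CONTROL_STRUCTURES = tuple(_CONTROL_TO_MARGIN)
STRUCTURE_KINDS = CASE_STRUCTURES + CONTROL_STRUCTURES


def cell_labels(structure_kind: str) -> tuple[str, ...]:
    """Frozen cell ordering for a data structure (interchange contract)."""
    if structure_kind not in STRUCTURE_KINDS:
        raise ValueError(f"unknown structure_kind {structure_kind!r}")
    margin = _CONTROL_TO_MARGIN.get(structure_kind, structure_kind)
    return _CASE_MARGINS[margin][0]


def collapse_matrix(structure_kind: str) -> np.ndarray:
    margin = _CONTROL_TO_MARGIN.get(structure_kind, structure_kind)
    return _CASE_MARGINS[margin][1]


def hwe_mu(a2: float) -> np.ndarray:
    """Mating-type weights mu1..mu6 implied by HWE and random mating."""
    p, q = a2, 1.0 - a2
    return np.array([p ** 4, p ** 3 * q, p ** 2 * q ** 2,
                     p ** 2 * q ** 2, p * q ** 3, q ** 4])


@dataclass(frozen=True)
class NuisanceModel:
    """Nuisance (mating-type) model: allele frequency or free mu1..mu6.

    Under ``hwe_rm_fixed_af`` / ``hwe_rm_free_af`` the six mating-type
    weights are functions of the risk-allele frequency ``a2``.  Under
    ``mating_symmetry`` they are free positive parameters identified up to
    scale; ``pae`` (parental allelic exchangeability) additionally imposes
    mu3 = mu4.
    """

    regime: str
    a2: float | None = None
    mu: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; known: {REGIMES}")
        if self.regime.startswith("hwe"):
            if self.a2 is None or not (0.0 < self.a2 < 1.0):
                raise ValueError("hwe regimes require a2 in (0, 1)")
            if self.mu is not None:
                raise ValueError("hwe regimes take a2, not mu")
        else:
            if self.mu is None or len(self.mu) != 6:
                raise ValueError(f"regime {self.regime!r} requires six mu values")
            if self.a2 is not None:
                raise ValueError(f"regime {self.regime!r} takes mu, not a2")
            if any(m <= 0 for m in self.mu):
                raise ValueError("mu values must be strictly positive")
            if self.regime == "pae" and not math.isclose(
                    self.mu[2], self.mu[3], rel_tol=1e-9):
                raise ValueError("pae regime requires mu3 == mu4")

    def mu_values(self) -> np.ndarray:
        if self.regime.startswith("hwe"):
            return hwe_mu(self.a2)
        return np.asarray(self.mu, dtype=float)

    def normalized(self) -> "NuisanceModel":
        """Rescale mu so the implied null trio table sums to 1."""
        if self.regime.startswith("hwe"):
            return self
        mu = self.mu_values()
        scale = float(mu @ _MT_MULTIPLICITY)
        return NuisanceModel(regime=self.regime, mu=tuple(mu / scale))


@dataclass(frozen=True)
class CellTable:
    """Normalized multinomial cell probabilities for one data structure."""

    structure_kind: str
    labels: tuple[str, ...]
    probs: np.ndarray
    weights: np.ndarray        # unnormalized cell weights
    sigma: float               # normalizing divisor of the 16 raw trio weights

    def __post_init__(self) -> None:
        if abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise AssertionError("cell probabilities must sum to 1")

    @property
    def cells(self) -> list[tuple[str, float]]:
        return list(zip(self.labels, self.probs.tolist()))

    def as_dict(self) -> dict[str, float]:
        return dict(self.cells)


@dataclass(frozen=True)
class StructureCounts:
    """Observed multinomial counts for one structure, in frozen cell order."""

    structure_kind: str
    counts: np.ndarray
    snp_id: str = "snp"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        expected = len(cell_labels(self.structure_kind))
        if counts.shape != (expected,):
            raise ValueError(
                f"{self.structure_kind} expects {expected} cells, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _ordered_weights(params: RiskParameters, nuisance: NuisanceModel) -> np.ndarray:
    logtheta = np.log([getattr(params, n) for n in
                       ("r1", "r2", "s1", "s2", "im", "ip",
                        "g11", "g12", "g21", "g22")])
    return np.exp(_E @ logtheta) * nuisance.mu_values()[_MT_INDEX]


def _null_weights(nuisance: NuisanceModel) -> np.ndarray:
    return nuisance.mu_values()[_MT_INDEX]


def _table_from_weights(structure_kind: str, w16: np.ndarray) -> CellTable:
    labels, mat = _CASE_MARGINS[
        _CONTROL_TO_MARGIN.get(structure_kind, structure_kind)]
    weights = mat @ w16
    sigma = float(w16.sum())
    return CellTable(structure_kind=structure_kind, labels=labels,
                     probs=weights / sigma, weights=weights, sigma=sigma)


def trio_cell_table(params: RiskParameters, nuisance: NuisanceModel) -> CellTable:
    """15-cell case/parent trio table (double-het cell = sum of 9a and 9b)."""
    return _table_from_weights("case_parent_trio", _ordered_weights(params, nuisance))


def duo_cell_table(params: RiskParameters, nuisance: NuisanceModel) -> CellTable:
    """7-cell case/mother duo table (father and allele origin marginalized)."""
    return _table_from_weights("case_mother_duo", _ordered_weights(params, nuisance))


def case_cell_table(structure_kind: str, params: RiskParameters,
                    nuisance: NuisanceModel) -> CellTable:
    """Cell table for any case-side structure."""
    if structure_kind not in _CASE_MARGINS:
        raise ValueError(f"unknown case-side structure {structure_kind!r}")
    return _table_from_weights(structure_kind, _ordered_weights(params, nuisance))


def collapse_structure(trio_table: CellTable, structure_kind: str) -> CellTable:
    """Collapse a 15-cell trio table to a thinner case-side structure.

    Splitting the observable double-het trio cell back into its two ordered
    components is done by an even split, which is exact here because every
    supported margin maps cells 9a and 9b to the same collapsed cell.
    """
    if trio_table.structure_kind != "case_parent_trio":
        raise ValueError("collapse_structure expects a case_parent_trio table")
    if structure_kind not in _CASE_MARGINS:
        raise ValueError(f"unknown structure_kind {structure_kind!r}")
    labels15, mat15 = _CASE_MARGINS["case_parent_trio"]
    labels, mat = _CASE_MARGINS[structure_kind]
    # map 15-cell weights back onto the 16 ordered cells: cells 9a/9b share
    # the same margin in every supported structure, so an even split is exact
    w16 = np.zeros(16)
    for k, cell in enumerate(_ORDERED):
        lab = cell[0].rstrip("ab")
        idx = labels15.index(lab)
        n_shared = 2 if lab == "9" else 1
        w16[k] = trio_table.weights[idx] / n_shared
    weights = mat @ w16
    return CellTable(structure_kind=structure_kind, labels=labels,
                     probs=weights / weights.sum(), weights=weights,
                     sigma=trio_table.sigma)


def control_cell_table(structure_kind: str, nuisance: NuisanceModel) -> CellTable:
    """Cell table for a control-side structure (population, no conditioning).

    Controls are treated as population samples of unknown disease status.
    Genuinely unaffected controls are acceptable only for a rare disease.
    """
    if structure_kind not in _CONTROL_TO_MARGIN:
        raise ValueError(f"unknown control-side structure {structure_kind!r}")
    return _table_from_weights(structure_kind, _null_weights(nuisance))


def structure_cell_table(structure_kind: str, params: RiskParameters,
                         nuisance: NuisanceModel) -> CellTable:
    """Cell table for any structure kind (case- or control-side)."""
    if structure_kind in _CONTROL_TO_MARGIN:
        return control_cell_table(structure_kind, nuisance)
    return case_cell_table(structure_kind, params, nuisance)


def prevalence(params: RiskParameters, nuisance: NuisanceModel) -> float:
    """Population disease prevalence K = alpha * Sigma.

    Valid when the mu weights are on the probability scale (the HWE weights
    are; free mu are rescaled via :meth:`NuisanceModel.normalized`).
    """
    alpha = params.require_alpha()
    nuis = nuisance.normalized()
    k = alpha * float(_ordered_weights(params, nuis).sum())
    if not 0.0 < k < 1.0:
        raise ValueError(f"implied prevalence {k:.4g} outside (0, 1)")
    return k


_LOG_FLOOR = 1e-300  # keeps the optimizer finite when a fitted prob -> 0


def joint_loglik(datasets: list[StructureCounts], params: RiskParameters,
                 nuisance: NuisanceModel) -> float:
    """Joint multinomial log-likelihood over independent data structures.

    A cell with zero fitted probability but nonzero count contributes -inf
    (reported, not raised).
    """
    total = 0.0
    for ds in datasets:
        table = structure_cell_table(ds.structure_kind, params, nuisance)
        p = table.probs
        c = ds.counts
        if ((p <= 0) & (c > 0)).any():
            return float("-inf")
        total += float(c @ np.log(np.maximum(p, _LOG_FLOOR)))
    return total
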