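"""Penetrance parameterizations for mother/child disease-risk models.

The canonical ("default") parameterization expresses the penetrance of a
child as a product of multiplicative factors:

    alpha * R_{g_c} * S_{g_m} * Im^{m} * Ip^{p} * gamma_{g_m, g_c}

where ``g_c``/``g_m`` count copies of the putative risk allele (allele 2) in
child and mother, ``m``/``p`` indicate whether the child's risk allele was
inherited from the mother or father (parent-of-origin / imprinting effects),
and the ``gamma_ij`` are maternal-fetal genotype interaction terms.

Several alternative parameterizations (dialects) from the family-based
association literature span the same family of penetrance tables; this module
holds exact conversions between them, verified by cell-by-cell table equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "RiskParameters",
    "DialectParameters",
    "PenetranceTable",
    "UnmappableDialectError",
    "PenetranceOverflowError",
    "build_penetrance_table",
    "solve_child_maternal",
    "to_default_dialect",
    "to_dialect",
    "identifiable_set",
    "FACTOR_NAMES",
    "DIALECT_NAMES",
    "ORDERED_CELLS",
    "COLLAPSED_CELLS",
]

#: multiplicative risk-factor names of the default dialect, in canonical order
FACTOR_NAMES = ("r1", "r2", "s1", "s2", "im", "ip", "g11", "g12", "g21", "g22")

# Mendelian-compatible (g_m, ordered g_c) combinations.  Child genotype is
# written maternal-then-paternal: "21" = risk allele of maternal origin only.
# A mother 11 cannot transmit a 2; a mother 22 cannot transmit a 1.
ORDERED_CELLS = (
    ("11", "11"), ("11", "12"),
    ("12", "11"), ("12", "12"), ("12", "21"), ("12", "22"),
    ("22", "21"), ("22", "22"),
)

#: observable (g_m, unordered g_c) combinations (Mendelian-compatible)
COLLAPSED_CELLS = (
    ("11", "11"), ("11", "12"),
    ("12", "11"), ("12", "12"), ("12", "22"),
    ("22", "12"), ("22", "22"),
)


class PenetranceOverflowError(ValueError):
    """A cell penetrance exceeds 1 under the given parameters."""


class UnmappableDialectError(ValueError):
    """The requested dialect cannot represent the given penetrance table."""


@dataclass(frozen=True)
class RiskParameters:
    """Multiplicative disease-risk factors of the default parameterization.

    ``baseline_alpha`` is the penetrance of the (g_m, g_c) = (11, 11)
    reference cell.  It cancels from the retrospective (case-conditional)
    likelihoods and is therefore optional; it is required only when actual
    penetrances are needed (simulation, penetrance tables, prevalence).
    """

    r1: float = 1.0
    r2: float = 1.0
    s1: float = 1.0
    s2: float = 1.0
    im: float = 1.0
    ip: float = 1.0
    g11: float = 1.0
    g12: float = 1.0
    g21: float = 1.0
    g22: float = 1.0
    baseline_alpha: float | None = None

    def __post_init__(self) -> None:
        for name in FACTOR_NAMES:
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ValueError(f"risk factor {name!r} must be strictly positive, got {v}")
        if self.baseline_alpha is not None and not (0.0 < self.baseline_alpha <= 1.0):
            raise ValueError(f"baseline_alpha must lie in (0, 1], got {self.baseline_alpha}")

    def factors(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FACTOR_NAMES}

    def risk_product(self, g_m: str, g_c_ordered: str) -> float:
        """Product of risk factors (alpha excluded) for an ordered-origin cell."""
        i = g_m.count("2")
        mat, pat = g_c_ordered[0] == "2", g_c_ordered[1] == "2"
        j = int(mat) + int(pat)
        out = 1.0
        if j == 1:
            out *= self.r1
        elif j == 2:
            out *= self.r2
        if i == 1:
            out *= self.s1
        elif i == 2:
            out *= self.s2
        if mat:
            out *= self.im
        if pat:
            out *= self.ip
        if i and j:
            out *= getattr(self, f"g{i}{j}")
        return out

    def require_alpha(self) -> float:
        if self.baseline_alpha is None:
            raise ValueError("baseline_alpha is required for penetrance-scale computations")
        return self.baseline_alpha


@dataclass(frozen=True)
class PenetranceTable:
    """Penetrances over ordered-origin cells and the 7 observable cells.

    The observable double-heterozygote cell (12, 12) is a mixture of the two
    ordered possibilities with mixing proportion ``weight_maternal`` on the
    maternal-origin cell; under HWE and random mating that weight equals the
    frequency A1 of the low-risk allele.
    """

    entries: dict[tuple[str, str], float]
    collapsed_view: dict[tuple[str, str], float]
    weight_maternal: float

    def max_penetrance(self) -> float:
        return max(self.entries.values())


def build_penetrance_table(params: RiskParameters, weight_maternal: float) -> PenetranceTable:
    """Build the ordered-origin and collapsed penetrance tables.

    Raises :class:`PenetranceOverflowError` naming the first offending cell if
    any entry exceeds 1.
    """
    if not 0.0 <= weight_maternal <= 1.0:
        raise ValueError(f"weight_maternal must lie in [0, 1], got {weight_maternal}")
    alpha = params.require_alpha()
    entries: dict[tuple[str, str], float] = {}
    for g_m, g_c in ORDERED_CELLS:
        pen = alpha * params.risk_product(g_m, g_c)
        if pen > 1.0 + 1e-12:
            raise PenetranceOverflowError(
                f"penetrance {pen:.6g} > 1 in cell (g_m={g_m}, g_c={g_c})"
            )
        entries[(g_m, g_c)] = min(pen, 1.0)
    collapsed: dict[tuple[str, str], float] = {}
    for g_m, g_c in COLLAPSED_CELLS:
        if g_m == "12" and g_c == "12":
            collapsed[(g_m, g_c)] = (
                weight_maternal * entries[("12", "21")]
                + (1.0 - weight_maternal) * entries[("12", "12")]
            )
        else:
            key = (g_m, "21" if (g_m == "22" and g_c == "12") else g_c)
            collapsed[(g_m, g_c)] = entries[key]
    return PenetranceTable(entries=entries, collapsed_view=collapsed,
                           weight_maternal=weight_maternal)


def solve_child_maternal(table: dict[tuple[str, str], float],
                         baseline: str = "11") -> tuple[float, ...]:
    """Exactly solve the five-parameter child+maternal model against a table.

    ``table`` maps the seven observable (g_m, g_c) cells to penetrances.
    With ``baseline='11'`` the effects are expressed relative to the
    (g_m, g_c) = (11, 11) cell; with ``baseline='22'`` relative to (22, 22)
    (the same table admits both representations, with reciprocal-flavoured
    parameter values).  Returns ``(alpha, r1, r2, s1, s2)``; raises if the
    table is not exactly of multiplicative child+maternal form.
    """
    t = table
    if baseline == "11":
        alpha = t[("11", "11")]
        r1 = t[("11", "12")] / alpha
        s1 = t[("12", "11")] / alpha
        r2 = t[("12", "22")] / (alpha * s1)
        s2 = t[("22", "12")] / (alpha * r1)
        checks = {("12", "12"): alpha * r1 * s1, ("22", "22"): alpha * r2 * s2}
    elif baseline == "22":
        alpha = t[("22", "22")]
        r1 = t[("22", "12")] / alpha
        s1 = t[("12", "22")] / alpha
        r2 = t[("12", "11")] / (alpha * s1)
        s2 = t[("11", "12")] / (alpha * r1)
        checks = {("12", "12"): alpha * r1 * s1, ("11", "11"): alpha * r2 * s2}
    else:
        raise ValueError("baseline must be '11' or '22'")
    for cell, implied in checks.items():
        if not math.isclose(t[cell], implied, rel_tol=1e-9):
            raise ValueError(
                f"table is not of multiplicative child+maternal form: cell "
                f"{cell} is {t[cell]}, model implies {implied}")
    return alpha, r1, r2, s1, s2


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

# name -> (required value names, optional value names)
_DIALECT_FIELDS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "default": (FACTOR_NAMES, ("alpha",)),
    "weinberg_original_im": (("r1", "r2", "s1", "s2", "im"), ("alpha",)),
    "weinberg_original_ip": (("r1", "r2", "s1", "s2", "ip"), ("alpha",)),
    "weinberg_later_im": (("r1", "r2", "s1", "s2", "im"), ("alpha",)),
    "weinberg_later_ip": (("r1", "r2", "s1", "s2", "ip"), ("alpha",)),
    "mfg_1a": (("rho1", "rho2", "eta1", "eta2", "mu0"), ("alpha", "im", "ip")),
    "mfg_1b": (("rho1", "rho2", "eta1", "eta2", "mu0", "mu2"), ("alpha", "im", "ip")),
    "matching": (("rho1", "rho2", "eta1", "eta2", "mu"), ("alpha",)),
    "parimi_li": (("a0", "d0", "am", "dm", "i_m", "i_c"), ("mu",)),
    "saturated_delta": (("d00", "d01", "d10", "d11", "d12", "d21", "d22"), ()),
    "rm_rp": (("rm", "rp", "r2"), ("alpha", "s1", "s2")),
}

DIALECT_NAMES = tuple(_DIALECT_FIELDS)


@dataclass(frozen=True)
class DialectParameters:
    """Named parameter values of one dialect.

    ``parimi_li`` values are on the log scale (they are regression
    coefficients in the source parameterization); all other dialects use
    positive multiplicative factors.
    """

    dialect: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in _DIALECT_FIELDS:
            raise ValueError(f"unknown dialect {self.dialect!r}; known: {DIALECT_NAMES}")
        required, optional = _DIALECT_FIELDS[self.dialect]
        allowed = set(required) | set(optional)
        unknown = set(self.values) - allowed
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)} for dialect {self.dialect!r}; "
                f"allowed: {sorted(allowed)}"
            )
        missing = set(required) - set(self.values)
        if missing:
            raise ValueError(
                f"dialect {self.dialect!r} is missing parameter(s) {sorted(missing)}"
            )
        if self.dialect != "parimi_li":
            for name, v in self.values.items():
                if not (v > 0 and math.isfinite(v)):
                    raise ValueError(f"dialect value {name!r} must be positive, got {v}")

    def get(self, name: str, default: float) -> float:
        return self.values.get(name, default)


def _to_default(dp: DialectParameters) -> tuple[RiskParameters, list[str]]:
    d, v = dp.dialect, dp.values
    notes: list[str] = []
    alpha = v.get("alpha")
    if d == "default":
        return RiskParameters(baseline_alpha=alpha,
                              **{k: v.get(k, 1.0) for k in FACTOR_NAMES}), notes
    if d in ("weinberg_original_im", "weinberg_original_ip"):
        key = "im" if d.endswith("_im") else "ip"
        notes.append(f"{'ip' if key == 'im' else 'im'} and all gamma fixed at 1")
        return RiskParameters(baseline_alpha=alpha, r1=v["r1"], r2=v["r2"],
                              s1=v["s1"], s2=v["s2"], **{key: v[key]}), notes
    if d in ("weinberg_later_im", "weinberg_later_ip"):
        # the later parameterization restricts the imprinting factor to
        # heterozygous children; its R2 equals R2 * I of the original
        key = "im" if d.endswith("_im") else "ip"
        i = v[key]
        notes.append(f"R2(original) = R2(later) / {key.capitalize()}")
        return RiskParameters(baseline_alpha=alpha, r1=v["r1"], r2=v["r2"] / i,
                              s1=v["s1"], s2=v["s2"], **{key: i}), notes
    if d in ("mfg_1a", "mfg_1b"):
        mu0 = v["mu0"]
        mu2 = v.get("mu2", 1.0)
        notes.append("identification: gamma12 = gamma21 = 1")
        return RiskParameters(
            baseline_alpha=alpha,
            r1=v["rho1"] * mu0, r2=v["rho2"], s1=v["eta1"], s2=v["eta2"] * mu2 / mu0,
            g11=1.0 / mu0, g22=mu0 / mu2,
            im=v.get("im", 1.0), ip=v.get("ip", 1.0),
        ), notes
    if d == "matching":
        mu = v["mu"]
        notes.append("identification: gamma12 = gamma21 = gamma22 = 1; alpha' = alpha/gamma11")
        return RiskParameters(
            baseline_alpha=None if alpha is None else alpha * mu,
            r1=v["rho1"] / mu, r2=v["rho2"], s1=v["eta1"], s2=v["eta2"], g11=mu,
        ), notes
    if d == "parimi_li":
        jm, jc = math.exp(v["i_m"]), math.exp(v["i_c"])
        r1, r2 = math.exp(v["a0"] + v["d0"]), math.exp(2.0 * v["a0"])
        s1, s2 = math.exp(v["am"] + v["dm"]), math.exp(2.0 * v["am"])
        a = None
        if "mu" in v:
            a = math.exp(v["mu"] - v["am"] - v["a0"])
        notes.append("heterozygote parent-of-origin term j_m mapped to Ip; "
                     "mismatch term j_c absorbed into R1, S1 and gamma11")
        return RiskParameters(
            baseline_alpha=a,
            r1=r1 * jc, r2=r2 / jm, s1=s1 * jc, s2=s2, ip=jm, g11=1.0 / jc ** 2,
        ), notes
    if d == "saturated_delta":
        # one parameter per observable cell; canonical origin-free representation
        a = v["d00"]
        r1, s1 = v["d01"] / a, v["d10"] / a
        r2, s2 = v["d12"] / v["d10"], v["d21"] / v["d01"]
        g11 = v["d11"] * a / (v["d01"] * v["d10"])
        g22 = v["d22"] / (a * r2 * s2)
        notes.append("identification: Im = Ip = gamma12 = gamma21 = 1")
        return RiskParameters(baseline_alpha=a if a <= 1.0 else None,
                              r1=r1, r2=r2, s1=s1, s2=s2, g11=g11, g22=g22), notes
    if d == "rm_rp":
        rm, rp = v["rm"], v["rp"]
        notes.append("identification: Ip = 1, so R1 = Rp, Im = Rm/Rp")
        return RiskParameters(
            baseline_alpha=alpha, r1=rp, im=rm / rp, r2=v["r2"] * rp / rm,
            s1=v.get("s1", 1.0), s2=v.get("s2", 1.0),
        ), notes
    raise AssertionError(d)  # pragma: no cover


def _tables_equal(a: RiskParameters, b: RiskParameters, tol: float = 1e-10) -> bool:
    for g_m, g_c in ORDERED_CELLS:
        x, y = a.risk_product(g_m, g_c), b.risk_product(g_m, g_c)
        if abs(x - y) > tol * max(1.0, abs(x), abs(y)):
            return False
    return True


def _collapsed_equal(a: RiskParameters, b: RiskParameters, w: float,
                     tol: float = 1e-10) -> bool:
    pa = replace(a, baseline_alpha=None)
    pb = replace(b, baseline_alpha=None)
    for g_m, g_c in COLLAPSED_CELLS:
        if (g_m, g_c) == ("12", "12"):
            x = w * pa.risk_product("12", "21") + (1 - w) * pa.risk_product("12", "12")
            y = w * pb.risk_product("12", "21") + (1 - w) * pb.risk_product("12", "12")
        else:
            key = (g_m, "21" if (g_m == "22" and g_c == "12") else g_c)
            x, y = pa.risk_product(*key), pb.risk_product(*key)
        if abs(x - y) > tol * max(1.0, abs(x), abs(y)):
            return False
    return True


def to_default_dialect(dp: DialectParameters) -> tuple[RiskParameters, list[str]]:
    """Convert dialect parameters to the default-dialect representation.

    Returns the :class:`RiskParameters` whose induced penetrance table is
    cell-identical to the source dialect's table, together with notes on the
    identification constraints applied where the map is many-to-one.
    """
    return _to_default(dp)


def _from_default(params: RiskParameters, dialect: str,
                  weight_maternal: float) -> DialectParameters:
    p = params
    a = p.baseline_alpha
    v: dict[str, float]
    if dialect == "default":
        v = p.factors()
    elif dialect in ("weinberg_original_im", "weinberg_original_ip"):
        key = "im" if dialect.endswith("_im") else "ip"
        v = {"r1": p.r1, "r2": p.r2, "s1": p.s1, "s2": p.s2, key: getattr(p, key)}
    elif dialect in ("weinberg_later_im", "weinberg_later_ip"):
        key = "im" if dialect.endswith("_im") else "ip"
        i = getattr(p, key)
        v = {"r1": p.r1, "r2": p.r2 * i, "s1": p.s1, "s2": p.s2, key: i}
    elif dialect in ("mfg_1a", "mfg_1b"):
        v = {
            "rho1": p.r1 * p.g11, "rho2": p.r2 * p.g12, "eta1": p.s1,
            "eta2": p.s2 * p.g22 / p.g12, "mu0": 1.0 / p.g11,
            "mu2": p.g12 * p.g21 / (p.g11 * p.g22),
        }
        if dialect == "mfg_1a":
            if abs(v["mu2"] - 1.0) > 1e-10:
                raise UnmappableDialectError(
                    "mfg_1a has a single incompatibility parameter; the given table "
                    "requires mu2 != 1 (use mfg_1b)")
            del v["mu2"]
        if p.im != 1.0:
            v["im"] = p.im
        if p.ip != 1.0:
            v["ip"] = p.ip
    elif dialect == "matching":
        v = {"mu": p.g11, "rho1": p.r1 * p.g11, "rho2": p.r2,
             "eta1": p.s1, "eta2": p.s2}
        if a is not None:
            v["alpha"] = a / p.g11
        a = None  # alpha handled above (primed baseline)
    elif dialect == "parimi_li":
        # saturated on the 7 observable cells: solve exactly against the
        # collapsed risk-product table (heterozygote mixture weight w)
        w = weight_maternal
        base = replace(p, baseline_alpha=None)
        t = {}
        for g_m, g_c in COLLAPSED_CELLS:
            if (g_m, g_c) == ("12", "12"):
                val = (w * base.risk_product("12", "21")
                       + (1 - w) * base.risk_product("12", "12"))
            else:
                key = (g_m, "21" if (g_m == "22" and g_c == "12") else g_c)
                val = base.risk_product(*key)
            t[f"{g_m.count('2')}{g_c.count('2')}"] = val
        jm = t["01"] * t["10"] * t["22"] / (t["12"] * t["21"])
        het = w + (1 - w) * jm
        jc2 = t["12"] * t["21"] * het / (t["22"] * t["11"])
        if jm <= 0 or jc2 <= 0:
            raise UnmappableDialectError("parimi_li requires positive factors")
        jc = math.sqrt(jc2)
        s1 = t["10"] / jc
        r1 = t["11"] / (het * s1)
        s2 = t["21"] / (r1 * jc)
        r2 = t["22"] / s2
        a0, am = 0.5 * math.log(r2), 0.5 * math.log(s2)
        v = {"a0": a0, "d0": math.log(r1) - a0, "am": am,
             "dm": math.log(s1) - am, "i_m": math.log(jm), "i_c": math.log(jc)}
        if a is not None:
            v["mu"] = math.log(a) + am + a0
        a = None
    elif dialect == "saturated_delta":
        alpha = a if a is not None else 1.0
        table = {}
        base = replace(p, baseline_alpha=None)
        for g_m, g_c in COLLAPSED_CELLS:
            if (g_m, g_c) == ("12", "12"):
                val = (weight_maternal * base.risk_product("12", "21")
                       + (1 - weight_maternal) * base.risk_product("12", "12"))
            else:
                key = (g_m, "21" if (g_m == "22" and g_c == "12") else g_c)
                val = base.risk_product(*key)
            table[f"d{g_m.count('2')}{g_c.count('2')}"] = alpha * val
        v = table
        a = None
    elif dialect == "rm_rp":
        v = {"rm": p.r1 * p.im, "rp": p.r1 * p.ip, "r2": p.r2 * p.im * p.ip}
        if p.s1 != 1.0:
            v["s1"] = p.s1
        if p.s2 != 1.0:
            v["s2"] = p.s2
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if a is not None:
        v["alpha"] = a
    return DialectParameters(dialect=dialect, values=v)


def to_dialect(params: RiskParameters, dialect: str,
               weight_maternal: float = 0.5) -> DialectParameters:
    """Represent a default-dialect model in another dialect.

    The result is verified by round-tripping through
    :func:`to_default_dialect` and comparing penetrance tables cell-by-cell
    (relative tolerance 1e-10).  Raises :class:`UnmappableDialectError` when
    the target dialect cannot represent the table.
    """
    dp = _from_default(params, dialect, weight_maternal)
    back, _ = to_default_dialect(dp)
    # saturated and parimi_li dialects only pin down the 7 observable cells
    collapsed_only = dialect in ("saturated_delta", "parimi_li")
    ok = (_collapsed_equal(params, back, weight_maternal) if collapsed_only
          else _tables_equal(params, back))
    if not ok:
        raise UnmappableDialectError(
            f"dialect {dialect!r} cannot represent this penetrance table under "
            "its identification constraints")
    return dp


# ---------------------------------------------------------------------------
# identifiability bookkeeping
# ---------------------------------------------------------------------------

#: composite interpretation of each canonical trio parameter if the fixing
#: assumption (Ip = gamma12 = gamma21 = 1) fails
_COMPOSITES_FIX_IP = {
    "r1": "R1*Ip",
    "r2": "R2*gamma12",
    "s1": "S1",
    "s2": "S2*gamma21",
    "im": "Im/Ip",
    "g11": "gamma11",
    "g22": "gamma22/(gamma12*gamma21)",
}
_COMPOSITES_FIX_IM = dict(_COMPOSITES_FIX_IP, ip="Ip/Im", r1="R1*Im")
del _COMPOSITES_FIX_IM["im"]


@dataclass(frozen=True)
class IdentifiableParam:
    name: str
    composite: str


@dataclass(frozen=True)
class IdentifiableSet:
    params: tuple[IdentifiableParam, ...]
    max_free: int
    warning: str | None = None

    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)


def identifiable_set(structure_kinds: set[str] | frozenset[str],
                     regime: str, fix: str = "ip",
                     requested: tuple[str, ...] | None = None) -> IdentifiableSet:
    """Canonical identifiable free risk-parameter set for given data structures.

    For trios, seven relative-risk parameters are identifiable
    ({R1, R2, S1, S2, Im, gamma11, gamma22} with Ip = gamma12 = gamma21 fixed
    at 1; pass ``fix='im'`` for the mirror convention).  Each returned
    parameter carries the composite it represents should the fixing assumption
    fail.  Duo-only data support at most six free parameters in total
    (7 observable cells minus one normalization), including any free nuisance
    parameter such as the allele frequency.
    """
    if not structure_kinds:
        raise ValueError("structure_kinds must be nonempty")
    comp = _COMPOSITES_FIX_IM if fix == "im" else _COMPOSITES_FIX_IP
    canonical = tuple(IdentifiableParam(n, comp[n]) for n in comp)
    has_trios = "case_parent_trio" in structure_kinds
    if has_trios:
        max_free = 7 + (0 if regime == "hwe_rm_fixed_af" else
                        (1 if regime.startswith("hwe") else 5))
        return IdentifiableSet(canonical, max_free=max_free)
    # duo-only (or thinner) case-side data: 7 cells - 1 normalization
    max_free = 6
    warning = None
    if requested is not None and len(requested) > max_free:
        warning = (f"{len(requested)} free parameters requested but at most "
                   f"{max_free} are estimable from duo-only data")
    elif requested is not None:
        warning = ("joint identifiability of the requested set should be "
                   "verified at the fit (information-matrix) level")
    params = canonical if requested is None else tuple(
        IdentifiableParam(n, comp.get(n, n)) for n in requested)
    return IdentifiableSet(params, max_free=max_free, warning=warning)
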