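"""Maximum-likelihood fitting, tests and model comparison.

The retrospective multinomial likelihood is maximized directly over
log-transformed relative-risk parameters and transformed nuisance parameters
(logit allele frequency, or log mating-type weights with mu6 fixed at 1 —
the likelihood depends on the mu only up to scale).  Standard errors come
from the inverse observed information on the transformed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .params import DialectParameters, FACTOR_NAMES, to_default_dialect
from .tables import (CONTROL_STRUCTURES, NuisanceModel, StructureCounts,
                     _E, _MT_INDEX, _MT_MULTIPLICITY, cell_labels,
                     collapse_matrix)

__all__ = [
    "ModelSpec",
    "FitResult",
    "Estimate",
    "fit_model",
    "likelihood_ratio_test",
    "fit_method",
    "logistic_duo_comparator",
    "model_sequence",
    "METHOD_IDS",
    "IdentifiabilityError",
]

METHOD_IDS = ("0", "1", "2", "2a", "2b", "3", "4", "5", "6", "7", "8", "9")

#: information-matrix condition number beyond which a fit is flagged
COND_THRESHOLD = 1e10

_LOG_FLOOR = 1e-300


class IdentifiabilityError(ValueError):
    """The requested design/parameter set is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Which risk parameters are free, which are fixed, and the nuisance regime.

    ``free_risk``/``fixed_risk`` name parameters in the chosen dialect's
    vocabulary (the default dialect uses r1, r2, s1, s2, im, ip, g11, g12,
    g21, g22).  Parameters not named are fixed at their null value (1, or 0
    for the log-scale parimi_li dialect).
    """

    free_risk: tuple[str, ...] = ()
    fixed_risk: dict[str, float] = field(default_factory=dict)
    regime: str = "hwe_rm_free_af"
    a2: float | None = None            # required fixed value under hwe_rm_fixed_af
    dialect: str = "default"
    name: str = ""

    def __post_init__(self) -> None:
        if self.regime == "hwe_rm_fixed_af":
            if self.a2 is None or not (0.0 < self.a2 < 1.0):
                raise ValueError("hwe_rm_fixed_af requires a fixed a2 in (0, 1)")
        dup = set(self.free_risk) & set(self.fixed_risk)
        if dup:
            raise ValueError(f"parameters both free and fixed: {sorted(dup)}")

    @property
    def n_free_nuisance(self) -> int:
        return {"hwe_rm_fixed_af": 0, "hwe_rm_free_af": 1,
                "pae": 4, "mating_symmetry": 5}[self.regime]

    @property
    def n_free(self) -> int:
        return len(self.free_risk) + self.n_free_nuisance

    def null_spec(self) -> "ModelSpec":
        return replace(self, free_risk=(), fixed_risk={},
                       name=(self.name + ":null") if self.name else "null")


@dataclass(frozen=True)
class Estimate:
    value: float
    se: float | None
    log_value: float
    log_se: float | None


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    estimates: dict[str, Estimate]
    nuisance: NuisanceModel
    max_loglik: float
    null_loglik: float
    converged: bool
    identifiable: bool
    n_iter: int
    message: str = ""

    @property
    def total_se(self) -> float:
        """Sum of risk-parameter log-scale SEs (0 when any is inestimable)."""
        ses = [e.log_se for e in self.estimates.values()]
        if any(s is None for s in ses):
            return 0.0
        return float(sum(ses))

    def estimate(self, name: str) -> float:
        return self.estimates[name].value


# ---------------------------------------------------------------------------
# objective construction
# ---------------------------------------------------------------------------

_THETA_INDEX = {n: i for i, n in enumerate(FACTOR_NAMES)}


def _risk_logtheta_default(spec: ModelSpec, x_risk: np.ndarray) -> np.ndarray:
    lt = np.zeros(10)
    for name, v in spec.fixed_risk.items():
        lt[_THETA_INDEX[name]] = math.log(v)
    for name, v in zip(spec.free_risk, x_risk):
        lt[_THETA_INDEX[name]] = v
    return lt


def _risk_logtheta_dialect(spec: ModelSpec, x_risk: np.ndarray) -> np.ndarray:
    log_scale = spec.dialect == "parimi_li"
    values = dict(spec.fixed_risk)
    for name, v in zip(spec.free_risk, x_risk):
        values[name] = v if log_scale else math.exp(v)
    # fill remaining required names at their null value
    from .params import _DIALECT_FIELDS  # frozen vocabulary
    required, _optional = _DIALECT_FIELDS[spec.dialect]
    for name in required:
        values.setdefault(name, 0.0 if log_scale else 1.0)
    rp, _ = to_default_dialect(DialectParameters(spec.dialect, values))
    return np.log([getattr(rp, n) for n in FACTOR_NAMES])


def _mu_from_x(spec: ModelSpec, x_nuis: np.ndarray) -> np.ndarray:
    if spec.regime == "hwe_rm_fixed_af":
        from .tables import hwe_mu
        return hwe_mu(spec.a2)
    if spec.regime == "hwe_rm_free_af":
        from .tables import hwe_mu
        return hwe_mu(float(expit(x_nuis[0])))
    if spec.regime == "pae":
        m1, m2, m34, m5 = np.exp(x_nuis)
        return np.array([m1, m2, m34, m34, m5, 1.0])
    m = np.exp(x_nuis)  # mating_symmetry: mu1..mu5, mu6 = 1
    return np.array([m[0], m[1], m[2], m[3], m[4], 1.0])


class _Objective:
    """Fast negative joint log-likelihood over prepared datasets."""

    def __init__(self, datasets: list[StructureCounts], spec: ModelSpec):
        if not datasets:
            raise ValueError("at least one dataset is required")
        if all(ds.total == 0 for ds in datasets):
            raise ValueError("all datasets have zero total count")
        self.spec = spec
        self.k_risk = len(spec.free_risk)
        self.parts = []
        for ds in datasets:
            is_ctrl = ds.structure_kind in CONTROL_STRUCTURES
            self.parts.append((collapse_matrix(ds.structure_kind),
                               ds.counts.astype(float), is_ctrl))
        self._risk_fun = (_risk_logtheta_default if spec.dialect == "default"
                          else _risk_logtheta_dialect)

    def __call__(self, x: np.ndarray) -> float:
        lt = self._risk_fun(self.spec, x[:self.k_risk])
        mu = _mu_from_x(self.spec, x[self.k_risk:])
        mu_cells = mu[_MT_INDEX]
        w = np.exp(_E @ lt) * mu_cells
        s_case = w.sum()
        s_ctrl = float(mu @ _MT_MULTIPLICITY)
        ll = 0.0
        for mat, counts, is_ctrl in self.parts:
            if is_ctrl:
                probs = (mat @ mu_cells) / s_ctrl
            else:
                probs = (mat @ w) / s_case
            ll += float(counts @ np.log(np.maximum(probs, _LOG_FLOOR)))
        return -ll


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                val = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _x0(spec: ModelSpec) -> np.ndarray:
    x = np.zeros(spec.n_free)
    if spec.regime == "hwe_rm_free_af":
        x[-1] = logit(spec.a2 if spec.a2 is not None else 0.5)
    return x


def _optimize(obj: _Objective, spec: ModelSpec, seed: int,
              x_start: np.ndarray | None = None):
    x0 = _x0(spec) if x_start is None else x_start
    if len(x0) == 0:
        # fully fixed model: the likelihood is a constant
        return optimize.OptimizeResult(
            fun=obj(x0), x=x0, success=True, nit=0,
            message="no free parameters")
    best = None
    rng = np.random.default_rng(seed)
    for attempt in range(4):  # initial try + 3 seeded random restarts
        x_try = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=len(x0))
        res = optimize.minimize(obj, x_try, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-13,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success:
            break
    return best


def fit_model(datasets: list[StructureCounts], spec: ModelSpec,
              seed: int = 0, compute_se: bool = True,
              _fit_null: bool = True) -> FitResult:
    """Maximize the joint multinomial likelihood under a model specification.

    The null log-likelihood (all risk factors at their null value, nuisance
    profiled) is fitted alongside; when the optimizer leaves the full model
    below its nested null, the full fit is re-polished from the null optimum.
    """
    obj = _Objective(datasets, spec)
    res = _optimize(obj, spec, seed)

    null_ll = -math.inf
    if _fit_null:
        nspec = spec.null_spec()
        if spec.free_risk:
            nres = _optimize(_Objective(datasets, nspec), nspec, seed)
            null_ll = -nres.fun
            if -res.fun < null_ll - 1e-10:
                # restart the full fit from the null optimum (nested models)
                x_start = np.zeros(spec.n_free)
                x_start[len(spec.free_risk):] = nres.x[:]
                res2 = _optimize(obj, spec, seed + 1, x_start=x_start)
                if res2.fun < res.fun:
                    res = res2
        else:
            null_ll = -res.fun

    x = res.x
    k = len(spec.free_risk)
    log_scale_dialect = spec.dialect == "parimi_li"

    ses = [None] * len(x)
    identifiable = True
    message_extra = ""
    # a saturated (or over-parameterized) fit reproduces the observed cell
    # frequencies exactly; the parameters are then separated only by model
    # curvature and are not usefully identifiable
    df_total = sum(len(ds.counts) - 1 for ds in datasets)
    if spec.n_free >= df_total:
        identifiable = False
        message_extra = (f"; {spec.n_free} free parameters saturate the "
                         f"{df_total} available multinomial df")
    if compute_se and len(x):
        hess = _numerical_hessian(obj, x)
        try:
            cond = np.linalg.cond(hess)
            if not np.isfinite(cond) or cond > COND_THRESHOLD:
                identifiable = False
            cov = np.linalg.inv(hess)
            d = np.diag(cov)
            if (d <= 0).any():
                identifiable = False
            ses = [math.sqrt(v) if v > 0 else None for v in d]
        except np.linalg.LinAlgError:
            identifiable = False

    estimates = {}
    for i, name in enumerate(spec.free_risk):
        lv = float(x[i])
        se = ses[i]
        if log_scale_dialect:
            estimates[name] = Estimate(value=lv, se=se, log_value=lv, log_se=se)
        else:
            estimates[name] = Estimate(value=math.exp(lv),
                                       se=None if se is None else math.exp(lv) * se,
                                       log_value=lv, log_se=se)

    mu = _mu_from_x(spec, x[k:])
    if spec.regime.startswith("hwe"):
        a2 = spec.a2 if spec.regime == "hwe_rm_fixed_af" else float(expit(x[k]))
        nuis = NuisanceModel(regime=spec.regime, a2=a2)
    else:
        nuis = NuisanceModel(regime=spec.regime, mu=tuple(mu)).normalized()

    return FitResult(spec=spec, estimates=estimates, nuisance=nuis,
                     max_loglik=-res.fun, null_loglik=null_ll,
                     converged=bool(res.success), identifiable=identifiable,
                     n_iter=int(res.nit),
                     message=str(res.message) + message_extra)


def likelihood_ratio_test(full: FitResult, null: FitResult):
    """LRT of nested model specifications.

    Returns ``(statistic, df, p_value)``; df is the difference in free risk
    parameters (nuisance parameters are profiled under both hypotheses).
    """
    if not set(null.spec.free_risk) <= set(full.spec.free_risk):
        raise ValueError(
            f"null free set {null.spec.free_risk} is not nested in "
            f"{full.spec.free_risk}")
    df = len(full.spec.free_risk) - len(null.spec.free_risk)
    stat = max(0.0, 2.0 * (full.max_loglik - null.max_loglik))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# method presets
# ---------------------------------------------------------------------------

_METHOD_CONFIG = {
    # method -> (regime, required control structure or None)
    "1": ("hwe_rm_fixed_af", None),
    "2": ("hwe_rm_free_af", None),
    "2a": ("hwe_rm_free_af", None),
    "2b": ("mating_symmetry", None),
    "3": ("hwe_rm_free_af", "control"),
    "4": ("hwe_rm_free_af", "parents_of_control"),
    "5": ("pae", "parents_of_control"),
    "6": ("mating_symmetry", "parents_of_control"),
    "7": ("hwe_rm_free_af", "control_mother_duo"),
    "8": ("pae", "control_mother_duo"),
    "9": ("mating_symmetry", "control_mother_duo"),
}


def fit_method(method_id: str, case_datasets: list[StructureCounts],
               control_datasets: list[StructureCounts] | None = None,
               free_risk: tuple[str, ...] = ("r1", "r2", "s1", "s2"),
               fixed_risk: dict[str, float] | None = None,
               fixed_a2: float | None = None,
               weight_maternal: float | None = None,
               seed: int = 0) -> FitResult:
    """Fit one of the preset analysis methods.

    Methods 1/2(a) assume HWE and random mating (method 1 with the allele
    frequency fixed externally); 2b/6/9 freely estimate the six mating-type
    stratification parameters; 5/8 assume parental allelic exchangeability
    (mu3 = mu4); 3/4/7 add the respective control-sample likelihood under
    HWE and random mating.  Method 0 is the logistic-regression comparator
    on case/mother vs. control/mother duos.
    """
    method_id = str(method_id)
    if method_id not in METHOD_IDS:
        raise ValueError(f"unknown method {method_id!r}")
    control_datasets = control_datasets or []
    if method_id == "0":
        case_duo = _require_structure(case_datasets, "case_mother_duo", "0")
        ctrl_duo = _require_structure(control_datasets, "control_mother_duo", "0")
        return logistic_duo_comparator(case_duo, ctrl_duo, free_risk=free_risk,
                                       weight_maternal=weight_maternal)
    regime, required = _METHOD_CONFIG[method_id]
    datasets = list(case_datasets)
    if required is not None:
        datasets.append(_require_structure(control_datasets, required, method_id))
    spec = ModelSpec(free_risk=tuple(free_risk),
                     fixed_risk=dict(fixed_risk or {}),
                     regime=regime, a2=fixed_a2, name=f"method{method_id}")
    return fit_model(datasets, spec, seed=seed)


def _require_structure(datasets, kind, method_id):
    for ds in datasets:
        if ds.structure_kind == kind:
            return ds
    raise ValueError(f"method {method_id} requires a {kind!r} sample")


# ---------------------------------------------------------------------------
# logistic comparator (Method 0)
# ---------------------------------------------------------------------------

# covariate value per duo cell for each default-dialect parameter; the
# double-heterozygote imprinting covariates use the fractional plug-in weight
# w = A1 estimated from the control duos (origin is ambiguous in that cell)
def _duo_design_row(label: str, name: str, w: float) -> float:
    gm = label[1:3]
    gc = label[5:7]
    i, j = gm.count("2"), gc.count("2")
    if name == "r1":
        return float(j == 1)
    if name == "r2":
        return float(j == 2)
    if name == "s1":
        return float(i == 1)
    if name == "s2":
        return float(i == 2)
    if name == "im":
        if (i, j) == (1, 1):
            return w
        return float(i == 2 and j >= 1 or (i, j) == (1, 2))
    if name == "ip":
        if (i, j) == (1, 1):
            return 1.0 - w
        return float((i, j) in ((0, 1), (1, 2), (2, 2)))
    if name in ("g11", "g12", "g21", "g22"):
        return float((i, j) == (int(name[1]), int(name[2])))
    raise ValueError(f"unknown parameter {name!r} for logistic design")


def _irls_logistic(X: np.ndarray, y: np.ndarray, wts: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-10):
    """Newton (IRLS) maximum-likelihood logistic fit on aggregated rows."""
    beta = np.zeros(X.shape[1])
    for it in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (wts * (y - p))
        Wd = wts * p * (1.0 - p)
        info = X.T @ (X * Wd[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise IdentifiabilityError("singular information matrix in "
                                       "logistic fit") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    ll = float(wts @ (y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    Wd = wts * p * (1.0 - p)
    info = X.T @ (X * Wd[:, None])
    return beta, ll, info, it + 1


def logistic_duo_comparator(case_duos: StructureCounts,
                            control_duos: StructureCounts,
                            free_risk: tuple[str, ...] = ("r1", "r2", "s1", "s2"),
                            weight_maternal: float | None = None) -> FitResult:
    """Prospective logistic regression of case vs. control duos (Method 0).

    Case/control status is regressed on cell-level covariates coded from the
    chosen parameterization over the seven observable (g_m, g_c) cells.
    """
    if case_duos.structure_kind != "case_mother_duo":
        raise ValueError("case_duos must be a case_mother_duo structure")
    if control_duos.structure_kind != "control_mother_duo":
        raise ValueError("control_duos must be a control_mother_duo structure")
    labels = cell_labels("case_mother_duo")
    if weight_maternal is None:
        # plug-in w = A1 from the control duos (mother + child genotypes)
        alleles2 = 0
        total = 0
        for lab, n in zip(labels, control_duos.counts):
            gm, gc = lab[1:3], lab[5:7]
            alleles2 += n * (gm.count("2") + gc.count("2"))
            total += 4 * n
        weight_maternal = 1.0 - alleles2 / total if total else 0.5

    rows_X, rows_y, rows_w = [], [], []
    for y, ds in ((1.0, case_duos), (0.0, control_duos)):
        for lab, n in zip(labels, ds.counts):
            covs = [_duo_design_row(lab, name, weight_maternal)
                    for name in free_risk]
            rows_X.append([1.0] + covs)
            rows_y.append(y)
            rows_w.append(float(n))
    X = np.array(rows_X)
    y = np.array(rows_y)
    wts = np.array(rows_w)
    used = X[wts > 0]
    if np.linalg.matrix_rank(used) < X.shape[1]:
        raise IdentifiabilityError(
            "rank-deficient logistic design for the requested parameters")
    beta, ll, info, n_iter = _irls_logistic(X, y, wts)
    beta0, ll0, _, _ = _irls_logistic(X[:, :1], y, wts)

    try:
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        identifiable = bool(np.linalg.cond(info) < COND_THRESHOLD)
    except np.linalg.LinAlgError:
        ses = np.full(len(beta), np.nan)
        identifiable = False

    estimates = {
        name: Estimate(value=math.exp(beta[i + 1]),
                       se=math.exp(beta[i + 1]) * float(ses[i + 1]),
                       log_value=float(beta[i + 1]), log_se=float(ses[i + 1]))
        for i, name in enumerate(free_risk)
    }
    spec = ModelSpec(free_risk=tuple(free_risk), regime="hwe_rm_free_af",
                     a2=0.5, name="method0")
    nuis = NuisanceModel(regime="hwe_rm_free_af",
                         a2=float(np.clip(1.0 - weight_maternal, 1e-6, 1 - 1e-6)))
    return FitResult(spec=spec, estimates=estimates, nuisance=nuis,
                     max_loglik=ll, null_loglik=ll0, converged=True,
                     identifiable=identifiable, n_iter=n_iter,
                     message="logistic comparator")


# ---------------------------------------------------------------------------
# model sequences / AIC
# ---------------------------------------------------------------------------

def model_sequence(datasets: list[StructureCounts],
                   specs: list[ModelSpec], seed: int = 0):
    """Fit an ordered sequence of specifications and compare by AIC.

    AIC = 2k - 2 max_loglik with k counting free risk plus free nuisance
    parameters.  Ties break toward the earliest spec in user order.
    Returns ``(rows, best_index)`` where each row is ``(spec, FitResult,
    aic)``.
    """
    if len(specs) < 2:
        raise ValueError("model_sequence expects at least two specifications")
    rows = []
    for spec in specs:
        fr = fit_model(datasets, spec, seed=seed)
        aic = 2.0 * spec.n_free - 2.0 * fr.max_loglik
        rows.append((spec, fr, aic))
    best = 0
    for i, (_, _, aic) in enumerate(rows):
        if aic < rows[best][2] - 1e-12:
            best = i
    return rows, best
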