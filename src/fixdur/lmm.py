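"""Zero-correlation-parameter linear mixed models with crossed random effects.

The model is a Gaussian LMM for log fixation durations,

    y = X b + sum_k Z_k u_k + e,     u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I),

where every random component k (an intercept or a slope for one grouping
factor: subject, scene item, scene list, subject group) is independent of
all others -- the zero-correlation-parameter model (zcpLMM).  The full model
has 23 fixed effects: the intercept, 15 local image-feature terms (5
features x 3 triplet positions), and 7 oculomotor/spatiotemporal terms with
quadratic components for the previous-saccade amplitude and viewing time.

Estimation profiles out the fixed effects and the residual variance and
optimizes the REML (or ML) criterion over the relative standard deviations
lambda_k = sigma_k / sigma_e >= 0, exactly the parameterization in which
variance components may legitimately converge to zero.  For each candidate
lambda the penalized normal equations

    [ L' Z'Z L + I   L' Z'X ] [u*]   [ L' Z'y ]
    [   X'Z L         X'X   ] [b ] = [  X'y   ]      (L = diag(lambda))

are solved by dense Cholesky factorizations of the two diagonal blocks
after elimination; the profiled criterion follows the standard
penalized-least-squares identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

from .triplets import FEATURE_COLS, POSITIONS

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FitResult",
    "R2Pair",
    "ModelComparison",
    "FULL_FIXED_TERMS",
    "FEATURE_TERMS",
    "OCULOMOTOR_TERMS",
    "standardize",
    "log_duration",
    "build_design",
    "fit_zcplmm",
    "fixed_effect_tests",
    "count_random_params",
    "full_zcp_spec",
    "reduce_random_structure",
    "nonfeature_spec",
    "feature_only_spec",
    "r2_lmm",
    "compare_models",
]

#: the 15 local image-feature terms (5 features at fixations n, n-1, n+1)
FEATURE_TERMS = [f"{f}_{p}" for f in FEATURE_COLS for p in POSITIONS]

#: oculomotor and spatiotemporal terms; *_sq are quadratic in the z-scored input
OCULOMOTOR_TERMS = [
    "sacc_amp_prev",
    "sacc_amp_prev_sq",
    "sacc_amp_next",
    "delta_angle",
    "viewing_time",
    "viewing_time_sq",
    "central_distance",
]

#: full fixed-effects structure: intercept + 15 feature + 7 oculomotor = 23
FULL_FIXED_TERMS = ["1"] + FEATURE_TERMS + OCULOMOTOR_TERMS

_QUADRATIC_OF = {"sacc_amp_prev_sq": "sacc_amp_prev", "viewing_time_sq": "viewing_time"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative fixed + random structure of a zcpLMM.

    ``random`` maps a grouping-factor column name to the list of terms
    ("1" for the intercept, otherwise fixed-term names) that receive an
    independent variance component for that factor.
    """

    fixed_terms: tuple[str, ...]
    random: dict[str, tuple[str, ...]] = field(default_factory=dict)
    correlation_free: bool = True

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(
            self, "random", {f: tuple(t) for f, t in self.random.items()}
        )

    @property
    def n_components(self) -> int:
        return sum(len(t) for t in self.random.values())

    def component_names(self) -> list[str]:
        return [f"{fac}:{term}" for fac, terms in self.random.items() for term in terms]


def full_zcp_spec(
    subject_col: str = "subject_id",
    item_col: str = "scene_id",
    list_col: str = "scene_list",
    group_col: str = "subject_group",
) -> ModelSpec:
    """The full zcpLMM: 23 by-subject + 23 by-item components, plus random
    intercepts for scene list and subject group (48 variance components)."""
    terms = tuple(FULL_FIXED_TERMS)
    return ModelSpec(
        fixed_terms=terms,
        random={
            subject_col: terms,
            item_col: terms,
            list_col: ("1",),
            group_col: ("1",),
        },
    )


def reduce_random_structure(spec: ModelSpec) -> ModelSpec:
    """Drop the by-subject image-feature slopes and the quadratic
    previous-saccade slopes (both factors), 48 -> 31 components.

    Empirically-zero by-subject feature slopes and unsupported quadratic
    previous-saccade slopes are removed; idempotent.
    """
    factors = list(spec.random)
    if len(factors) < 2:
        raise ValueError("spec must have by-subject and by-item random terms")
    subject_col, item_col = factors[0], factors[1]
    new_random = dict(spec.random)
    new_random[subject_col] = tuple(
        t
        for t in spec.random[subject_col]
        if t not in FEATURE_TERMS and t != "sacc_amp_prev_sq"
    )
    new_random[item_col] = tuple(
        t for t in spec.random[item_col] if t != "sacc_amp_prev_sq"
    )
    return replace(spec, random=new_random)


def nonfeature_spec(spec: ModelSpec) -> ModelSpec:
    """Partial model without the local image features: drop the 15 feature
    terms from the fixed effects and from every random factor."""
    return replace(
        spec,
        fixed_terms=tuple(t for t in spec.fixed_terms if t not in FEATURE_TERMS),
        random={
            fac: tuple(t for t in terms if t not in FEATURE_TERMS)
            for fac, terms in spec.random.items()
        },
    )


def feature_only_spec(spec: ModelSpec) -> ModelSpec:
    """The five-feature distributed-processing partial model: intercept plus
    the 15 feature terms; random structure keeps intercepts and feature
    slopes only."""
    keep = set(FEATURE_TERMS) | {"1"}
    return replace(
        spec,
        fixed_terms=tuple(t for t in spec.fixed_terms if t in keep),
        random={
            fac: tuple(t for t in terms if t in keep)
            for fac, terms in spec.random.items()
        },
    )


def count_random_params(n_terms: int, structure: str = "maximal") -> int:
    """Parameters per grouping factor: n(n+1)/2 for a maximal (fully
    correlated) structure, n for the zero-correlation structure."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if structure == "maximal":
        return n_terms * (n_terms + 1) // 2
    if structure == "zero_correlation":
        return n_terms
    raise ValueError(f"unknown structure {structure!r}")


def standardize(values) -> tuple[np.ndarray, float, float]:
    """z-transform: subtract the sample mean, divide by the sample SD.

    Returns the z-scores plus the transform parameters for back-mapping.
    Zero-variance input is an error (the predictor is degenerate).
    """
    arr = np.asarray(values, dtype=np.float64)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if not sd > 0:
        name = getattr(values, "name", None)
        raise ValueError(
            f"zero variance in predictor{f' {name!r}' if name else ''}; cannot standardize"
        )
    return (arr - mean) / sd, mean, sd


def log_duration(duration_ms) -> np.ndarray:
    """Natural log of fixation duration in milliseconds."""
    arr = np.asarray(duration_ms, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("durations must be > 0")
    return np.log(arr)


@dataclass
class DesignMatrices:
    """Response, fixed-effect matrix and random-effect incidence structures."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, p)
    fixed_names: list[str]
    component_names: list[str]  # "factor:term" per variance component
    component_slices: list[slice]  # columns of Z per component
    Z: sparse.csr_matrix  # (n, q)
    factor_levels: dict[str, list]  # factor -> ordered level values
    scaling: dict[str, tuple[float, float]]  # input -> (mean, sd)
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]


def build_design(
    table: pd.DataFrame,
    spec: ModelSpec,
    response: str = "log_duration",
) -> DesignMatrices:
    """Assemble y, X and the random-effect incidence structure from an
    analysis table.

    Every non-quadratic input variable is z-standardized on the table
    (per-task tables imply per-task scaling); quadratic terms are the
    elementwise squares of the standardized linear columns and are not
    re-standardized, so linear and quadratic estimates stay interpretable
    independently of each other.
    """
    n = len(table)
    scaling: dict[str, tuple[float, float]] = {}
    z_cols: dict[str, np.ndarray] = {}

    def z_of(name: str) -> np.ndarray:
        if name in z_cols:
            return z_cols[name]
        if name in _QUADRATIC_OF:
            z_cols[name] = z_of(_QUADRATIC_OF[name]) ** 2
        else:
            if name not in table.columns:
                raise KeyError(f"unknown predictor {name!r}")
            z, mean, sd = standardize(table[name])
            scaling[name] = (mean, sd)
            z_cols[name] = z
        return z_cols[name]

    cols = []
    for term in spec.fixed_terms:
        cols.append(np.ones(n) if term == "1" else z_of(term))
    X = np.column_stack(cols)

    y = table[response].to_numpy(dtype=np.float64)

    comp_names: list[str] = []
    comp_slices: list[slice] = []
    blocks = []
    factor_levels: dict[str, list] = {}
    q = 0
    for factor, terms in spec.random.items():
        if factor not in table.columns:
            raise KeyError(f"grouping factor {factor!r} not in table")
        codes, levels = pd.factorize(table[factor], sort=True)
        factor_levels[factor] = list(levels)
        m = len(levels)
        if m < 2:
            raise ValueError(f"grouping factor {factor!r} is degenerate ({m} level)")
        rows = np.arange(n)
        for term in terms:
            vals = np.ones(n) if term == "1" else z_of(term)
            blocks.append(
                sparse.csr_matrix((vals, (rows, codes)), shape=(n, m))
            )
            comp_names.append(f"{factor}:{term}")
            comp_slices.append(slice(q, q + m))
            q += m
    Z = (
        sparse.hstack(blocks, format="csr")
        if blocks
        else sparse.csr_matrix((n, 0))
    )
    return DesignMatrices(
        y=y,
        X=X,
        fixed_names=list(spec.fixed_terms),
        component_names=comp_names,
        component_slices=comp_slices,
        Z=Z,
        factor_levels=factor_levels,
        scaling=scaling,
        spec=spec,
    )


class ConvergenceError(RuntimeError):
    """The REML/ML optimizer failed to converge; carries the trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class FitResult:
    """Estimates and diagnostics of one zcpLMM fit."""

    b: np.ndarray
    se: np.ndarray
    fixed_names: list[str]
    variance_components: dict[str, float]  # sigma_k^2 per "factor:term"
    residual_var: float
    criterion: str  # "REML" or "ML"
    deviance: float  # -2 * (restricted) log-likelihood at the optimum
    n_obs: int
    n_fixed: int
    fitted: np.ndarray
    residuals: np.ndarray
    ranef: dict[str, np.ndarray]  # BLUPs per component (original scale)
    cov_b: np.ndarray
    n_iter: int
    n_eval: int
    converged: bool
    design: DesignMatrices | None = None

    @property
    def t(self) -> np.ndarray:
        return self.b / self.se

    @property
    def n_params(self) -> int:
        """Count of estimated parameters: fixed effects + variance
        components + the residual variance."""
        return self.n_fixed + len(self.variance_components) + 1

    def fixed_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.fixed_names, "b": self.b, "SE": self.se, "t": self.t}
        )


class _ProfiledDeviance:
    """Profiled REML/ML deviance as a function of the relative SDs lambda."""

    def __init__(self, dm: DesignMatrices, criterion: str):
        X, y, Z = dm.X, dm.y, dm.Z
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.criterion = criterion
        self.slices = dm.component_slices
        self.ZtZ = np.asarray((Z.T @ Z).todense()) if self.q else np.zeros((0, 0))
        self.ZtX = np.asarray(Z.T @ X) if self.q else np.zeros((0, self.p))
        self.Zty = np.asarray(Z.T @ y).ravel() if self.q else np.zeros(0)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def expand(self, lam_k: np.ndarray) -> np.ndarray:
        lam = np.empty(self.q)
        for lk, sl in zip(lam_k, self.slices):
            lam[sl] = lk
        return lam

    def solve(self, lam_k: np.ndarray):
        if self.q == 0:
            cS = linalg.cho_factor(self.XtX, lower=True, check_finite=False)
            b = linalg.cho_solve(cS, self.Xty, check_finite=False)
            pwrss = max(self.yty - b @ self.Xty, np.finfo(float).tiny)
            return dict(
                lam=np.zeros(0), b=b, u=np.zeros(0), pwrss=pwrss,
                logdet_A=0.0, logdet_S=2.0 * np.sum(np.log(np.diag(cS[0]))), cS=cS,
            )
        lam = self.expand(np.maximum(lam_k, 0.0))
        A = self.ZtZ * lam[:, None] * lam[None, :]
        A[np.diag_indices_from(A)] += 1.0
        cA = linalg.cho_factor(A, lower=True, check_finite=False)
        logdet_A = 2.0 * np.sum(np.log(np.diag(cA[0])))
        B = lam[:, None] * self.ZtX
        c = lam * self.Zty
        W = linalg.cho_solve(cA, B, check_finite=False)
        v = linalg.cho_solve(cA, c, check_finite=False)
        S = self.XtX - B.T @ W
        cS = linalg.cho_factor(S, lower=True, check_finite=False)
        logdet_S = 2.0 * np.sum(np.log(np.diag(cS[0])))
        b = linalg.cho_solve(cS, self.Xty - B.T @ v, check_finite=False)
        u = v - W @ b
        pwrss = self.yty - b @ self.Xty - u @ c
        pwrss = max(pwrss, np.finfo(float).tiny)
        return dict(
            lam=lam, b=b, u=u, pwrss=pwrss, logdet_A=logdet_A, logdet_S=logdet_S, cS=cS
        )

    def deviance(self, lam_k: np.ndarray) -> float:
        s = self.solve(lam_k)
        n, p = self.n, self.p
        if self.criterion == "REML":
            return s["logdet_A"] + s["logdet_S"] + (n - p) * (
                1.0 + np.log(2.0 * np.pi * s["pwrss"] / (n - p))
            )
        return s["logdet_A"] + n * (1.0 + np.log(2.0 * np.pi * s["pwrss"] / n))


def fit_zcplmm(
    dm: DesignMatrices,
    criterion: str = "REML",
    start: np.ndarray | None = None,
    max_eval: int = 50_000,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the zcpLMM by profiled REML or ML.

    Variance components are parameterized as relative standard deviations
    (bounded below by zero), so components may converge to exactly zero.
    Raises :class:`ConvergenceError` if the bounded quasi-Newton optimizer
    reports failure, and a singular-design ``LinAlgError`` if the fixed
    part is rank-deficient.
    """
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be 'REML' or 'ML'")
    n, p = dm.X.shape
    if n <= p:
        raise ValueError(f"n_obs ({n}) must exceed the number of fixed effects ({p})")
    prof = _ProfiledDeviance(dm, criterion)
    K = len(dm.component_slices)

    if K == 0:
        lam_opt = np.zeros(0)
        res_nit, res_nfev, success = 0, 1, True
    else:
        x0 = np.full(K, 0.5) if start is None else np.asarray(start, dtype=float)
        res = optimize.minimize(
            prof.deviance,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * K,
            options={"maxfun": max_eval, "ftol": tol, "gtol": 1e-9},
        )
        lam_opt = np.maximum(res.x, 0.0)
        res_nit, res_nfev = res.nit, res.nfev
        success = bool(res.success)
        if not success:
            # a line-search breakdown at an interior optimum still yields a
            # usable solution; only treat budget exhaustion as fatal
            if res_nfev >= max_eval:
                raise ConvergenceError(
                    f"zcpLMM did not converge in {max_eval} evaluations", trace=res
                )
            warnings.warn(
                f"optimizer stopped early ({res.message}); using best point",
                RuntimeWarning,
                stacklevel=2,
            )

    s = prof.solve(lam_opt)
    dev = prof.deviance(lam_opt)
    denom = n - p if criterion == "REML" else n
    sigma2_e = s["pwrss"] / denom
    var_comp = {
        name: float(lam_opt[k] ** 2 * sigma2_e)
        for k, name in enumerate(dm.component_names)
    }
    cov_b = sigma2_e * linalg.cho_solve(s["cS"], np.eye(p), check_finite=False)
    se = np.sqrt(np.diag(cov_b))
    u_orig = s["lam"] * s["u"] if prof.q else np.zeros(0)
    fitted = dm.X @ s["b"] + (dm.Z @ u_orig if prof.q else 0.0)
    ranef = {
        name: u_orig[sl] for name, sl in zip(dm.component_names, dm.component_slices)
    }
    return FitResult(
        b=s["b"],
        se=se,
        fixed_names=dm.fixed_names,
        variance_components=var_comp,
        residual_var=float(sigma2_e),
        criterion=criterion,
        deviance=float(dev),
        n_obs=n,
        n_fixed=p,
        fitted=fitted,
        residuals=dm.y - fitted,
        ranef=ranef,
        cov_b=cov_b,
        n_iter=res_nit,
        n_eval=res_nfev,
        converged=success,
        design=dm,
    )


def fixed_effect_tests(fit: FitResult) -> pd.DataFrame:
    """Label each coefficient: significant (|t| > 1.96), marginal
    (1.645 < |t| <= 1.96), else nonsignificant."""
    t = np.abs(fit.t)
    label = np.where(
        t > 1.96, "significant", np.where(t > 1.645, "marginal", "nonsignificant")
    )
    out = fit.fixed_table()
    out["label"] = label
    return out


@dataclass(frozen=True)
class R2Pair:
    """Marginal (fixed-effects) and conditional (fixed + random) R^2."""

    marginal: float
    conditional: float

    def __post_init__(self):
        if not (0 <= self.marginal <= self.conditional <= 1):
            raise ValueError("require 0 <= marginal <= conditional <= 1")


def r2_lmm(fit: FitResult) -> R2Pair:
    """Marginal and conditional R^2 for the mixed model.

    Fixed-effect variance is the population variance of X b; the
    slope-aware random-effect variance is the observation-averaged diagonal
    of the random-effect covariance projected through Z (for independent
    components: sum_k sigma_k^2 * mean(z_k^2)).
    """
    dm = fit.design
    if dm is None:
        raise ValueError("fit carries no design (needed for R^2)")
    var_f = float(np.var(dm.X @ fit.b))
    var_r = 0.0
    for name, sl in zip(dm.component_names, dm.component_slices):
        zcol = dm.Z[:, sl]
        mean_z2 = float(zcol.multiply(zcol).sum() / dm.n_obs)
        var_r += fit.variance_components[name] * mean_z2
    total = var_f + var_r + fit.residual_var
    return R2Pair(marginal=var_f / total, conditional=(var_f + var_r) / total)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio test and BIC comparison of two nested ML fits."""

    lrt_chi2: float
    df: int
    p: float
    bic_full: float
    bic_reduced: float


def compare_models(full: FitResult, reduced: FitResult) -> ModelComparison:
    """LRT (chi^2 reference) and BIC for nested ML-fitted models.

    Both fits must use the ML criterion on the identical rows; the reduced
    model's fixed terms and variance components must nest in the full
    model's.  BIC = deviance + k * ln(n) with k counting fixed effects,
    variance components, and the residual variance.
    """
    from scipy.stats import chi2 as chi2_dist

    if full.criterion != "ML" or reduced.criterion != "ML":
        raise ValueError("model comparison requires ML fits")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fit on different numbers of observations")
    if not set(reduced.fixed_names) <= set(full.fixed_names):
        raise ValueError("reduced fixed effects do not nest in the full model")
    if not set(reduced.variance_components) <= set(full.variance_components):
        raise ValueError("reduced random structure does not nest in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than the reduced model")
    chi2 = max(reduced.deviance - full.deviance, 0.0)
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else 1.0
    logn = np.log(full.n_obs)
    return ModelComparison(
        lrt_chi2=float(chi2),
        df=int(df),
        p=p,
        bic_full=float(full.deviance + full.n_params * logn),
        bic_reduced=float(reduced.deviance + reduced.n_params * logn),
    )
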