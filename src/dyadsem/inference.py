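"""Fitting and testing maternal/fetal path models.

The central object is :class:`MaternalFetalSEM`, a scikit-learn style
estimator wrapping maximum-likelihood optimisation of the path model in
:mod:`dyadsem.sem_core`.  It accepts either a per-individual table (raw
full-information likelihood) or a list of per-pattern covariance summaries
(equivalent and ~100x faster), and exposes estimates, standard errors and the
-2 log-likelihood as fitted attributes.

Model variants are chosen with two flags (free maternal path, free fetal
path), giving the full model, the two single-path reductions and the null
model used by the 2-degree-of-freedom omnibus test.  Wald tests come from the
inverse numerical Hessian at the optimum; likelihood-ratio tests compare
nested fits.  Comparator ordinary-least-squares regressions of each phenotype
on dosage — the design used by standard genetic association studies, biased
whenever the other path is nonzero — and a two-estimate Cochran-Q/I²
heterogeneity test round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from . import sem_core
from .sem_core import (
    BOTH,
    BW,
    BWO,
    OFFSPRING_ONLY,
    OWN_ONLY,
    SNP,
    GroupSummary,
    InvalidParameterError,
    PathModelParams,
    neg2_loglik_cov,
    neg2_loglik_raw,
    summaries_from_data,
)

__all__ = [
    "ModelSpec",
    "FULL",
    "FETAL_ONLY",
    "MATERNAL_ONLY",
    "NULL",
    "FitResult",
    "TestResult",
    "MaternalFetalSEM",
    "NotConvergedError",
    "fit_model",
    "wald_test",
    "lrt",
    "two_df_test",
    "linear_model_effects",
    "LinearEffect",
    "heterogeneity_i2",
    "summary_stats_to_group",
]


class NotConvergedError(RuntimeError):
    """No optimisation attempt converged with a usable Hessian."""


@dataclass(frozen=True)
class ModelSpec:
    """Which path coefficients are freely estimated."""

    free_maternal: bool = True
    free_fetal: bool = True

    @property
    def n_paths(self) -> int:
        return int(self.free_maternal) + int(self.free_fetal)

    def nests(self, other: "ModelSpec") -> bool:
        """True if ``other`` is nested within (a restriction of) this spec."""
        return (other.free_maternal <= self.free_maternal) and (
            other.free_fetal <= self.free_fetal
        )


FULL = ModelSpec(free_maternal=True, free_fetal=True)
FETAL_ONLY = ModelSpec(free_maternal=False, free_fetal=True)
MATERNAL_ONLY = ModelSpec(free_maternal=True, free_fetal=False)
NULL = ModelSpec(free_maternal=False, free_fetal=False)


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: PathModelParams
    se_m: float | None
    se_f: float | None
    neg2ll: float
    converged: bool
    n_restarts_used: int
    n_obs: int
    param_names: tuple[str, ...] = ()
    cov_params: np.ndarray | None = None


@dataclass
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# parameter layout: free-parameter vector <-> PathModelParams
# ---------------------------------------------------------------------------


class _ParamLayout:
    """Maps the optimizer's working vector onto :class:`PathModelParams`.

    Variance parameters are optimized on the log scale to enforce positivity;
    the residual covariance is unconstrained with positive definiteness
    checked at each objective evaluation.  Parameters of variables never
    observed in any supplied group, and the residual covariance when no group
    observes both phenotypes, are excluded (structurally inestimable).
    """

    def __init__(self, spec: ModelSpec, groups: list[GroupSummary]):
        observed = set()
        for g in groups:
            observed.update(g.pattern.observed_variables)
        self.has_bw = BW in observed
        self.has_bwo = BWO in observed
        self.has_both_group = any(g.pattern.label == "both" for g in groups)
        names: list[str] = []
        if spec.free_maternal:
            names.append("m")
        if spec.free_fetal:
            names.append("f")
        names.append("log_phi")
        if self.has_bw:
            names.append("log_var_e")
        if self.has_bwo:
            names.append("log_var_eo")
        if self.has_both_group:
            names.append("rho")
        if self.has_bw:
            names.append("mu_bw")
        if self.has_bwo:
            names.append("mu_bwo")
        names.append("mu_snp")
        self.names = tuple(names)
        self.spec = spec

    @property
    def size(self) -> int:
        return len(self.names)

    def to_params(self, x: np.ndarray) -> PathModelParams:
        d = dict(zip(self.names, x))
        return PathModelParams(
            m=d.get("m", 0.0),
            f=d.get("f", 0.0),
            phi=math.exp(d["log_phi"]),
            var_e=math.exp(d.get("log_var_e", 0.0)),
            var_eo=math.exp(d.get("log_var_eo", 0.0)),
            rho=d.get("rho", 0.0),
            mu_bw=d.get("mu_bw", 0.0),
            mu_bwo=d.get("mu_bwo", 0.0),
            mu_snp=d["mu_snp"],
        )

    def to_vector(self, params: PathModelParams) -> np.ndarray:
        lookup = {
            "m": params.m,
            "f": params.f,
            "log_phi": math.log(params.phi),
            "log_var_e": math.log(params.var_e),
            "log_var_eo": math.log(params.var_eo),
            "rho": params.rho,
            "mu_bw": params.mu_bw,
            "mu_bwo": params.mu_bwo,
            "mu_snp": params.mu_snp,
        }
        return np.array([lookup[n] for n in self.names])


def moment_match(groups: list[GroupSummary], spec: ModelSpec = FULL) -> PathModelParams:
    """Method-of-moments parameter point used to initialise the optimizer.

    For a single complete-data group and the full model this is the ML
    solution itself (the model is just-identified); otherwise it is a sensible
    starting point built from pooled sample moments.
    """

    def _entry(g: GroupSummary, a: str, b: str) -> float:
        va = g.pattern.observed_variables
        return float(g.sample_cov[va.index(a), va.index(b)])

    w_total = sum(g.n for g in groups)
    phi = sum(g.n * _entry(g, SNP, SNP) for g in groups) / w_total
    phi = max(phi, 1e-8)

    # genotype-phenotype covariances scaled by phi: a = f + m/2, b = m + f/2
    a_groups = [g for g in groups if BW in g.pattern.observed_variables]
    b_groups = [g for g in groups if BWO in g.pattern.observed_variables]
    a = (
        sum(g.n * _entry(g, BW, SNP) for g in a_groups)
        / sum(g.n for g in a_groups)
        / phi
        if a_groups
        else None
    )
    b = (
        sum(g.n * _entry(g, BWO, SNP) for g in b_groups)
        / sum(g.n for g in b_groups)
        / phi
        if b_groups
        else None
    )
    m = f = 0.0
    if spec.free_fetal and spec.free_maternal:
        if a is not None and b is not None:
            f = (4.0 * a - 2.0 * b) / 3.0
            m = (4.0 * b - 2.0 * a) / 3.0
        elif a is not None:
            f = a
        elif b is not None:
            m = b
    elif spec.free_fetal:
        f = a if a is not None else (2.0 * b if b is not None else 0.0)
    elif spec.free_maternal:
        m = b if b is not None else (2.0 * a if a is not None else 0.0)

    gvar = phi * (m * m + f * f + m * f)
    var_e = var_eo = 1.0
    mu_bw = mu_bwo = 0.0
    if a_groups:
        vbw = sum(g.n * _entry(g, BW, BW) for g in a_groups) / sum(
            g.n for g in a_groups
        )
        var_e = max(vbw - gvar, 0.05 * vbw)
        mu_bw = sum(
            g.n * g.sample_mean[g.pattern.observed_variables.index(BW)]
            for g in a_groups
        ) / sum(g.n for g in a_groups)
    if b_groups:
        vbwo = sum(g.n * _entry(g, BWO, BWO) for g in b_groups) / sum(
            g.n for g in b_groups
        )
        var_eo = max(vbwo - gvar, 0.05 * vbwo)
        mu_bwo = sum(
            g.n * g.sample_mean[g.pattern.observed_variables.index(BWO)]
            for g in b_groups
        ) / sum(g.n for g in b_groups)
    rho = 0.0
    both_groups = [g for g in groups if g.pattern.label == "both"]
    if both_groups:
        cbb = sum(g.n * _entry(g, BW, BWO) for g in both_groups) / sum(
            g.n for g in both_groups
        )
        rho = cbb - phi * ((m * m + f * f) / 2.0 + 1.25 * m * f)
        cap = 0.95 * math.sqrt(var_e * var_eo)
        rho = max(-cap, min(cap, rho))
    mu_snp = sum(
        g.n * g.sample_mean[g.pattern.observed_variables.index(SNP)] for g in groups
    ) / w_total
    return PathModelParams(
        m=m, f=f, phi=phi, var_e=var_e, var_eo=var_eo, rho=rho,
        mu_bw=mu_bw, mu_bwo=mu_bwo, mu_snp=mu_snp,
    )


# jitter scale per working parameter for multi-start restarts
_JITTER = {
    "m": 0.05, "f": 0.05, "rho": 0.1,
    "log_phi": 0.2, "log_var_e": 0.2, "log_var_eo": 0.2,
    "mu_bw": 0.1, "mu_bwo": 0.1, "mu_snp": 0.1,
}

_PENALTY = 1e10
_HESS_STEP = 1e-4


def _central_hessian(fun, x: np.ndarray, h: float = _HESS_STEP) -> np.ndarray:
    """Central-difference Hessian with a fixed step on the working scale."""
    k = len(x)
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        hess[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / (h * h)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h * h)
    return hess


class MaternalFetalSEM(BaseEstimator):
    """Maximum-likelihood path model for maternal and fetal genetic effects.

    Parameters
    ----------
    free_maternal, free_fetal
        Whether the maternal / fetal path coefficient is freely estimated
        (fixed at zero otherwise).  Both free gives the full model; both
        fixed gives the null model of the 2-degree-of-freedom omnibus test.
    restarts
        Maximum optimisation attempts.  The first starts from a
        method-of-moments point; later attempts jitter it.  Attempts stop at
        the first fit that converges with an invertible Hessian.
    method
        ``"cov"`` fits from per-pattern covariance summaries (default, fast);
        ``"raw"`` evaluates the per-record full-information likelihood.
        Both yield the same estimates.
    random_state
        Seed for the restart jitter.

    Attributes
    ----------
    m_, f_ : float
        Estimated maternal and fetal path coefficients.
    se_m_, se_f_ : float or None
        Wald standard errors (None for paths fixed at zero).
    params_ : PathModelParams
        All parameter estimates.
    neg2ll_ : float
        -2 log-likelihood at the optimum.
    converged_ : bool
    n_restarts_used_ : int

    Examples
    --------
    >>> from dyadsem.simulate import ScenarioConfig, simulate_dataset
    >>> data = simulate_dataset(ScenarioConfig(v_fetal=0.0004, seed=7))
    >>> sem = MaternalFetalSEM().fit(data)
    >>> abs(sem.f_ - 0.02) < 3 * sem.se_f_
    True
    """

    def __init__(
        self,
        free_maternal: bool = True,
        free_fetal: bool = True,
        restarts: int = 10,
        method: str = "cov",
        random_state: int | None = None,
    ):
        self.free_maternal = free_maternal
        self.free_fetal = free_fetal
        self.restarts = restarts
        self.method = method
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _objective(self, layout: _ParamLayout, data, groups):
        if self.method == "raw":
            def fun(x: np.ndarray) -> float:
                try:
                    return neg2_loglik_raw(layout.to_params(x), data)
                except (InvalidParameterError, np.linalg.LinAlgError, ValueError):
                    return _PENALTY
        else:
            def fun(x: np.ndarray) -> float:
                try:
                    return neg2_loglik_cov(layout.to_params(x), groups)
                except (InvalidParameterError, np.linalg.LinAlgError):
                    return _PENALTY
        return fun

    def fit(self, X, y=None) -> "MaternalFetalSEM":
        """Fit the model to a per-individual table or covariance summaries.

        Parameters
        ----------
        X
            Either a :class:`pandas.DataFrame` with columns ``bw``,
            ``bw_offspring``, ``dosage`` (NaN marking a missing phenotype; a
            ``pattern`` column is inferred if absent) or a list of
            :class:`dyadsem.sem_core.GroupSummary`.
        """
        if self.method not in ("cov", "raw"):
            raise ValueError("method must be 'cov' or 'raw'")
        data = None
        if isinstance(X, pd.DataFrame):
            from .io import infer_patterns

            data = infer_patterns(X)
            groups = summaries_from_data(data)
        else:
            groups = list(X)
            if not groups:
                raise ValueError("need at least one group")
            if self.method == "raw":
                raise ValueError("method='raw' requires a per-individual table")

        spec = ModelSpec(self.free_maternal, self.free_fetal)
        layout = _ParamLayout(spec, groups)
        fun = self._objective(layout, data, groups)
        x0 = layout.to_vector(moment_match(groups, spec))
        rng = np.random.default_rng(self.random_state)
        jitter = np.array([_JITTER[n] for n in layout.names])

        best = None
        attempts = 0
        for attempt in range(max(1, int(self.restarts))):
            attempts = attempt + 1
            start = x0 if attempt == 0 else x0 + jitter * rng.standard_normal(
                layout.size
            )
            res = optimize.minimize(
                fun,
                start,
                method="L-BFGS-B",
                options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-7},
            )
            if not np.isfinite(res.fun) or res.fun >= _PENALTY:
                continue
            if best is None or res.fun < best.fun - 1e-9:
                cand = self._finalize(res, layout, fun)
                if cand is not None:
                    best = res
                    fitted = cand
                    if res.success:
                        break
        if best is None:
            raise NotConvergedError(
                f"no optimisation attempt converged in {attempts} restarts"
            )
        params, se, cov_params = fitted
        self.params_ = params
        self.m_ = params.m
        self.f_ = params.f
        self.se_m_ = se.get("m")
        self.se_f_ = se.get("f")
        self.neg2ll_ = float(best.fun)
        self.converged_ = bool(best.success)
        self.n_restarts_used_ = attempts
        self.n_obs_ = sum(g.n for g in groups)
        self.param_names_ = layout.names
        self.cov_params_ = cov_params
        self.layout_ = layout
        return self

    def _finalize(self, res, layout: _ParamLayout, fun):
        """Hessian-based standard errors; None signals an unusable optimum."""
        hess = _central_hessian(fun, res.x)
        try:
            cov = 2.0 * np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        diag = np.diag(cov)
        se: dict[str, float] = {}
        for name in ("m", "f"):
            if name in layout.names:
                v = diag[layout.names.index(name)]
                if not np.isfinite(v) or v <= 0:
                    return None
                se[name] = math.sqrt(v)
        return layout.to_params(res.x), se, cov

    @property
    def result_(self) -> FitResult:
        return FitResult(
            spec=ModelSpec(self.free_maternal, self.free_fetal),
            estimates=self.params_,
            se_m=self.se_m_,
            se_f=self.se_f_,
            neg2ll=self.neg2ll_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            n_obs=self.n_obs_,
            param_names=self.param_names_,
            cov_params=self.cov_params_,
        )


def fit_model(
    data_or_groups,
    spec: ModelSpec = FULL,
    restarts: int = 10,
    seed: int | None = None,
    method: str = "cov",
) -> FitResult:
    """Functional wrapper over :class:`MaternalFetalSEM`."""
    est = MaternalFetalSEM(
        free_maternal=spec.free_maternal,
        free_fetal=spec.free_fetal,
        restarts=restarts,
        method=method,
        random_state=seed,
    ).fit(data_or_groups)
    return est.result_


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def wald_test(fit: FitResult, which: str) -> TestResult:
    """Single-path Wald chi-square test, ``(estimate/SE)^2`` on 1 df."""
    if which == "maternal":
        if not fit.spec.free_maternal:
            raise ValueError("maternal path is not free in this fit")
        est, se, name = fit.estimates.m, fit.se_m, "wald_m"
    elif which == "fetal":
        if not fit.spec.free_fetal:
            raise ValueError("fetal path is not free in this fit")
        est, se, name = fit.estimates.f, fit.se_f, "wald_f"
    else:
        raise ValueError("which must be 'maternal' or 'fetal'")
    if se is None or not np.isfinite(se) or se <= 0:
        raise NotConvergedError(f"standard error unavailable for {which} path")
    statistic = (est / se) ** 2
    return TestResult(name, statistic, 1, float(stats.chi2.sf(statistic, 1)))


def lrt(full: FitResult, reduced: FitResult) -> TestResult:
    """Likelihood-ratio test of a nested path restriction.

    The statistic is floored at zero: a reduced model occasionally attains a
    numerically lower objective through optimizer noise.
    """
    if not full.spec.nests(reduced.spec) or full.spec == reduced.spec:
        raise ValueError("reduced spec must be strictly nested in full spec")
    df = full.spec.n_paths - reduced.spec.n_paths
    statistic = max(0.0, reduced.neg2ll - full.neg2ll)
    if df == 2:
        name = "two_df"
    elif full.spec.free_maternal and not reduced.spec.free_maternal:
        name = "lrt_m"
    else:
        name = "lrt_f"
    return TestResult(name, statistic, df, float(stats.chi2.sf(statistic, df)))


def two_df_test(full: FitResult, null: FitResult) -> TestResult:
    """Omnibus 2-df likelihood-ratio test of any genotype effect."""
    res = lrt(full, null)
    if res.df != 2:
        raise ValueError("two_df_test requires the both-paths-fixed null fit")
    return res


# ---------------------------------------------------------------------------
# comparators and auxiliary analyses
# ---------------------------------------------------------------------------


@dataclass
class LinearEffect:
    beta: float
    se: float
    p: float
    n: int


def linear_model_effects(data: pd.DataFrame) -> dict[str, LinearEffect]:
    """Unconditional OLS comparators for the fetal and maternal effects.

    Regresses own phenotype on dosage (``"fetal"`` entry) and offspring
    phenotype on dosage (``"maternal"`` entry), each on its available-case
    subset.  When both paths are active each slope is biased by half the
    other path (the dosage is correlated 1/2 with the untyped relative's
    genotype): E[fetal slope] = f + m/2 and E[maternal slope] = m + f/2.
    """
    out: dict[str, LinearEffect] = {}
    for label, pheno in (("fetal", BW), ("maternal", BWO)):
        sub = data[[pheno, SNP]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >=3 complete pairs for the {label} regression")
        x = sub[SNP].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("constant genotype column")
        model = sm.OLS(sub[pheno].to_numpy(dtype=float), sm.add_constant(x)).fit()
        out[label] = LinearEffect(
            beta=float(model.params[1]),
            se=float(model.bse[1]),
            p=float(model.pvalues[1]),
            n=len(sub),
        )
    return out


def heterogeneity_i2(
    b1: float, se1: float, b2: float, se2: float
) -> tuple[float, float, float]:
    """Cochran's Q and I² for two estimates of the same quantity.

    Inverse-variance weights; ``Q = sum w (b - bbar)^2``,
    ``I² = max(0, (Q-1)/Q) * 100`` percent, p from chi-square on 1 df.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    bbar = (w1 * b1 + w2 * b2) / (w1 + w2)
    q = w1 * (b1 - bbar) ** 2 + w2 * (b2 - bbar) ** 2
    i2 = max(0.0, (q - 1.0) / q) * 100.0 if q > 0 else 0.0
    return q, i2, float(stats.chi2.sf(q, 1))


def summary_stats_to_group(
    eaf: float, beta: float, pheno_var: float, n: int, which: str
) -> GroupSummary:
    """Rebuild a covariance-summary group from unconditional GWAS statistics.

    A cohort that can only share (effect-allele frequency, regression slope of
    a standardized phenotype on dosage, phenotype variance, N) contributes a
    2-variable group: own phenotype + dosage for ``"fetal_arm"`` cohorts,
    offspring phenotype + dosage for ``"maternal_arm"`` cohorts.  Fitted
    jointly with other groups these share (m, f, phi) and so raise precision.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError("effect-allele frequency must lie strictly in (0, 1)")
    if pheno_var <= 0:
        raise ValueError("phenotype variance must be positive")
    if n < 3:
        raise ValueError("n must be at least 3")
    var_snp = 2.0 * eaf * (1.0 - eaf)
    cov = beta * var_snp
    r2 = cov * cov / (var_snp * pheno_var)
    if r2 >= 1.0:
        raise ValueError("summary statistics imply |correlation| >= 1")
    if which == "fetal_arm":
        pattern = OWN_ONLY
    elif which == "maternal_arm":
        pattern = OFFSPRING_ONLY
    else:
        raise ValueError("which must be 'fetal_arm' or 'maternal_arm'")
    return GroupSummary(
        pattern=pattern,
        n=int(n),
        sample_mean=np.array([0.0, 2.0 * eaf]),
        sample_cov=np.array([[pheno_var, cov], [cov, var_snp]]),
    )
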