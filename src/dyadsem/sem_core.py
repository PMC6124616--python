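"""Path model linking maternal and fetal genotypes to birthweight.

The model has three observed variables per genotyped individual: their own
birthweight (``bw``), the birthweight of their first offspring
(``bw_offspring``) and their allele dosage at one biallelic variant
(``dosage``).  Two latent genotypes — the individual's mother's (grand-maternal)
genotype and the offspring's genotype — are connected to the observed dosage by
Mendelian transmission paths fixed at 1/2.  A maternal path coefficient ``m``
carries a genotype's effect onto the phenotype of that person's offspring, and
a fetal path coefficient ``f`` carries a genotype's effect onto that person's
own phenotype.  All genotype variables share a common variance ``phi``.

With those constraints the genotype covariances are
``Cov(G_grandmother, SNP) = Cov(SNP, G_offspring) = phi/2`` and
``Cov(G_grandmother, G_offspring) = phi/4``, and path tracing gives the
model-implied moments coded in :func:`implied_moments`.

Individuals may be observed on only one of the two phenotypes.  Each record
then contributes the multivariate-normal likelihood of exactly its observed
subvector (full-information maximum likelihood); equivalently the sample can be
split into homogeneous observation-pattern groups and fitted from per-group
means and covariance matrices, which is much faster and yields the same
estimates.  Both objectives live here; optimisation lives in
:mod:`dyadsem.inference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BW",
    "BWO",
    "SNP",
    "BOTH",
    "OWN_ONLY",
    "OFFSPRING_ONLY",
    "PATTERNS",
    "InvalidParameterError",
    "ObservationPattern",
    "PathModelParams",
    "ImpliedMoments",
    "GroupSummary",
    "implied_moments",
    "neg2_loglik_raw",
    "neg2_loglik_cov",
    "summaries_from_data",
]

# Canonical variable names/order used throughout the package.
BW = "bw"
BWO = "bw_offspring"
SNP = "dosage"
_FULL_ORDER = (BW, BWO, SNP)


class InvalidParameterError(ValueError):
    """Parameter point whose implied covariance matrix is not positive definite."""


@dataclass(frozen=True)
class ObservationPattern:
    """Which variables a subset of individuals is observed on.

    The dosage is always observed; only the two phenotypes can be missing.
    """

    label: str
    observed_variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if SNP not in self.observed_variables:
            raise ValueError("dosage must always be observed")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(_FULL_ORDER.index(v) for v in self.observed_variables)

    @property
    def k(self) -> int:
        return len(self.observed_variables)


BOTH = ObservationPattern("both", (BW, BWO, SNP))
OWN_ONLY = ObservationPattern("own_only", (BW, SNP))
OFFSPRING_ONLY = ObservationPattern("offspring_only", (BWO, SNP))
PATTERNS = {p.label: p for p in (BOTH, OWN_ONLY, OFFSPRING_ONLY)}


@dataclass
class PathModelParams:
    """Free parameters of the path model.

    Parameters
    ----------
    m, f
        Maternal and fetal path coefficients, in phenotype-SD units per unit
        of genotype SD when dosages are standardized.
    phi
        Variance of each genotype variable (observed and latent); ``2p(1-p)``
        for an unstandardized biallelic dosage, ~1 after standardization.
    var_e, var_eo
        Residual variances of own and offspring phenotype.  These absorb all
        non-modelled (shared and unique) sources of variation.
    rho
        Covariance between the two phenotype residuals, capturing residual
        genetic/environmental mother-offspring similarity.
    mu_bw, mu_bwo, mu_snp
        Means of the three observed variables.
    """

    m: float = 0.0
    f: float = 0.0
    phi: float = 1.0
    var_e: float = 1.0
    var_eo: float = 1.0
    rho: float = 0.0
    mu_bw: float = 0.0
    mu_bwo: float = 0.0
    mu_snp: float = 0.0

    def validate(self) -> None:
        if not (self.phi > 0 and self.var_e > 0 and self.var_eo > 0):
            raise InvalidParameterError(
                "phi, var_e and var_eo must all be strictly positive"
            )
        if abs(self.rho) > math.sqrt(self.var_e * self.var_eo):
            raise InvalidParameterError(
                "|rho| exceeds sqrt(var_e * var_eo); residual covariance invalid"
            )

    def copy(self) -> "PathModelParams":
        return replace(self)


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied mean vector and covariance matrix for one pattern."""

    pattern: ObservationPattern
    mean: np.ndarray
    cov: np.ndarray


def _implied_full(params: PathModelParams) -> tuple[np.ndarray, np.ndarray]:
    m, f, phi = params.m, params.f, params.phi
    gvar = phi * (m * m + f * f + m * f)
    cov = np.array(
        [
            [gvar + params.var_e,
             phi * ((m * m + f * f) / 2.0 + 1.25 * m * f) + params.rho,
             phi * (f + m / 2.0)],
            [0.0, gvar + params.var_eo, phi * (m + f / 2.0)],
            [0.0, 0.0, phi],
        ]
    )
    cov[1, 0] = cov[0, 1]
    cov[2, 0] = cov[0, 2]
    cov[2, 1] = cov[1, 2]
    mean = np.array([params.mu_bw, params.mu_bwo, params.mu_snp])
    return mean, cov


def implied_moments(
    params: PathModelParams, pattern: ObservationPattern = BOTH
) -> ImpliedMoments:
    """Model-implied moments of the observed variables under ``pattern``.

    Closed forms (derived by path tracing with transmission paths fixed at
    1/2)::

        Var(BW)       = phi (m^2 + f^2 + m f) + var_e
        Var(BW_O)     = phi (m^2 + f^2 + m f) + var_eo
        Var(SNP)      = phi
        Cov(BW, SNP)  = phi (f + m/2)
        Cov(BW_O,SNP) = phi (m + f/2)
        Cov(BW, BW_O) = phi ((m^2 + f^2)/2 + (5/4) m f) + rho

    Reduced patterns return the corresponding subvector/submatrix.

    Raises
    ------
    InvalidParameterError
        If the implied covariance matrix is not positive definite.
    """
    params.validate()
    mean, cov = _implied_full(params)
    idx = np.asarray(pattern.indices)
    sub_mean = mean[idx]
    sub_cov = cov[np.ix_(idx, idx)]
    try:
        np.linalg.cholesky(sub_cov)
    except np.linalg.LinAlgError:
        raise InvalidParameterError(
            f"implied covariance for pattern {pattern.label!r} is not positive definite"
        ) from None
    return ImpliedMoments(pattern=pattern, mean=sub_mean, cov=sub_cov)


@dataclass
class GroupSummary:
    """Sufficient statistics for one observation-pattern group.

    ``sample_cov`` uses the maximum-likelihood (divide-by-n) convention so that
    the covariance objective reproduces the raw-data likelihood exactly.
    """

    pattern: ObservationPattern
    n: int
    sample_mean: np.ndarray
    sample_cov: np.ndarray

    def __post_init__(self) -> None:
        self.sample_mean = np.asarray(self.sample_mean, dtype=float)
        self.sample_cov = np.asarray(self.sample_cov, dtype=float)
        k = self.pattern.k
        if self.sample_mean.shape != (k,) or self.sample_cov.shape != (k, k):
            raise ValueError(
                f"summary dimensions do not match pattern {self.pattern.label!r}"
            )
        if self.n < k + 1:
            raise ValueError(
                f"group of pattern {self.pattern.label!r} needs n >= {k + 1}, got {self.n}"
            )
        if not np.allclose(self.sample_cov, self.sample_cov.T):
            raise ValueError("sample covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(self.sample_cov)[0]
        if eigmin < -1e-8 * max(1.0, np.abs(self.sample_cov).max()):
            raise ValueError("sample covariance must be positive semi-definite")


_LOG2PI = math.log(2.0 * math.pi)


def neg2_loglik_raw(params: PathModelParams, data: pd.DataFrame) -> float:
    """-2 log-likelihood of per-individual records under the path model.

    Each record contributes the log multivariate-normal density of exactly its
    observed subvector (its 2-variable marginal for the reduced patterns), so
    no case is dropped for partial missingness.

    ``data`` must carry a ``pattern`` column labelling each row (see
    :func:`dyadsem.io.infer_patterns`).
    """
    if "pattern" not in data.columns:
        raise ValueError("data must carry a 'pattern' column")
    if len(data) == 0:
        raise ValueError("data must contain at least one record")
    total = 0.0
    for label, block in data.groupby("pattern", sort=False):
        pattern = PATTERNS[str(label)]
        moments = implied_moments(params, pattern)
        x = block.loc[:, list(pattern.observed_variables)].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(
                f"missing values inside pattern {pattern.label!r} block"
            )
        logpdf = stats.multivariate_normal.logpdf(
            x, mean=moments.mean, cov=moments.cov
        )
        total += -2.0 * float(np.sum(logpdf))
    return total


def neg2_loglik_cov(
    params: PathModelParams, groups: list[GroupSummary] | tuple[GroupSummary, ...]
) -> float:
    """-2 log-likelihood from per-group means and ML covariance matrices.

    For each group with implied moments (mu, Sigma) and observed (xbar, S)::

        n * [ k log(2 pi) + log|Sigma| + tr(S Sigma^-1)
              + (xbar - mu)' Sigma^-1 (xbar - mu) ]

    summed over groups.  The constant is retained so the value coincides with
    :func:`neg2_loglik_raw` on the same data, not merely up to a constant.
    """
    if not groups:
        raise ValueError("at least one group is required")
    total = 0.0
    for g in groups:
        moments = implied_moments(params, g.pattern)
        chol = np.linalg.cholesky(moments.cov)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        # tr(S Sigma^-1) and Mahalanobis term via triangular solves
        sol = np.linalg.solve(moments.cov, g.sample_cov)
        trace = float(np.trace(sol))
        d = g.sample_mean - moments.mean
        maha = float(d @ np.linalg.solve(moments.cov, d))
        total += g.n * (g.pattern.k * _LOG2PI + logdet + trace + maha)
    return total


def summaries_from_data(data: pd.DataFrame) -> list[GroupSummary]:
    """Split records by observation pattern into :class:`GroupSummary` objects.

    Uses the ML (divide-by-n) covariance so that minimizing
    :func:`neg2_loglik_cov` over these summaries is exactly equivalent to
    minimizing :func:`neg2_loglik_raw` over the records.
    """
    if "pattern" not in data.columns:
        raise ValueError("data must carry a 'pattern' column")
    groups = []
    for label in ("both", "own_only", "offspring_only"):
        block = data[data["pattern"] == label]
        if len(block) == 0:
            continue
        pattern = PATTERNS[label]
        x = block.loc[:, list(pattern.observed_variables)].to_numpy(dtype=float)
        mean = x.mean(axis=0)
        xc = x - mean
        cov = (xc.T @ xc) / len(x)
        groups.append(
            GroupSummary(pattern=pattern, n=len(x), sample_mean=mean, sample_cov=cov)
        )
    if not groups:
        raise ValueError("no recognizable pattern groups in data")
    return groups
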