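"""Mother-offspring dyad simulator with known maternal/fetal effects.

Generates three generations of genotypes at one biallelic autosomal locus
under Hardy-Weinberg equilibrium and Mendelian transmission (grandmother ->
mother -> offspring, with independent fathers in each generation), then builds
the two phenotypes

    BW   = m * G_grandmother + f * SNP        + beta_u * U + eps
    BW_O = m * SNP           + f * G_offspring + beta_u * U + eps_o

where ``U ~ N(0,1)`` is shared within a family (residual genetic and
environmental mother-offspring similarity) and the residual variances are
chosen so each phenotype has unit variance asymptotically.  Effect sizes enter
as signed fractions of phenotypic variance: a scenario value ``v`` maps to
the path coefficient ``sign(v) * sqrt(|v|)``.

Optional degradations emulate survey data: classical (additive Gaussian)
measurement error parameterized by the R-squared of degraded-on-true
regression, rounding of the offspring phenotype to the nearest unit, and four
missing-completely-at-random designs in which half or all of the sample lacks
one of the two phenotypes.

The generated table keeps the hidden truth columns (latent genotypes and the
shared confounder) so every dataset can serve as its own oracle in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .sem_core import BW, BWO, SNP

__all__ = [
    "ScenarioConfig",
    "path_coefficient",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "add_classical_error",
    "discretize_offspring",
    "apply_missingness",
]

MISSING_DESIGNS = ("complete", "i", "ii", "iii", "iv")


def path_coefficient(v: float) -> float:
    """Signed square root mapping a variance fraction to a path coefficient."""
    return math.copysign(math.sqrt(abs(v)), v)


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    Defaults reproduce the base study conditions: 30 000 complete dyads,
    allele frequency 0.5, shared-confounder loading 0.5, clean phenotypes.

    ``v_fetal`` / ``v_maternal`` are signed fractions of phenotypic variance
    explained by the fetal and maternal paths (e.g. ``0.0004`` for 0.04%,
    negative for a decreasing effect).
    """

    n_families: int = 30_000
    allele_freq: float = 0.5
    v_fetal: float = 0.0
    v_maternal: float = 0.0
    beta_u: float = 0.5
    r2_own: float = 1.0
    r2_offspring: float = 1.0
    discretize_offspring: bool = False
    missing_design: str = "complete"
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie strictly between 0 and 1")
        if abs(self.v_fetal) > 1 or abs(self.v_maternal) > 1:
            raise ValueError("variance fractions must lie in [-1, 1]")
        if not (0.0 < self.r2_own <= 1.0 and 0.0 < self.r2_offspring <= 1.0):
            raise ValueError("measurement-error R^2 must lie in (0, 1]")
        if self.missing_design not in MISSING_DESIGNS:
            raise ValueError(
                f"missing_design must be one of {MISSING_DESIGNS}, "
                f"got {self.missing_design!r}"
            )
        if self.residual_variance <= 0.0:
            raise ValueError(
                "infeasible scenario: paths and confounder leave no residual variance"
            )

    @property
    def m(self) -> float:
        return path_coefficient(self.v_maternal)

    @property
    def f(self) -> float:
        return path_coefficient(self.v_fetal)

    @property
    def residual_variance(self) -> float:
        """Residual variance giving unit phenotype variance asymptotically."""
        m, f = path_coefficient(self.v_maternal), path_coefficient(self.v_fetal)
        return 1.0 - (m * m + f * f + m * f) - self.beta_u**2

    @property
    def true_rho(self) -> float:
        """Residual phenotype covariance induced by the shared confounder."""
        return self.beta_u * self.beta_u

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_genotypes(
    n: int, p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized dosages for grandmother, individual and offspring.

    Grandmaternal dosage is two Hardy-Weinberg alleles; each descendant
    receives one allele transmitted uniformly at random from their mother plus
    one allele from an independent Hardy-Weinberg father.  All three are
    centered at ``2p`` and scaled by ``sqrt(2p(1-p))``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly between 0 and 1")
    g_g = rng.binomial(2, p, size=n).astype(float)
    # transmitted allele is Bernoulli(g/2): certain for homozygotes, a coin
    # flip for heterozygotes
    snp = (rng.random(n) < g_g / 2.0).astype(float) + rng.binomial(1, p, size=n)
    g_o = (rng.random(n) < snp / 2.0).astype(float) + rng.binomial(1, p, size=n)
    scale = math.sqrt(2.0 * p * (1.0 - p))
    return tuple((x - 2.0 * p) / scale for x in (g_g, snp, g_o))


def simulate_phenotypes(
    genotypes: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build the dyad phenotypes from standardized genotype triples.

    Returns a complete-data table with observed columns (``bw``,
    ``bw_offspring``, ``dosage``) and hidden truth columns (``g_grandmother``,
    ``g_offspring``, ``u``).
    """
    g_g, snp, g_o = genotypes
    n = len(snp)
    m, f = config.m, config.f
    sd_resid = math.sqrt(config.residual_variance)
    u = rng.standard_normal(n)
    bw = m * g_g + f * snp + config.beta_u * u + sd_resid * rng.standard_normal(n)
    bwo = m * snp + f * g_o + config.beta_u * u + sd_resid * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "family_id": np.arange(n),
            BW: bw,
            BWO: bwo,
            SNP: snp,
            "pattern": "both",
            "g_grandmother": g_g,
            "g_offspring": g_o,
            "u": u,
        }
    )


def add_classical_error(
    values: np.ndarray, r2: float, rng: np.random.Generator
) -> np.ndarray:
    """Degrade measurements with additive Gaussian noise of a target R².

    The noise variance solves ``r2 = Var(x) / (Var(x) + Var(noise))`` using
    the empirical variance of ``values``; ``r2 = 1`` returns the input
    unchanged.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    if r2 == 1.0:
        return values
    noise_var = np.var(values) * (1.0 - r2) / r2
    return values + math.sqrt(noise_var) * rng.standard_normal(values.shape)


def discretize_offspring(values: np.ndarray) -> np.ndarray:
    """Round phenotype values to the nearest integer on their current scale.

    On a unit-variance scale this leaves roughly six occupied categories,
    emulating offspring birthweight reported to the nearest pound.
    """
    return np.round(np.asarray(values, dtype=float))


def apply_missingness(
    data: pd.DataFrame, design: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Mask phenotypes completely at random according to a named design.

    Designs (fractions of the sample):

    - ``complete``: no masking, all records pattern ``both``
    - ``i``:   1/2 both + 1/2 own phenotype only
    - ``ii``:  1/2 both + 1/2 offspring phenotype only
    - ``iii``: 1/2 both + 1/4 own only + 1/4 offspring only
    - ``iv``:  1/2 own only + 1/2 offspring only (no overlap; the residual
      covariance is then structurally inestimable)

    Assignment is by fixed index blocks after a seeded shuffle.
    """
    if design not in MISSING_DESIGNS:
        raise ValueError(f"unknown missingness design {design!r}")
    data = data.copy()
    if design == "complete":
        data["pattern"] = "both"
        return data
    n = len(data)
    order = rng.permutation(n)
    half, quarter = n // 2, n // 4
    if design == "i":
        blocks = [("both", order[:half]), ("own_only", order[half:])]
    elif design == "ii":
        blocks = [("both", order[:half]), ("offspring_only", order[half:])]
    elif design == "iii":
        blocks = [
            ("both", order[:half]),
            ("own_only", order[half : half + quarter]),
            ("offspring_only", order[half + quarter :]),
        ]
    else:  # iv
        blocks = [("own_only", order[:half]), ("offspring_only", order[half:])]
    pattern = np.empty(n, dtype=object)
    for label, idx in blocks:
        pattern[idx] = label
    data["pattern"] = pattern
    bw = data[BW].to_numpy(dtype=float, copy=True)
    bwo = data[BWO].to_numpy(dtype=float, copy=True)
    bw[pattern == "offspring_only"] = np.nan
    bwo[pattern == "own_only"] = np.nan
    data[BW] = bw
    data[BWO] = bwo
    return data


def simulate_dataset(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One full draw: genotypes, phenotypes, degradation and missingness.

    All randomness flows from ``config.seed`` when ``rng`` is not supplied, so
    identical configs reproduce identical tables bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config.n_families, config.allele_freq, rng)
    data = simulate_phenotypes(genotypes, config, rng)
    if config.r2_own < 1.0:
        data[BW] = add_classical_error(data[BW].to_numpy(), config.r2_own, rng)
    if config.r2_offspring < 1.0:
        data[BWO] = add_classical_error(
            data[BWO].to_numpy(), config.r2_offspring, rng
        )
    if config.discretize_offspring:
        data[BWO] = discretize_offspring(data[BWO].to_numpy())
    data = apply_missingness(data, config.missing_design, rng)
    return data
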