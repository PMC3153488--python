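"""Exact population-genetic theory for marker–QTL association in admixed populations.

This module works entirely at the population level (no sampling): two-locus
joint genotype distributions under random mating, linkage-disequilibrium (LD)
moments of a two-way admixture, the decomposition of marker–trait covariance
into a genuine (within-subpopulation LD) part and a spurious (stratification)
part, the control-marker variance-inflation signal used to remove the spurious
part, theoretical regression coefficients for the association tests, and
noncentral-t power prediction for the slope test.

Notation
--------
A biallelic QTL with alleles A/a (frequency ``q`` of A) affects a quantitative
trait: genotypes AA, Aa, aa have means ``mu + d``, ``mu + h`` and ``mu - d``
with residual variance ``sigma2``.  A biallelic test marker T/t (frequency
``p`` of T) is scored as the count of allele T (0/1/2) and is in LD ``D`` with
the QTL.  A control marker C/c (frequency ``c``) is assumed unassociated with
both loci within each subpopulation.  The admixed population is an instant
mixture of two randomly mating subpopulations in proportions ``m`` and
``1 - m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "LocusPair",
    "QtlEffects",
    "SubpopulationModel",
    "AdmixtureSpec",
    "CovDecomposition",
    "PowerPrediction",
    "lewontin_bounds",
    "joint_genotype_distribution",
    "mixture_ld",
    "mixture_covariance",
    "marker_variance",
    "trait_variance",
    "control_covariances",
    "structure_variance_inflation",
    "theoretical_coefficient",
    "predict_power",
]


def lewontin_bounds(p: float, q: float) -> tuple[float, float]:
    """Range of admissible LD coefficients D for allele frequencies (p, q).

    The haplotype frequencies p*q + D, p*(1-q) - D, (1-p)*q - D and
    (1-p)*(1-q) + D must all be non-negative, giving
    ``-min(pq, (1-p)(1-q)) <= D <= min(p(1-q), (1-p)q)``.
    """
    return -min(p * q, (1 - p) * (1 - q)), min(p * (1 - q), (1 - p) * q)


def _check_open_unit(value: float, name: str) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie in the open interval (0, 1); got {value!r}")


@dataclass(frozen=True)
class LocusPair:
    """A test marker and a QTL segregating in one randomly mating population.

    Parameters
    ----------
    q : frequency of QTL allele A, in (0, 1).
    p : frequency of marker allele T, in (0, 1).
    D : LD coefficient between marker and QTL (haplotype frequency of TA
        minus ``p * q``), within the Lewontin bounds for (p, q).
    """

    q: float
    p: float
    D: float = 0.0

    def __post_init__(self) -> None:
        _check_open_unit(self.q, "q")
        _check_open_unit(self.p, "p")
        lo, hi = lewontin_bounds(self.p, self.q)
        eps = 1e-12
        if not (lo - eps <= self.D <= hi + eps):
            raise ValueError(
                f"LD coefficient D={self.D!r} violates the Lewontin bounds "
                f"[{lo:.6g}, {hi:.6g}] for p={self.p!r}, q={self.q!r}"
            )

    @property
    def Q(self) -> float:
        """P(marker allele T | QTL allele A) = (pq + D) / q."""
        return (self.p * self.q + self.D) / self.q

    @property
    def R(self) -> float:
        """P(marker allele T | QTL allele a) = (p(1-q) - D) / (1-q)."""
        return (self.p * (1 - self.q) - self.D) / (1 - self.q)


@dataclass(frozen=True)
class QtlEffects:
    """Genotypic means and residual variance of the trait model.

    AA, Aa and aa individuals have trait means ``mu + d``, ``mu + h`` and
    ``mu - d``; the residual (environmental) variance is ``sigma2``.
    """

    mu: float = 0.0
    d: float = 1.0
    h: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive; got {self.sigma2!r}")

    def genotypic_values(self) -> np.ndarray:
        """Trait means for QTL genotypes (AA, Aa, aa)."""
        return np.array([self.mu + self.d, self.mu + self.h, self.mu - self.d])


@dataclass(frozen=True)
class SubpopulationModel:
    """Allele frequencies and within-population LD of one source subpopulation.

    The control marker is assumed to be in linkage equilibrium with both the
    QTL and the test marker within each subpopulation; only its allele
    frequency ``c`` enters the theory.
    """

    q: float
    p: float
    c: float
    D: float = 0.0

    def __post_init__(self) -> None:
        _check_open_unit(self.q, "q")
        _check_open_unit(self.p, "p")
        _check_open_unit(self.c, "c")
        # delegate the LD bound check
        LocusPair(q=self.q, p=self.p, D=self.D)

    @property
    def locus_pair(self) -> LocusPair:
        return LocusPair(q=self.q, p=self.p, D=self.D)


@dataclass(frozen=True)
class AdmixtureSpec:
    """Full parametric description of a two-way admixed study population."""

    m: float
    subpop1: SubpopulationModel
    subpop2: SubpopulationModel
    effects: QtlEffects = field(default_factory=QtlEffects)

    def __post_init__(self) -> None:
        if not (0.0 < self.m <= 1.0):
            raise ValueError(f"admixture proportion m must lie in (0, 1]; got {self.m!r}")

    @property
    def subpops(self) -> tuple[SubpopulationModel, SubpopulationModel]:
        return (self.subpop1, self.subpop2)


@dataclass(frozen=True)
class CovDecomposition:
    """Marker–trait covariance in the mixture, split into genuine and spurious parts.

    ``total = genuine + spurious`` holds exactly: ``genuine`` is the
    admixture-weighted combination of within-subpopulation covariances (driven
    by LD), ``spurious`` is the cross term created by allele-frequency and
    trait-mean differences between the subpopulations.
    """

    total: float
    genuine: float
    spurious: float


@dataclass(frozen=True)
class PowerPrediction:
    """Predicted power of the two-sided t-test of a regression slope."""

    power: float
    v: int
    ncp: float
    alpha: float


# ---------------------------------------------------------------------------
# population-level moments
# ---------------------------------------------------------------------------

def joint_genotype_distribution(pair: LocusPair) -> np.ndarray:
    """3x3 joint probability table of (QTL genotype x marker genotype).

    Rows index QTL genotypes (AA, Aa, aa), columns marker genotypes
    (TT, Tt, tt).  Under random mating the table factorises through the
    conditional allele probabilities Q = P(T|A) and R = P(T|a):

    ==== =============== ======================= ==================
    row  TT              Tt                      tt
    ==== =============== ======================= ==================
    AA   (qQ)^2          2 q^2 Q(1-Q)            q^2 (1-Q)^2
    Aa   2q(1-q) QR      2q(1-q)(Q+R-2QR)        2q(1-q)(1-Q)(1-R)
    aa   (1-q)^2 R^2     2(1-q)^2 R(1-R)         (1-q)^2 (1-R)^2
    ==== =============== ======================= ==================

    Marginals recover HWE proportions at each locus; the covariance of the
    two allele counts equals 2D.
    """
    q, Q, R = pair.q, pair.Q, pair.R
    table = np.array(
        [
            [(q * Q) ** 2, 2 * q**2 * Q * (1 - Q), q**2 * (1 - Q) ** 2],
            [
                2 * q * (1 - q) * Q * R,
                2 * q * (1 - q) * (Q + R - 2 * Q * R),
                2 * q * (1 - q) * (1 - Q) * (1 - R),
            ],
            [
                (1 - q) ** 2 * R**2,
                2 * (1 - q) ** 2 * R * (1 - R),
                (1 - q) ** 2 * (1 - R) ** 2,
            ],
        ]
    )
    # D on a Lewontin boundary can leave cells at -1e-17; clamp rounding noise
    table[(table < 0) & (table > -1e-9)] = 0.0
    return table / table.sum()


def subpop_trait_mean(sub: SubpopulationModel, effects: QtlEffects) -> float:
    """Trait mean of one subpopulation: mu + d(2q - 1) + 2 h q (1 - q)."""
    q = sub.q
    return effects.mu + effects.d * (2 * q - 1) + 2 * effects.h * q * (1 - q)


def within_covariance(sub: SubpopulationModel, effects: QtlEffects) -> float:
    """Cov(marker count, trait) within one subpopulation: 2 D (d + (1 - 2q) h)."""
    return 2 * sub.D * (effects.d + (1 - 2 * sub.q) * effects.h)


def mixture_ld(spec: AdmixtureSpec) -> float:
    """LD between test marker and QTL in the admixed population.

    ``D_mix = m D1 + (1-m) D2 + m(1-m)(p1 - p2)(q1 - q2)``: even loci in
    linkage equilibrium within each subpopulation show mixture LD when their
    allele frequencies co-vary across subpopulations.
    """
    m = spec.m
    s1, s2 = spec.subpops
    return m * s1.D + (1 - m) * s2.D + m * (1 - m) * (s1.p - s2.p) * (s1.q - s2.q)


def mixture_covariance(spec: AdmixtureSpec) -> CovDecomposition:
    """Marker–trait covariance of the mixture, decomposed exactly.

    genuine  = m Cov1 + (1-m) Cov2  with Cov_i = 2 D_i (d + (1 - 2 q_i) h)
    spurious = 2 m (1-m) (p1 - p2)(mu1 - mu2)

    where mu_i is the trait mean of subpopulation i.  The sum equals the
    covariance of marker allele count and trait computed from the exact
    mixture distribution.
    """
    m = spec.m
    s1, s2 = spec.subpops
    genuine = m * within_covariance(s1, spec.effects) + (1 - m) * within_covariance(
        s2, spec.effects
    )
    mu1 = subpop_trait_mean(s1, spec.effects)
    mu2 = subpop_trait_mean(s2, spec.effects)
    spurious = 2 * m * (1 - m) * (s1.p - s2.p) * (mu1 - mu2)
    return CovDecomposition(total=genuine + spurious, genuine=genuine, spurious=spurious)


def marker_variance(spec: AdmixtureSpec) -> float:
    """Variance of the test-marker allele count in the mixture.

    ``2 pbar (1 - pbar) + 2 m (1-m) (p1 - p2)^2`` — the HWE variance at the
    pooled frequency plus the Wahlund excess.
    """
    m = spec.m
    s1, s2 = spec.subpops
    pbar = m * s1.p + (1 - m) * s2.p
    return 2 * pbar * (1 - pbar) + 2 * m * (1 - m) * (s1.p - s2.p) ** 2


def trait_variance(spec: AdmixtureSpec) -> float:
    """Total trait variance in the mixture (genetic + residual)."""
    m = spec.m
    values = spec.effects.genotypic_values()
    total_mean = 0.0
    total_sq = 0.0
    for weight, sub in zip((m, 1 - m), spec.subpops):
        probs = np.array([sub.q**2, 2 * sub.q * (1 - sub.q), (1 - sub.q) ** 2])
        total_mean += weight * probs @ values
        total_sq += weight * probs @ values**2
    return total_sq - total_mean**2 + spec.effects.sigma2


def control_covariances(spec: AdmixtureSpec) -> tuple[float, float]:
    """(Cov(X, Z), Cov(Z, Y)) between control-marker count Z and the test marker / trait.

    Within subpopulations Z is independent of both, so only the admixture
    cross terms survive:

    Cov(X, Z) = 4 m (1-m) (p1 - p2)(c1 - c2)
    Cov(Z, Y) = 2 m (1-m) (c1 - c2)(mu1 - mu2)
    """
    m = spec.m
    s1, s2 = spec.subpops
    dc = s1.c - s2.c
    cov_xz = 4 * m * (1 - m) * (s1.p - s2.p) * dc
    mu1 = subpop_trait_mean(s1, spec.effects)
    mu2 = subpop_trait_mean(s2, spec.effects)
    cov_zy = 2 * m * (1 - m) * dc * (mu1 - mu2)
    return cov_xz, cov_zy


def structure_variance_inflation(
    m: float, c1: float, c2: float
) -> tuple[float, float, float]:
    """Expected vs observed variance of a control-marker count under admixture.

    Returns ``(var_expected, var_observed, delta)`` where

    var_expected = 2 cbar (1 - cbar)    (HWE at the pooled frequency)
    var_observed = var_expected + 2 m (1-m) (c1 - c2)^2
    delta        = var_observed - var_expected >= 0

    A positive delta is the Wahlund signal of population structure that the
    corrected association test divides by.
    """
    if not (0.0 < m < 1.0):
        raise ValueError(f"m must lie in (0, 1); got {m!r}")
    _check_open_unit(c1, "c1")
    _check_open_unit(c2, "c2")
    cbar = m * c1 + (1 - m) * c2
    var_expected = 2 * cbar * (1 - cbar)
    delta = 2 * m * (1 - m) * (c1 - c2) ** 2
    return var_expected, var_expected + delta, delta


def corrected_covariance(spec: AdmixtureSpec) -> float:
    """Population-level control-marker-corrected marker–trait covariance.

    ``Cov* = Cov(X,Y) - Cov(X,Z) Cov(Z,Y) / (2 delta)`` with delta the
    control-marker variance excess.  At the population level this subtraction
    is exact: Cov* equals the genuine covariance ``m Cov1 + (1-m) Cov2``
    whatever (c1, c2) with c1 != c2 is used.
    """
    s1, s2 = spec.subpops
    if math.isclose(s1.c, s2.c):
        raise ValueError(
            "control marker has equal allele frequencies in both subpopulations; "
            "structure is uncorrectable by this control marker"
        )
    decomp = mixture_covariance(spec)
    cov_xz, cov_zy = control_covariances(spec)
    _, _, delta = structure_variance_inflation(spec.m, s1.c, s2.c)
    return decomp.total - cov_xz * cov_zy / (2 * delta)


def theoretical_coefficient(spec: AdmixtureSpec, method: str = "corrected") -> float:
    """Population-level regression coefficient of trait on marker count.

    method="simple":     b = Cov(X, Y) / Var(X)     (no correction)
    method="corrected":  b* = Cov* / Var(X), the control-marker-corrected
    coefficient, which is zero whenever the within-subpopulation LD is zero
    in both subpopulations regardless of structure.
    method="structured": the partial regression coefficient of Y on X given
    the true membership indicator, b1 = genuine-covariance divided by the
    admixture-weighted *within*-subpopulation marker variance
    ``m 2p1(1-p1) + (1-m) 2p2(1-p2)`` (membership absorbs the between-
    subpopulation parts of both Cov(X, Y) and Var(X)).
    """
    var_x = marker_variance(spec)
    if method == "simple":
        return mixture_covariance(spec).total / var_x
    if method == "corrected":
        if spec.m == 1.0:
            # single population: nothing to correct
            return mixture_covariance(spec).genuine / var_x
        return corrected_covariance(spec) / var_x
    if method == "structured":
        m = spec.m
        s1, s2 = spec.subpops
        within_var = m * 2 * s1.p * (1 - s1.p) + (1 - m) * 2 * s2.p * (1 - s2.p)
        return mixture_covariance(spec).genuine / within_var
    raise ValueError(
        f"unknown method {method!r}; expected 'simple', 'corrected' or 'structured'"
    )


# ---------------------------------------------------------------------------
# power prediction
# ---------------------------------------------------------------------------

def _gamma_factor(v: int) -> float:
    """Small-sample factor sqrt(2/v) * Gamma(v/2) / Gamma((v-1)/2) -> 1 as v -> inf."""
    return math.sqrt(2.0 / v) * math.exp(
        special.gammaln(v / 2.0) - special.gammaln((v - 1) / 2.0)
    )


def predict_power(
    b: float,
    var_x: float,
    sigma2_resid: float,
    n: int,
    alpha: float = 0.05,
    ncp_form: str = "gamma",
) -> PowerPrediction:
    """Power of the two-sided slope t-test at size alpha.

    The test statistic b_hat / se(b_hat) follows a noncentral t distribution
    with ``v = n - 3`` degrees of freedom; the power is
    ``P(|T'_{v, ncp}| > t_{alpha/2, v})``.  The noncentrality parameter is

        ncp = kappa_v * b * sqrt(n * var_x / sigma2_resid)

    where ``kappa_v = sqrt(2/v) Gamma(v/2) / Gamma((v-1)/2)`` is a
    small-sample gamma-function factor (Johnson & Kotz); ``ncp_form=
    "asymptotic"`` drops the factor (kappa = 1).

    Parameters
    ----------
    b : population regression coefficient under the alternative.
    var_x : variance of the marker count.
    sigma2_resid : residual trait variance about the regression line.
    n : sample size (> 3).
    alpha : two-sided test size.
    """
    if n <= 3:
        raise ValueError(f"sample size n must exceed 3; got {n!r}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha!r}")
    if var_x <= 0 or sigma2_resid <= 0:
        raise ValueError("var_x and sigma2_resid must be positive")
    if ncp_form not in ("gamma", "asymptotic"):
        raise ValueError(f"unknown ncp_form {ncp_form!r}")
    v = n - 3
    ncp = b * math.sqrt(n * var_x / sigma2_resid)
    if ncp_form == "gamma":
        ncp *= _gamma_factor(v)
    tcrit = stats.t.ppf(1 - alpha / 2, v)
    if ncp == 0.0:
        power = alpha
    else:
        upper = float(stats.nct.sf(tcrit, v, ncp))
        lower = float(stats.nct.cdf(-tcrit, v, ncp))
        # scipy's noncentral t loses the far tail at large v; the normal
        # limit T' ~ N(ncp, 1) is exact enough wherever that happens
        if math.isnan(upper):
            upper = float(stats.norm.sf(tcrit - ncp))
        if math.isnan(lower):
            lower = float(stats.norm.cdf(-tcrit - ncp))
        power = upper + lower
    return PowerPrediction(power=power, v=v, ncp=ncp, alpha=alpha)
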