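"""Association tests for quantitative traits in possibly structured samples.

Three tests of marker–trait association are provided, all regression-based
and all reporting a Student-t p-value for the slope:

* :func:`fit_corrected` — simple regression whose marker–trait covariance is
  corrected for population stratification using a single control marker
  (the method this package exists for);
* :func:`fit_simple` — ordinary single-marker regression, no correction;
* :func:`fit_structured` — multiple regression with the probability of
  membership to subpopulation 1 as a covariate.

Alongside the tests live the control-marker machinery (screening candidates,
ranking them by the Wahlund variance excess) and structure diagnostics
(per-marker Hardy–Weinberg tests, genome-wide HWE scan, Sidak thresholds).

Missing genotypes/phenotypes are NaN; every fit is complete-case and reports
``n_used``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "AssociationResult",
    "ControlMarkerChoice",
    "WeakControlMarkerError",
    "fit_simple",
    "fit_corrected",
    "fit_structured",
    "control_marker_stats",
    "delta_jackknife_se",
    "screen_control_candidates",
    "select_control_marker",
    "hwe_tests",
    "genomewide_hwe_scan",
    "sidak_threshold",
    "sidak_family_alpha",
    "is_autosome",
]

_TINY = float(np.finfo(float).tiny)


class WeakControlMarkerError(ValueError):
    """The chosen control marker carries no detectable structure signal."""


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one marker–trait association test."""

    b: float
    se: float
    t: float
    df: int
    p: float
    method: str
    n_used: int


@dataclass(frozen=True)
class ControlMarkerChoice:
    """A candidate control marker scored by its structure signal.

    ``delta = var_observed - var_expected`` where ``var_expected`` is the
    Hardy–Weinberg variance ``2 phat (1 - phat)`` at the pooled allele
    frequency and ``var_observed`` the n-1 sample variance of the genotype
    counts; under admixture delta estimates the Wahlund variance excess.
    """

    marker: str
    var_expected: float
    var_observed: float
    delta: float
    allele_freq: float
    missing_fraction: float


def _as_float(a) -> np.ndarray:
    return np.asarray(a, dtype=float).ravel()


def _complete_mask(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(arrays[0].shape, dtype=bool)
    for a in arrays:
        mask &= ~np.isnan(a)
    return mask


def _slope_result(
    b: float, sxx: float, syy: float, sse: float, n: int, df: int, method: str
) -> AssociationResult:
    sse = max(sse, 0.0)
    s2 = sse / df
    se = math.sqrt(s2 / sxx) if s2 > 0 else 0.0
    if se > 0:
        t = b / se
        p = float(2 * stats.t.sf(abs(t), df))
    elif b == 0.0:
        t, p = 0.0, 1.0
    else:  # perfect fit: infinitely significant, keep p in (0, 1]
        t, p = math.copysign(math.inf, b), _TINY
    return AssociationResult(
        b=b, se=max(se, _TINY), t=t, df=df, p=max(p, _TINY), method=method, n_used=n
    )


def fit_simple(X, Y) -> AssociationResult:
    """Ordinary least-squares regression of trait Y on marker count X.

    b = Cov(X, Y) / Var(X) with the usual OLS standard error on n - 2
    degrees of freedom.  Complete-case over (X, Y).
    """
    X, Y = _as_float(X), _as_float(Y)
    mask = _complete_mask(X, Y)
    x, y = X[mask], Y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete (X, Y) pairs; got {n}")
    xc, yc = x - x.mean(), y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("zero marker variance: test marker is monomorphic")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    b = sxy / sxx
    sse = syy - b * sxy
    return _slope_result(b, sxx, syy, sse, n, n - 2, "simple")


def control_marker_stats(Z) -> tuple[float, float, float]:
    """(var_expected, var_observed, delta) for a control-marker genotype vector.

    var_expected = 2 phat (1 - phat), phat = mean(Z) / 2 (pooled frequency);
    var_observed = sample variance of Z with n - 1 denominator.  Their
    difference delta estimates the Wahlund variance excess and is >= 0 in
    expectation under admixture, 0 under panmixia.
    """
    z = _as_float(Z)
    z = z[~np.isnan(z)]
    if z.size < 2:
        raise ValueError("need at least 2 non-missing control genotypes")
    phat = z.mean() / 2.0
    var_expected = 2 * phat * (1 - phat)
    var_observed = float(z.var(ddof=1))
    return var_expected, var_observed, var_observed - var_expected


def delta_jackknife_se(Z) -> float:
    """Leave-one-out jackknife standard error of the control-marker delta."""
    z = _as_float(Z)
    z = z[~np.isnan(z)]
    n = z.size
    if n < 3:
        raise ValueError("jackknife needs at least 3 non-missing genotypes")
    s1, s2 = z.sum(), (z**2).sum()
    loo_mean = (s1 - z) / (n - 1)
    loo_var = (s2 - z**2 - (n - 1) * loo_mean**2) / (n - 2)
    loo_delta = loo_var - (loo_mean - loo_mean**2 / 2.0)
    return float(np.sqrt((n - 1) / n * ((loo_delta - loo_delta.mean()) ** 2).sum()))


def _loo_cov(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Vector of leave-one-out sample covariances (denominator n - 2)."""
    sa, sb, sab = a.sum(), b.sum(), (a * b).sum()
    return (sab - a * b - (sa - a) * (sb - b) / (n - 1)) / (n - 2)


def _corrected_slope(cov_xy, cov_xz, cov_zy, var_x, delta):
    return (cov_xy - cov_xz * cov_zy / (2 * delta)) / var_x


def fit_corrected(
    X,
    Z,
    Y,
    *,
    delta_se_multiple: float = 2.0,
    fallback: bool = False,
    se_method: str = "jackknife",
) -> AssociationResult:
    """Control-marker-corrected regression of trait Y on marker count X.

    The marker–trait covariance is purged of its stratification component
    before forming the slope:

        Cov* = Cov(X, Y) - Cov(X, Z) Cov(Z, Y) / (2 delta)
        b*   = Cov* / Var(X)

    where Z is the control-marker genotype vector and delta its observed
    minus Hardy–Weinberg-expected variance.  At the population level the
    subtraction removes the spurious covariance exactly.  The slope is
    tested by Student's t with n - 3 degrees of freedom.

    The default standard error is the delete-one jackknife of b*, which
    accounts for the sampling noise of the correction term itself and keeps
    the type-I error at its nominal level; ``se_method="ols"`` gives the
    plug-in OLS-style slope standard error built from the corrected
    coefficient of determination, which is mildly anti-conservative because
    it treats the correction as noiseless.

    delta must exceed ``delta_se_multiple`` jackknife standard errors of
    itself — a control marker without a real structure signal makes the
    correction a division by noise.  Below the tolerance a
    :class:`WeakControlMarkerError` is raised, or, with ``fallback=True``,
    the uncorrected :func:`fit_simple` result is returned (tagged
    ``simple``) so callers can degrade gracefully in unstructured samples.
    """
    if se_method not in ("jackknife", "ols"):
        raise ValueError(f"unknown se_method {se_method!r}")
    X, Z, Y = _as_float(X), _as_float(Z), _as_float(Y)
    mask = _complete_mask(X, Z, Y)
    x, z, y = X[mask], Z[mask], Y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete (X, Z, Y) triples; got {n}")
    _, _, delta = control_marker_stats(z)
    tol = delta_se_multiple * delta_jackknife_se(z)
    if delta <= tol:
        if fallback:
            return fit_simple(x, y)
        raise WeakControlMarkerError(
            f"control marker carries no structure signal (delta={delta:.4g} "
            f"<= {delta_se_multiple} x jackknife SE {tol / max(delta_se_multiple, _TINY):.4g})"
        )
    xc = x - x.mean()
    zc = z - z.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("zero marker variance: test marker is monomorphic")
    cov_xy = float(xc @ yc) / (n - 1)
    cov_xz = float(xc @ zc) / (n - 1)
    cov_zy = float(zc @ yc) / (n - 1)
    var_x = sxx / (n - 1)
    b = _corrected_slope(cov_xy, cov_xz, cov_zy, var_x, delta)
    syy = float(yc @ yc)
    if se_method == "ols":
        sse = syy - b**2 * sxx
        return _slope_result(b, sxx, syy, sse, n, n - 3, "corrected")
    # delete-one jackknife of the whole corrected-slope statistic
    loo_cov_xy = _loo_cov(x, y, n)
    loo_cov_xz = _loo_cov(x, z, n)
    loo_cov_zy = _loo_cov(z, y, n)
    loo_var_x = _loo_cov(x, x, n)
    loo_var_z = _loo_cov(z, z, n)
    loo_mean_z = (z.sum() - z) / (n - 1)
    loo_delta = loo_var_z - (loo_mean_z - loo_mean_z**2 / 2.0)
    loo_b = _corrected_slope(loo_cov_xy, loo_cov_xz, loo_cov_zy, loo_var_x, loo_delta)
    se = float(np.sqrt((n - 1) / n * ((loo_b - loo_b.mean()) ** 2).sum()))
    df = n - 3
    if se > 0:
        t = b / se
        p = float(2 * stats.t.sf(abs(t), df))
    elif b == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = math.copysign(math.inf, b), _TINY
    return AssociationResult(
        b=b, se=max(se, _TINY), t=t, df=df, p=max(p, _TINY), method="corrected", n_used=n
    )


def fit_structured(X, membership_prob, Y) -> AssociationResult:
    """Multiple regression of Y on marker count X and membership probability P.

    Y = b0 + b1 X + b2 P + e.  The marker effect b1 is tested by Student's t
    with n - 3 degrees of freedom; P absorbs the mean trait difference
    between subpopulations when the membership information is accurate.

    A constant membership column carries no information and is dropped (b1
    then equals the simple-regression slope, still on n - 3 df); a
    membership column collinear with the marker genotype is a confounded
    design and an error.
    """
    X, P, Y = _as_float(X), _as_float(membership_prob), _as_float(Y)
    mask = _complete_mask(X, P, Y)
    x, p_, y = X[mask], P[mask], Y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete (X, P, Y) rows; got {n}")
    if np.ptp(p_) == 0.0:
        # constant membership: orthogonal to the slope, only costs a df
        simple = fit_simple(x, y)
        df = n - 3
        p_val = float(2 * stats.t.sf(abs(simple.t), df)) if np.isfinite(simple.t) else simple.p
        return AssociationResult(
            b=simple.b, se=simple.se, t=simple.t, df=df,
            p=max(p_val, _TINY), method="structured", n_used=n,
        )
    design = np.column_stack([np.ones(n), x, p_])
    rank = np.linalg.matrix_rank(design)
    if rank < 3:
        raise ValueError(
            "confounded design: marker genotype and membership probability "
            "are collinear (or one is constant)"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - 3
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se1 = math.sqrt(max(s2 * xtx_inv[1, 1], 0.0))
    b1 = float(coef[1])
    if se1 > 0:
        t = b1 / se1
        p = float(2 * stats.t.sf(abs(t), df))
    elif b1 == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = math.copysign(math.inf, b1), _TINY
    return AssociationResult(
        b=b1, se=max(se1, _TINY), t=t, df=df, p=max(p, _TINY), method="structured", n_used=n
    )


# ---------------------------------------------------------------------------
# control-marker selection
# ---------------------------------------------------------------------------

_NON_AUTOSOMES = {"x", "y", "mt", "m", "xy", "chrx", "chry", "chrmt", "chrm", "w", "z"}


def is_autosome(chrom) -> bool:
    """Heuristic autosome flag: numeric chromosome labels (with/without 'chr')."""
    label = str(chrom).strip().lower()
    if label in _NON_AUTOSOMES:
        return False
    return label.removeprefix("chr").isdigit()


def screen_control_candidates(
    marker_map: pd.DataFrame,
    test_marker: str,
    max_missing_fraction: float = 0.1,
    missing_fraction: pd.Series | None = None,
) -> list[str]:
    """Markers eligible to serve as control for ``test_marker``.

    Keeps autosomal markers on chromosomes different from the test marker's
    whose missing-genotype fraction is below ``max_missing_fraction``; the
    test marker itself is always excluded.

    Parameters
    ----------
    marker_map : DataFrame indexed by marker id with columns ``chrom`` and
        ``pos``.
    missing_fraction : optional Series of per-marker missing fractions
        (defaults to 0 for all markers).
    """
    if test_marker not in marker_map.index:
        raise KeyError(f"test marker {test_marker!r} not in marker map")
    test_chrom = marker_map.loc[test_marker, "chrom"]
    keep = []
    for marker, row in marker_map.iterrows():
        if marker == test_marker or row["chrom"] == test_chrom:
            continue
        if not is_autosome(row["chrom"]):
            continue
        miss = 0.0 if missing_fraction is None else float(missing_fraction.get(marker, 0.0))
        if miss >= max_missing_fraction:
            continue
        keep.append(marker)
    if not keep:
        raise ValueError(f"no eligible control markers for test marker {test_marker!r}")
    return keep


def select_control_marker(
    genotypes: pd.DataFrame, marker_map: pd.DataFrame | None = None
) -> ControlMarkerChoice:
    """Pick the control marker with the largest structure signal.

    ``genotypes`` is a markers-by-samples DataFrame of 0/1/2 counts (NaN
    missing), typically restricted to the ids returned by
    :func:`screen_control_candidates`.  The marker maximising
    ``delta = var_observed - var_expected`` is returned; ties break to the
    lowest (chromosome, position) when a map is supplied, else to the first
    marker in input order.
    """
    if genotypes.shape[0] == 0:
        raise ValueError("no candidate control markers supplied")
    choices = []
    for marker, row in genotypes.iterrows():
        z = row.to_numpy(dtype=float)
        miss = float(np.isnan(z).mean())
        ve, vo, delta = control_marker_stats(z)
        zz = z[~np.isnan(z)]
        choices.append(
            ControlMarkerChoice(
                marker=str(marker),
                var_expected=ve,
                var_observed=vo,
                delta=delta,
                allele_freq=float(zz.mean() / 2.0),
                missing_fraction=miss,
            )
        )
    if marker_map is not None:
        def sort_key(c: ControlMarkerChoice):
            row = marker_map.loc[c.marker]
            return (-c.delta, str(row["chrom"]), int(row["pos"]))
    else:
        order = {c.marker: i for i, c in enumerate(choices)}
        def sort_key(c: ControlMarkerChoice):
            return (-c.delta, order[c.marker])
    return sorted(choices, key=sort_key)[0]


# ---------------------------------------------------------------------------
# Hardy–Weinberg diagnostics
# ---------------------------------------------------------------------------

def hwe_tests(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float, float]:
    """Per-marker Hardy–Weinberg tests from genotype counts.

    Returns ``(chi2, p_chi2, p_fisher)``: the 1-df Pearson chi-square against
    HWE expectations at the sample allele frequency, and the exact test
    p-value obtained by enumerating all heterozygote counts compatible with
    the observed allele counts and summing the probabilities of
    configurations no more likely than the observed one.

    A monomorphic marker returns (0, 1, 1) by convention.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype is required")
    n_A = 2 * counts[0] + counts[1]
    n_a = 2 * counts[2] + counts[1]
    if n_A == 0 or n_a == 0:
        return 0.0, 1.0, 1.0
    phat = n_A / (2 * n)
    expected = np.array([n * phat**2, 2 * n * phat * (1 - phat), n * (1 - phat) ** 2])
    chi2 = float((((np.array(counts) - expected) ** 2) / expected).sum())
    p_chi2 = float(stats.chi2.sf(chi2, df=1))

    # exact test: P(het count | allele counts) under HWE, conditional
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    log_probs = (
        hets * math.log(2)
        - special.gammaln(hets + 1)
        - special.gammaln((n_A - hets) / 2 + 1)
        - special.gammaln((n_a - hets) / 2 + 1)
    )
    log_probs -= special.logsumexp(log_probs)
    probs = np.exp(log_probs)
    obs_prob = probs[np.searchsorted(hets, counts[1])]
    p_fisher = float(min(probs[probs <= obs_prob * (1 + 1e-12)].sum(), 1.0))
    return chi2, p_chi2, p_fisher


def genomewide_hwe_scan(
    genotypes: pd.DataFrame, alpha: float = 0.05, correction: str = "sidak"
) -> pd.DataFrame:
    """Hardy–Weinberg scan over a markers-by-samples genotype matrix.

    Applies :func:`hwe_tests` per marker and flags departures at the
    Sidak-corrected per-test level for the family-wise ``alpha`` (or at
    ``alpha`` directly with ``correction="none"``).  In a pooled sample of
    diverged subpopulations the Wahlund heterozygote deficit makes the
    violator count far exceed its null expectation.

    Returns a DataFrame indexed by marker with columns chi2, p_chi2,
    p_fisher, sig_chi2, sig_fisher and attrs ``threshold``, ``n_sig_chi2``,
    ``n_sig_fisher``.
    """
    if genotypes.shape[0] == 0:
        raise ValueError("empty genotype matrix")
    if correction == "sidak":
        threshold = sidak_threshold(alpha, genotypes.shape[0])
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    records = []
    for marker, row in genotypes.iterrows():
        g = row.to_numpy(dtype=float)
        g = g[~np.isnan(g)]
        counts = (int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
        chi2, p_chi2, p_fisher = hwe_tests(*counts)
        records.append((marker, chi2, p_chi2, p_fisher))
    out = pd.DataFrame(
        records, columns=["marker", "chi2", "p_chi2", "p_fisher"]
    ).set_index("marker")
    out["sig_chi2"] = out["p_chi2"] < threshold
    out["sig_fisher"] = out["p_fisher"] < threshold
    out.attrs["threshold"] = threshold
    out.attrs["n_sig_chi2"] = int(out["sig_chi2"].sum())
    out.attrs["n_sig_fisher"] = int(out["sig_fisher"].sum())
    return out


def sidak_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test level controlling the family-wise error at ``alpha_family``:
    ``1 - (1 - alpha)^(1/n)``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha_family < 1.0):
        raise ValueError("alpha_family must lie in (0, 1)")
    return 1.0 - (1.0 - alpha_family) ** (1.0 / n_tests)


def sidak_family_alpha(alpha_per_test: float, n_tests: int) -> float:
    """Family-wise error implied by a per-test level: ``1 - (1 - alpha)^n``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha_per_test < 1.0):
        raise ValueError("alpha_per_test must lie in (0, 1)")
    return 1.0 - (1.0 - alpha_per_test) ** n_tests
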