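"""Simulation of admixed study populations and replicate study harnesses.

Samples are drawn from an :class:`~admixqtl.popmodel.AdmixtureSpec`: each
individual originates from subpopulation 1 with probability ``m``, receives a
(QTL, test-marker) genotype from the exact two-locus joint distribution of
its subpopulation, an independent control-marker genotype, and a normally
distributed trait value determined by its (latent) QTL genotype.  Marker
panels with a prescribed adjacent-locus LD profile are generated as a
haplotype Markov chain.  :func:`run_replicate_study` repeats
simulate-and-fit cycles to measure empirical size and power of the
association tests.

The QTL genotype is latent throughout: downstream analyses only ever see the
marker genotypes, the trait and (optionally corrupted) membership
information, mirroring real use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import assoc
from .popmodel import (
    AdmixtureSpec,
    QtlEffects,
    SubpopulationModel,
    joint_genotype_distribution,
    lewontin_bounds,
)

__all__ = [
    "SampleData",
    "StudySummary",
    "simulate_admixed_sample",
    "simulate_marker_panel",
    "corrupt_membership",
    "run_replicate_study",
    "make_scenario",
    "default_null_scenario",
    "table2_scenarios",
]


@dataclass
class SampleData:
    """One simulated admixed sample.

    ``X`` test-marker counts, ``Z`` control-marker counts, ``Y`` trait
    values; ``true_label`` the subpopulation of origin (1 or 2) and
    ``membership_prob`` the assigned probability of membership to
    subpopulation 1 (1/0 hard assignments unless corrupted).  An optional
    ``Z_panel`` (markers x samples) with ``panel_map`` holds candidate
    control markers.
    """

    n: int
    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    true_label: np.ndarray
    membership_prob: np.ndarray
    Z_panel: pd.DataFrame | None = None
    panel_map: pd.DataFrame | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("X", "Z", "Y", "true_label", "membership_prob"):
            arr = getattr(self, name)
            if arr.shape != (self.n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({self.n},)")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(self.n)]


@dataclass(frozen=True)
class StudySummary:
    """Monte-Carlo summary of one association method over replicates."""

    method: str
    mean_b: float
    se_b: float
    prop_significant: float
    n_reps: int
    n_failed: int = 0


def _draw_joint(rng: np.random.Generator, sub: SubpopulationModel, size: int):
    """Draw (QTL allele count, marker allele count) pairs from the exact joint."""
    table = joint_genotype_distribution(sub.locus_pair).ravel()
    cells = rng.choice(9, size=size, p=table)
    qtl = 2 - cells // 3   # row 0 = AA
    x = 2 - cells % 3      # col 0 = TT
    return qtl, x


def simulate_admixed_sample(
    spec: AdmixtureSpec,
    n: int,
    control_freqs: tuple[float, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> SampleData:
    """Draw ``n`` individuals from an admixed population.

    Membership is Bernoulli(m); within each subpopulation the (QTL, test
    marker) genotype pair comes from the exact two-locus joint distribution,
    the control marker independently from Binomial(2, c_i), and the trait is
    the QTL genotypic mean plus Normal(0, sigma2) noise.  ``control_freqs``
    overrides the control-marker frequencies of the spec.

    A fixed ``seed`` makes the output fully reproducible.
    """
    if n < 0:
        raise ValueError(f"sample size must be non-negative; got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if control_freqs is not None:
        spec = replace(
            spec,
            subpop1=replace(spec.subpop1, c=control_freqs[0]),
            subpop2=replace(spec.subpop2, c=control_freqs[1]),
        )
    label = np.where(rng.random(n) < spec.m, 1, 2)
    X = np.zeros(n)
    Z = np.zeros(n)
    Y = np.zeros(n)
    values = spec.effects.genotypic_values()  # AA, Aa, aa
    for lab, sub in ((1, spec.subpop1), (2, spec.subpop2)):
        idx = np.flatnonzero(label == lab)
        if idx.size == 0:
            continue
        qtl, x = _draw_joint(rng, sub, idx.size)
        X[idx] = x
        Z[idx] = rng.binomial(2, sub.c, size=idx.size)
        Y[idx] = values[2 - qtl] + rng.normal(0.0, np.sqrt(spec.effects.sigma2), idx.size)
    return SampleData(
        n=n,
        X=X,
        Z=Z,
        Y=Y,
        true_label=label,
        membership_prob=(label == 1).astype(float),
    )


def simulate_marker_panel(
    freqs,
    adjacent_ld,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a multi-locus genotype matrix with a prescribed LD profile.

    Haplotypes are generated as a first-order Markov chain along the loci:
    the allele at locus j+1 is drawn from its distribution conditional on the
    allele at locus j, implied by the two-locus haplotype frequencies
    ``p_j p_{j+1} + D_j`` etc.  Each individual receives two independent
    haplotypes; genotypes are their sums.  This reproduces the marginal
    frequencies, HWE within the population, and the specified adjacent LD.

    Parameters
    ----------
    freqs : allele frequency per locus, all in (0, 1).
    adjacent_ld : LD coefficient between consecutive loci; length
        ``len(freqs) - 1``, each within the Lewontin bounds of its pair.
    n : number of individuals.

    Returns
    -------
    ndarray of shape (n_loci, n) with 0/1/2 genotype counts.
    """
    freqs = np.asarray(freqs, dtype=float)
    adjacent_ld = np.asarray(adjacent_ld, dtype=float)
    n_loci = freqs.size
    if adjacent_ld.size != max(n_loci - 1, 0):
        raise ValueError("adjacent_ld must have one entry per consecutive locus pair")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("all allele frequencies must lie in (0, 1)")
    for j, D in enumerate(adjacent_ld):
        lo, hi = lewontin_bounds(freqs[j], freqs[j + 1])
        if not (lo - 1e-12 <= D <= hi + 1e-12):
            raise ValueError(
                f"adjacent LD {D!r} between loci {j} and {j + 1} violates "
                f"the Lewontin bounds [{lo:.6g}, {hi:.6g}]"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haplotypes = np.zeros((2, n, n_loci), dtype=np.int8)
    haplotypes[:, :, 0] = rng.random((2, n)) < freqs[0]
    for j in range(n_loci - 1):
        pj, pk, D = freqs[j], freqs[j + 1], adjacent_ld[j]
        prob_given1 = (pj * pk + D) / pj
        prob_given0 = (pk * (1 - pj) - D) / (1 - pj)
        prev = haplotypes[:, :, j]
        cond = np.where(prev == 1, prob_given1, prob_given0)
        haplotypes[:, :, j + 1] = rng.random((2, n)) < cond
    return haplotypes.sum(axis=0).T.astype(float)


def corrupt_membership(
    true_label,
    fraction_random: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Degrade membership information: a random fraction of individuals is
    reassigned to either subpopulation with probability 1/2.

    The rest keep their true label as a hard 1/0 probability of membership to
    subpopulation 1.  ``fraction_random=0`` is the identity;
    ``fraction_random=1`` destroys all information (about half the
    assignments agree with truth by chance).
    """
    if not (0.0 <= fraction_random <= 1.0):
        raise ValueError("fraction_random must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    label = np.asarray(true_label)
    prob = (label == 1).astype(float)
    scramble = rng.random(label.size) < fraction_random
    prob[scramble] = (rng.random(int(scramble.sum())) < 0.5).astype(float)
    return prob


def run_replicate_study(
    spec: AdmixtureSpec,
    n: int,
    n_reps: int = 100,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("corrected", "simple", "structured"),
    membership_fraction_random: float = 0.0,
    control_freqs: tuple[float, float] | None = None,
    seed: int | None = None,
    fallback_weak_control: bool = False,
) -> dict[str, StudySummary]:
    """Repeated simulate-and-fit cycles measuring size/power of each method.

    Per replicate a fresh sample is simulated and each requested method
    fitted; the regression coefficient and its significance at ``alpha`` are
    recorded.  Under a null spec (zero within-subpopulation LD) the
    proportion significant is the empirical type-I error; under a non-null
    spec it is the empirical power.  Fit failures (e.g. a monomorphic draw or
    a weak control marker) are counted per method, not fatal.

    Replicate RNG streams are spawned from one seed so the study is
    reproducible and order-independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    results: dict[str, list[tuple[float, bool]]] = {meth: [] for meth in methods}
    failures = {meth: 0 for meth in methods}
    for ss in streams:
        rng = np.random.default_rng(ss)
        sample = simulate_admixed_sample(spec, n, control_freqs=control_freqs, seed=rng)
        membership = corrupt_membership(
            sample.true_label, membership_fraction_random, seed=rng
        )
        for meth in methods:
            try:
                if meth == "simple":
                    res = assoc.fit_simple(sample.X, sample.Y)
                elif meth == "corrected":
                    res = assoc.fit_corrected(
                        sample.X, sample.Z, sample.Y, fallback=fallback_weak_control
                    )
                elif meth == "structured":
                    res = assoc.fit_structured(sample.X, membership, sample.Y)
                else:
                    raise ValueError(f"unknown method {meth!r}")
            except (ValueError, np.linalg.LinAlgError):
                failures[meth] += 1
                continue
            results[meth].append((res.b, res.p < alpha))
    summaries = {}
    for meth in methods:
        rows = results[meth]
        if rows:
            bs = np.array([r[0] for r in rows])
            sig = np.array([r[1] for r in rows])
            mean_b = float(bs.mean())
            se_b = float(bs.std(ddof=1) / np.sqrt(bs.size)) if bs.size > 1 else 0.0
            prop = float(sig.mean())
        else:
            mean_b, se_b, prop = float("nan"), float("nan"), float("nan")
        summaries[meth] = StudySummary(
            method=meth,
            mean_b=mean_b,
            se_b=se_b,
            prop_significant=prop,
            n_reps=len(rows),
            n_failed=failures[meth],
        )
    return summaries


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------

def make_scenario(
    delta_p: float = 0.6,
    delta_q: float = 0.6,
    delta_c: float = 0.6,
    D1: float = 0.0,
    D2: float = 0.0,
    m: float = 0.5,
    d: float = 1.0,
    h: float = 0.0,
    sigma2: float = 1.0,
    mu: float = 0.0,
    base: float = 0.5,
) -> AdmixtureSpec:
    """Build an :class:`AdmixtureSpec` from allele-frequency differences.

    Frequencies are centred on ``base``: subpopulation 1 gets
    ``base + delta/2`` and subpopulation 2 ``base - delta/2`` at each locus,
    so ``delta_p``/``delta_q``/``delta_c`` are the between-subpopulation
    frequency differences at the test marker, QTL and control marker.
    """
    effects = QtlEffects(mu=mu, d=d, h=h, sigma2=sigma2)
    sub1 = SubpopulationModel(
        q=base + delta_q / 2, p=base + delta_p / 2, c=base + delta_c / 2, D=D1
    )
    sub2 = SubpopulationModel(
        q=base - delta_q / 2, p=base - delta_p / 2, c=base - delta_c / 2, D=D2
    )
    return AdmixtureSpec(m=m, subpop1=sub1, subpop2=sub2, effects=effects)


def default_null_scenario() -> AdmixtureSpec:
    """Strong-structure null: 0.6 frequency differences at all three loci and
    zero within-subpopulation LD.  Any marker–trait association in this
    population is purely spurious."""
    return make_scenario(delta_p=0.6, delta_q=0.6, delta_c=0.6, D1=0.0, D2=0.0)


def table2_scenarios() -> dict[str, AdmixtureSpec]:
    """Default replicate-study scenario library (n = 200 intended).

    Four structured null populations (zero within-subpopulation LD, so the
    mixture LD is entirely spurious) and five populations with genuine LD
    partly masked or inflated by structure, plus one weak-structure null.
    Frequency differences use the {0.2, 0.4, 0.6} grid and within-
    subpopulation LD the {0, 0.05, 0.08} grid; m = 0.5, d = 1, h = 0,
    sigma2 = 1 throughout.
    """
    return {
        "null-moderate": make_scenario(0.4, 0.4, 0.4),
        "null-moderate-strongcontrol": make_scenario(0.4, 0.4, 0.6),
        "null-strong-opposed": make_scenario(0.6, -0.6, 0.6),
        "null-strong": make_scenario(0.6, 0.6, 0.6),
        "ld-weak": make_scenario(0.6, -0.2, 0.6, D1=0.05, D2=0.05),
        "ld-mid": make_scenario(0.6, -0.2, 0.6, D1=0.08, D2=0.05),
        "ld-strong": make_scenario(0.6, -0.2, 0.6, D1=0.08, D2=0.08),
        "ld-strong-balanced": make_scenario(0.4, -0.4, 0.4, D1=0.08, D2=0.08),
        "ld-opposed-control": make_scenario(0.4, -0.4, 0.6, D1=0.08, D2=0.08),
        "null-weak": make_scenario(0.2, -0.2, 0.4),
    }


def power_agreement_grid() -> dict[str, AdmixtureSpec]:
    """Non-null scenarios for comparing empirical power with theory.

    All use a control marker with the largest frequency divergence (0.6), as
    recommended for the corrected test: the noncentral-t power prediction
    treats the control-marker correction as noiseless, which holds to good
    approximation only when the control marker carries a strong structure
    signal: balanced admixture (m = 0.5) and a 0.6 frequency difference at
    the control marker maximise the Wahlund variance excess
    ``2 m (1-m) (c1-c2)^2`` the correction divides by.  (Weaker structure
    signals — a less diverged control marker, or strongly unbalanced
    admixture — let the correction's own sampling noise erode the realised
    power below the prediction; ``ld-strong-balanced`` in
    :func:`table2_scenarios` exhibits this.)  The five scenarios span the
    power range by varying within-subpopulation LD and the QTL effect size.
    """
    return {
        "ld-weak": make_scenario(0.6, -0.2, 0.6, D1=0.05, D2=0.05),
        "ld-mid": make_scenario(0.6, -0.2, 0.6, D1=0.08, D2=0.05),
        "ld-strong": make_scenario(0.6, -0.2, 0.6, D1=0.08, D2=0.08),
        "ld-opposed-control": make_scenario(0.4, -0.4, 0.6, D1=0.08, D2=0.08),
        "ld-strong-effect": make_scenario(0.6, -0.2, 0.6, D1=0.08, D2=0.08, d=1.3),
    }
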