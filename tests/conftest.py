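"""Shared fixtures and independent brute-force oracles.

The oracle enumerates the full discrete mixture distribution over
(subpopulation, QTL genotype, test-marker genotype, control-marker genotype)
and computes moments directly from it — no formula from the package is
reused, so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from admixqtl.popmodel import AdmixtureSpec, QtlEffects, SubpopulationModel


def enumerate_mixture_moments(spec: AdmixtureSpec) -> dict[str, float]:
    """Exact moments of (X, Y, Z) in the admixed population by enumeration.

    X = test-marker allele count, Z = control-marker count, Y is replaced by
    its conditional mean given the QTL genotype (residual noise has mean
    zero and is independent of everything, so all covariances are exact;
    var_y adds sigma2 back).
    """
    eff = spec.effects
    y_of = {2: eff.mu + eff.d, 1: eff.mu + eff.h, 0: eff.mu - eff.d}
    weights = {}
    for w, sub in zip((spec.m, 1 - spec.m), (spec.subpop1, spec.subpop2)):
        # two-locus genotype table from haplotype frequencies, independently
        # of the package's conditional-probability formulation
        h = {
            (1, 1): sub.p * sub.q + sub.D,      # T A
            (1, 0): sub.p * (1 - sub.q) - sub.D,  # T a
            (0, 1): (1 - sub.p) * sub.q - sub.D,  # t A
            (0, 0): (1 - sub.p) * (1 - sub.q) + sub.D,  # t a
        }
        for (m1, q1), (m2, q2) in itertools.product(h, repeat=2):
            x, g = m1 + m2, q1 + q2
            for z in (0, 1, 2):
                pz = math.comb(2, z) * sub.c**z * (1 - sub.c) ** (2 - z)
                key = (x, g, z)
                weights[key] = weights.get(key, 0.0) + w * h[(m1, q1)] * h[(m2, q2)] * pz
    total = sum(weights.values())
    assert abs(total - 1.0) < 1e-12
    ex = ey = ez = exx = eyy = ezz = exy = exz = ezy = 0.0
    for (x, g, z), w in weights.items():
        y = y_of[g]
        ex += w * x
        ey += w * y
        ez += w * z
        exx += w * x * x
        eyy += w * y * y
        ezz += w * z * z
        exy += w * x * y
        exz += w * x * z
        ezy += w * z * y
    return {
        "mean_x": ex,
        "mean_y": ey,
        "mean_z": ez,
        "var_x": exx - ex * ex,
        "var_y": eyy - ey * ey + eff.sigma2,
        "var_z": ezz - ez * ez,
        "cov_xy": exy - ex * ey,
        "cov_xz": exz - ex * ez,
        "cov_zy": ezy - ez * ey,
    }


def random_spec(rng: np.random.Generator, null: bool = False) -> AdmixtureSpec:
    """A random valid AdmixtureSpec (optionally with zero within-pop LD)."""
    m = rng.uniform(0.1, 0.9)
    subs = []
    for _ in range(2):
        p = rng.uniform(0.1, 0.9)
        q = rng.uniform(0.1, 0.9)
        c = rng.uniform(0.1, 0.9)
        if null:
            D = 0.0
        else:
            lo = -min(p * q, (1 - p) * (1 - q))
            hi = min(p * (1 - q), (1 - p) * q)
            D = rng.uniform(0.8 * lo, 0.8 * hi)
        subs.append(SubpopulationModel(q=q, p=p, c=c, D=D))
    if abs(subs[0].c - subs[1].c) < 0.05:  # keep the control marker usable
        subs[1] = SubpopulationModel(
            q=subs[1].q, p=subs[1].p, c=min(0.9, subs[0].c + 0.3) if subs[0].c < 0.6
            else max(0.1, subs[0].c - 0.3), D=subs[1].D,
        )
    effects = QtlEffects(
        mu=rng.uniform(-1, 1), d=rng.uniform(0.2, 2.0),
        h=rng.uniform(-0.5, 0.5), sigma2=rng.uniform(0.5, 2.0),
    )
    return AdmixtureSpec(m=m, subpop1=subs[0], subpop2=subs[1], effects=effects)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
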