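"""Spurious association in an admixed sample, and its removal.

Simulates a sample from two diverged subpopulations in which the test
marker has NO linkage disequilibrium with the QTL inside either
subpopulation — any association is an artefact of the admixture — then
fits the three tests.  The uncorrected regression finds a strong (bogus)
effect; the control-marker-corrected and membership-covariate regressions
do not.
"""

from admixqtl import (
    default_null_scenario,
    fit_corrected,
    fit_simple,
    fit_structured,
    simulate_admixed_sample,
    theoretical_coefficient,
)

spec = default_null_scenario()
sample = simulate_admixed_sample(spec, n=200, seed=42)

simple = fit_simple(sample.X, sample.Y)
corrected = fit_corrected(sample.X, sample.Z, sample.Y)
structured = fit_structured(sample.X, sample.membership_prob, sample.Y)

print(f"population-level slopes: simple b = "
      f"{theoretical_coefficient(spec, 'simple'):.3f}, "
      f"corrected b = {theoretical_coefficient(spec, 'corrected'):.3f}")
print(f"{'method':<12} {'b':>8} {'se':>7} {'p':>10}")
for res in (simple, corrected, structured):
    print(f"{res.method:<12} {res.b:8.3f} {res.se:7.3f} {res.p:10.2e}")
print("\nThe simple regression declares a highly significant slope that is "
      "pure stratification artefact;\nthe corrected test (using only one "
      "control marker on another chromosome) removes it.")
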