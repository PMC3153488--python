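"""Monte-Carlo size and power of the three tests over scenario presets.

Runs 200-replicate studies on a structured null (zero within-subpopulation
LD: the proportion significant is the type-I error) and on a scenario with
genuine LD partly masked by structure (the proportion is power).
"""

from admixqtl import run_replicate_study, table2_scenarios, theoretical_coefficient

for name in ("null-strong", "ld-strong"):
    spec = table2_scenarios()[name]
    out = run_replicate_study(spec, n=200, n_reps=200, alpha=0.05,
                              methods=("corrected", "simple", "structured"),
                              seed=7)
    kind = "type-I error" if name.startswith("null") else "power"
    print(f"\nscenario {name}  (proportion significant = {kind})")
    print(f"{'method':<12} {'mean b':>8} {'(theory)':>9} {'prop sig':>9}")
    for method, s in out.items():
        theory = theoretical_coefficient(spec, method)
        print(f"{method:<12} {s.mean_b:8.3f} {theory:9.3f} "
              f"{s.prop_significant:9.2f}")
print("\nOn the null the corrected test rejects at ~5% while the simple "
      "test rejects nearly always;\nwith genuine LD the corrected test "
      "retains power where the simple test has almost none.")
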