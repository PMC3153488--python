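"""A miniature eQTL scan: peak calling and cis/trans classification.

Builds a small admixed cohort where an expression trait is driven by a QTL
in LD with a marker near its own transcript (a cis architecture), plus
structured but causally unrelated markers on another chromosome.  The
corrected scan recovers the cis peak; the uncorrected scan also produces
spurious trans peaks.
"""

import numpy as np
import pandas as pd

from admixqtl import make_scenario, simulate_admixed_sample, sidak_threshold
from admixqtl.eqtl import TranscriptAnnotation, call_peaks, classify_cis_trans, scan_trait, summarize_scan

rng = np.random.default_rng(11)
spec = make_scenario(0.6, 0.6, 0.6, D1=0.1, D2=0.1)
n = 400
sample = simulate_admixed_sample(spec, n, seed=rng)

rows = {"rs_cis": sample.X}
chroms, positions = {"rs_cis": "1"}, {"rs_cis": 10_050_000}
for i in range(6):  # structured markers, no relation to the trait
    freqs = np.where(sample.true_label == 1, 0.8, 0.2)
    name = f"rs_bg{i}"
    rows[name] = rng.binomial(2, freqs).astype(float)
    chroms[name], positions[name] = "2", 5_000_000 + 6_000_000 * i
genotypes = pd.DataFrame(rows).T
genotypes.columns = [f"S{i}" for i in range(n)]
marker_map = pd.DataFrame({"chrom": pd.Series(chroms), "pos": pd.Series(positions)})
trait = pd.Series(sample.Y, index=genotypes.columns)
annot = TranscriptAnnotation(gene="GENE1", chrom="1", start=10_000_000,
                             end=10_020_000, strand="+")
threshold = sidak_threshold(0.05, len(genotypes))

for method in ("simple", "corrected"):
    kwargs = {"control": "auto"} if method == "corrected" else {}
    results = scan_trait(trait, genotypes, marker_map, method=method, **kwargs)
    peaks = call_peaks(results, threshold, gene="GENE1")
    for peak in peaks:
        classify_cis_trans(peak, annot, marker_map=marker_map)
    print(f"\n{method} scan: threshold {threshold:.2e}, {len(peaks)} peak(s)")
    for peak in peaks:
        print(f"  chr{peak.chrom}:{peak.position:,}  p = {peak.min_p:.2e}  "
              f"{peak.classification}  (R^2 = {peak.r2:.2f})")
    print(summarize_scan(peaks).T.to_string())
print("\nThe marker 30 kb from the transcript is called cis by both scans; "
      "the correction removes most\nof the structure-driven trans peaks on "
      "chromosome 2 and deflates the significance of the rest.")
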