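"""Peak calling, cis/trans classification and scan behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixqtl import assoc, simulate
from admixqtl.eqtl import (
    EqtlPeak,
    TranscriptAnnotation,
    call_peaks,
    classify_cis_trans,
    scan_trait,
    summarize_scan,
)


def results_frame(rows):
    """Minimal per-marker results table: (marker, chrom, pos, p)."""
    df = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "p"])
    return df.set_index("marker")


def make_structured_dataset(rng, n=200, causal_d=0.12, delta=0.6, n_chr2=8):
    """Admixed sample with one causal marker on chr1 and structured but
    trait-independent markers on chr1/chr2 (all frequency difference
    ``delta`` between subpopulations)."""
    spec = simulate.make_scenario(0.6, delta, delta, D1=causal_d * 2 / 3,
                                  D2=causal_d * 2 / 3)
    sample = simulate.simulate_admixed_sample(spec, n, seed=rng)
    rows = {"chr1_causal": sample.X}
    chroms = {"chr1_causal": "1"}
    positions = {"chr1_causal": 50_000_000}
    hi, lo = 0.5 + delta / 2, 0.5 - delta / 2
    def structured_marker():
        freqs = np.where(sample.true_label == 1, hi, lo)
        return rng.binomial(2, freqs).astype(float)
    for i in range(3):
        name = f"chr1_null_{i}"
        rows[name] = structured_marker()
        chroms[name] = "1"
        positions[name] = 60_000_000 + 6_000_000 * i
    for i in range(n_chr2):
        name = f"chr2_null_{i}"
        rows[name] = structured_marker()
        chroms[name] = "2"
        positions[name] = 10_000_000 + 6_000_000 * i
    genotypes = pd.DataFrame(rows).T
    genotypes.columns = [f"S{i}" for i in range(n)]
    marker_map = pd.DataFrame(
        {"chrom": pd.Series(chroms), "pos": pd.Series(positions)}
    ).loc[genotypes.index]
    trait = pd.Series(sample.Y, index=genotypes.columns)
    return genotypes, marker_map, trait


class TestScanTrait:
    def test_composition_matches_direct_fits(self, rng):
        genotypes = pd.DataFrame(
            rng.binomial(2, 0.5, (3, 30)).astype(float),
            index=["m1", "m2", "m3"],
            columns=[f"S{i}" for i in range(30)],
        )
        marker_map = pd.DataFrame(
            {"chrom": ["1", "1", "2"], "pos": [100, 200, 300]}, index=genotypes.index
        )
        trait = pd.Series(rng.normal(size=30), index=genotypes.columns)
        table = scan_trait(trait, genotypes, marker_map, method="simple")
        assert len(table) == 3
        for marker in genotypes.index:
            direct = assoc.fit_simple(genotypes.loc[marker].to_numpy(), trait.to_numpy())
            assert table.loc[marker, "p"] == pytest.approx(direct.p)
            assert table.loc[marker, "b"] == pytest.approx(direct.b)

    def test_all_missing_marker_flagged_not_dropped(self, rng):
        genotypes = pd.DataFrame(
            [[0, 1, 2, 1, 0, 1] * 5, [np.nan] * 30],
            index=["ok", "void"],
            columns=[f"S{i}" for i in range(30)],
            dtype=float,
        )
        marker_map = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1, 2]}, index=genotypes.index
        )
        trait = pd.Series(rng.normal(size=30), index=genotypes.columns)
        table = scan_trait(trait, genotypes, marker_map, method="simple")
        assert table.loc["void", "status"] == "all genotypes missing"
        assert np.isnan(table.loc["void", "p"])
        peaks = call_peaks(table, threshold=1.0)
        assert all("void" not in p.markers for p in peaks)

    def test_sample_alignment_by_id(self, rng):
        genotypes = pd.DataFrame(
            rng.binomial(2, 0.5, (1, 40)).astype(float),
            index=["m1"], columns=[f"S{i}" for i in range(40)],
        )
        marker_map = pd.DataFrame({"chrom": ["1"], "pos": [5]}, index=["m1"])
        trait = pd.Series(rng.normal(size=40), index=genotypes.columns)
        shuffled = trait.sample(frac=1.0, random_state=1)
        a = scan_trait(trait, genotypes, marker_map, method="simple")
        b = scan_trait(shuffled, genotypes, marker_map, method="simple")
        assert a.loc["m1", "p"] == pytest.approx(b.loc["m1", "p"])

    def test_disjoint_samples_error(self, rng):
        genotypes = pd.DataFrame([[0.0, 1.0]], index=["m1"], columns=["A", "B"])
        marker_map = pd.DataFrame({"chrom": ["1"], "pos": [1]}, index=["m1"])
        trait = pd.Series([1.0, 2.0], index=["C", "D"])
        with pytest.raises(ValueError, match="no overlapping sample"):
            scan_trait(trait, genotypes, marker_map, method="simple")


class TestCallPeaks:
    def test_no_significant_markers_no_peaks(self):
        res = results_frame([("a", "1", 100, 0.5), ("b", "1", 200, 0.9)])
        assert call_peaks(res, threshold=1e-3) == []

    def test_markers_within_5mb_merge(self):
        res = results_frame(
            [("a", "1", 1_000_000, 1e-6), ("b", "1", 4_000_000, 1e-8)]
        )
        peaks = call_peaks(res, threshold=1e-4)
        assert len(peaks) == 1
        assert peaks[0].position == 4_000_000  # summit at the smaller p
        assert peaks[0].min_p == 1e-8
        assert set(peaks[0].markers) == {"a", "b"}

    def test_markers_beyond_5mb_split(self):
        res = results_frame(
            [("a", "1", 1_000_000, 1e-6), ("b", "1", 7_000_001, 1e-8)]
        )
        assert len(call_peaks(res, threshold=1e-4)) == 2

    def test_exactly_5mb_still_merges(self):
        res = results_frame(
            [("a", "1", 1_000_000, 1e-6), ("b", "1", 6_000_000, 1e-8)]
        )
        assert len(call_peaks(res, threshold=1e-4)) == 1

    def test_chain_merging_is_single_linkage(self):
        # consecutive gaps of 4 Mb chain into one peak spanning 8 Mb
        res = results_frame(
            [("a", "1", 1_000_000, 1e-6), ("b", "1", 5_000_000, 1e-7),
             ("c", "1", 9_000_000, 1e-6)]
        )
        peaks = call_peaks(res, threshold=1e-4)
        assert len(peaks) == 1 and len(peaks[0].markers) == 3

    def test_chromosomes_never_merge_and_partition_is_exact(self):
        res = results_frame(
            [("a", "1", 1, 1e-6), ("b", "2", 2, 1e-6), ("c", "2", 10, 1e-6)]
        )
        peaks = call_peaks(res, threshold=1e-4)
        assert len(peaks) == 2
        members = [m for p in peaks for m in p.markers]
        assert sorted(members) == ["a", "b", "c"]  # each marker exactly once
        for p in peaks:
            assert len({res.loc[m, "chrom"] for m in p.markers}) == 1
            assert all(res.loc[m, "p"] >= p.min_p for m in p.markers)

    def test_order_invariance_and_idempotence(self, rng):
        rows = [(f"m{i}", "1", int(pos), float(p)) for i, (pos, p) in enumerate(
            zip(rng.integers(1, 100_000_000, 30), rng.random(30) * 1e-3)
        )]
        res = results_frame(rows)
        shuffled = res.sample(frac=1.0, random_state=4)
        peaks_a = call_peaks(res, threshold=1e-3)
        peaks_b = call_peaks(shuffled, threshold=1e-3)
        key = lambda p: (p.chrom, p.position)
        assert sorted([(p.position, p.min_p, sorted(p.markers)) for p in peaks_a]) == \
               sorted([(p.position, p.min_p, sorted(p.markers)) for p in peaks_b])
        # idempotence: re-calling on the summits alone returns the summits
        summits = results_frame(
            [(p.markers[0], p.chrom, p.position, p.min_p) for p in peaks_a
             if True]
        )
        resummit = call_peaks(summits, threshold=1e-3)
        assert {p.position for p in resummit} <= {p.position for p in peaks_a}

    def test_tie_break_lowest_position(self):
        res = results_frame([("b", "1", 2_000_000, 1e-8), ("a", "1", 1_000_000, 1e-8)])
        peaks = call_peaks(res, threshold=1e-4)
        assert peaks[0].position == 1_000_000


class TestClassifyCisTrans:
    annot = TranscriptAnnotation(gene="G", chrom="1", start=10_000_000,
                                 end=10_050_000, strand="+")

    def peak_at(self, pos, chrom="1"):
        return EqtlPeak(gene="G", chrom=chrom, position=pos, min_p=1e-9,
                        markers=["m"])

    def test_upstream_within_window_is_cis(self):
        assert classify_cis_trans(self.peak_at(10_000_000 - 400_000), self.annot) == "cis"

    def test_downstream_past_window_is_trans(self):
        assert classify_cis_trans(self.peak_at(10_050_000 + 501_000), self.annot) == "trans"

    def test_boundary_inclusive(self):
        assert classify_cis_trans(self.peak_at(10_050_000 + 500_000), self.annot) == "cis"

    def test_other_chromosome_is_trans(self):
        assert classify_cis_trans(self.peak_at(10_000_000, chrom="2"), self.annot) == "trans"

    def test_minus_strand_window_symmetric(self):
        minus = TranscriptAnnotation(gene="G", chrom="1", start=10_000_000,
                                     end=10_050_000, strand="-")
        # 400 kb beyond the 3' end (low-coordinate side for '-') is cis
        assert classify_cis_trans(self.peak_at(10_000_000 - 400_000), minus) == "cis"
        assert classify_cis_trans(self.peak_at(10_050_000 + 400_000), minus) == "cis"

    def test_missing_annotation_is_unknown(self):
        assert classify_cis_trans(self.peak_at(1), None) == "unknown"

    def test_any_member_marker_counts(self):
        marker_map = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [9_700_000, 20_000_000]},
            index=["near", "far"],
        )
        peak = EqtlPeak(gene="G", chrom="1", position=20_000_000, min_p=1e-9,
                        markers=["near", "far"])
        assert classify_cis_trans(peak, self.annot, marker_map=marker_map) == "cis"


class TestSummarizeScan:
    def test_empty(self):
        table = summarize_scan([])
        assert (table["count"] == 0).all()

    def test_small_example(self):
        peaks = [
            EqtlPeak("g1", "1", 100, 1e-9, ["a"], classification="cis"),
            EqtlPeak("g1", "2", 200, 1e-8, ["b"], classification="trans"),
        ]
        table = summarize_scan(peaks)["count"]
        assert table["2"] == 1 and table["1"] == 0
        assert table["total_eqtls"] == 2
        assert table["cis_eqtls"] == 1 and table["trans_eqtls"] == 1

    def test_totals_conserved_over_traits(self, rng):
        peaks = []
        per_trait = {}
        for t in range(10):
            k = int(rng.integers(0, 14))
            per_trait[f"g{t}"] = k
            for j in range(k):
                peaks.append(EqtlPeak(f"g{t}", "1", j, 1e-9, [f"m{j}"],
                                      classification="trans"))
        table = summarize_scan(peaks)["count"]
        assert table["total_eqtls"] == sum(per_trait.values())
        hist_total = sum(
            table[str(i)] * i for i in range(1, 10)
        ) + sum(v for v in per_trait.values() if v >= 10)
        assert hist_total == table["total_eqtls"]


class TestScanScience:
    def test_planted_cis_qtl_localised(self, rng):
        """With a strongly associated marker in an unstructured population
        the minimum p-value lands on the causal marker almost always."""
        spec = simulate.make_scenario(0.0, 0.0, 0.0, m=1.0, D1=0.2, D2=0.2)
        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            sample = simulate.simulate_admixed_sample(spec, 500, seed=rng)
            pvals = {"causal": assoc.fit_simple(sample.X, sample.Y).p}
            for j in range(7):
                noise = rng.binomial(2, 0.5, 500).astype(float)
                pvals[f"noise{j}"] = assoc.fit_simple(noise, sample.Y).p
            if min(pvals, key=pvals.get) == "causal":
                hits += 1
        assert hits >= 95

    def test_correction_removes_off_chromosome_peaks(self, rng):
        """Paired over replicates, the corrected scan yields fewer spurious
        off-chromosome peaks than the uncorrected scan (sign test)."""
        m1_wins = m2_wins = 0
        n_reps = 50
        for _ in range(n_reps):
            genotypes, marker_map, trait = make_structured_dataset(rng, n=150)
            threshold = assoc.sidak_threshold(0.05, len(genotypes))
            off = {}
            for method in ("corrected", "simple"):
                kwargs = {"control": "auto"} if method == "corrected" else {}
                res = scan_trait(trait, genotypes, marker_map, method=method,
                                 **kwargs)
                peaks = call_peaks(res, threshold)
                off[method] = sum(1 for p in peaks if p.chrom == "2")
            if off["corrected"] < off["simple"]:
                m1_wins += 1
            elif off["corrected"] > off["simple"]:
                m2_wins += 1
        assert stats.binomtest(m1_wins, m1_wins + m2_wins, 0.5,
                               alternative="greater").pvalue < 0.01
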