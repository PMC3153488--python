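"""File formats and run configuration.

Genotypes travel either as VCF (biallelic SNPs, ALT-allele counts) or as a
plain TSV dialect with columns ``marker, chrom, pos, <sample ids...>`` and
0/1/2/NA entries.  Phenotypes are TSV with a leading sample-id column and
one numeric column per trait.  Transcript annotation is read from BED
(0-based half-open, converted) or a 1-based TSV dialect.  All coordinates
are 1-based inclusive internally, matching VCF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eqtl import TranscriptAnnotation
from .popmodel import AdmixtureSpec, QtlEffects, SubpopulationModel
from .simulate import SampleData

__all__ = [
    "GenotypeDataset",
    "RunConfig",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes_tsv",
    "read_annotation",
    "spec_from_dict",
    "spec_to_dict",
    "read_scenario_yaml",
    "dataset_from_sample",
    "write_manifest",
]


@dataclass
class GenotypeDataset:
    """Genotype matrix plus marker map and provenance.

    ``matrix`` is markers-by-samples, float 0/1/2 with NaN for missing;
    ``marker_map`` is indexed by marker id with columns chrom, pos;
    ``counted_allele`` records which allele each count refers to.
    """

    matrix: pd.DataFrame
    marker_map: pd.DataFrame
    counted_allele: dict[str, str] = field(default_factory=dict)
    source: str = ""

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def markers(self) -> list[str]:
        return list(self.matrix.index)

    def missing_fraction(self) -> pd.Series:
        return self.matrix.isna().mean(axis=1)

    def __post_init__(self) -> None:
        if list(self.matrix.index) != list(self.marker_map.index):
            raise ValueError("matrix rows and marker map must list the same markers")
        vals = self.matrix.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype for marker {self.markers[bad[0]]!r}, sample "
                f"{self.samples[bad[1]]!r} is not in {{0, 1, 2, NA}}"
            )
        # keep the map position-sorted within each chromosome
        order = self.marker_map.sort_values(["chrom", "pos"], kind="stable").index
        self.marker_map = self.marker_map.loc[order]
        self.matrix = self.matrix.loc[order]


def read_genotypes(path, fmt: str = "tsv012") -> GenotypeDataset:
    """Load a genotype dataset from ``path`` ("tsv012" or "vcf")."""
    path = Path(path)
    if fmt == "tsv012":
        return _read_tsv012(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_tsv012(path: Path) -> GenotypeDataset:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["marker", "chrom", "pos"]:
            raise ValueError(
                f"{path}:1: expected header starting 'marker\\tchrom\\tpos'; got {header[:3]}"
            )
        samples = header[3:]
        if not samples:
            raise ValueError(f"{path}:1: no sample columns")
        markers, chroms, poss, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            markers.append(parts[0])
            chroms.append(parts[1])
            try:
                poss.append(int(parts[2]))
                row = [float("nan") if v in ("NA", ".", "") else float(v) for v in parts[3:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if any(not (np.isnan(v) or v in (0.0, 1.0, 2.0)) for v in row):
                raise ValueError(f"{path}:{lineno}: genotype values must be 0/1/2/NA")
            rows.append(row)
    if not markers:
        raise ValueError(f"{path}: zero markers")
    matrix = pd.DataFrame(rows, index=markers, columns=samples, dtype=float)
    marker_map = pd.DataFrame({"chrom": chroms, "pos": poss}, index=markers)
    return GenotypeDataset(matrix=matrix, marker_map=marker_map, source=str(path))


def _read_vcf(path: Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, chroms, poss, rows, counted = [], [], [], [], {}
    n_skipped = 0
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_skipped += 1
            continue
        marker = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = variant.gt_types
        row = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt.astype(float)))
        markers.append(marker)
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        rows.append(row)
        counted[marker] = variant.ALT[0]
    if n_skipped:
        import logging

        logging.getLogger(__name__).info(
            "%s: skipped %d non-biallelic-SNP records", path, n_skipped
        )
    if not markers:
        raise ValueError(f"{path}: zero biallelic SNP markers")
    matrix = pd.DataFrame(np.vstack(rows), index=markers, columns=samples, dtype=float)
    marker_map = pd.DataFrame({"chrom": chroms, "pos": poss}, index=markers)
    return GenotypeDataset(
        matrix=matrix, marker_map=marker_map, counted_allele=counted, source=str(path)
    )


def write_genotypes_tsv(dataset: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos\t" + "\t".join(dataset.samples) + "\n")
        for marker in dataset.markers:
            row = dataset.matrix.loc[marker]
            vals = "\t".join(
                "NA" if np.isnan(v) else str(int(v)) for v in row.to_numpy(dtype=float)
            )
            m = dataset.marker_map.loc[marker]
            fh.write(f"{marker}\t{m['chrom']}\t{int(m['pos'])}\t{vals}\n")


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write the dataset as a minimal uncompressed VCF v4.2 (GT only).

    Counts are emitted as ALT-allele dosages: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1,
    NA -> ./. .  REF/ALT default to A/T unless a counted allele is recorded.
    """
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        for marker in dataset.markers:
            m = dataset.marker_map.loc[marker]
            alt = dataset.counted_allele.get(marker, "T")
            ref = "A" if alt != "A" else "G"
            gts = "\t".join(
                "./." if np.isnan(v) else gt_code[v]
                for v in dataset.matrix.loc[marker].to_numpy(dtype=float)
            )
            fh.write(f"{m['chrom']}\t{int(m['pos'])}\t{marker}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Trait table keyed by sample id (first TSV column).

    Duplicate sample ids and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index(id_col)
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col].replace({"NA": None, "": None}))
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, "
                f"sample {bad.index[0]!r}"
            ) from None
    return pd.DataFrame(out, index=df.index)


def write_phenotypes_tsv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def read_annotation(path, fmt: str = "tsv") -> dict[str, TranscriptAnnotation]:
    """Transcript annotation from BED (0-based half-open) or TSV (1-based).

    TSV columns: gene, chrom, start, end, strand.  BED columns: chrom,
    start, end, name[, score, strand]; BED intervals are converted to
    1-based inclusive.
    """
    annotations: dict[str, TranscriptAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end, gene = parts[0], int(parts[1]) + 1, int(parts[2]), parts[3]
                    strand = parts[5] if len(parts) > 5 else "+"
                elif fmt == "tsv":
                    if lineno == 1 and parts[0].lower() == "gene":
                        continue
                    gene, chrom, start, end, strand = (
                        parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4],
                    )
                else:
                    raise ValueError(f"unknown annotation format {fmt!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            annotations[gene] = TranscriptAnnotation(
                gene=gene, chrom=chrom, start=start, end=end, strand=strand
            )
    if not annotations:
        raise ValueError(f"{path}: no annotation records")
    return annotations


# ---------------------------------------------------------------------------
# scenario / run configuration
# ---------------------------------------------------------------------------

def spec_to_dict(spec: AdmixtureSpec) -> dict:
    return {
        "m": spec.m,
        "subpop1": asdict(spec.subpop1),
        "subpop2": asdict(spec.subpop2),
        "effects": asdict(spec.effects),
    }


def spec_from_dict(data: dict) -> AdmixtureSpec:
    return AdmixtureSpec(
        m=float(data["m"]),
        subpop1=SubpopulationModel(**data["subpop1"]),
        subpop2=SubpopulationModel(**data["subpop2"]),
        effects=QtlEffects(**data.get("effects", {})),
    )


def read_scenario_yaml(path) -> tuple[AdmixtureSpec, dict]:
    """Load an admixture scenario plus extra run settings from YAML.

    The file holds the spec fields (m, subpop1, subpop2, effects) and any
    further keys (n, alpha, n_reps, seed ...) which are returned untouched.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    spec = spec_from_dict(data)
    extras = {k: v for k, v in data.items() if k not in ("m", "subpop1", "subpop2", "effects")}
    return spec, extras


@dataclass
class RunConfig:
    """Settings of one analysis run; YAML round-trips losslessly."""

    method: str = "corrected"
    alpha_family: float = 0.05
    correction: str = "sidak"
    max_missing_fraction: float = 0.1
    merge_distance: int = 5_000_000
    cis_window: int = 500_000
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_family", "max_missing_fraction"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("merge_distance", "cis_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def dataset_from_sample(
    sample: SampleData,
    test_marker: tuple[str, str, int] = ("test", "1", 1_000_000),
    control_marker: tuple[str, str, int] = ("control", "2", 2_000_000),
    trait_name: str = "trait",
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Package a simulated sample as (GenotypeDataset, phenotype table).

    The test and control markers become two rows of the genotype matrix
    (optionally joined by the candidate panel if present) so simulated data
    round-trips through the public readers and writers.
    """
    ids = sample.sample_ids
    rows = {test_marker[0]: sample.X, control_marker[0]: sample.Z}
    chroms = {test_marker[0]: test_marker[1], control_marker[0]: control_marker[1]}
    poss = {test_marker[0]: test_marker[2], control_marker[0]: control_marker[2]}
    if sample.Z_panel is not None:
        for i, marker in enumerate(sample.Z_panel.index):
            rows[marker] = sample.Z_panel.loc[marker].to_numpy(dtype=float)
            chroms[marker] = sample.panel_map.loc[marker, "chrom"]
            poss[marker] = int(sample.panel_map.loc[marker, "pos"])
    matrix = pd.DataFrame(rows, index=ids).T
    marker_map = pd.DataFrame(
        {"chrom": pd.Series(chroms), "pos": pd.Series(poss)}
    ).loc[matrix.index]
    dataset = GenotypeDataset(matrix=matrix, marker_map=marker_map, source="simulated")
    traits = pd.DataFrame({trait_name: sample.Y}, index=pd.Index(ids, name="sample"))
    return dataset, traits


def write_manifest(path, config: dict, input_paths: list) -> None:
    """Reproducibility manifest: config, package version, input SHA-256."""
    from . import __version__

    digests = {}
    for p in input_paths:
        p = Path(p)
        digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"version": __version__, "config": config, "inputs": digests}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
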