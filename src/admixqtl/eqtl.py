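"""Genome-wide eQTL scanning: per-trait association profiles, peak calling
and cis/trans classification.

An eQTL is an independent peak in the p-value profile of one expression
trait along one chromosome: significant markers closer than a merge
distance (default 5 Mb) are chained into a single peak, located at the
member marker with the smallest p-value.  A peak is *cis* to its trait's
transcript if any member marker falls within a window extending 500 kb
upstream of the transcript start to 500 kb downstream of the 3' end
(strand-aware), and *trans* otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc

__all__ = [
    "TranscriptAnnotation",
    "EqtlPeak",
    "scan_trait",
    "call_peaks",
    "classify_cis_trans",
    "summarize_scan",
    "choose_controls_per_chromosome",
]

logger = logging.getLogger(__name__)

MERGE_DISTANCE = 5_000_000
CIS_WINDOW = 500_000


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Genomic extent of one transcript (1-based inclusive coordinates).

    ``start <= end`` regardless of strand; ``strand`` records transcription
    direction ('+' or '-'), which decides which side is "upstream of the
    transcript start" and which "downstream of the 3' end".
    """

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene}: start ({self.start}) must not exceed end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-'; got {self.strand!r}")


@dataclass
class EqtlPeak:
    """One independent association peak for one trait."""

    gene: str
    chrom: str
    position: int
    min_p: float
    markers: list[str] = field(default_factory=list)
    classification: str = "unclassified"
    r2: float = float("nan")


def _align_samples(trait: pd.Series, genotypes: pd.DataFrame) -> list[str]:
    shared = [s for s in genotypes.columns if s in trait.index]
    if not shared:
        raise ValueError("no overlapping sample ids between trait and genotypes")
    return shared


def choose_controls_per_chromosome(
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    max_missing_fraction: float = 0.1,
) -> dict[str, str]:
    """Best control marker for test markers of each chromosome.

    For every chromosome carrying test markers, candidates are autosomal
    markers on *other* chromosomes with tolerable missingness; the one with
    the largest variance excess (structure signal) is chosen.  Chromosomes
    with no eligible candidate are omitted (callers treat their markers as
    uncorrectable).
    """
    missing = genotypes.isna().mean(axis=1)
    controls: dict[str, str] = {}
    for chrom in marker_map["chrom"].unique():
        any_marker = marker_map.index[marker_map["chrom"] == chrom][0]
        try:
            candidates = assoc.screen_control_candidates(
                marker_map, any_marker, max_missing_fraction, missing
            )
        except ValueError:
            continue
        choice = assoc.select_control_marker(genotypes.loc[candidates], marker_map)
        controls[str(chrom)] = choice.marker
    return controls


def scan_trait(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    marker_map: pd.DataFrame,
    method: str = "corrected",
    control=None,
    membership=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Association test of one trait against every marker.

    Parameters
    ----------
    trait : Series of trait values indexed by sample id.
    genotypes : markers-by-samples DataFrame of 0/1/2 counts (NaN missing).
    marker_map : DataFrame indexed by marker id with columns chrom, pos.
    method : "corrected", "simple" or "structured".
    control : for method="corrected": either a control genotype vector
        aligned to the genotype columns, "auto" to pick the best control
        marker per test-marker chromosome from the matrix itself, or a
        mapping chromosome -> control marker id.
    membership : for method="structured": probability of membership to
        subpopulation 1, aligned to the genotype columns (Series by sample
        id or array in column order).

    Returns
    -------
    DataFrame with one row per marker: chrom, pos, b, se, t, df, p, r2,
    n_used, method, control_marker, status.  Markers that cannot be tested
    (monomorphic, all missing, weak control ...) keep their row with the
    failure reason in ``status`` and NaN statistics.
    """
    samples = _align_samples(trait, genotypes)
    y = trait.loc[samples].to_numpy(dtype=float)
    G = genotypes[samples]

    controls_by_chrom: dict[str, str] = {}
    control_vector: np.ndarray | None = None
    if method == "corrected":
        if control is None:
            raise ValueError("method='corrected' requires a control source")
        if isinstance(control, str) and control == "auto":
            controls_by_chrom = choose_controls_per_chromosome(G, marker_map)
        elif isinstance(control, dict):
            controls_by_chrom = {str(k): v for k, v in control.items()}
        else:
            control_vector = np.asarray(control, dtype=float)
    elif method == "structured":
        if membership is None:
            raise ValueError("method='structured' requires membership probabilities")
        if isinstance(membership, pd.Series):
            membership = membership.loc[samples]
        membership = np.asarray(membership, dtype=float)

    rows = []
    for marker in genotypes.index:
        chrom = marker_map.loc[marker, "chrom"]
        pos = int(marker_map.loc[marker, "pos"])
        x = G.loc[marker].to_numpy(dtype=float)
        record = {
            "marker": marker,
            "chrom": chrom,
            "pos": pos,
            "b": np.nan,
            "se": np.nan,
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "r2": np.nan,
            "n_used": 0,
            "method": method,
            "control_marker": "",
            "status": "ok",
        }
        try:
            if np.isnan(x).all():
                raise ValueError("all genotypes missing")
            if method == "simple":
                res = assoc.fit_simple(x, y)
            elif method == "corrected":
                if control_vector is not None:
                    z, z_id = control_vector, "user"
                else:
                    z_id = controls_by_chrom.get(str(chrom))
                    if z_id is None:
                        raise assoc.WeakControlMarkerError(
                            "no eligible control marker for this chromosome"
                        )
                    z = G.loc[z_id].to_numpy(dtype=float)
                res = assoc.fit_corrected(x, z, y, **fit_kwargs)
                record["control_marker"] = z_id
            elif method == "structured":
                res = assoc.fit_structured(x, membership, y)
            else:
                raise ValueError(f"unknown method {method!r}")
        except (ValueError, np.linalg.LinAlgError) as exc:
            record["status"] = str(exc) or type(exc).__name__
            logger.debug("marker %s skipped: %s", marker, exc)
            rows.append(record)
            continue
        t2 = res.t**2
        record.update(
            b=res.b,
            se=res.se,
            t=res.t,
            df=res.df,
            p=res.p,
            r2=t2 / (t2 + res.df) if np.isfinite(t2) else 1.0,
            n_used=res.n_used,
        )
        rows.append(record)
    return pd.DataFrame(rows).set_index("marker")


def call_peaks(
    results: pd.DataFrame,
    threshold: float,
    merge_distance: int = MERGE_DISTANCE,
    gene: str = "",
) -> list[EqtlPeak]:
    """Group significant markers into independent peaks per chromosome.

    Markers with p below ``threshold`` are chained by single linkage: a
    significant marker within ``merge_distance`` of any member of a peak
    joins that peak.  Each chain becomes one :class:`EqtlPeak` located at
    its smallest p-value (ties break to the lowest position).

    ``results`` needs columns chrom, pos, p (as produced by
    :func:`scan_trait`); rows with NaN p are ignored.
    """
    sig = results[results["p"].notna() & (results["p"] < threshold)]
    peaks: list[EqtlPeak] = []
    for chrom, group in sig.groupby("chrom", sort=False):
        group = group.sort_values(["pos", "p"], kind="stable")
        current: list[tuple[str, int, float]] = []
        last_pos = None
        for marker, row in group.iterrows():
            pos = int(row["pos"])
            if last_pos is not None and pos - last_pos > merge_distance:
                peaks.append(_make_peak(gene, str(chrom), current, results))
                current = []
            current.append((str(marker), pos, float(row["p"])))
            last_pos = pos
        if current:
            peaks.append(_make_peak(gene, str(chrom), current, results))
    return peaks


def _make_peak(
    gene: str, chrom: str, members: list[tuple[str, int, float]], results: pd.DataFrame
) -> EqtlPeak:
    best = min(members, key=lambda m: (m[2], m[1]))
    r2 = float("nan")
    if "r2" in results.columns:
        r2 = float(results.loc[best[0], "r2"])
    return EqtlPeak(
        gene=gene,
        chrom=chrom,
        position=best[1],
        min_p=best[2],
        markers=[m[0] for m in members],
        r2=r2,
    )


def classify_cis_trans(
    peak: EqtlPeak,
    annotation: TranscriptAnnotation | None,
    window: int = CIS_WINDOW,
    marker_map: pd.DataFrame | None = None,
) -> str:
    """Label a peak cis or trans relative to its trait's transcript.

    cis requires the same chromosome and at least one member marker inside
    the interval stretching ``window`` bp upstream of the transcript start
    to ``window`` bp downstream of the 3' end.  For a '+' strand transcript
    that is [start - window, end + window]; for a '-' strand transcript
    upstream lies at higher coordinates and downstream at lower ones, which
    yields the same genomic interval because the window is symmetric.

    Member positions are looked up in ``marker_map`` when given, otherwise
    the peak summit position is used for all members.  A missing annotation
    returns "unknown" (logged).
    """
    if annotation is None:
        logger.warning("no annotation for trait %s: classification unknown", peak.gene)
        peak.classification = "unknown"
        return "unknown"
    if str(peak.chrom) != str(annotation.chrom):
        peak.classification = "trans"
        return "trans"
    lo = annotation.start - window
    hi = annotation.end + window
    if marker_map is not None:
        positions = [int(marker_map.loc[m, "pos"]) for m in peak.markers]
    else:
        positions = [peak.position]
    label = "cis" if any(lo <= pos <= hi for pos in positions) else "trans"
    peak.classification = label
    return label


def summarize_scan(peaks: list[EqtlPeak]) -> pd.DataFrame:
    """eQTL-count histogram over traits plus cis/trans totals.

    Rows "1".."9" count traits with that many peaks, ">=10" traits with ten
    or more; then "total_eqtls", "cis_eqtls", "trans_eqtls".  Peaks
    classified "unknown"/"unclassified" count in the total only.
    """
    per_trait: dict[str, int] = {}
    cis = trans = 0
    for peak in peaks:
        per_trait[peak.gene] = per_trait.get(peak.gene, 0) + 1
        if peak.classification == "cis":
            cis += 1
        elif peak.classification == "trans":
            trans += 1
    index = [str(k) for k in range(1, 10)] + [">=10", "total_eqtls", "cis_eqtls", "trans_eqtls"]
    counts = dict.fromkeys(index, 0)
    for n_peaks in per_trait.values():
        key = str(n_peaks) if n_peaks < 10 else ">=10"
        counts[key] += 1
    counts["total_eqtls"] = len(peaks)
    counts["cis_eqtls"] = cis
    counts["trans_eqtls"] = trans
    return pd.DataFrame({"count": counts})
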