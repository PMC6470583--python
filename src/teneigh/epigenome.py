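"""Per-gene epigenetic summaries: histone fold-enrichment means and methylation calls.

Histone state comes in as bedGraph-style fold-enrichment segments per mark
and cell type. The per-gene summary is the segment fold values averaged over
the *whole* gene body: positions not covered by any segment contribute fold
0, so a gene sitting in a signal desert scores near zero.

Methylation comes in as region-level calls: intervals whose mean methylation
ratio (methylated / total reads at CpGs) is below 0.25 (hypo) or above 0.75
(hyper); intermediate regions are absent from the input by construction. A
gene's methylation mean is the overlap-length-weighted average of the
ratios of regions intersecting it, and the gene is called hypo-/hyper-
methylated when that mean crosses the same 0.25 / 0.75 thresholds,
"standard" otherwise (including genes no region touches, whose mean is
undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import GeneRecord, GenomicInterval, intersect_length

HISTONE_MARKS = ("H3K27me3", "H3K9me3", "H3K27ac", "H3K4me1", "H3K4me3", "H3K36me3")
HYPO_THRESHOLD = 0.25
HYPER_THRESHOLD = 0.75


@dataclass(frozen=True, slots=True)
class EnrichmentTrack:
    """Non-overlapping fold-enrichment segments for one mark in one cell type."""

    mark: str
    cell_type: str
    segments: tuple[tuple[GenomicInterval, float], ...]

    def __post_init__(self) -> None:
        for _, fold in self.segments:
            if not math.isfinite(fold) or fold < 0:
                raise ValueError(f"fold enrichment must be finite and >= 0, got {fold}")


@dataclass(frozen=True, slots=True)
class MethylationRegion:
    interval: GenomicInterval
    mean_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_ratio <= 1.0:
            raise ValueError(f"methylation ratio outside [0,1]: {self.mean_ratio}")

    @property
    def call(self) -> str:
        if self.mean_ratio < HYPO_THRESHOLD:
            return "hypo"
        if self.mean_ratio > HYPER_THRESHOLD:
            return "hyper"
        return "standard"


@dataclass(frozen=True, slots=True)
class EpigeneticSummary:
    gene_id: str
    cell_type: str
    mean_enrichment: dict  # mark -> mean fold over gene body
    methylation_mean: Optional[float]
    methylation_status: str


def mean_histone_enrichment(gene: GeneRecord, track: EnrichmentTrack) -> float:
    """Average fold enrichment over the gene body, uncovered positions counting as 0."""
    giv = gene.interval
    total = 0.0
    for seg_iv, fold in track.segments:
        ov = intersect_length(giv, seg_iv)
        if ov:
            total += fold * ov
    return total / giv.length


def methylation_status(
    mean: Optional[float],
    hypo: float = HYPO_THRESHOLD,
    hyper: float = HYPER_THRESHOLD,
) -> str:
    if mean is None:
        return "standard"
    if mean < hypo:
        return "hypo"
    if mean > hyper:
        return "hyper"
    return "standard"


def gene_methylation(
    gene: GeneRecord, regions: Sequence[MethylationRegion]
) -> tuple[Optional[float], str]:
    """Length-weighted mean methylation ratio over regions covering the gene.

    Returns ``(None, "standard")`` when no region intersects the gene: the
    mean is undefined and such genes are excluded from correlation analyses.
    """
    giv = gene.interval
    weighted = 0.0
    weight = 0
    for region in regions:
        ov = intersect_length(giv, region.interval)
        if ov:
            weighted += region.mean_ratio * ov
            weight += ov
    if weight == 0:
        return None, "standard"
    mean = weighted / weight
    return mean, methylation_status(mean)


# ---------------------------------------------------------------------------
# readers and batch summarization


def read_bedgraph_track(path: Union[str, Path], mark: str, cell_type: str) -> EnrichmentTrack:
    """Read a bedGraph (chrom, start, end, value) into an EnrichmentTrack."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    segments = tuple(
        (GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.value))
        for r in df.itertuples(index=False)
    )
    return EnrichmentTrack(mark=mark, cell_type=cell_type, segments=segments)


def read_methylation_regions(path: Union[str, Path]) -> list[MethylationRegion]:
    """Read a TSV/BED-like table (chrom, start, end, mean_ratio)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "mean_ratio"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "mean_ratio": float},
    )
    return [
        MethylationRegion(GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.mean_ratio))
        for r in df.itertuples(index=False)
    ]


class _SegmentIndex:
    """Per-chromosome sorted segment index (same scheme as TEIndex)."""

    def __init__(self, spans: Sequence[tuple[GenomicInterval, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, v in spans:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, v))
        self._data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.array([(s, e) for s, e, _ in rows], dtype=np.int64)
            vals = np.array([v for _, _, v in rows], dtype=float)
            self._data[chrom] = (arr[:, 0], arr[:, 1], np.maximum.accumulate(arr[:, 1]), vals)

    def overlapping(self, chrom: str, start: int, end: int):
        entry = self._data.get(chrom)
        if entry is None:
            return np.empty((0, 2), dtype=np.int64), np.empty(0)
        starts, ends, cummax, vals = entry
        hi = np.searchsorted(starts, end, side="left")
        lo = np.searchsorted(cummax[:hi], start, side="right")
        mask = ends[lo:hi] > start
        spans = np.column_stack([starts[lo:hi][mask], ends[lo:hi][mask]])
        return spans, vals[lo:hi][mask]


def summarize_genes(
    genes: Sequence[GeneRecord],
    tracks: Sequence[EnrichmentTrack],
    methylation: dict,
    cell_type: str,
    hypo: float = HYPO_THRESHOLD,
    hyper: float = HYPER_THRESHOLD,
) -> list[EpigeneticSummary]:
    """Batch per-gene summaries for one cell type.

    ``tracks`` holds one EnrichmentTrack per histone mark; ``methylation``
    maps nothing in particular -- pass the region list under key
    ``"regions"`` (kept as a mapping so callers can add metadata).
    """
    track_index = {t.mark: _SegmentIndex(t.segments) for t in tracks}
    regions = methylation.get("regions", [])
    meth_index = _SegmentIndex([(r.interval, r.mean_ratio) for r in regions])
    out = []
    for gene in genes:
        giv = gene.interval
        enrich = {}
        for mark, idx in track_index.items():
            spans, vals = idx.overlapping(giv.chrom, giv.start, giv.end)
            if len(spans) == 0:
                enrich[mark] = 0.0
            else:
                ov = np.minimum(spans[:, 1], giv.end) - np.maximum(spans[:, 0], giv.start)
                enrich[mark] = float((vals * ov).sum() / giv.length)
        spans, vals = meth_index.overlapping(giv.chrom, giv.start, giv.end)
        if len(spans) == 0:
            mmean: Optional[float] = None
        else:
            ov = np.minimum(spans[:, 1], giv.end) - np.maximum(spans[:, 0], giv.start)
            mmean = float((vals * ov).sum() / ov.sum())
        out.append(
            EpigeneticSummary(
                gene_id=gene.gene_id,
                cell_type=cell_type,
                mean_enrichment=enrich,
                methylation_mean=mmean,
                methylation_status=methylation_status(mmean, hypo, hyper),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[EpigeneticSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"gene_id": s.gene_id, "cell_type": s.cell_type}
        row.update({mark: s.mean_enrichment.get(mark, 0.0) for mark in HISTONE_MARKS})
        row["methylation_mean"] = np.nan if s.methylation_mean is None else s.methylation_mean
        row["methylation_status"] = s.methylation_status
        rows.append(row)
    return pd.DataFrame(rows)
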