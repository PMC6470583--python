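"""Genomic interval arithmetic and readers for the tabular formats used throughout.

All coordinates are held internally as 0-based half-open spans (BED-native).
GFF3 input, which is 1-based inclusive, is converted on read. Strand is
carried for completeness but no downstream metric conditions on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import pandas as pd

Strand = Literal["+", "-", "."]

#: sentinel returned by :func:`gene_pair_distance`
DIFFERENT_CHROMOSOMES = "different_chromosomes"
OVERLAPPING = "overlapping"


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A located gene; the span is the full annotated gene body."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True, slots=True)
class TEInsertion:
    """One assembled transposable-element insertion."""

    te_id: str
    interval: GenomicInterval
    family_label: str = ""


@dataclass(slots=True)
class FamilyRecord:
    """A two-gene (duplicated) family with its substitution-rate estimates.

    ``omega`` is dN/dS; it is undefined (``nan``, ``omega_defined=False``)
    when dS is zero.
    """

    family_id: str
    gene1_id: str
    gene2_id: str
    dS: float
    dN: float
    omega: float = field(default=math.nan)
    omega_defined: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.gene1_id == self.gene2_id:
            raise ValueError(f"family {self.family_id}: members must differ")
        if self.dS < 0 or self.dN < 0:
            raise ValueError(f"family {self.family_id}: negative substitution rate")
        if self.dS > 0:
            self.omega = self.dN / self.dS
            self.omega_defined = True
        else:
            self.omega = math.nan
            self.omega_defined = False


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if disjoint or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gene_pair_distance(g1: GeneRecord, g2: GeneRecord) -> Union[str, int]:
    """Physical separation of two genes.

    Returns :data:`DIFFERENT_CHROMOSOMES` when the genes are on different
    chromosomes, :data:`OVERLAPPING` when their spans intersect, and otherwise
    the gap in bp between the nearest ends.
    """
    a, b = g1.interval, g2.interval
    if a.chrom != b.chrom:
        return DIFFERENT_CHROMOSOMES
    if intersect_length(a, b) > 0 or a.end == b.start or b.end == a.start:
        # abutting genes have zero gap; report the gap (0) only for a strict
        # empty intersection -- touching spans do not overlap
        if intersect_length(a, b) > 0:
            return OVERLAPPING
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bed_line(fields: Sequence[str], lineno: int, path: str) -> tuple[str, int, int, str, str]:
    if len(fields) < 4:
        raise ValueError(f"{path}:{lineno}: BED line needs >= 4 columns, got {len(fields)}")
    chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or end < 0:
        raise ValueError(f"{path}:{lineno}: negative coordinate")
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    return chrom, start, end, name, strand


def _parse_gff3_line(fields: Sequence[str], lineno: int, path: str) -> tuple[str, int, int, str, str]:
    if len(fields) < 9:
        raise ValueError(f"{path}:{lineno}: GFF3 line needs 9 columns, got {len(fields)}")
    chrom, start_s, end_s, strand_s = fields[0], fields[3], fields[4], fields[6]
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start1 < 1 or end1 < 1:
        raise ValueError(f"{path}:{lineno}: GFF3 coordinates are 1-based and positive")
    name = ""
    for attr in fields[8].split(";"):
        attr = attr.strip()
        if attr.startswith("ID="):
            name = attr[3:]
            break
    if not name:
        name = f"feature_{lineno}"
    strand = strand_s if strand_s in ("+", "-") else "."
    # 1-based inclusive -> 0-based half-open
    return chrom, start1 - 1, end1, name, strand


def read_intervals(
    path: Union[str, Path],
    fmt: Literal["bed", "gff3"] = "bed",
    as_: Literal["gene", "te"] = "gene",
) -> list:
    """Read gene or TE records from a BED (>=4 columns) or GFF3 file.

    BED is taken as 0-based half-open; GFF3 is converted from 1-based
    inclusive. Malformed lines raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    parse = _parse_bed_line if fmt == "bed" else _parse_gff3_line
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            chrom, start, end, name, strand = parse(line.split("\t"), lineno, str(path))
            iv = GenomicInterval(chrom, start, end, strand)
            if as_ == "gene":
                records.append(GeneRecord(name, iv))
            else:
                records.append(TEInsertion(name, iv))
    return records


def write_bed(records: Iterable[Union[GeneRecord, TEInsertion]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            name = rec.gene_id if isinstance(rec, GeneRecord) else rec.te_id
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")


def read_families(path: Union[str, Path]) -> list[FamilyRecord]:
    """Read a family table (TSV with header: family_id, gene1_id, gene2_id, dS, dN)."""
    df = pd.read_csv(path, sep="\t")
    required = {"family_id", "gene1_id", "gene2_id", "dS", "dN"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FamilyRecord(str(r.family_id), str(r.gene1_id), str(r.gene2_id), float(r.dS), float(r.dN))
        for r in df.itertuples(index=False)
    ]


def write_families(families: Iterable[FamilyRecord], path: Union[str, Path]) -> None:
    rows = [
        {"family_id": f.family_id, "gene1_id": f.gene1_id, "gene2_id": f.gene2_id, "dS": f.dS, "dN": f.dN}
        for f in families
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    """Read a two-column chrom<TAB>size table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need chrom<TAB>size")
            sizes[parts[0]] = int(parts[1])
    return sizes
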