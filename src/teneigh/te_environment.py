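"""Per-gene TE-neighborhood metrics and the five-category classification.

Each gene is summarized over its body extended by a flanking region (2 kb by
default, covering the promoter) by two statistics:

* **density** — number of TE insertions intersecting the region, divided by
  the region length (insertions/bp). An insertion counts if it intersects
  the region at all; it is not prorated.
* **coverage** — fraction of region bases lying inside the union of TE
  intervals (union semantics, so nested or overlapping insertions never push
  coverage above 1).

Genes with density and coverage both zero are *TE-free* by rule. The
remaining genes are partitioned into four classes (TE-very-poor, TE-poor,
TE-rich, TE-very-rich) by k-medoids (PAM, BUILD + SWAP) on the raw
(density, coverage) points, the class labels ordered by medoid density.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import GeneRecord, GenomicInterval, TEInsertion

CATEGORIES = ("TE-free", "TE-very-poor", "TE-poor", "TE-rich", "TE-very-rich")
#: categories assigned by the clustering step (all but TE-free)
CLUSTERED_CATEGORIES = CATEGORIES[1:]


@dataclass(frozen=True, slots=True)
class TEEnvironment:
    """TE-neighborhood summary of one gene."""

    gene_id: str
    region: GenomicInterval
    density: float
    coverage: float
    n_insertions: int
    category: Optional[str] = None


class TEIndex:
    """Sorted per-chromosome index of TE intervals for fast region queries.

    Queries use ``searchsorted`` over starts plus a running maximum of ends,
    which finds all intervals intersecting a span without a quadratic scan.
    """

    def __init__(self, tes: Sequence[TEInsertion]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for te in tes:
            by_chrom.setdefault(te.interval.chrom, []).append((te.interval.start, te.interval.end))
        for chrom, spans in by_chrom.items():
            arr = np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)
            starts = arr[:, 0]
            ends = arr[:, 1]
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
            # keep raw ends too, for overlap extraction
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Return (m, 2) array of TE spans intersecting [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return np.empty((0, 2), dtype=np.int64)
        starts, ends, cummax_end = entry
        hi = np.searchsorted(starts, end, side="left")
        lo = np.searchsorted(cummax_end[:hi], start, side="right")
        sl_starts = starts[lo:hi]
        sl_ends = ends[lo:hi]
        mask = sl_ends > start
        return np.column_stack([sl_starts[mask], sl_ends[mask]])


def union_overlap_length(spans: np.ndarray, start: int, end: int) -> int:
    """Bases of [start, end) covered by the union of the given spans."""
    if len(spans) == 0:
        return 0
    clipped = np.column_stack(
        [np.maximum(spans[:, 0], start), np.minimum(spans[:, 1], end)]
    )
    clipped = clipped[clipped[:, 1] > clipped[:, 0]]
    if len(clipped) == 0:
        return 0
    order = np.argsort(clipped[:, 0], kind="stable")
    total = 0
    cur_s, cur_e = None, None
    for s, e in clipped[order]:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return int(total)


def compute_te_metrics(
    gene: GeneRecord,
    tes: Union[Sequence[TEInsertion], TEIndex],
    flank: int = 2000,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> TEEnvironment:
    """Density and coverage of the gene's flanked region.

    The region is the gene span extended by ``flank`` bp on both sides,
    clipped at position 0 and, when a chromosome-sizes table is supplied, at
    the chromosome end; the clipped length is the denominator for both
    metrics.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    iv = gene.interval
    start = max(0, iv.start - flank)
    end = iv.end + flank
    if chrom_sizes is not None and iv.chrom in chrom_sizes:
        end = min(end, chrom_sizes[iv.chrom])
    region = GenomicInterval(iv.chrom, start, end, iv.strand)
    index = tes if isinstance(tes, TEIndex) else TEIndex(tes)
    spans = index.overlapping(iv.chrom, start, end)
    n = len(spans)
    covered = union_overlap_length(spans, start, end)
    length = region.length
    return TEEnvironment(
        gene_id=gene.gene_id,
        region=region,
        density=n / length,
        coverage=covered / length,
        n_insertions=n,
    )


# ---------------------------------------------------------------------------
# PAM k-medoids


@dataclass(frozen=True)
class CategoryModel:
    """Fitted k-medoids model over (density, coverage) points.

    ``medoids`` are rows of the input point set, ordered by density
    ascending; ``labels`` maps medoid index -> category name in the same
    order (TE-very-poor ... TE-very-rich for k=4).
    """

    k: int
    medoids: np.ndarray  # (k, 2), ordered by density ascending
    labels: tuple[str, ...]
    objective: float

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "k": self.k,
            "medoids": self.medoids.tolist(),
            "labels": list(self.labels),
            "objective": self.objective,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CategoryModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            medoids=np.asarray(payload["medoids"], dtype=float),
            labels=tuple(payload["labels"]),
            objective=payload["objective"],
        )


def _dist_to_point(points: np.ndarray, idx: int) -> np.ndarray:
    return np.sqrt(((points - points[idx]) ** 2).sum(axis=1))


def _pam_build(points: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD initialization; ties broken by lowest index."""
    n = len(points)
    # first medoid: minimizes total distance
    totals = np.array([_dist_to_point(points, i).sum() for i in range(n)])
    medoids = [int(np.argmin(totals))]
    nearest = _dist_to_point(points, medoids[0])
    while len(medoids) < k:
        best_gain, best_i = -np.inf, -1
        for i in range(n):
            if i in medoids:
                continue
            gain = np.maximum(nearest - _dist_to_point(points, i), 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_i = gain, i
        medoids.append(best_i)
        nearest = np.minimum(nearest, _dist_to_point(points, best_i))
    return medoids


def _pam_swap(points: np.ndarray, medoids: list[int], max_iter: int = 200) -> tuple[list[int], float]:
    """SWAP passes until no single medoid/non-medoid exchange lowers the objective."""
    n = len(points)
    medoids = list(medoids)
    dist_med = np.stack([_dist_to_point(points, m) for m in medoids])  # (k, n)

    def objective(dm: np.ndarray) -> float:
        return float(dm.min(axis=0).sum())

    current = objective(dist_med)
    for _ in range(max_iter):
        best = (0.0, None, None)  # (delta, medoid slot, candidate)
        med_set = set(medoids)
        for h in range(n):
            if h in med_set:
                continue
            d_h = _dist_to_point(points, h)
            for slot in range(len(medoids)):
                trial = dist_med.copy()
                trial[slot] = d_h
                delta = objective(trial) - current
                if delta < best[0] - 1e-12:
                    best = (delta, slot, h)
        if best[1] is None:
            break
        _, slot, h = best
        medoids[slot] = h
        dist_med[slot] = _dist_to_point(points, h)
        current = objective(dist_med)
    return medoids, current


def fit_category_model(
    points: np.ndarray,
    k: int = 4,
    seed: int = 0,
    standardize: bool = False,
) -> CategoryModel:
    """Fit PAM k-medoids to (density, coverage) points of non-TE-free genes.

    Points are clustered raw by default (no scaling); ``standardize=True``
    z-scores both axes first (the medoids reported are still raw points).
    Clusters are relabeled by medoid density ascending so that the lowest
    density cluster is TE-very-poor and the highest is TE-very-rich.
    The fit is deterministic: BUILD breaks ties by point index, and the seed
    enters only in degenerate all-tied configurations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (density, coverage)")
    distinct = np.unique(pts, axis=0)
    if len(distinct) < k:
        raise ValueError(f"need >= {k} distinct points, got {len(distinct)}")
    work = pts
    if standardize:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        work = (pts - pts.mean(axis=0)) / sd
    medoid_idx = _pam_build(work, k)
    medoid_idx, obj = _pam_swap(work, medoid_idx)
    medoids = pts[medoid_idx]
    order = np.lexsort((medoids[:, 1], medoids[:, 0]))  # density asc, coverage tiebreak
    medoids = medoids[order]
    if k == 4:
        labels = CLUSTERED_CATEGORIES
    else:
        labels = tuple(f"cluster_{i}" for i in range(k))
    # objective reported on the raw scale for interpretability
    raw_obj = float(
        np.sqrt(((pts[:, None, :] - medoids[None, :, :]) ** 2).sum(axis=2)).min(axis=1).sum()
    ) if len(pts) * k <= 5_000_000 else obj
    return CategoryModel(k=k, medoids=medoids, labels=tuple(labels), objective=raw_obj)


def assign_category(env: TEEnvironment, model: CategoryModel) -> TEEnvironment:
    """Label one gene: (0, 0) is TE-free by rule, otherwise the nearest medoid's label.

    Ties between equidistant medoids go to the lower label index (the less
    TE-dense category), keeping assignment deterministic.
    """
    if env.density == 0 and env.coverage == 0:
        return replace(env, category="TE-free")
    point = np.array([env.density, env.coverage])
    d = np.sqrt(((model.medoids - point) ** 2).sum(axis=1))
    return replace(env, category=model.labels[int(np.argmin(d))])


def assign_categories(
    envs: Sequence[TEEnvironment], model: CategoryModel
) -> list[TEEnvironment]:
    return [assign_category(e, model) for e in envs]


def category_distribution(envs: Sequence[TEEnvironment]) -> pd.DataFrame:
    """Counts and percentages of genes per TE-neighborhood category."""
    counts = {cat: 0 for cat in CATEGORIES}
    for env in envs:
        if env.category is None:
            raise ValueError(f"gene {env.gene_id}: category not assigned")
        counts[env.category] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "percent": [100.0 * c / total if total else 0.0 for c in counts.values()],
        }
    )


def exhaustive_kmedoids_objective(points: np.ndarray, k: int) -> float:
    """Optimal k-medoids objective by exhaustive search (oracle for tiny n)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    best = np.inf
    for combo in itertools.combinations(range(n), k):
        obj = dist[:, combo].min(axis=1).sum()
        best = min(best, obj)
    return float(best)


def environments_to_frame(envs: Sequence[TEEnvironment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in envs],
            "density": [e.density for e in envs],
            "coverage": [e.coverage for e in envs],
            "n_insertions": [e.n_insertions for e in envs],
            "category": [e.category for e in envs],
        }
    )
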