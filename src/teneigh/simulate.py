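"""Synthetic input generator for the full pipeline.

Emulates the structure of the real inputs (a repeat annotation, a coding
gene set, two-copy families with substitution-rate estimates, histone
fold-enrichment tracks, methylation region calls, and an FPKM table over
four blood cell types) with controlled statistical structure:

* genes are packed without overlap on multiple chromosomes, lengths
  log-normal;
* each gene carries a latent TE-neighborhood component (TE-free plus four
  classes whose (density, coverage) profiles default to the values observed
  for the human gene set); TE insertions are laid down inside the flanked
  gene region to realize that profile, plus Poisson background insertions in
  intergenic space;
* families share their component with a calibrated copy probability so the
  realized fraction of same-category pairs matches ``p_same_category``;
* per-family epigenetic values (histone enrichment, methylation level) are
  tied by a Gaussian copula whose parameter is chosen so the within-family
  *Spearman* correlation equals ``rho_epigenome`` / ``rho_methylation``;
* expression profiles over the four cell types come from a per-family
  shared Dirichlet mean, with the member-level concentration decreasing
  with family age so expression divergence d_m grows with dS.

The ``uniform`` placement mode instead scatters TEs as a homogeneous
Poisson process along each chromosome, for rate-recovery checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .epigenome import HISTONE_MARKS, EnrichmentTrack, MethylationRegion
from .intervals import (
    FamilyRecord,
    GeneRecord,
    GenomicInterval,
    TEInsertion,
    write_bed,
    write_families,
)

CELL_TYPES = ("CD14", "erythroblast", "CD8T", "macrophage")

#: default component mixture over TE-neighborhood classes (human coding-gene
#: proportions: TE-free, very-poor, poor, rich, very-rich)
DEFAULT_CATEGORY_WEIGHTS = (0.0408, 0.2550, 0.3108, 0.2560, 0.1374)

#: default (density in insertions/bp, coverage fraction) per clustered class
DEFAULT_CATEGORY_PROFILES = (
    (0.0003, 0.086),
    (0.0007, 0.196),
    (0.0012, 0.304),
    (0.0025, 0.419),
)


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent bivariate-normal correlation giving Spearman rho_s after any
    monotone marginal transform (Gaussian copula identity)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic bundle; defaults mirror the human study scale."""

    n_chromosomes: int = 22
    chromosome_length: int = 100_000_000
    n_genes: int = 18_938
    gene_length_log_mean: float = math.log(20_000)
    gene_length_log_sd: float = 0.8
    min_gene_length: int = 500
    flank: int = 2000

    placement: str = "stratified"  # or "uniform"
    te_rate: float = 1.0e-3  # background / uniform insertion rate per bp
    te_length_log_mean: float = math.log(300.0)
    te_length_log_sd: float = 0.8
    category_weights: tuple = DEFAULT_CATEGORY_WEIGHTS
    category_profiles: tuple = DEFAULT_CATEGORY_PROFILES
    profile_noise_sd: float = 0.15  # lognormal jitter on per-gene density/coverage targets

    n_families: int = 1420
    p_same_category: float = 0.319
    p_same_chromosome: float = 0.132

    rho_epigenome: float = 0.4  # target within-family Spearman rho, histone marks
    rho_methylation: float = 0.4
    enrichment_gamma_shape: float = 2.0
    enrichment_gamma_scale: float = 1.0
    methylation_beta: tuple = (2.5, 1.5)
    p_methylation_missing: float = 0.1

    # family age mixture (young, middle-age, old) and dS models per class
    age_weights: tuple = (99 / 1420, 189 / 1420, 1132 / 1420)
    old_ds_gamma: tuple = (2.0, 0.82)  # shape, scale; dS = 2 + gamma
    omega_log_median: float = math.log(0.129)
    omega_log_sd: float = 0.6

    dirichlet_mean_alpha: float = 1.2
    kappa_by_age: tuple = (60.0, 15.0, 5.0)  # young, middle-age, old
    fpkm_log_mean: float = math.log(10.0)
    fpkm_log_sd: float = 1.2
    p_family_both_silent: float = 0.188
    p_family_one_silent: float = 0.137
    p_singleton_silent: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.category_weights) - 1.0) > 1e-6:
            raise ValueError("category_weights must sum to 1")
        if not 0.0 <= self.p_same_category <= 1.0:
            raise ValueError("p_same_category must lie in [0,1]")
        if abs(sum(self.age_weights) - 1.0) > 1e-6:
            raise ValueError("age_weights must sum to 1")
        if self.placement not in ("stratified", "uniform"):
            raise ValueError("placement must be 'stratified' or 'uniform'")
        if 2 * self.n_families > self.n_genes:
            raise ValueError("need at least 2 genes per family")

    def copy_probability(self) -> float:
        """Component copy probability calibrated so that the realized fraction
        of same-category families targets p_same_category.

        With s the collision probability of two independent component draws,
        realized same-category ~= p_copy + (1 - p_copy) * s, so
        p_copy = (target - s) / (1 - s).
        """
        w = np.asarray(self.category_weights)
        s = float((w**2).sum())
        return float(np.clip((self.p_same_category - s) / (1.0 - s), 0.0, 1.0))


@dataclass
class Bundle:
    """In-memory synthetic dataset, writable as a plain-text file tree."""

    genes: list
    tes: list
    families: list
    chrom_sizes: dict
    enrichment_tracks: dict  # (cell_type, mark) -> EnrichmentTrack
    methylation: dict  # cell_type -> list[MethylationRegion]
    fpkm: pd.DataFrame  # genes x cell types
    components: dict = field(default_factory=dict)  # gene_id -> latent component index
    config: Optional[GeneratorConfig] = None

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(self.genes, outdir / "genes.bed")
        write_bed(self.tes, outdir / "tes.bed")
        write_families(self.families, outdir / "families.tsv")
        with open(outdir / "chrom.sizes", "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        self.fpkm.rename_axis("gene_id").reset_index().to_csv(
            outdir / "fpkm.tsv", sep="\t", index=False
        )
        for ct, regions in self.methylation.items():
            with open(outdir / f"methylation_{ct}.tsv", "w") as fh:
                for r in regions:
                    iv = r.interval
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.mean_ratio:.6f}\n")
        for (ct, mark), track in self.enrichment_tracks.items():
            with open(outdir / f"enrichment_{ct}_{mark}.bedGraph", "w") as fh:
                for iv, v in track.segments:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6f}\n")
        if self.config is not None:
            (outdir / "generator_config.json").write_text(
                json.dumps(asdict(self.config), indent=2, default=list)
            )


# ---------------------------------------------------------------------------
# generation steps


def _place_genes(cfg: GeneratorConfig, rng: np.random.Generator) -> list:
    """Pack non-overlapping genes; flanked regions are separated too."""
    min_gap = 2 * cfg.flank + 200
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    genes = []
    gid = 0
    for c in range(cfg.n_chromosomes):
        n = int(per_chrom[c])
        if n == 0:
            continue
        lengths = np.maximum(
            rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd, n),
            cfg.min_gene_length,
        ).astype(np.int64)
        required = int(lengths.sum()) + (n + 1) * min_gap
        if required > cfg.chromosome_length:
            raise ValueError(
                f"infeasible packing: chromosome {c + 1} needs {required} bp "
                f"for {n} genes but has {cfg.chromosome_length}"
            )
        slack = cfg.chromosome_length - required
        gaps = min_gap + np.floor(rng.dirichlet(np.ones(n + 1)) * slack).astype(np.int64)
        pos = 0
        chrom = f"chr{c + 1}"
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneRecord(f"G{gid:06d}", GenomicInterval(chrom, start, end, strand)))
            pos = end
    return genes


def _sample_components(
    cfg: GeneratorConfig, rng: np.random.Generator, genes: list, family_pairs: list
) -> np.ndarray:
    """Latent TE-neighborhood component per gene (0 = TE-free)."""
    w = np.asarray(cfg.category_weights)
    comp = rng.choice(len(w), size=len(genes), p=w)
    p_copy = cfg.copy_probability()
    for i1, i2 in family_pairs:
        if rng.random() < p_copy:
            comp[i2] = comp[i1]
    return comp


def _place_tes_stratified(
    cfg: GeneratorConfig, rng: np.random.Generator, genes: list, comp: np.ndarray
) -> list:
    tes: list = []
    tid = 0
    regions_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene, c in zip(genes, comp):
        iv = gene.interval
        start = max(0, iv.start - cfg.flank)
        end = iv.end + cfg.flank
        regions_by_chrom.setdefault(iv.chrom, []).append((start, end))
        if c == 0:
            continue  # TE-free: leave the whole region empty
        dens, cov = cfg.category_profiles[c - 1]
        L = end - start
        dens_t = dens * rng.lognormal(0.0, cfg.profile_noise_sd)
        cov_t = float(np.clip(cov * rng.lognormal(0.0, cfg.profile_noise_sd), 0.005, 0.95))
        n_te = max(1, int(rng.poisson(dens_t * L)))
        covered = max(n_te, int(round(cov_t * L)))
        pieces = np.maximum(1, np.floor(rng.dirichlet(np.full(n_te, 2.0)) * covered)).astype(
            np.int64
        )
        free = L - int(pieces.sum())
        if free < 0:  # extreme draw; shrink proportionally
            pieces = np.maximum(1, (pieces * (0.9 * L / pieces.sum())).astype(np.int64))
            free = L - int(pieces.sum())
        gaps = np.floor(rng.dirichlet(np.ones(n_te + 1)) * free).astype(np.int64)
        pos = start
        for k in range(n_te):
            pos += int(gaps[k])
            tid += 1
            tes.append(
                TEInsertion(f"TE{tid:07d}", GenomicInterval(iv.chrom, pos, pos + int(pieces[k])))
            )
            pos += int(pieces[k])
    # background insertions strictly inside intergenic space
    for chrom, regions in regions_by_chrom.items():
        regions.sort()
        bounds = [0] + [b for r in regions for b in r] + [cfg.chromosome_length]
        for gstart, gend in zip(bounds[::2], bounds[1::2]):
            gap = gend - gstart
            if gap <= 10:
                continue
            n_bg = rng.poisson(cfg.te_rate * gap)
            if n_bg == 0:
                continue
            starts = np.sort(rng.integers(gstart, gend, size=n_bg))
            lengths = np.maximum(
                1, rng.lognormal(cfg.te_length_log_mean, cfg.te_length_log_sd, n_bg)
            ).astype(np.int64)
            for s, ln in zip(starts, lengths):
                e = min(int(s) + int(ln), gend)
                if e <= s:
                    continue
                tid += 1
                tes.append(TEInsertion(f"TE{tid:07d}", GenomicInterval(chrom, int(s), e)))
    return tes


def _place_tes_uniform(cfg: GeneratorConfig, rng: np.random.Generator) -> list:
    tes = []
    tid = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        n = rng.poisson(cfg.te_rate * cfg.chromosome_length)
        starts = np.sort(rng.integers(0, cfg.chromosome_length, size=n))
        lengths = np.maximum(
            1, rng.lognormal(cfg.te_length_log_mean, cfg.te_length_log_sd, n)
        ).astype(np.int64)
        for s, ln in zip(starts, lengths):
            tid += 1
            tes.append(
                TEInsertion(
                    f"TE{tid:07d}",
                    GenomicInterval(chrom, int(s), min(int(s) + int(ln), cfg.chromosome_length)),
                )
            )
    return tes


def _sample_families(
    cfg: GeneratorConfig, rng: np.random.Generator, genes: list
) -> tuple[list, list]:
    """Pick disjoint gene pairs; a fraction shares a chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.interval.chrom, []).append(i)
    order = rng.permutation(len(genes))
    used = np.zeros(len(genes), dtype=bool)
    pairs = []
    pos = 0
    while len(pairs) < cfg.n_families and pos < len(order):
        i1 = int(order[pos])
        pos += 1
        if used[i1]:
            continue
        used[i1] = True
        i2 = -1
        if rng.random() < cfg.p_same_chromosome:
            candidates = [j for j in by_chrom[genes[i1].interval.chrom] if not used[j]]
            if candidates:
                i2 = int(candidates[int(rng.integers(len(candidates)))])
        if i2 < 0:
            while pos < len(order) and used[int(order[pos])]:
                pos += 1
            if pos >= len(order):
                break
            i2 = int(order[pos])
            pos += 1
        used[i2] = True
        pairs.append((i1, i2))
    if len(pairs) < cfg.n_families:
        raise ValueError("could not pair enough genes into families")

    age_idx = rng.choice(3, size=len(pairs), p=np.asarray(cfg.age_weights))
    families = []
    for k, (i1, i2) in enumerate(pairs):
        a = int(age_idx[k])
        if a == 0:
            dS = float(rng.beta(0.55, 1.0))  # young, mass near 0
        elif a == 1:
            dS = float(1.0 + rng.random())  # middle-age, uniform [1,2)
        else:
            shape, scale = cfg.old_ds_gamma
            dS = float(2.0 + rng.gamma(shape, scale))
        omega = float(rng.lognormal(cfg.omega_log_median, cfg.omega_log_sd))
        families.append(
            FamilyRecord(
                family_id=f"F{k + 1:05d}",
                gene1_id=genes[i1].gene_id,
                gene2_id=genes[i2].gene_id,
                dS=dS,
                dN=omega * dS,
            )
        )
    return families, pairs


def _correlated_normals(
    rng: np.random.Generator, n_genes: int, pairs: list, rho_s: float
) -> np.ndarray:
    """Standard normals, family pairs correlated to hit Spearman rho_s."""
    z = rng.standard_normal(n_genes)
    r = spearman_to_pearson_latent(rho_s)
    eps = rng.standard_normal(len(pairs))
    for k, (i1, i2) in enumerate(pairs):
        z[i2] = r * z[i1] + math.sqrt(1.0 - r * r) * eps[k]
    return z


def _make_epigenome(
    cfg: GeneratorConfig, rng: np.random.Generator, genes: list, pairs: list
) -> tuple[dict, dict]:
    tracks: dict = {}
    methylation: dict = {}
    n = len(genes)
    for ct in CELL_TYPES:
        for mark in HISTONE_MARKS:
            z = _correlated_normals(rng, n, pairs, cfg.rho_epigenome)
            target = stats.gamma.ppf(
                stats.norm.cdf(z), a=cfg.enrichment_gamma_shape, scale=cfg.enrichment_gamma_scale
            )
            segments = []
            for gi, gene in enumerate(genes):
                iv = gene.interval
                t = float(target[gi])
                # three abutting pieces whose length-weighted mean equals the target
                w = rng.dirichlet(np.ones(3))
                u = rng.gamma(2.0, 1.0, size=3)
                denom = float((w * u).sum())
                vals = u * (t / denom) if denom > 0 else np.full(3, t)
                cut1 = iv.start + max(1, int(w[0] * iv.length))
                cut2 = min(iv.end - 1, cut1 + max(1, int(w[1] * iv.length)))
                cut1 = min(cut1, cut2 - 1) if cut2 - 1 > iv.start else cut1
                spans = [(iv.start, cut1), (cut1, cut2), (cut2, iv.end)]
                for (s, e), v in zip(spans, vals):
                    if e > s:
                        segments.append((GenomicInterval(iv.chrom, s, e), float(max(v, 0.0))))
            tracks[(ct, mark)] = EnrichmentTrack(mark=mark, cell_type=ct, segments=tuple(segments))

        z = _correlated_normals(rng, n, pairs, cfg.rho_methylation)
        a, b = cfg.methylation_beta
        mu = stats.beta.ppf(stats.norm.cdf(z), a, b)
        missing = rng.random(n) < cfg.p_methylation_missing
        regions = []
        for gi, gene in enumerate(genes):
            if missing[gi]:
                continue
            iv = gene.interval
            m = float(np.clip(mu[gi], 1e-4, 1 - 1e-4))
            if m < 0.25 or m > 0.75:
                regions.append(MethylationRegion(iv, m))
            else:
                # mix one hypo and one hyper region so the length-weighted
                # gene mean lands at the intermediate target
                r1, r2 = 0.08, 0.92
                w1 = (r2 - m) / (r2 - r1)
                cut = iv.start + max(1, min(iv.length - 1, int(round(w1 * iv.length))))
                regions.append(MethylationRegion(GenomicInterval(iv.chrom, iv.start, cut), r1))
                regions.append(MethylationRegion(GenomicInterval(iv.chrom, cut, iv.end), r2))
        methylation[ct] = regions
    return tracks, methylation


def _make_expression(
    cfg: GeneratorConfig, rng: np.random.Generator, genes: list, families: list, pairs: list
) -> pd.DataFrame:
    n = len(genes)
    k_types = len(CELL_TYPES)
    fpkm = np.zeros((n, k_types))
    in_family = np.zeros(n, dtype=bool)
    kappa = dict(zip(("young", "middle-age", "old"), cfg.kappa_by_age))
    from .families import assign_age_class

    for fam, (i1, i2) in zip(families, pairs):
        in_family[i1] = in_family[i2] = True
        u = rng.random()
        silent1 = silent2 = False
        if u < cfg.p_family_both_silent:
            silent1 = silent2 = True
        elif u < cfg.p_family_both_silent + cfg.p_family_one_silent:
            if rng.random() < 0.5:
                silent1 = True
            else:
                silent2 = True
        mean = rng.dirichlet(np.full(k_types, cfg.dirichlet_mean_alpha))
        kap = kappa[assign_age_class(fam.dS)]
        for idx, silent in ((i1, silent1), (i2, silent2)):
            if silent:
                continue
            profile = rng.dirichlet(np.maximum(kap * mean, 0.05))
            total = rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sd)
            fpkm[idx] = total * profile
    singles = ~in_family
    n_single = int(singles.sum())
    silent_single = rng.random(n_single) < cfg.p_singleton_silent
    profiles = rng.dirichlet(np.full(k_types, cfg.dirichlet_mean_alpha), size=n_single)
    totals = rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sd, n_single)
    fpkm[singles] = np.where(silent_single[:, None], 0.0, totals[:, None] * profiles)
    return pd.DataFrame(fpkm, index=[g.gene_id for g in genes], columns=list(CELL_TYPES))


def generate(config: GeneratorConfig, seed: int = 0) -> Bundle:
    """Draw a complete synthetic input bundle, deterministic under the seed."""
    rng = np.random.default_rng(seed)
    genes = _place_genes(config, rng)
    families, pairs = _sample_families(config, rng, genes)
    comp = _sample_components(config, rng, genes, pairs)
    if config.placement == "stratified":
        tes = _place_tes_stratified(config, rng, genes, comp)
    else:
        tes = _place_tes_uniform(config, rng)
    tracks, methylation = _make_epigenome(config, rng, genes, pairs)
    fpkm = _make_expression(config, rng, genes, families, pairs)
    chrom_sizes = {f"chr{c + 1}": config.chromosome_length for c in range(config.n_chromosomes)}
    return Bundle(
        genes=genes,
        tes=tes,
        families=families,
        chrom_sizes=chrom_sizes,
        enrichment_tracks=tracks,
        methylation=methylation,
        fpkm=fpkm,
        components={g.gene_id: int(c) for g, c in zip(genes, comp)},
        config=config,
    )


# ---------------------------------------------------------------------------
# hand-sized worked fixture


def worked_fixture() -> tuple[Bundle, dict]:
    """A miniature bundle whose metric values are hand-computed.

    Returns the bundle and a dict of expected values (per-gene density,
    coverage, enrichment and methylation for cell type CD14 / mark H3K4me3;
    per-family d_m) for use as an end-to-end oracle.
    """
    g = {
        "G1": GeneRecord("G1", GenomicInterval("chr1", 10_000, 11_000, "+")),
        "G2": GeneRecord("G2", GenomicInterval("chr1", 30_000, 31_000, "+")),
        "G3": GeneRecord("G3", GenomicInterval("chr1", 50_000, 51_000, "-")),
        "G4": GeneRecord("G4", GenomicInterval("chr1", 70_000, 71_000, "+")),
        "G5": GeneRecord("G5", GenomicInterval("chr2", 10_000, 11_000, "+")),
        "G6": GeneRecord("G6", GenomicInterval("chr2", 30_000, 31_000, "-")),
        "G7": GeneRecord("G7", GenomicInterval("chr2", 50_000, 51_000, "+")),
        "G8": GeneRecord("G8", GenomicInterval("chr2", 70_000, 71_000, "+")),
    }
    tes = [
        # G1 region [8000,13000): two insertions, 1000 covered bases
        TEInsertion("T1", GenomicInterval("chr1", 8_500, 9_000)),
        TEInsertion("T2", GenomicInterval("chr1", 12_000, 12_500)),
        # G2 region [28000,33000): overlapping pair crossing the region edge,
        # union within region = [28000,28600) = 600 bases
        TEInsertion("T3", GenomicInterval("chr1", 27_500, 28_500)),
        TEInsertion("T4", GenomicInterval("chr1", 28_400, 28_600)),
        # G4 region [68000,73000): one 2500-bp insertion -> coverage 0.5
        TEInsertion("T5", GenomicInterval("chr1", 69_000, 71_500)),
        # G5 region [8000,13000): three 500-bp insertions -> coverage 0.3
        TEInsertion("T6", GenomicInterval("chr2", 8_200, 8_700)),
        TEInsertion("T7", GenomicInterval("chr2", 9_500, 10_000)),
        TEInsertion("T8", GenomicInterval("chr2", 11_000, 11_500)),
        # G7 region [48000,53000): four insertions, 2000 covered
        TEInsertion("T9", GenomicInterval("chr2", 48_100, 48_600)),
        TEInsertion("T10", GenomicInterval("chr2", 49_000, 49_500)),
        TEInsertion("T11", GenomicInterval("chr2", 50_200, 50_700)),
        TEInsertion("T12", GenomicInterval("chr2", 51_800, 52_300)),
    ]
    families = [
        FamilyRecord("F1", "G1", "G2", dS=0.5, dN=0.05),
        FamilyRecord("F2", "G3", "G6", dS=1.5, dN=0.30),
        FamilyRecord("F3", "G4", "G7", dS=2.5, dN=0.25),
    ]
    ct = "CD14"
    mark = "H3K4me3"
    tracks = {
        (ct, mark): EnrichmentTrack(
            mark=mark,
            cell_type=ct,
            segments=(
                # G1: 500 bases at fold 4 inside a 1000-bp gene -> mean 2.0
                (GenomicInterval("chr1", 10_200, 10_700), 4.0),
                # G2: 300 bases at fold 2 + 200 bases at fold 5 -> mean 1.6
                (GenomicInterval("chr1", 30_000, 30_300), 2.0),
                (GenomicInterval("chr1", 30_600, 30_800), 5.0),
            ),
        )
    }
    methylation = {
        ct: [
            # G1 fully covered at ratio 0.8 -> hyper
            MethylationRegion(GenomicInterval("chr1", 10_000, 11_000), 0.8),
            # G2: 600 bases at 0.1 + 400 bases at 0.9 -> mean 0.42 -> standard
            MethylationRegion(GenomicInterval("chr1", 30_000, 30_600), 0.1),
            MethylationRegion(GenomicInterval("chr1", 30_600, 31_000), 0.9),
        ]
    }
    # singleton genes G5/G8 balance the columns to a common total (15), so
    # TPM conversion preserves every gene's cross-cell-type profile and the
    # hand-computed d_m values apply to the TPM path too
    fpkm = pd.DataFrame(
        {
            "CD14": [2.0, 1.0, 3.0, 1.0, 3.0, 3.0, 0.0, 2.0],
            "erythroblast": [2.0, 1.0, 1.0, 0.0, 5.0, 1.0, 1.0, 4.0],
            "CD8T": [0.0, 1.0, 2.0, 0.0, 5.0, 2.0, 0.0, 5.0],
            "macrophage": [0.0, 1.0, 4.0, 0.0, 3.0, 4.0, 0.0, 3.0],
        },
        index=list(g),
    )
    bundle = Bundle(
        genes=list(g.values()),
        tes=tes,
        families=families,
        chrom_sizes={"chr1": 100_000, "chr2": 100_000},
        enrichment_tracks=tracks,
        methylation=methylation,
        fpkm=fpkm,
        config=None,
    )
    expected = {
        "te_metrics": {
            "G1": {"density": 4.0e-4, "coverage": 0.2},
            "G2": {"density": 4.0e-4, "coverage": 0.12},
            "G3": {"density": 0.0, "coverage": 0.0},
            "G4": {"density": 2.0e-4, "coverage": 0.5},
            "G5": {"density": 6.0e-4, "coverage": 0.3},
            "G6": {"density": 0.0, "coverage": 0.0},
            "G7": {"density": 8.0e-4, "coverage": 0.4},
            "G8": {"density": 0.0, "coverage": 0.0},
        },
        "enrichment": {("G1", ct, mark): 2.0, ("G2", ct, mark): 1.6},
        "methylation": {
            ("G1", ct): (0.8, "hyper"),
            ("G2", ct): (0.42, "standard"),
            ("G3", ct): (None, "standard"),
        },
        # F1: (2,2,0,0) vs (1,1,1,1) -> 0.5; F2: (3,1,2,4) vs (3,1,2,4) -> 0.0;
        # F3: (1,0,0,0) vs (0,1,0,0) -> 1.0
        "d_m": {"F1": 0.5, "F2": 0.0, "F3": 1.0},
        "age_class": {"F1": "young", "F2": "middle-age", "F3": "old"},
    }
    return bundle, expected


def write_expected(expected: dict, path: Union[str, Path]) -> None:
    """Serialize the worked-fixture expectations as JSON (tuple keys flattened)."""
    flat = {}
    for section, values in expected.items():
        flat[section] = {
            "|".join(k) if isinstance(k, tuple) else k: v for k, v in values.items()
        }
    Path(path).write_text(json.dumps(flat, indent=2))
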