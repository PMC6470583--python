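"""End-to-end orchestration: bundle in, report tables and statistics out.

``run`` takes a directory of input files (genes BED, TEs BED, families TSV,
per-cell-type methylation TSVs, per-cell-type/mark enrichment bedGraphs,
FPKM TSV) and produces:

* per-gene TE density/coverage/category (TSV) and the fitted category model
  (JSON);
* the category distribution of all genes and of duplicated genes;
* the unordered pair-context table with its goodness-of-fit statistic and
  Monte-Carlo p-value;
* within-family Spearman correlations of each epigenetic summary, BH
  adjusted within each declared battery;
* expression divergence d_m per family with its class and age class, and
  the Kruskal-Wallis / Kolmogorov-Smirnov distribution comparisons;
* a machine-readable JSON of every statistic with the config and seeds
  echoed.

``from_printed_tables`` runs only the pair-context test from category
marginals and pair counts supplied directly, so the test battery can be
applied to published tables without interval data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import expression as xm
from . import families as fam
from . import te_environment as te
from .epigenome import (
    HISTONE_MARKS,
    read_bedgraph_track,
    read_methylation_regions,
    summaries_to_frame,
    summarize_genes,
)
from .intervals import read_chrom_sizes, read_families, read_intervals
from .simulate import CELL_TYPES, Bundle

logger = logging.getLogger("teneigh")


@dataclass
class PipelineConfig:
    """All numeric knobs of the analysis; defaults are the study's values."""

    flank: int = 2000
    k: int = 4
    hypo_threshold: float = 0.25
    hyper_threshold: float = 0.75
    expression_threshold: float = 0.5
    age_thresholds: tuple = (1.0, 2.0)
    mc_replicates: int = 2000
    marginal_source: str = "duplicated"  # or "genome-wide"
    seed: int = 0
    stratify_correlations_by_age: bool = True

    def __post_init__(self) -> None:
        if not self.hypo_threshold < self.hyper_threshold:
            raise ValueError("methylation thresholds must be ordered")
        if self.marginal_source not in ("duplicated", "genome-wide"):
            raise ValueError("marginal_source must be 'duplicated' or 'genome-wide'")


def read_bundle(indir: Union[str, Path]) -> Bundle:
    """Load a file bundle written by the generator (or laid out the same way)."""
    indir = Path(indir)
    genes = read_intervals(indir / "genes.bed", "bed", as_="gene")
    tes = read_intervals(indir / "tes.bed", "bed", as_="te")
    families = read_families(indir / "families.tsv")
    chrom_sizes = read_chrom_sizes(indir / "chrom.sizes") if (indir / "chrom.sizes").exists() else {}
    fpkm = xm.read_fpkm_table(indir / "fpkm.tsv")
    cell_types = [c for c in fpkm.columns]
    methylation = {}
    tracks = {}
    for ct in cell_types:
        mpath = indir / f"methylation_{ct}.tsv"
        methylation[ct] = read_methylation_regions(mpath) if mpath.exists() else []
        for mark in HISTONE_MARKS:
            tpath = indir / f"enrichment_{ct}_{mark}.bedGraph"
            if tpath.exists():
                tracks[(ct, mark)] = read_bedgraph_track(tpath, mark, ct)
    return Bundle(
        genes=genes,
        tes=tes,
        families=families,
        chrom_sizes=chrom_sizes,
        enrichment_tracks=tracks,
        methylation=methylation,
        fpkm=fpkm,
        config=None,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    te_environments: pd.DataFrame
    category_model: te.CategoryModel
    category_distribution_all: pd.DataFrame
    category_distribution_duplicated: pd.DataFrame
    pair_table: fam.PairContextTable
    same_fraction: float
    family_frame: pd.DataFrame
    epigenome_frame: pd.DataFrame
    correlations: pd.DataFrame
    distribution_tests: dict
    stats: dict = field(default_factory=dict)

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.te_environments.to_csv(outdir / "te_environment.tsv", sep="\t", index=False)
        self.category_model.to_json(outdir / "category_model.json")
        self.category_distribution_all.to_csv(outdir / "category_distribution_all.tsv", sep="\t", index=False)
        self.category_distribution_duplicated.to_csv(
            outdir / "category_distribution_duplicated.tsv", sep="\t", index=False
        )
        self.pair_table.to_frame().to_csv(outdir / "pair_context.tsv", sep="\t", index=False)
        self.family_frame.to_csv(outdir / "families.tsv", sep="\t", index=False)
        self.epigenome_frame.to_csv(outdir / "epigenome_summaries.tsv", sep="\t", index=False)
        self.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        (outdir / "statistics.json").write_text(json.dumps(self.stats, indent=2))


def _correlation_battery(
    summaries: pd.DataFrame,
    families: Sequence,
    env_labels: Mapping[str, str],
    age_by_family: Mapping[str, str],
    cell_types: Sequence[str],
    seed: int,
    by_age: bool,
) -> pd.DataFrame:
    """Spearman correlations per (cell type x measure x partition [x age]).

    BH adjustment is applied within four batteries: histone tests pooled
    over all ages, methylation tests pooled over all ages, and the same two
    stratified by age. The battery an entry belongs to is recoverable from
    its age column.
    """
    measures = list(HISTONE_MARKS) + ["methylation_mean"]
    ages = ["all"] + (list(fam.AGE_CLASSES) if by_age else [])
    results: list[fam.CorrelationResult] = []
    per_ct = {ct: df.set_index("gene_id") for ct, df in summaries.groupby("cell_type")}
    # cell types taken together: pairs concatenated across cell types
    for partition in ("all", "same", "different"):
        fams_sel = [
            f for f in families if partition == "all" or env_labels.get(f.family_id) == partition
        ]
        for measure in measures:
            values_by_ct = {ct: per_ct[ct][measure].to_dict() for ct in cell_types if ct in per_ct}
            results.append(
                fam.pooled_within_family_correlation(
                    values_by_ct, fams_sel, stratum=("pooled", measure, partition, "all"), seed=seed
                )
            )
    for age in ages:
        fams_age = [
            f for f in families if age == "all" or age_by_family.get(f.family_id) == age
        ]
        for partition in ("all", "same", "different"):
            fams_sel = [
                f
                for f in fams_age
                if partition == "all" or env_labels.get(f.family_id) == partition
            ]
            for ct in cell_types:
                if ct not in per_ct:
                    continue
                table = per_ct[ct]
                for measure in measures:
                    values = table[measure].to_dict()
                    res = fam.within_family_correlation(
                        values, fams_sel, stratum=(ct, measure, partition, age), seed=seed
                    )
                    results.append(res)
    # BH within batteries
    def battery(r: fam.CorrelationResult) -> tuple:
        is_meth = r.stratum[1] == "methylation_mean"
        return (is_meth, r.stratum[3] == "all", r.stratum[0] == "pooled")

    for key in {battery(r) for r in results}:
        fam.attach_qvalues([r for r in results if battery(r) == key])
    return fam.correlation_frame(results)


def run(
    bundle: Union[Bundle, str, Path],
    config: Optional[PipelineConfig] = None,
    outdir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run every stage on a bundle (in memory or a directory path)."""
    cfg = config or PipelineConfig()
    if not isinstance(bundle, Bundle):
        bundle = read_bundle(bundle)
    genes = bundle.genes
    by_id = {g.gene_id: g for g in genes}
    logger.info("stage te-classify: %d genes, %d TE insertions", len(genes), len(bundle.tes))

    index = te.TEIndex(bundle.tes)
    envs = [
        te.compute_te_metrics(g, index, flank=cfg.flank, chrom_sizes=bundle.chrom_sizes or None)
        for g in genes
    ]
    points = np.array([(e.density, e.coverage) for e in envs if not (e.density == 0 and e.coverage == 0)])
    model = te.fit_category_model(points, k=cfg.k, seed=cfg.seed)
    envs = te.assign_categories(envs, model)
    env_frame = te.environments_to_frame(envs)
    categories = dict(zip(env_frame.gene_id, env_frame.category))

    dist_all = te.category_distribution(envs)
    dup_ids = {gid for f in bundle.families for gid in (f.gene1_id, f.gene2_id)}
    dup_envs = [e for e in envs if e.gene_id in dup_ids]
    dist_dup = te.category_distribution(dup_envs)

    logger.info("stage analyze: %d families", len(bundle.families))
    table = fam.pair_context_counts(bundle.families, categories)
    if cfg.marginal_source == "duplicated":
        marginals = dist_dup.set_index("category")["count"].reindex(list(te.CATEGORIES)).to_numpy()
    else:
        marginals = dist_all.set_index("category")["count"].reindex(list(te.CATEGORIES)).to_numpy()
    table = fam.pair_context_test(table, marginals, B=cfg.mc_replicates, seed=cfg.seed)
    env_labels, same_fraction = fam.same_environment_partition(bundle.families, categories)

    # epigenome summaries
    cell_types = list(bundle.fpkm.columns) if len(bundle.fpkm.columns) else list(CELL_TYPES)
    summaries = []
    for ct in cell_types:
        tracks = [t for (c, _), t in bundle.enrichment_tracks.items() if c == ct]
        regions = bundle.methylation.get(ct, [])
        summaries.extend(
            summarize_genes(
                genes, tracks, {"regions": regions}, ct,
                hypo=cfg.hypo_threshold, hyper=cfg.hyper_threshold,
            )
        )
    epi_frame = summaries_to_frame(summaries)

    # expression
    tpm = xm.fpkm_frame_to_tpm(bundle.fpkm)
    age_by_family = {f.family_id: fam.assign_age_class(f.dS) for f in bundle.families}
    fam_rows = []
    for f in bundle.families:
        v1 = tpm.loc[f.gene1_id].to_numpy() if f.gene1_id in tpm.index else None
        v2 = tpm.loc[f.gene2_id].to_numpy() if f.gene2_id in tpm.index else None
        both_silent = (
            v1 is None or v2 is None or (float(v1.sum()) == 0 and float(v2.sum()) == 0)
        )
        one_silent = (
            not both_silent
            and v1 is not None
            and v2 is not None
            and (float(v1.sum()) == 0 or float(v2.sum()) == 0)
        )
        d_m = None if both_silent else xm.manhattan_divergence(v1, v2)
        fam_rows.append(
            {
                "family_id": f.family_id,
                "gene1_id": f.gene1_id,
                "gene2_id": f.gene2_id,
                "dS": f.dS,
                "dN": f.dN,
                "omega": f.omega,
                "age_class": age_by_family[f.family_id],
                "te_environment": env_labels[f.family_id],
                "d_m": np.nan if d_m is None else d_m,
                "d_m_class": None if d_m is None else xm.divergence_class(d_m),
                "one_member_silent": bool(one_silent),
                "excluded_both_silent": bool(both_silent),
            }
        )
    family_frame = pd.DataFrame(fam_rows)

    correlations = _correlation_battery(
        epi_frame,
        bundle.families,
        env_labels,
        age_by_family,
        cell_types,
        seed=cfg.seed,
        by_age=cfg.stratify_correlations_by_age,
    )

    # distribution comparisons
    usable = family_frame[~family_frame.excluded_both_silent]
    dm_by_age = {a: usable.loc[usable.age_class == a, "d_m"].dropna().to_numpy() for a in fam.AGE_CLASSES}
    omega_same = family_frame.loc[family_frame.te_environment == "same", "omega"].dropna().to_numpy()
    omega_diff = family_frame.loc[family_frame.te_environment == "different", "omega"].dropna().to_numpy()
    dist_tests = {
        "d_m_by_age_kruskal": fam.kruskal_wallis(dm_by_age),
        "omega_same_vs_different_ks": fam.ks_two_sample(omega_same, omega_diff),
    }
    for env_label in ("same", "different"):
        sub = usable[usable.te_environment == env_label]
        groups = {a: sub.loc[sub.age_class == a, "d_m"].dropna().to_numpy() for a in fam.AGE_CLASSES}
        dist_tests[f"d_m_by_age_kruskal_{env_label}"] = fam.kruskal_wallis(groups)

    # auxiliary goodness-of-fit statistics, in their natural form:
    # (a) same-vs-different counts against the independence baseline (df = 1)
    q_pair = table.expected_probs
    diag_mask = np.array([i == j for i, j in fam.PAIR_CELLS])
    s_base = float(q_pair[diag_mask].sum())
    n_same = int(round(same_fraction * table.n))
    same_vs_random_chisq = fam.chisq_gof(
        [n_same, table.n - n_same], np.array([s_base, 1.0 - s_base])
    )
    # (b) duplicated-gene category counts against genome-wide proportions (df = 4)
    all_counts = dist_all.set_index("category")["count"].reindex(list(te.CATEGORIES)).to_numpy()
    dup_counts = dist_dup.set_index("category")["count"].reindex(list(te.CATEGORIES)).to_numpy()
    dup_vs_genome_chisq = (
        fam.chisq_gof(dup_counts, all_counts / all_counts.sum())
        if all_counts.sum() > 0 and (all_counts > 0).all()
        else None
    )

    stats = {
        "config": dataclasses.asdict(cfg),
        "n_genes": len(genes),
        "n_te_insertions": len(bundle.tes),
        "n_families": len(bundle.families),
        "category_distribution_all": dist_all.set_index("category")["count"].to_dict(),
        "category_distribution_duplicated": dist_dup.set_index("category")["count"].to_dict(),
        "pair_context": {
            "counts": table.counts.tolist(),
            "n": table.n,
            "chisq": table.chisq,
            "mc_pvalue": table.mc_pvalue,
            "B": table.mc_replicates,
            "seed": table.mc_seed,
            "marginal_source": cfg.marginal_source,
        },
        "same_environment_fraction": same_fraction,
        "same_vs_random_chisq": {"chisq": same_vs_random_chisq, "df": 1,
                                 "baseline_same_prob": s_base},
        "duplicated_vs_genome_chisq": {"chisq": dup_vs_genome_chisq, "df": len(te.CATEGORIES) - 1},
        "n_families_excluded_both_silent": int(family_frame.excluded_both_silent.sum()),
        "age_class_counts": family_frame.age_class.value_counts().to_dict(),
        "distribution_tests": dist_tests,
        "correlation_batteries": "BH within histone/methylation x pooled/age-stratified",
    }
    result = PipelineResult(
        config=cfg,
        te_environments=env_frame,
        category_model=model,
        category_distribution_all=dist_all,
        category_distribution_duplicated=dist_dup,
        pair_table=table,
        same_fraction=same_fraction,
        family_frame=family_frame,
        epigenome_frame=epi_frame,
        correlations=correlations,
        distribution_tests=dist_tests,
        stats=stats,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def from_printed_tables(
    marginal_counts: Sequence[float],
    pair_counts: Sequence[float],
    B: int = 2000,
    seed: int = 0,
) -> dict:
    """Pair-context goodness-of-fit test from published category marginals
    (5 counts, TE-free .. TE-very-rich) and unordered pair counts (15 cells
    in canonical order)."""
    q = fam.expected_pair_probs(marginal_counts)
    obs = np.asarray(pair_counts, dtype=float)
    chisq = fam.chisq_gof(obs, q)
    p = fam.monte_carlo_pvalue(obs, q, B=B, seed=seed)
    diag = sum(c for c, (i, j) in zip(obs, fam.PAIR_CELLS) if i == j)
    return {
        "n": int(obs.sum()),
        "chisq": chisq,
        "mc_pvalue": p,
        "B": B,
        "seed": seed,
        "expected_probs": q.tolist(),
        "same_environment_fraction": float(diag / obs.sum()),
    }
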