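"""Family-level statistics for duplicated genes.

Covers the family age classes (dS bins), the unordered 15-cell TE-category
pair-context table with its Pearson goodness-of-fit statistic and
Monte-Carlo p-value, the same/different TE-environment partition,
within-family Spearman correlations of epigenetic summaries with
Benjamini-Hochberg correction, and the Kruskal-Wallis / Kolmogorov-Smirnov
distribution comparisons.

The pair-context null: if the two members of a family drew their TE
category independently from the marginal category frequencies p_1..p_5,
the unordered pair {i, j} has probability p_i^2 on the diagonal and
2 p_i p_j off it. The observed table is tested against these cell
probabilities with Pearson's X^2, and the p-value comes from B multinomial
resamples of size n under the null with the (1 + exceedances) / (B + 1)
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import FamilyRecord
from .te_environment import CATEGORIES

AGE_CLASSES = ("young", "middle-age", "old")

#: unordered category pairs (i <= j by category index), the table's cell order
PAIR_CELLS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(len(CATEGORIES)) for j in range(i, len(CATEGORIES))
)


def assign_age_class(dS: float) -> str:
    """young: dS < 1; middle-age: 1 <= dS < 2; old: dS >= 2."""
    if dS < 0:
        raise ValueError("dS must be non-negative")
    if dS < 1:
        return "young"
    if dS < 2:
        return "middle-age"
    return "old"


# ---------------------------------------------------------------------------
# pair-context table and goodness-of-fit test


@dataclass
class PairContextTable:
    """15-cell unordered TE-category pair contingency table."""

    counts: np.ndarray  # length 15, order of PAIR_CELLS
    n: int
    expected_probs: Optional[np.ndarray] = None
    chisq: Optional[float] = None
    mc_pvalue: Optional[float] = None
    mc_replicates: Optional[int] = None
    mc_seed: Optional[int] = None

    def cell_labels(self) -> list[str]:
        return [f"{CATEGORIES[i]}|{CATEGORIES[j]}" for i, j in PAIR_CELLS]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pair": self.cell_labels(), "count": self.counts.astype(int)})
        if self.expected_probs is not None:
            df["expected"] = self.n * self.expected_probs
        return df

    @property
    def diagonal_fraction(self) -> float:
        diag = sum(
            c for c, (i, j) in zip(self.counts, PAIR_CELLS) if i == j
        )
        return diag / self.n


def pair_context_counts(
    families: Sequence[FamilyRecord], categories: Mapping[str, str]
) -> PairContextTable:
    """Count families by the unordered pair of their members' TE categories."""
    cat_index = {c: k for k, c in enumerate(CATEGORIES)}
    cell_index = {cell: k for k, cell in enumerate(PAIR_CELLS)}
    counts = np.zeros(len(PAIR_CELLS), dtype=np.int64)
    for fam in families:
        for gid in (fam.gene1_id, fam.gene2_id):
            if gid not in categories or categories[gid] is None:
                raise ValueError(f"gene {gid} (family {fam.family_id}) has no TE category")
        a = cat_index[categories[fam.gene1_id]]
        b = cat_index[categories[fam.gene2_id]]
        i, j = min(a, b), max(a, b)
        counts[cell_index[(i, j)]] += 1
    return PairContextTable(counts=counts, n=int(counts.sum()))


def expected_pair_probs(marginal_counts: Sequence[float]) -> np.ndarray:
    """Null cell probabilities for unordered pairs from category marginals.

    With p the normalized marginals, diagonal cells get p_i^2 and
    off-diagonal cells 2 p_i p_j; the 15 values sum to 1.
    """
    m = np.asarray(marginal_counts, dtype=float)
    if len(m) != len(CATEGORIES):
        raise ValueError(f"need {len(CATEGORIES)} marginal counts")
    if (m < 0).any() or m.sum() <= 0:
        raise ValueError("marginal counts must be non-negative and not all zero")
    p = m / m.sum()
    q = np.empty(len(PAIR_CELLS))
    for k, (i, j) in enumerate(PAIR_CELLS):
        q[k] = p[i] ** 2 if i == j else 2 * p[i] * p[j]
    return q


def chisq_gof(observed: Sequence[float], expected_probs: Sequence[float]) -> float:
    """Pearson X^2 = sum (O_c - n q_c)^2 / (n q_c) over cells with q_c > 0."""
    obs = np.asarray(observed, dtype=float)
    q = np.asarray(expected_probs, dtype=float)
    if obs.shape != q.shape:
        raise ValueError("observed and expected_probs must align")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts sum to zero")
    zero_prob = q == 0
    if (obs[zero_prob] > 0).any():
        raise ValueError("observed count in a zero-probability cell")
    e = n * q[~zero_prob]
    o = obs[~zero_prob]
    return float(((o - e) ** 2 / e).sum())


def monte_carlo_pvalue(
    observed: Sequence[float],
    expected_probs: Sequence[float],
    B: int = 2000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo p-value for the goodness-of-fit statistic.

    Draws B multinomial(n, q) tables under the null, recomputes X^2 for
    each, and returns (1 + #{X^2_sim >= X^2_obs}) / (B + 1). The +1
    convention guarantees p > 0 and makes an observed statistic beyond every
    replicate report exactly 1/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = np.asarray(observed, dtype=float)
    q = np.asarray(expected_probs, dtype=float)
    n = int(round(obs.sum()))
    x_obs = chisq_gof(obs, q)
    gen = rng if rng is not None else np.random.default_rng(seed)
    sims = gen.multinomial(n, q, size=B).astype(float)
    expected = n * q
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (sims - expected) ** 2 / expected
    terms[:, expected == 0] = 0.0
    x_sim = terms.sum(axis=1)
    exceed = int((x_sim >= x_obs - 1e-12).sum())
    return (1 + exceed) / (B + 1)


def pair_context_test(
    table: PairContextTable,
    marginal_counts: Sequence[float],
    B: int = 2000,
    seed: int = 0,
) -> PairContextTable:
    """Attach expected probabilities, X^2 and Monte-Carlo p to a pair table."""
    q = expected_pair_probs(marginal_counts)
    table.expected_probs = q
    table.chisq = chisq_gof(table.counts, q)
    table.mc_pvalue = monte_carlo_pvalue(table.counts, q, B=B, seed=seed)
    table.mc_replicates = B
    table.mc_seed = seed
    return table


def same_environment_partition(
    families: Sequence[FamilyRecord], categories: Mapping[str, str]
) -> tuple[dict[str, str], float]:
    """Label each family same/different TE environment; return labels and same-fraction."""
    labels: dict[str, str] = {}
    same = 0
    for fam in families:
        c1 = categories.get(fam.gene1_id)
        c2 = categories.get(fam.gene2_id)
        if c1 is None or c2 is None:
            raise ValueError(f"family {fam.family_id}: member without TE category")
        if c1 == c2:
            labels[fam.family_id] = "same"
            same += 1
        else:
            labels[fam.family_id] = "different"
    return labels, same / len(families) if families else 0.0


# ---------------------------------------------------------------------------
# within-family correlations


@dataclass
class CorrelationResult:
    stratum: tuple  # (cell_type, measure, partition, age)
    rho: float
    p: float
    n: int
    q: float = field(default=np.nan)
    computable: bool = True


def within_family_correlation(
    values_by_gene: Mapping[str, float],
    families: Sequence[FamilyRecord],
    stratum: tuple = ("all", "value", "all", "all"),
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation of a per-gene summary between family members.

    Families where either member's value is missing (absent or NaN) are
    dropped. Which member plays "gene 1" is randomized per family under the
    seed, since rank correlation over pairs is orientation-sensitive in
    principle; the randomization makes the estimate free of input-order
    artifacts while staying reproducible.
    """
    rng = np.random.default_rng(seed)
    x, y = [], []
    for fam in families:
        v1 = values_by_gene.get(fam.gene1_id)
        v2 = values_by_gene.get(fam.gene2_id)
        if v1 is None or v2 is None or not np.isfinite(v1) or not np.isfinite(v2):
            continue
        if rng.random() < 0.5:
            v1, v2 = v2, v1
        x.append(v1)
        y.append(v2)
    if len(x) < 3 or len(set(x)) < 2 or len(set(y)) < 2:
        return CorrelationResult(stratum=stratum, rho=np.nan, p=np.nan, n=len(x), computable=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(stratum=stratum, rho=float(rho), p=float(p), n=len(x))


def pooled_within_family_correlation(
    values_by_cell_type: Mapping[str, Mapping[str, float]],
    families: Sequence[FamilyRecord],
    stratum: tuple = ("pooled", "value", "all", "all"),
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation over family pairs concatenated across cell types.

    Each (family, cell type) combination with both members defined
    contributes one pair; pooling is by concatenation, not by averaging
    per-cell-type coefficients, and the choice is visible in the stratum
    label.
    """
    rng = np.random.default_rng(seed)
    x, y = [], []
    for fam in families:
        flip = rng.random() < 0.5
        for values in values_by_cell_type.values():
            v1 = values.get(fam.gene1_id)
            v2 = values.get(fam.gene2_id)
            if v1 is None or v2 is None or not np.isfinite(v1) or not np.isfinite(v2):
                continue
            if flip:
                v1, v2 = v2, v1
            x.append(v1)
            y.append(v2)
    if len(x) < 3 or len(set(x)) < 2 or len(set(y)) < 2:
        return CorrelationResult(stratum=stratum, rho=np.nan, p=np.nan, n=len(x), computable=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(stratum=stratum, rho=float(rho), p=float(p), n=len(x))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_qvalues(results: Sequence[CorrelationResult]) -> list[CorrelationResult]:
    """BH-adjust one battery of correlation tests in place (skipping non-computable ones)."""
    idx = [i for i, r in enumerate(results) if r.computable]
    if idx:
        q = bh_adjust([results[i].p for i in idx])
        for i, qi in zip(idx, q):
            results[i].q = float(qi)
    return list(results)


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_type": [r.stratum[0] for r in results],
            "measure": [r.stratum[1] for r in results],
            "partition": [r.stratum[2] for r in results],
            "age": [r.stratum[3] for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "n": [r.n for r in results],
            "computable": [r.computable for r in results],
        }
    )


# ---------------------------------------------------------------------------
# distribution comparisons


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of distributions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        return {"test": "ks", "computable": False, "n": (len(a), len(b))}
    res = stats.ks_2samp(a, b)
    return {
        "test": "ks",
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "n": (len(a), len(b)),
        "computable": True,
    }


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis H (reported as chi-squared) across k groups."""
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if any(len(v) < 2 for v in arrays.values()) or len(arrays) < 2:
        return {"test": "kruskal-wallis", "computable": False,
                "n": {k: len(v) for k, v in arrays.items()}}
    h, p = stats.kruskal(*arrays.values())
    return {
        "test": "kruskal-wallis",
        "chisq": float(h),
        "df": len(arrays) - 1,
        "p": float(p),
        "n": {k: len(v) for k, v in arrays.items()},
        "computable": True,
    }
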