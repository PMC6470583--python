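"""Expression normalization and the Manhattan expression-divergence d_m.

FPKM values per cell type are rescaled to TPM (``TPM_i = FPKM_i / sum_j
FPKM_j * 1e6``), a gene counts as expressed at FPKM >= 0.5, and the
divergence between the two members of a family is

    d_m = 1/2 * sum_k | g1_k / sum(g1) - g2_k / sum(g2) |

over the four cell types, i.e. the total-variation distance between the two
genes' cell-type-normalized profiles: 0 for proportional profiles, 1 for
disjoint support.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

EXPRESSION_THRESHOLD = 0.5
DIVERGENCE_CLASSES = ("very low", "low", "medium", "high")
#: one member silent in all cell types: its normalized profile is the zero
#: vector, giving d_m = 0.5 (flagged in pipeline output)
ONE_SILENT_DM = 0.5


def fpkm_to_tpm(fpkm_by_gene: Mapping[str, float]) -> dict[str, float]:
    """Rescale one cell type's FPKM values so they sum to 1e6."""
    total = float(sum(fpkm_by_gene.values()))
    if total <= 0:
        raise ValueError("all-zero FPKM in cell type: TPM normalization undefined")
    return {g: v / total * 1e6 for g, v in fpkm_by_gene.items()}


def fpkm_frame_to_tpm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Column-wise FPKM -> TPM for a gene x cell-type table."""
    totals = fpkm.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero FPKM in cell type(s) {bad}: TPM undefined")
    return fpkm / totals * 1e6


def is_expressed(fpkm: float) -> bool:
    """Expressed at FPKM >= 0.5 (boundary inclusive)."""
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    return fpkm >= EXPRESSION_THRESHOLD


def manhattan_divergence(
    g1: Union[Sequence[float], np.ndarray], g2: Union[Sequence[float], np.ndarray]
) -> float:
    """Total-variation distance between two genes' normalized expression profiles.

    Exactly one all-zero vector is treated as the zero profile, yielding
    d_m = 0.5; both all-zero is an error (such families are removed
    upstream).
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have the same number of cell types")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    sa, sb = a.sum(), b.sum()
    if sa == 0 and sb == 0:
        raise ValueError("both members silent in all cell types: d_m undefined")
    pa = a / sa if sa > 0 else np.zeros_like(a)
    pb = b / sb if sb > 0 else np.zeros_like(b)
    return float(0.5 * np.abs(pa - pb).sum())


def divergence_class(d_m: float) -> str:
    """Bin d_m into very low / low / medium / high.

    Intervals are left-closed, right-open ([0,0.25), [0.25,0.5), [0.5,0.75))
    with the last closed at 1.
    """
    if not 0.0 <= d_m <= 1.0 + 1e-12:
        raise ValueError(f"d_m outside [0,1]: {d_m}")
    if d_m < 0.25:
        return "very low"
    if d_m < 0.5:
        return "low"
    if d_m < 0.75:
        return "medium"
    return "high"


def read_fpkm_table(path) -> pd.DataFrame:
    """Read a TSV of FPKM values with a gene_id column and one column per cell type."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative FPKM values")
    return df
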