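"""Published summary counts for the human duplicated-gene dataset.

These are the published dataset summaries for human two-copy gene families
(GRCh38): the per-category gene counts and the unordered
pair-context family counts. They let the pair-context test run directly on
the published tables without any interval data, and anchor the worked
examples.
"""

from __future__ import annotations

import numpy as np

from .families import PAIR_CELLS
from .te_environment import CATEGORIES

#: number of human protein-coding genes per TE-neighborhood category
ALL_GENE_CATEGORY_COUNTS = {
    "TE-free": 773,
    "TE-very-poor": 4830,
    "TE-poor": 5885,
    "TE-rich": 4848,
    "TE-very-rich": 2602,
}

#: duplicated (two-copy family) genes per TE-neighborhood category
DUPLICATED_CATEGORY_COUNTS = {
    "TE-free": 109,
    "TE-very-poor": 713,
    "TE-poor": 915,
    "TE-rich": 729,
    "TE-very-rich": 374,
}

#: families per unordered TE-category pair of their two members
PAIR_CONTEXT_COUNTS = {
    ("TE-free", "TE-free"): 20,
    ("TE-free", "TE-very-poor"): 36,
    ("TE-very-poor", "TE-very-poor"): 121,
    ("TE-free", "TE-poor"): 18,
    ("TE-very-poor", "TE-poor"): 220,
    ("TE-poor", "TE-poor"): 169,
    ("TE-free", "TE-rich"): 13,
    ("TE-very-poor", "TE-rich"): 143,
    ("TE-poor", "TE-rich"): 229,
    ("TE-rich", "TE-rich"): 110,
    ("TE-free", "TE-very-rich"): 2,
    ("TE-very-poor", "TE-very-rich"): 72,
    ("TE-poor", "TE-very-rich"): 110,
    ("TE-rich", "TE-very-rich"): 124,
    ("TE-very-rich", "TE-very-rich"): 33,
}

#: duplicated genes located on a different chromosome than their partner,
#: out of all duplicated genes
DIFFERENT_CHROMOSOME_GENES = 2464
TOTAL_DUPLICATED_GENES = 2840

#: family counts per age class (dS < 1, 1 <= dS < 2, dS >= 2)
AGE_CLASS_COUNTS = {"young": 99, "middle-age": 189, "old": 1132}

#: reported (density, coverage) means of the four clustered categories
CLUSTER_PROFILE_MEANS = {
    "TE-very-poor": (0.0003, 0.086),
    "TE-poor": (0.0007, 0.196),
    "TE-rich": (0.0012, 0.304),
    "TE-very-rich": (0.0025, 0.419),
}


def duplicated_marginals() -> np.ndarray:
    """Duplicated-gene category counts in canonical category order."""
    return np.array([DUPLICATED_CATEGORY_COUNTS[c] for c in CATEGORIES], dtype=float)


def pair_context_vector() -> np.ndarray:
    """Pair-context family counts in canonical cell order (PAIR_CELLS)."""
    out = np.zeros(len(PAIR_CELLS), dtype=np.int64)
    for k, (i, j) in enumerate(PAIR_CELLS):
        out[k] = PAIR_CONTEXT_COUNTS[(CATEGORIES[i], CATEGORIES[j])]
    return out
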