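"""Expression divergence (ED) of duplicate pairs from count matrices.

The ED statistic for a pair of duplicates is

    ED = (C1 + C2) / C

where C1 and C2 are the numbers of conditions in which only the first or
only the second copy is detected, and C the number of conditions in which at
least one of them is detected.  ED = 0 means the two copies are always
expressed in the same conditions; ED = 1 means they are never detected
together.  The statistic works on detection profiles (sets of conditions),
which makes it robust to the heterogeneous dynamic ranges of a compendium of
mixed experiments.

Pipeline: raw integer counts -> low-expression filter (row sum must reach
twice the number of conditions) -> optional counts-per-million transform ->
per-gene detection profile (value above a threshold) -> pairwise ED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "cpm_transform",
    "low_expression_filter",
    "detection_profiles",
    "EDRecord",
    "compute_ed",
    "compute_ed_table",
]


def cpm_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each cell scaled by its condition's library size.

    ``counts`` is genes x conditions, nonnegative.  A condition whose column
    sums to zero has no library to normalize against and raises a ValueError
    naming the condition.
    """
    if (counts.values < 0).any():
        raise ValueError("cpm_transform: negative counts")
    colsums = counts.sum(axis=0)
    dead = colsums[colsums == 0]
    if len(dead):
        raise ValueError(
            f"cpm_transform: all-zero condition column(s): {', '.join(map(str, dead.index))}"
        )
    return counts / colsums * 1e6


def low_expression_filter(counts: pd.DataFrame, multiplier: float = 2.0) -> pd.Index:
    """Genes whose total count reaches ``multiplier`` times the condition count.

    Returns the retained gene index.  A gene is removed iff its row sum is
    strictly lower than ``multiplier * n_conditions`` (so a row sum exactly at
    the boundary is kept).
    """
    n_cond = counts.shape[1]
    if n_cond == 0:
        raise ValueError("low_expression_filter: matrix has no conditions")
    return counts.index[counts.sum(axis=1) >= multiplier * n_cond]


def detection_profiles(
    matrix: pd.DataFrame, threshold: float = 0.0
) -> dict[str, frozenset]:
    """Per-gene set of conditions where the value exceeds ``threshold``.

    The default (0 on raw counts) calls a gene detected wherever at least one
    read mapped; pass a CPM matrix and a positive threshold for a stricter
    rule.
    """
    detected = matrix.values > threshold
    cols = np.asarray(matrix.columns)
    return {
        gene: frozenset(cols[detected[i]]) for i, gene in enumerate(matrix.index)
    }


@dataclass(frozen=True)
class EDRecord:
    """ED of one pair: c1/c2 private conditions, c the detected union."""

    gene_a: str
    gene_b: str
    c1: int
    c2: int
    c: int

    @property
    def ed(self) -> float:
        return (self.c1 + self.c2) / self.c


def compute_ed(
    gene_a: str, gene_b: str, profiles: Mapping[str, frozenset]
) -> EDRecord | str:
    """ED record for one pair, or an exclusion reason string.

    Exclusion reasons: ``"missing_gene"`` (a copy absent from the filtered
    matrix — not represented in the expression data) and ``"not_detected"``
    (both copies present but detected nowhere, leaving ED undefined).
    """
    if gene_a not in profiles or gene_b not in profiles:
        return "missing_gene"
    a, b = profiles[gene_a], profiles[gene_b]
    c = len(a | b)
    if c == 0:
        return "not_detected"
    return EDRecord(gene_a, gene_b, c1=len(a - b), c2=len(b - a), c=c)


def compute_ed_table(
    pairs: pd.DataFrame, profiles: Mapping[str, frozenset]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ED for every pair of a catalog.

    Returns ``(ed, exclusions)``: ``ed`` has columns gene_a, gene_b, c1, c2,
    c, ed; ``exclusions`` has gene_a, gene_b, reason.  Both are indexed like
    the corresponding ``pairs`` rows.
    """
    ed_rows, ex_rows = {}, {}
    for idx, row in pairs.iterrows():
        rec = compute_ed(row["gene_a"], row["gene_b"], profiles)
        if isinstance(rec, EDRecord):
            ed_rows[idx] = dict(
                gene_a=rec.gene_a, gene_b=rec.gene_b,
                c1=rec.c1, c2=rec.c2, c=rec.c, ed=rec.ed,
            )
        else:
            ex_rows[idx] = dict(gene_a=row["gene_a"], gene_b=row["gene_b"], reason=rec)
    ed = pd.DataFrame.from_dict(ed_rows, orient="index")
    exclusions = pd.DataFrame.from_dict(
        ex_rows, orient="index", columns=["gene_a", "gene_b", "reason"]
    )
    if ed.empty:
        ed = pd.DataFrame(columns=["gene_a", "gene_b", "c1", "c2", "c", "ed"])
    return ed, exclusions
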