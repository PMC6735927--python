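"""Correlation panels, representation tests and flat GO-slim enrichment.

Correlation panels report Pearson's r and Spearman's rho for every requested
variable pair (Ks, SD, ED, ID) within every partition and Ks subset, with the
conventional significance stars (*** below 1e-10, ** below 1e-5, * below
0.05).  Representation tests ask whether a trait (e.g. having PPIs) is over-
or under-represented in each category of a count table via two-sided Fisher
exact tests with Benjamini-Hochberg correction.  GO enrichment uses the flat
GO-slim annotation sets (no DAG propagation) and reports both hypergeometric
tails per term.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "star_bin",
    "correlation_panel",
    "representation_test",
    "representation_test_table1",
    "go_enrichment",
    "bh_correct",
]


def star_bin(p: float) -> str:
    """Significance stars: *** < 1e-10, ** < 1e-5, * < 0.05, else ns."""
    if not np.isfinite(p):
        return "ns"
    if p < 1e-10:
        return "***"
    if p < 1e-5:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlation_panel(
    records: pd.DataFrame,
    variables: Sequence[str] = ("ks", "sd", "ed"),
    partition_col: str = "mode",
    ks_subsets: Sequence[str] = ("ks<5", "ks<1"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson + Spearman correlations for all variable pairs per cell.

    One cell = (variable pair, partition, Ks subset).  Rows with a NaN in
    either variable are dropped per cell; cells with fewer than ``min_n``
    complete observations are flagged ``computed=False`` with NaN statistics.
    Spearman uses average ranks for ties (scipy's default).
    """
    subset_bounds = {"ks<5": 5.0, "ks<1": 1.0}
    rows = []
    for part, grp in records.groupby(partition_col, sort=True):
        for subset in ks_subsets:
            bound = subset_bounds[subset]
            sub = grp[grp["ks"] < bound]
            for var_x, var_y in combinations(variables, 2):
                cell = sub[[var_x, var_y]].dropna()
                n = len(cell)
                for method in ("pearson", "spearman"):
                    if n < min_n:
                        rows.append(
                            dict(var_x=var_x, var_y=var_y, partition=part,
                                 ks_subset=subset, method=method, n=n,
                                 coefficient=np.nan, p_value=np.nan,
                                 stars="ns", computed=False)
                        )
                        continue
                    if method == "pearson":
                        res = stats.pearsonr(cell[var_x], cell[var_y])
                    else:
                        res = stats.spearmanr(cell[var_x], cell[var_y])
                    coef, p = float(res.statistic), float(res.pvalue)
                    rows.append(
                        dict(var_x=var_x, var_y=var_y, partition=part,
                             ks_subset=subset, method=method, n=n,
                             coefficient=coef, p_value=p,
                             stars=star_bin(p), computed=True)
                    )
    return pd.DataFrame(rows)


def representation_test(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category over/under-representation of a trait.

    ``table``: one row per category, columns ``with`` and ``without`` (counts
    of members carrying / not carrying the trait).  Each category is tested
    against the union of the remaining categories in a 2x2 two-sided Fisher
    exact test; p-values are BH-corrected across categories and the direction
    is taken from the odds ratio (over = trait more frequent in the category
    than in the rest).
    """
    if not {"with", "without"}.issubset(table.columns):
        raise ValueError("representation_test: need 'with' and 'without' columns")
    tot_with = int(table["with"].sum())
    tot_without = int(table["without"].sum())
    rows = []
    for cat, row in table.iterrows():
        w, wo = int(row["with"]), int(row["without"])
        rest = [[tot_with - w, tot_without - wo]]
        res = stats.fisher_exact([[w, wo]] + rest)
        in_frac = w / (w + wo) if (w + wo) else np.nan
        rest_n = (tot_with - w) + (tot_without - wo)
        rest_frac = (tot_with - w) / rest_n if rest_n else np.nan
        rows.append(
            dict(category=cat, n_with=w, n_without=wo,
                 odds_ratio=float(res.statistic), p_value=float(res.pvalue),
                 direction="over" if in_frac >= rest_frac else "under")
        )
    out = pd.DataFrame(rows).set_index("category")
    out["q_value"] = bh_correct(out["p_value"].to_numpy())
    return out


def representation_test_table1(
    pairs: pd.DataFrame,
    units: str = "pairs",
    include_unclassified: bool = False,
) -> pd.DataFrame:
    """Fisher tests of PPI representation across duplication modes.

    Builds the mode x {with, without PPI} count table from a pair catalog
    (boolean ``with_ppi`` column required) and runs
    :func:`representation_test`.  Two ambiguities of this construction are
    exposed as flags rather than resolved: ``units`` counts ``"pairs"`` or
    ``"genes"`` (two genes per pair, inheriting the pair's status), and
    ``include_unclassified`` controls whether unclassified pairs enter the
    background against which each mode is tested.
    """
    if units not in ("pairs", "genes"):
        raise ValueError("units must be 'pairs' or 'genes'")
    df = pairs if include_unclassified else pairs[pairs["mode"] != "unclassified"]
    weight = 2 if units == "genes" else 1
    rows = {}
    for mode, grp in df.groupby("mode", sort=True):
        rows[mode] = dict(
            **{"with": weight * int(grp["with_ppi"].sum())},
            without=weight * int((~grp["with_ppi"]).sum()),
        )
    table = pd.DataFrame.from_dict(rows, orient="index")[["with", "without"]]
    return representation_test(table)


def go_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment of ``gene_set`` against ``background``.

    ``annotations`` maps genes to flat GO-slim terms (columns ``gene_id``,
    ``term_id``); only terms annotating at least one background gene are
    tested.  For each term with K annotated background genes out of N, and k
    annotated sample genes out of n, the over-representation tail is
    P(X >= k) and the under-representation tail P(X <= k) for
    X ~ Hypergeom(N, K, n); both are reported, the smaller tail names the
    direction, and BH correction runs across all tested terms on the
    directional (smaller) p-value.
    """
    sample = set(gene_set)
    bg = set(background)
    if not bg:
        raise ValueError("go_enrichment: empty background")
    if not sample <= bg:
        raise ValueError("go_enrichment: gene set must be a subset of the background")
    ann = annotations[annotations["gene_id"].isin(bg)]
    n_bg = len(bg)
    n_sample = len(sample)
    rows = []
    for term, grp in ann.groupby("term_id", sort=True):
        genes_with_term = set(grp["gene_id"])
        big_k = len(genes_with_term)
        k = len(genes_with_term & sample)
        p_over = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_sample))
        p_under = float(stats.hypergeom.cdf(k, n_bg, big_k, n_sample))
        direction = "over" if p_over <= p_under else "under"
        rows.append(
            dict(term_id=term, k=k, n=n_sample, K=big_k, N=n_bg,
                 p_over=p_over, p_under=p_under, direction=direction,
                 p_value=min(p_over, p_under))
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p_over", "p_under",
                       "direction", "p_value"],
    )
    out["q_value"] = bh_correct(out["p_value"].to_numpy()) if len(out) else []
    return out


def bh_correct(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of m * p_(j) / j on the ascending ordering,
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("bh_correct: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
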