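"""Duplicate-pair catalogs: tandem classification, Ks filtering, partitions.

A catalog is a pandas DataFrame with columns ``species, gene_a, gene_b, mode,
ks, kn`` where ``mode`` is one of ``tandem`` (small-scale duplicates arranged
in clusters along a chromosome), ``block`` (duplicates in collinear regions,
putatively from whole-genome duplication) or ``unclassified`` (conflicting or
undecidable evidence; always dropped from comparative analyses).

Collinearity (block) evidence is consumed from the input — detecting it is a
genome-alignment problem outside this package.  What is implemented here is
the tandem rule (same chromosome, at most ``max_gap`` intervening genes), the
conflict rule (tandem *and* block evidence, or neither, gives
``unclassified``) and the Ks analysis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

MODES = ("tandem", "block", "unclassified")

__all__ = [
    "classify_tandem",
    "apply_ks_window",
    "KsWindowResult",
    "partition",
    "summarize_counts",
]


def classify_tandem(
    pairs: pd.DataFrame,
    positions: pd.DataFrame,
    max_gap: int = 30,
    inclusive: bool = True,
) -> pd.Series:
    """Assign a duplication mode to each candidate pair.

    Parameters
    ----------
    pairs
        DataFrame with ``gene_a``, ``gene_b`` and an optional boolean
        ``is_block`` column carrying collinearity evidence (default False).
    positions
        DataFrame with ``gene_id``, ``chromosome`` and ``rank`` (0-based gene
        order along the chromosome).
    max_gap
        Maximum number of intervening genes for a pair to count as tandem.
        With ``inclusive`` (default) a pair with exactly ``max_gap``
        intervening genes is tandem.

    Returns a Series of mode labels aligned with ``pairs``.  A pair flagged
    both tandem and block, or neither, is ``unclassified``.  Pairs with a
    missing position are ``unclassified`` with a warning, never dropped.
    """
    pos = positions.set_index("gene_id")
    if pos.index.has_duplicates:
        raise ValueError("positions: duplicate gene_id entries")
    is_block = (
        pairs["is_block"].astype(bool)
        if "is_block" in pairs.columns
        else pd.Series(False, index=pairs.index)
    )

    labels = []
    n_missing = 0
    for idx, row in pairs.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        if a not in pos.index or b not in pos.index:
            n_missing += 1
            labels.append("unclassified")
            continue
        pa, pb = pos.loc[a], pos.loc[b]
        intervening = abs(int(pa["rank"]) - int(pb["rank"])) - 1
        within = intervening <= max_gap if inclusive else intervening < max_gap
        is_tandem = (pa["chromosome"] == pb["chromosome"]) and within
        if is_tandem and not is_block.loc[idx]:
            labels.append("tandem")
        elif is_block.loc[idx] and not is_tandem:
            labels.append("block")
        else:
            labels.append("unclassified")
    if n_missing:
        warnings.warn(
            f"{n_missing} pair(s) had a gene without a position and were "
            "labeled 'unclassified'",
            stacklevel=2,
        )
    return pd.Series(labels, index=pairs.index, name="mode")


@dataclass(frozen=True)
class KsWindowResult:
    retained: pd.DataFrame
    n_discarded_low: int
    n_discarded_high: int


def apply_ks_window(
    pairs: pd.DataFrame, ks_min: float = 0.05, ks_max: float = 5.0
) -> KsWindowResult:
    """Keep pairs with ``ks_min <= ks <= ks_max`` (boundaries inclusive).

    The low cut removes pairs whose near-identity suggests genetic redundancy
    or assembly artifacts; the high cut removes pairs where synonymous-site
    saturation makes Ks unreliable.
    """
    if pairs["ks"].isna().any():
        raise ValueError("apply_ks_window: ks missing for some pairs")
    low = pairs["ks"] < ks_min
    high = pairs["ks"] > ks_max
    return KsWindowResult(
        retained=pairs.loc[~(low | high)].copy(),
        n_discarded_low=int(low.sum()),
        n_discarded_high=int(high.sum()),
    )


_KS_SUBSETS = {"ks<5": 5.0, "ks<1": 1.0, None: None}


def partition(
    pairs: pd.DataFrame,
    by: str = "mode",
    ks_subset: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Split a catalog into disjoint named partitions.

    ``by`` is one of ``mode`` (tandem vs block; unclassified pairs are
    excluded), ``ppi_status`` (requires boolean column ``with_ppi``) or
    ``mode_x_ppi`` (the four crossed groups).  ``ks_subset`` optionally
    restricts to young pairs first: ``"ks<5"`` or ``"ks<1"`` (strict).
    Empty partitions are kept (flagged by their zero length).
    """
    if ks_subset not in _KS_SUBSETS:
        raise ValueError(f"unknown ks_subset {ks_subset!r}")
    df = pairs
    if ks_subset is not None:
        df = df[df["ks"] < _KS_SUBSETS[ks_subset]]

    if by == "mode":
        df = df[df["mode"] != "unclassified"]
        groups = {m: df[df["mode"] == m] for m in ("tandem", "block")}
    elif by == "ppi_status":
        _require(df, "with_ppi")
        groups = {
            "with_ppi": df[df["with_ppi"]],
            "without_ppi": df[~df["with_ppi"]],
        }
    elif by == "mode_x_ppi":
        _require(df, "with_ppi")
        df = df[df["mode"] != "unclassified"]
        groups = {}
        for m in ("tandem", "block"):
            for label, mask in (("with_ppi", df["with_ppi"]), ("without_ppi", ~df["with_ppi"])):
                groups[f"{m}|{label}"] = df[(df["mode"] == m) & mask]
    else:
        raise ValueError(f"unknown partition scheme {by!r}")
    return {k: v.copy() for k, v in groups.items()}


def _require(df: pd.DataFrame, col: str) -> None:
    if col not in df.columns:
        raise ValueError(f"partition requires a {col!r} column")


def summarize_counts(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-species pair counts by mode and PPI status.

    Returns a table with one row per species and hierarchical columns
    ``(mode, {total, with_ppi, without_ppi})`` plus a grand ``total`` —
    the usual "distribution of duplicates with and without PPIs" summary.
    Requires ``mode`` and boolean ``with_ppi`` columns.
    """
    _require(pairs, "with_ppi")
    species = sorted(pairs["species"].unique()) if len(pairs) else []
    cols = pd.MultiIndex.from_tuples(
        [(m, c) for m in MODES for c in ("total", "with_ppi", "without_ppi")]
        + [("all", "total")]
    )
    out = pd.DataFrame(0, index=pd.Index(species, name="species"), columns=cols)
    for sp in species:
        sub = pairs[pairs["species"] == sp]
        for m in MODES:
            msub = sub[sub["mode"] == m]
            out.loc[sp, (m, "total")] = len(msub)
            out.loc[sp, (m, "with_ppi")] = int(msub["with_ppi"].sum())
            out.loc[sp, (m, "without_ppi")] = int((~msub["with_ppi"]).sum())
        out.loc[sp, ("all", "total")] = len(sub)
    return out
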