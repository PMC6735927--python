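"""Protein-protein interaction networks and interaction divergence (ID).

The ID statistic for a duplicate pair is one minus the partner retention
rate:

    ID = 1 - 2 * I12 / (I1 + I2)

with I1, I2 the partner counts (degrees) of the two copies and I12 the number
of partners they share — i.e. one minus the Sorensen-Dice coefficient of the
two partner sets.  Because experimental PPI data have a high false-negative
rate, ID is flagged eligible only for pairs where one copy has at least
``min_deg_high`` partners and the other at least ``min_deg_low`` (defaults 4
and 1), and the cutoff can be swept to check robustness.

PPI status can be projected from a reference species onto other species
through gene families: a family counts as "with PPI" as soon as any
reference-species member has at least one interaction, and every co-ortholog
in the family inherits that status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = [
    "merge_networks",
    "IDRecord",
    "compute_id",
    "compute_id_table",
    "sweep_id_cutoffs",
    "project_ppi_status",
    "pair_ppi_status",
    "shared_partner_banding",
    "BandingResult",
]


def _normalize_id(identifier: str, uppercase: bool = True, strip_version: bool = False) -> str:
    s = str(identifier).strip()
    if strip_version and "." in s:
        s = s.rsplit(".", 1)[0]
    return s.upper() if uppercase else s


def merge_networks(
    edge_lists: Iterable[pd.DataFrame | str | Path],
    uppercase: bool = True,
    strip_version: bool = False,
) -> nx.Graph:
    """Union of two-column edge lists into one undirected simple graph.

    Self-interactions are dropped and duplicate edges (in either orientation,
    within or across sources) collapsed.  Identifiers are whitespace-stripped
    and optionally uppercased / version-stripped before merging; identifiers
    that collide only after normalization are reported with a warning.
    Malformed rows (null entries) raise with their source and line number.

    The merge report (node/edge counts, numbers removed) is stored in
    ``graph.graph``.
    """
    g = nx.Graph()
    n_self = 0
    n_dup = 0
    collisions: set[str] = set()
    seen_raw: dict[str, str] = {}
    for src_i, source in enumerate(edge_lists):
        if isinstance(source, (str, Path)):
            df = pd.read_csv(source, sep="\t", dtype=str)
            name = str(source)
        else:
            df = source
            name = f"edge_list[{src_i}]"
        if df.shape[1] < 2:
            raise ValueError(f"{name}: expected two columns")
        for line, (raw_a, raw_b) in enumerate(df.iloc[:, :2].itertuples(index=False), start=2):
            if pd.isna(raw_a) or pd.isna(raw_b) or not str(raw_a).strip() or not str(raw_b).strip():
                raise ValueError(f"{name}, line {line}: malformed row {raw_a!r}\t{raw_b!r}")
            a = _normalize_id(raw_a, uppercase, strip_version)
            b = _normalize_id(raw_b, uppercase, strip_version)
            for norm, raw in ((a, str(raw_a).strip()), (b, str(raw_b).strip())):
                prev = seen_raw.setdefault(norm, raw)
                if prev != raw:
                    collisions.add(norm)
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if collisions:
        warnings.warn(
            f"{len(collisions)} identifier(s) collide after normalization: "
            + ", ".join(sorted(collisions)[:10]),
            stacklevel=2,
        )
    g.graph.update(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_self_dropped=n_self,
        n_duplicates_collapsed=n_dup,
    )
    return g


@dataclass(frozen=True)
class IDRecord:
    """Interaction divergence of one pair.

    ``id_value`` is NaN when neither copy has a partner (or a copy is absent
    from the network); ``eligible`` applies the degree cutoffs.
    """

    gene_a: str
    gene_b: str
    i1: int
    i2: int
    i12: int
    id_value: float
    eligible: bool

    @property
    def retention(self) -> float:
        return 1.0 - self.id_value


def compute_id(
    gene_a: str,
    gene_b: str,
    network: nx.Graph,
    min_deg_high: int = 4,
    min_deg_low: int = 1,
    exclude_partner_gene: bool = True,
) -> IDRecord:
    """ID record for one pair against a merged PPI network.

    ``exclude_partner_gene`` removes each copy from the other's partner set
    before counting, so that a pair of heterodimerizing paralogs does not
    score an automatic shared partner through their mutual interaction.
    """
    a_norm, b_norm = _normalize_id(gene_a), _normalize_id(gene_b)
    if a_norm not in network or b_norm not in network:
        return IDRecord(gene_a, gene_b, 0, 0, 0, float("nan"), False)
    part_a = set(network.neighbors(a_norm))
    part_b = set(network.neighbors(b_norm))
    if exclude_partner_gene:
        part_a.discard(b_norm)
        part_b.discard(a_norm)
    i1, i2 = len(part_a), len(part_b)
    i12 = len(part_a & part_b)
    id_value = 1.0 - 2.0 * i12 / (i1 + i2) if (i1 + i2) > 0 else float("nan")
    eligible = max(i1, i2) >= min_deg_high and min(i1, i2) >= min_deg_low
    return IDRecord(gene_a, gene_b, i1, i2, i12, id_value, eligible)


def compute_id_table(
    pairs: pd.DataFrame,
    network: nx.Graph,
    min_deg_high: int = 4,
    min_deg_low: int = 1,
    exclude_partner_gene: bool = True,
) -> pd.DataFrame:
    """ID for every pair of a catalog; indexed like ``pairs``."""
    rows = {}
    for idx, row in pairs.iterrows():
        rec = compute_id(
            row["gene_a"], row["gene_b"], network,
            min_deg_high, min_deg_low, exclude_partner_gene,
        )
        rows[idx] = dict(
            gene_a=rec.gene_a, gene_b=rec.gene_b, i1=rec.i1, i2=rec.i2,
            i12=rec.i12, id_value=rec.id_value, eligible=rec.eligible,
        )
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["gene_a", "gene_b", "i1", "i2", "i12", "id_value", "eligible"],
    )


def sweep_id_cutoffs(
    pairs: pd.DataFrame,
    network: nx.Graph,
    cutoffs: Sequence[int] = range(1, 15),
    min_deg_low: int = 1,
    exclude_partner_gene: bool = True,
) -> pd.DataFrame:
    """Eligible-pair counts as the high-degree cutoff is swept.

    For each cutoff k a pair is eligible iff max(I1, I2) >= k and
    min(I1, I2) >= ``min_deg_low``; the eligible set (and hence the count) is
    monotone nonincreasing in k.  Returns columns ``cutoff, n_eligible``.
    """
    base = compute_id_table(
        pairs, network, min_deg_high=1, min_deg_low=min_deg_low,
        exclude_partner_gene=exclude_partner_gene,
    )
    hi = base[["i1", "i2"]].max(axis=1)
    lo = base[["i1", "i2"]].min(axis=1)
    rows = [
        dict(cutoff=int(k), n_eligible=int(((hi >= k) & (lo >= min_deg_low)).sum()))
        for k in cutoffs
    ]
    return pd.DataFrame(rows)


def project_ppi_status(
    families: pd.DataFrame,
    reference_network: nx.Graph,
    reference_species: str,
) -> pd.DataFrame:
    """Per-gene PPI status across species, projected through families.

    Reference-species genes are "with PPI" iff they have at least one
    interaction themselves; genes of every other species inherit "with PPI"
    iff any reference gene in their family does.  Returns columns
    ``species, gene_id, with_ppi``.
    """
    norm = families.assign(_node=families["gene_id"].map(_normalize_id))
    ref = norm[norm["species"] == reference_species]
    ref_with = ref["_node"].map(
        lambda n: n in reference_network and reference_network.degree(n) >= 1
    )
    fam_with = (
        ref.assign(w=ref_with.values).groupby("family_id")["w"].any()
        if len(ref)
        else pd.Series(dtype=bool)
    )
    out = norm[["species", "gene_id", "family_id"]].copy()
    is_ref = out["species"] == reference_species
    out.loc[is_ref, "with_ppi"] = ref_with.values
    out.loc[~is_ref, "with_ppi"] = (
        out.loc[~is_ref, "family_id"].map(fam_with).fillna(False).astype(bool).values
    )
    out["with_ppi"] = out["with_ppi"].astype(bool)
    return out[["species", "gene_id", "with_ppi"]].reset_index(drop=True)


def pair_ppi_status(pairs: pd.DataFrame, gene_status: pd.DataFrame) -> pd.Series:
    """Pair-level status: "with PPI" iff at least one member is.

    Genes absent from the status table (typically genes missing from the
    family table) count as "without PPI" and trigger a coverage warning.
    """
    status = gene_status.set_index("gene_id")["with_ppi"]
    if status.index.has_duplicates:
        status = status.groupby(level=0).any()
    missing = sorted(
        set(pairs["gene_a"]).union(pairs["gene_b"]) - set(status.index)
    )
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) not covered by the family table; "
            "treated as without PPI",
            stacklevel=2,
        )
    lookup = status.to_dict()
    a = pairs["gene_a"].map(lambda g: bool(lookup.get(g, False)))
    b = pairs["gene_b"].map(lambda g: bool(lookup.get(g, False)))
    return (a | b).rename("with_ppi")


@dataclass(frozen=True)
class BandingResult:
    """Partner-conservation bands per partition plus Fisher comparisons.

    ``fractions`` rows: partition, n, frac_high_retention (strictly more than
    half the partners conserved, i.e. retention > 0.5), frac_zero_shared
    (no shared partner at all).  ``p_high_retention`` / ``p_zero_shared``:
    two-sided Fisher exact p comparing the first two partitions.
    """

    fractions: pd.DataFrame
    p_high_retention: float
    p_zero_shared: float


def shared_partner_banding(
    id_records: pd.DataFrame, partition_col: str = "mode"
) -> BandingResult:
    """Band eligible ID records by partner conservation, per partition."""
    elig = id_records[id_records["eligible"]].copy()
    elig["retention"] = 2.0 * elig["i12"] / (elig["i1"] + elig["i2"])
    rows = []
    tables_high, tables_zero = [], []
    for name, grp in elig.groupby(partition_col, sort=True):
        n = len(grp)
        n_high = int((grp["retention"] > 0.5).sum())
        n_zero = int((grp["i12"] == 0).sum())
        rows.append(
            dict(
                partition=name, n=n,
                frac_high_retention=n_high / n if n else float("nan"),
                frac_zero_shared=n_zero / n if n else float("nan"),
            )
        )
        tables_high.append([n_high, n - n_high])
        tables_zero.append([n_zero, n - n_zero])
    p_high = p_zero = float("nan")
    if len(rows) >= 2:
        p_high = float(stats.fisher_exact(tables_high[:2]).pvalue)
        p_zero = float(stats.fisher_exact(tables_zero[:2]).pvalue)
    return BandingResult(pd.DataFrame(rows), p_high, p_zero)
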