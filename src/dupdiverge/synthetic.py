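"""Synthetic multi-species duplicate-gene datasets with known ground truth.

The generator emulates the statistical structure of a comparative study of
gene duplicates: a catalog of duplicate pairs classified as tandem (small
scale) or block (whole-genome duplication) duplicates, per-species expression
count matrices, a protein-protein interaction (PPI) edge list for a reference
species, a cross-species gene-family table, and a flat GO-slim annotation
table.  Every latent quantity (Ks, divergence-curve values, realized ED/ID)
is recorded in a ground-truth sidecar so downstream estimators can be tested
against the values they are supposed to recover.

Construction guarantees, by design rather than by chance:

* expression detection profiles are built so that the expression-divergence
  statistic ED = (C1 + C2) / C recovers the latent curve value up to the
  rounding resolution 1 / (detected conditions);
* PPI partner sets are built so that the interaction-divergence statistic
  ID = 1 - 2*I12/(I1 + I2) equals the latent value up to partner-count
  rounding;
* every generated gene's count row survives the low-expression filter
  (row sum >= 2 * n_conditions).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MODES = ("tandem", "block", "unclassified")
MEASURES = ("sd", "ed", "id")

__all__ = [
    "CurvePair",
    "GoTermSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class CurvePair:
    """Saturation-curve parameters y = a*x/(b+x) for one partition.

    ``a`` is the divergence asymptote (the maximal divergence reached by old
    duplicates), ``b`` the half-saturation constant (the Ks at which half the
    asymptote is reached).
    """

    a: float
    b: float

    def value(self, ks: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(ks, dtype=float) / (self.b + np.asarray(ks, dtype=float))


@dataclass(frozen=True)
class GoTermSpec:
    """One GO-slim term with a base annotation probability and partition bias.

    ``bias`` maps a duplication mode ("tandem"/"block") to a multiplicative
    enrichment factor on the base probability; modes not listed use factor 1.
    """

    term_id: str
    base_prob: float
    bias: Mapping[str, float] = field(default_factory=dict)

    def prob(self, mode: str) -> float:
        return min(0.95, self.base_prob * float(self.bias.get(mode, 1.0)))


def _default_curves(measure: str) -> dict[str, CurvePair]:
    # Block (WGD) duplicates diverge slower: lower asymptote at equal b.
    if measure == "sd":
        return {"tandem": CurvePair(0.9, 1.2), "block": CurvePair(0.6, 1.2)}
    if measure == "ed":
        return {"tandem": CurvePair(0.45, 0.8), "block": CurvePair(0.25, 0.8)}
    return {"tandem": CurvePair(0.95, 0.4), "block": CurvePair(0.75, 0.5)}


DEFAULT_GO_TERMS: tuple[GoTermSpec, ...] = (
    GoTermSpec("GO:0003677", 0.08, {"block": 5.0}),   # DNA binding
    GoTermSpec("GO:0016301", 0.08, {"block": 3.0}),   # kinase activity
    GoTermSpec("GO:0005215", 0.08, {"tandem": 5.0}),  # transporter activity
    GoTermSpec("GO:0016787", 0.08, {"tandem": 3.0}),  # hydrolase activity
    GoTermSpec("GO:0003824", 0.15, {}),               # catalytic activity
    GoTermSpec("GO:0005515", 0.12, {}),               # protein binding
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Defaults mirror a desk-scale version of a three-species angiosperm
    duplicate study: a reference species carrying the experimental PPI
    network plus two species that receive PPI status only by ortholog-family
    projection; bimodal Ks for block duplicates (discrete WGD waves) versus
    quasi-continuous exponential Ks for tandem duplicates (ongoing birth);
    divergence rising with Ks along saturating curves whose asymptote is
    lower for block duplicates and lower again for pairs engaged in PPIs.
    """

    n_species: int = 3
    n_families: int = 600
    n_block_pairs: int = 150
    n_tandem_pairs: int = 150
    n_unclassified_pairs: int = 20
    block_ks_peaks: Sequence[tuple[float, float, float]] = (
        (0.8, 0.2, 0.5),
        (2.5, 0.5, 0.5),
    )
    tandem_ks_rate: float = 1.0
    ks_range: tuple[float, float] = (0.05, 5.0)
    sd_curve_params: Mapping[str, CurvePair] = field(default_factory=lambda: _default_curves("sd"))
    ed_curve_params: Mapping[str, CurvePair] = field(default_factory=lambda: _default_curves("ed"))
    id_curve_params: Mapping[str, CurvePair] = field(default_factory=lambda: _default_curves("id"))
    noise_sd: float | Mapping[str, float] = 0.05
    n_conditions: int = 60
    detection_prob: float = 0.7
    count_model: tuple[float, float] = (30.0, 0.3)  # (mean, dispersion)
    ppi_degree_mean: float = 6.0
    ppi_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"tandem": 0.35, "block": 0.65, "unclassified": 0.5}
    )
    ppi_asymptote_factor: float = 1.0
    go_terms: Sequence[GoTermSpec] = DEFAULT_GO_TERMS
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    def noise(self, measure: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(measure, 0.0))
        return float(self.noise_sd)

    def curves(self, measure: str) -> Mapping[str, CurvePair]:
        return {
            "sd": self.sd_curve_params,
            "ed": self.ed_curve_params,
            "id": self.id_curve_params,
        }[measure]

    @property
    def n_pairs(self) -> int:
        return self.n_block_pairs + self.n_tandem_pairs + self.n_unclassified_pairs

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_conditions < 10:
            raise ValueError(
                "n_conditions must be >= 10 to realize ED at a usable resolution"
            )
        if min(self.n_block_pairs, self.n_tandem_pairs) < 1 or self.n_unclassified_pairs < 0:
            raise ValueError("pair counts must be positive (unclassified may be zero)")
        if self.n_families < self.n_pairs:
            raise ValueError("n_families must be >= total number of duplicate pairs")
        lo, hi = self.ks_range
        if not lo < hi:
            raise ValueError("ks_range must satisfy min < max")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in (0, 1]")
        if round(self.detection_prob * self.n_conditions) < 1:
            raise ValueError("detection_prob * n_conditions must round to >= 1")
        if self.ppi_degree_mean <= 0:
            raise ValueError("ppi_degree_mean must be > 0")
        if not 0.0 < self.ppi_asymptote_factor <= 1.0:
            raise ValueError("ppi_asymptote_factor must be in (0, 1]")
        for mode, frac in self.ppi_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"ppi_fraction[{mode!r}] must be in [0, 1]")
        for measure in MEASURES:
            if self.noise(measure) < 0:
                raise ValueError("noise_sd must be nonnegative")
            for mode, cp in self.curves(measure).items():
                if cp.a < 0 or cp.b <= 0:
                    raise ValueError(f"{measure} curve for {mode!r}: need a >= 0, b > 0")
                if measure in ("ed", "id") and cp.a > 1:
                    raise ValueError(f"{measure} asymptote must lie in [0, 1]")
        total_weight = sum(w for _, _, w in self.block_ks_peaks)
        if total_weight <= 0:
            raise ValueError("block_ks_peaks weights must sum to > 0")


@dataclass
class SyntheticDataset:
    """In-memory synthetic study: catalog, matrices, network, ground truth."""

    catalog: pd.DataFrame
    counts: dict[str, pd.DataFrame]
    ppi_edges: pd.DataFrame
    families: pd.DataFrame
    go: pd.DataFrame
    positions: pd.DataFrame
    ground_truth: dict

    @property
    def species(self) -> list[str]:
        return sorted(self.counts)

    @property
    def reference_species(self) -> str:
        return self.ground_truth["reference_species"]


# ---------------------------------------------------------------------------
# Ks sampling


def _sample_block_ks(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated Gaussian-mixture Ks: distinct peaks mimic discrete WGD waves."""
    means, sds, weights = map(np.array, zip(*cfg.block_ks_peaks))
    weights = weights / weights.sum()
    lo, hi = cfg.ks_range
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(weights), size=m, p=weights)
        draw = rng.normal(means[comp], sds[comp])
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _sample_tandem_ks(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated exponential Ks: continuous ongoing tandem duplication."""
    lo, hi = cfg.ks_range
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        draw = rng.exponential(1.0 / cfg.tandem_ks_rate, size=m)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


# ---------------------------------------------------------------------------
# Generation


def _gene_names(species: str, family: int, kind: str) -> list[str]:
    stem = f"{species}_g{family:05d}"
    if kind == "pair":
        return [stem + "a", stem + "b"]
    return [stem + "s"]


def _latent_value(
    cfg: GeneratorConfig,
    measure: str,
    mode: str,
    has_ppi: bool,
    ks: float,
    rng: np.random.Generator,
) -> float:
    """Curve value plus Gaussian noise, clamped to the measure's bounds."""
    curves = cfg.curves(measure)
    cp = curves[mode] if mode in curves else curves["tandem"]
    a = cp.a * (cfg.ppi_asymptote_factor if has_ppi else 1.0)
    mu = a * ks / (cp.b + ks)
    val = mu + rng.normal(0.0, cfg.noise(measure)) if cfg.noise(measure) > 0 else mu
    if measure in ("ed", "id"):
        return float(min(1.0, max(0.0, val)))
    return float(max(0.0, val))


def _nb_counts(
    n: int, mean: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion * mean**2."""
    if dispersion <= 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset from ``config``.

    Deterministic: the same config (including its seed) always produces the
    same dataset.  Independent substreams are spawned from the single seed so
    that, e.g., changing the GO term list does not perturb the Ks draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (ks_seed, latent_seed, expr_seed, ppi_seed, go_seed, misc_seed) = ss.spawn(6)
    rng_ks = np.random.default_rng(ks_seed)
    rng_lat = np.random.default_rng(latent_seed)
    rng_expr = np.random.default_rng(expr_seed)
    rng_ppi = np.random.default_rng(ppi_seed)
    rng_go = np.random.default_rng(go_seed)
    rng_misc = np.random.default_rng(misc_seed)

    species = [f"sp{i + 1}" for i in range(config.n_species)]
    reference = species[0]

    # Family layout: one family per duplicate pair, then singleton families.
    modes = (
        ["block"] * config.n_block_pairs
        + ["tandem"] * config.n_tandem_pairs
        + ["unclassified"] * config.n_unclassified_pairs
    )
    n_pairs = len(modes)
    # Family-level PPI involvement drives both the reference network and the
    # status projected onto the other species.
    has_ppi = [
        bool(rng_misc.random() < config.ppi_fraction.get(mode, 0.5)) for mode in modes
    ]

    catalog_rows: list[dict] = []
    family_rows: list[dict] = []
    position_rows: list[dict] = []
    latent_rows: list[dict] = []
    counts: dict[str, pd.DataFrame] = {}
    cond_ids = [f"c{j:03d}" for j in range(config.n_conditions)]
    mean_count, dispersion = config.count_model

    detection_sets: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in species}

    for sp in species:
        # Ks is drawn per species: each genome has its own duplication history,
        # but family identity (mode, PPI status) is shared across species.
        ks_block = _sample_block_ks(config.n_block_pairs, config, rng_ks)
        ks_tandem = _sample_tandem_ks(config.n_tandem_pairs, config, rng_ks)
        ks_uncl = _sample_tandem_ks(config.n_unclassified_pairs, config, rng_ks) \
            if config.n_unclassified_pairs else np.empty(0)
        ks_all = np.concatenate([ks_block, ks_tandem, ks_uncl])

        for fam in range(n_pairs):
            mode, ppi_flag, ks = modes[fam], has_ppi[fam], float(ks_all[fam])
            gene_a, gene_b = _gene_names(sp, fam, "pair")
            # Unclassified pairs follow the tandem divergence process; they
            # exist only so downstream stages can be shown to drop them.
            lat_mode = "tandem" if mode == "unclassified" else mode
            sd = _latent_value(config, "sd", lat_mode, ppi_flag, ks, rng_lat)
            ed = _latent_value(config, "ed", lat_mode, ppi_flag, ks, rng_lat)
            idv = _latent_value(config, "id", lat_mode, ppi_flag, ks, rng_lat)

            catalog_rows.append(
                dict(species=sp, gene_a=gene_a, gene_b=gene_b, mode=mode, ks=ks, kn=sd)
            )
            for g in (gene_a, gene_b):
                family_rows.append(dict(family_id=f"fam{fam:05d}", species=sp, gene_id=g))
            latent_rows.append(
                dict(
                    family_id=f"fam{fam:05d}", species=sp, mode=mode,
                    has_ppi=ppi_flag, ks=ks, sd=sd, ed_latent=ed, id_latent=idv,
                )
            )

            # Detection profiles realizing ED exactly up to rounding:
            # C union conditions, U = round(ED*C) unique, odd remainder to the
            # lexicographically first gene (gene_a).
            c_union = int(round(config.detection_prob * config.n_conditions))
            chosen = rng_expr.choice(config.n_conditions, size=c_union, replace=False)
            u_total = int(round(ed * c_union))
            u_a = u_total - u_total // 2
            only_a = chosen[:u_a]
            only_b = chosen[u_a:u_total]
            shared = chosen[u_total:]
            detection_sets[sp][gene_a] = np.sort(np.concatenate([shared, only_a]))
            detection_sets[sp][gene_b] = np.sort(np.concatenate([shared, only_b]))
            latent_rows[-1]["ed_realized"] = u_total / c_union if c_union else math.nan

        # Singleton background genes fill the remaining families.
        for fam in range(n_pairs, config.n_families):
            (gene,) = _gene_names(sp, fam, "singleton")
            family_rows.append(dict(family_id=f"fam{fam:05d}", species=sp, gene_id=gene))
            det = np.flatnonzero(rng_expr.random(config.n_conditions) < config.detection_prob)
            if det.size == 0:
                det = np.array([int(rng_expr.integers(config.n_conditions))])
            detection_sets[sp][gene] = det

        # Count matrix: detected cells get a floor that guarantees survival of
        # the low-expression filter (row sum >= 2 * n_conditions), plus NB noise.
        genes = sorted(detection_sets[sp])
        mat = np.zeros((len(genes), config.n_conditions), dtype=np.int64)
        for i, g in enumerate(genes):
            det = detection_sets[sp][g]
            floor = math.ceil(2 * config.n_conditions / det.size)
            mat[i, det] = floor + _nb_counts(det.size, mean_count, dispersion, rng_expr)
        counts[sp] = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=cond_ids)

        # Gene positions: tandem pairs sit a few ranks apart on a shared
        # chromosome; block pairs on different chromosomes.  Unclassified
        # pairs are placed like tandems (their conflict comes from carrying a
        # collinearity flag as well).
        for fam in range(n_pairs):
            mode = modes[fam]
            gene_a, gene_b = _gene_names(sp, fam, "pair")
            if mode in ("tandem", "unclassified"):
                gap = int(rng_misc.integers(1, 6))  # 0-4 intervening genes
                position_rows.append(dict(gene_id=gene_a, chromosome=f"{sp}_chr1", rank=fam * 50))
                position_rows.append(dict(gene_id=gene_b, chromosome=f"{sp}_chr1", rank=fam * 50 + gap))
            else:
                position_rows.append(dict(gene_id=gene_a, chromosome=f"{sp}_chr2", rank=fam))
                position_rows.append(dict(gene_id=gene_b, chromosome=f"{sp}_chr3", rank=fam))

    # PPI network for the reference species: partner sets realize latent ID.
    ppi_rows: list[dict] = []
    latent_df = pd.DataFrame(latent_rows)
    ref_mask = latent_df["species"] == reference
    id_realized = np.full(len(latent_df), np.nan)
    n_partner_col = np.zeros(len(latent_df), dtype=int)
    shared_col = np.zeros(len(latent_df), dtype=int)
    for idx in latent_df.index[ref_mask]:
        row = latent_df.loc[idx]
        if not row["has_ppi"]:
            continue
        fam = row["family_id"]
        gene_a, gene_b = _gene_names(reference, int(fam[3:]), "pair")
        # Ancestral partner count N ~ Poisson truncated >= 1; the shared count
        # S = round((1-ID) * N) gives both genes degree N and realized
        # ID = 1 - S/N, i.e. the latent target up to rounding.
        n_part = 0
        while n_part < 1:
            n_part = int(rng_ppi.poisson(config.ppi_degree_mean))
        retention = 1.0 - row["id_latent"]
        n_shared = int(round(retention * n_part))
        for k in range(n_shared):
            partner = f"{fam}_ps{k}"
            ppi_rows.append(dict(protein_a=gene_a, protein_b=partner))
            ppi_rows.append(dict(protein_a=gene_b, protein_b=partner))
        for k in range(n_part - n_shared):
            ppi_rows.append(dict(protein_a=gene_a, protein_b=f"{fam}_pa{k}"))
            ppi_rows.append(dict(protein_a=gene_b, protein_b=f"{fam}_pb{k}"))
        id_realized[idx] = 1.0 - n_shared / n_part
        n_partner_col[idx] = n_part
        shared_col[idx] = n_shared
    latent_df["id_realized"] = id_realized
    latent_df["n_partners"] = n_partner_col
    latent_df["n_shared_partners"] = shared_col

    # GO annotations for reference-species genes, biased by duplication mode.
    go_rows: list[dict] = []
    for fam in range(config.n_families):
        mode = modes[fam] if fam < n_pairs else "singleton"
        genes = _gene_names(reference, fam, "pair" if fam < n_pairs else "singleton")
        for g in genes:
            for term in config.go_terms:
                if rng_go.random() < term.prob(mode):
                    go_rows.append(dict(gene_id=g, term_id=term.term_id))

    catalog = pd.DataFrame(catalog_rows)
    ground_truth = {
        "config": _config_to_json(config),
        "reference_species": reference,
        "modes_by_family": {f"fam{f:05d}": modes[f] for f in range(n_pairs)},
        "has_ppi_by_family": {f"fam{f:05d}": has_ppi[f] for f in range(n_pairs)},
        "note": (
            "All distributional choices (Ks mixtures, saturation curves, "
            "noise, count model, degree model) are the generator's own; "
            "latent and realized divergences per pair are listed under "
            "'pairs'."
        ),
        "pairs": latent_df.to_dict(orient="records"),
    }
    return SyntheticDataset(
        catalog=catalog,
        counts=counts,
        ppi_edges=pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b"]),
        families=pd.DataFrame(family_rows),
        go=pd.DataFrame(go_rows, columns=["gene_id", "term_id"]),
        positions=pd.DataFrame(position_rows),
        ground_truth=ground_truth,
    )


def _config_to_json(config: GeneratorConfig) -> dict:
    def convert(obj):
        if isinstance(obj, (CurvePair, GoTermSpec)):
            return dataclasses.asdict(obj)
        if isinstance(obj, Mapping):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return {f.name: convert(getattr(config, f.name)) for f in dataclasses.fields(config)}


# ---------------------------------------------------------------------------
# I/O


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> list[str]:
    """Write the dataset's external files; returns the manifest of paths.

    Files: catalog.tsv, counts.<species>.tsv (one per species), ppi.tsv,
    families.tsv, go.tsv, positions.tsv and a ground_truth.json sidecar.
    Writing is deterministic: identical datasets produce identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str, df: pd.DataFrame, **kwargs) -> None:
        df.to_csv(directory / name, sep="\t", float_format="%.10g", **kwargs)
        manifest.append(name)

    emit("catalog.tsv", dataset.catalog, index=False)
    for sp in dataset.species:
        emit(f"counts.{sp}.tsv", dataset.counts[sp], index=True)
    emit("ppi.tsv", dataset.ppi_edges, index=False)
    emit("families.tsv", dataset.families, index=False)
    emit("go.tsv", dataset.go, index=False)
    emit("positions.tsv", dataset.positions, index=False)

    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(dataset.ground_truth, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    manifest.append("ground_truth.json")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    catalog = pd.read_csv(directory / "catalog.tsv", sep="\t")
    counts = {}
    for path in sorted(directory.glob("counts.*.tsv")):
        sp = path.name.split(".")[1]
        counts[sp] = pd.read_csv(path, sep="\t", index_col=0)
    with open(directory / "ground_truth.json") as fh:
        ground_truth = json.load(fh)
    return SyntheticDataset(
        catalog=catalog,
        counts=counts,
        ppi_edges=pd.read_csv(directory / "ppi.tsv", sep="\t"),
        families=pd.read_csv(directory / "families.tsv", sep="\t"),
        go=pd.read_csv(directory / "go.tsv", sep="\t"),
        positions=pd.read_csv(directory / "positions.tsv", sep="\t"),
        ground_truth=ground_truth,
    )
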