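"""End-to-end orchestration over the documented TSV interfaces.

Each stage reads and writes plain tab-separated files inside one output
directory, so a run can be resumed, inspected or re-driven stage by stage
(from Python or via the CLI).  A run manifest records parameter values,
input-file hashes and the package version for reproducibility.

Stages: simulate -> filter -> ed -> id -> project -> fit -> correlate ->
enrich -> report.  ``run_all`` chains them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, catalog, expression, network, saturation, synthetic

log = logging.getLogger("dupdiverge")

__all__ = ["RunConfig", "run_all", "Stage", "STAGES"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    ``data_dir`` holds the input TSVs (written there by the simulate stage,
    or supplied externally in the same formats); ``out_dir`` receives results.
    """

    out_dir: str = "run"
    data_dir: str | None = None  # default: <out_dir>/data
    seed: int = 0
    # generator
    generator: dict = field(default_factory=dict)
    # filters
    ks_min: float = 0.05
    ks_max: float = 5.0
    low_expression_multiplier: float = 2.0
    detection_threshold: float = 0.0
    id_min_deg_high: int = 4
    id_min_deg_low: int = 1
    # inference
    schemes: tuple[str, ...] = ("mode", "ppi_status", "mode_x_ppi")
    measures: tuple[str, ...] = ("sd", "ed")
    min_partition_size: int = 10
    with_bands: bool = False
    n_boot: int = 200
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("schemes", "measures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def data_path(self) -> Path:
        return Path(self.data_dir) if self.data_dir else Path(self.out_dir) / "data"

    def validate_inputs(self, need: tuple[str, ...]) -> None:
        for name in need:
            path = self.data_path / name
            if not path.exists():
                raise FileNotFoundError(f"required input missing: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _update_manifest(cfg: RunConfig, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("version", __version__)
    manifest.setdefault("config", dataclasses.asdict(cfg))
    manifest.setdefault("stages", {})
    manifest["stages"][stage] = {
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", index=index)
    return path


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig) -> list[Path]:
    gen_cfg = synthetic.GeneratorConfig(**cfg.generator, seed=cfg.seed)
    dataset = synthetic.generate_dataset(gen_cfg)
    manifest = synthetic.write_dataset(dataset, cfg.data_path)
    log.info("simulate: wrote %d files to %s", len(manifest), cfg.data_path)
    outputs = [cfg.data_path / m for m in manifest]
    _update_manifest(cfg, "simulate", [], outputs)
    return outputs


def stage_filter(cfg: RunConfig) -> Path:
    cfg.validate_inputs(("catalog.tsv",))
    pairs = pd.read_csv(cfg.data_path / "catalog.tsv", sep="\t")
    result = catalog.apply_ks_window(pairs, cfg.ks_min, cfg.ks_max)
    log.info(
        "filter: kept %d pairs (discarded %d below Ks window, %d above)",
        len(result.retained), result.n_discarded_low, result.n_discarded_high,
    )
    out = _write(result.retained, Path(cfg.out_dir) / "catalog.filtered.tsv")
    _update_manifest(cfg, "filter", [cfg.data_path / "catalog.tsv"], [out])
    return out


def stage_ed(cfg: RunConfig) -> list[Path]:
    pairs = pd.read_csv(Path(cfg.out_dir) / "catalog.filtered.tsv", sep="\t")
    ed_parts, ex_parts = [], []
    inputs = []
    for sp, grp in pairs.groupby("species"):
        counts_path = cfg.data_path / f"counts.{sp}.tsv"
        if not counts_path.exists():
            raise FileNotFoundError(f"required input missing: {counts_path}")
        inputs.append(counts_path)
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        kept = expression.low_expression_filter(counts, cfg.low_expression_multiplier)
        matrix = counts.loc[kept]
        if cfg.detection_threshold > 0:  # thresholds are on the CPM scale
            matrix = expression.cpm_transform(matrix)
        profiles = expression.detection_profiles(matrix, threshold=cfg.detection_threshold)
        ed, exclusions = expression.compute_ed_table(grp, profiles)
        ed.insert(0, "species", sp)
        exclusions.insert(0, "species", sp)
        ed_parts.append(ed)
        ex_parts.append(exclusions)
    ed_all = pd.concat(ed_parts) if ed_parts else pd.DataFrame()
    ex_all = pd.concat(ex_parts) if ex_parts else pd.DataFrame()
    out1 = _write(ed_all, Path(cfg.out_dir) / "ed.tsv")
    out2 = _write(ex_all, Path(cfg.out_dir) / "ed_exclusions.tsv")
    log.info("ed: %d pairs scored, %d excluded", len(ed_all), len(ex_all))
    _update_manifest(cfg, "ed", inputs, [out1, out2])
    return [out1, out2]


def stage_id(cfg: RunConfig, reference_species: str | None = None) -> list[Path]:
    cfg.validate_inputs(("ppi.tsv",))
    pairs = pd.read_csv(Path(cfg.out_dir) / "catalog.filtered.tsv", sep="\t")
    net = network.merge_networks([cfg.data_path / "ppi.tsv"])
    ref = reference_species or sorted(pairs["species"].unique())[0]
    ref_pairs = pairs[pairs["species"] == ref]
    id_table = network.compute_id_table(
        ref_pairs, net, cfg.id_min_deg_high, cfg.id_min_deg_low
    )
    id_table.insert(0, "species", ref)
    sweep = network.sweep_id_cutoffs(ref_pairs, net, min_deg_low=cfg.id_min_deg_low)
    out1 = _write(id_table, Path(cfg.out_dir) / "id.tsv")
    out2 = _write(sweep, Path(cfg.out_dir) / "id_cutoff_sweep.tsv")
    log.info(
        "id: network %d nodes / %d edges; %d eligible pairs at cutoff %d",
        net.graph["n_nodes"], net.graph["n_edges"],
        int(id_table["eligible"].sum()), cfg.id_min_deg_high,
    )
    _update_manifest(cfg, "id", [cfg.data_path / "ppi.tsv"], [out1, out2])
    return [out1, out2]


def stage_project(cfg: RunConfig, reference_species: str | None = None) -> Path:
    cfg.validate_inputs(("ppi.tsv", "families.tsv"))
    families = pd.read_csv(cfg.data_path / "families.tsv", sep="\t")
    net = network.merge_networks([cfg.data_path / "ppi.tsv"])
    ref = reference_species or sorted(families["species"].unique())[0]
    status = network.project_ppi_status(families, net, ref)
    out = _write(status, Path(cfg.out_dir) / "ppi_status.tsv")
    log.info("project: %d genes labeled, reference %s", len(status), ref)
    _update_manifest(
        cfg, "project",
        [cfg.data_path / "ppi.tsv", cfg.data_path / "families.tsv"], [out],
    )
    return out


def _assemble_records(cfg: RunConfig) -> pd.DataFrame:
    """Join filtered catalog with ED, ID and pair-level PPI status."""
    out = Path(cfg.out_dir)
    pairs = pd.read_csv(out / "catalog.filtered.tsv", sep="\t")
    pairs = pairs.rename(columns={"kn": "sd"})
    ed = pd.read_csv(out / "ed.tsv", sep="\t")
    pairs = pairs.merge(
        ed[["species", "gene_a", "gene_b", "ed"]],
        on=["species", "gene_a", "gene_b"], how="left",
    )
    id_path = out / "id.tsv"
    if id_path.exists():
        idt = pd.read_csv(id_path, sep="\t")
        idt = idt[idt["eligible"]]
        pairs = pairs.merge(
            idt[["species", "gene_a", "gene_b", "id_value"]].rename(columns={"id_value": "id"}),
            on=["species", "gene_a", "gene_b"], how="left",
        )
    else:
        pairs["id"] = float("nan")
    status_path = out / "ppi_status.tsv"
    if status_path.exists():
        status = pd.read_csv(status_path, sep="\t")
        pairs["with_ppi"] = network.pair_ppi_status(pairs, status).values
    return pairs


def stage_fit(cfg: RunConfig) -> list[Path]:
    records = _assemble_records(cfg)
    fits, comparisons, skipped = [], [], []
    for scheme in cfg.schemes:
        if scheme != "mode" and "with_ppi" not in records.columns:
            log.warning("fit: scheme %s skipped (no PPI status); run project first", scheme)
            continue
        measures = tuple(cfg.measures)
        if records["id"].notna().sum() >= 2 * cfg.min_partition_size and scheme == "mode":
            measures = measures + ("id",)
        res = saturation.run_figure_suite(
            records, measures=measures, scheme=scheme,
            min_partition_size=cfg.min_partition_size,
            with_bands=cfg.with_bands, n_boot=cfg.n_boot, seed=cfg.seed,
        )
        fits.append(res.fits)
        comparisons.append(res.comparisons)
        skipped.append(res.skipped)
    out1 = _write(pd.concat(fits, ignore_index=True), Path(cfg.out_dir) / "fits.tsv")
    out2 = _write(pd.concat(comparisons, ignore_index=True), Path(cfg.out_dir) / "comparisons.tsv")
    out3 = _write(pd.concat(skipped, ignore_index=True), Path(cfg.out_dir) / "fit_skipped.tsv")
    log.info("fit: %d fits, %d comparisons", sum(map(len, fits)), sum(map(len, comparisons)))
    _update_manifest(cfg, "fit", [], [out1, out2, out3])
    return [out1, out2, out3]


def stage_correlate(cfg: RunConfig) -> Path:
    records = _assemble_records(cfg)
    variables = ["ks", "sd", "ed"] + (["id"] if records["id"].notna().any() else [])
    frames = [correlations := assoc.correlation_panel(
        records[records["mode"] != "unclassified"], variables=variables,
        partition_col="mode",
    )]
    if "with_ppi" in records.columns:
        rec = records.assign(
            ppi_status=records["with_ppi"].map({True: "with_ppi", False: "without_ppi"})
        )
        frames.append(
            assoc.correlation_panel(rec, variables=variables, partition_col="ppi_status")
        )
    out = _write(pd.concat(frames, ignore_index=True), Path(cfg.out_dir) / "correlations.tsv")
    _update_manifest(cfg, "correlate", [], [out])
    return out


def stage_enrich(cfg: RunConfig, reference_species: str | None = None) -> list[Path]:
    cfg.validate_inputs(("go.tsv",))
    annotations = pd.read_csv(cfg.data_path / "go.tsv", sep="\t")
    records = _assemble_records(cfg)
    ref = reference_species or sorted(records["species"].unique())[0]
    ref_rec = records[(records["species"] == ref) & (records["mode"] != "unclassified")]
    background = set(ref_rec["gene_a"]) | set(ref_rec["gene_b"])
    frames = []
    for mode, grp in ref_rec.groupby("mode"):
        genes = set(grp["gene_a"]) | set(grp["gene_b"])
        enr = assoc.go_enrichment(genes, background, annotations)
        enr.insert(0, "gene_set", mode)
        frames.append(enr)
    out1 = _write(pd.concat(frames, ignore_index=True), Path(cfg.out_dir) / "enrichment.tsv")
    outputs = [out1]
    if "with_ppi" in records.columns:
        rep = assoc.representation_test_table1(ref_rec)
        outputs.append(_write(rep, Path(cfg.out_dir) / "representation.tsv", index=True))
    _update_manifest(cfg, "enrich", [cfg.data_path / "go.tsv"], outputs)
    return outputs


def stage_report(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    lines = ["dupdiverge run report", "=" * 40]
    records = _assemble_records(cfg)
    if "with_ppi" in records.columns:
        lines.append("\nPair counts (mode x PPI status):")
        lines.append(catalog.summarize_counts(records).to_string())
    for name, title in (
        ("fits.tsv", "Saturation fits"),
        ("comparisons.tsv", "Nested-model F-tests"),
        ("correlations.tsv", "Correlation panel"),
        ("representation.tsv", "PPI representation by mode"),
        ("enrichment.tsv", "GO-slim enrichment (q < alpha)"),
    ):
        path = out / name
        if not path.exists():
            continue
        df = pd.read_csv(path, sep="\t")
        if name == "enrichment.tsv":
            df = df[df["q_value"] < cfg.alpha]
        lines.append(f"\n{title}:")
        lines.append(df.to_string(index=False))
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    _update_manifest(cfg, "report", [], [report])
    return report


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "ed": stage_ed,
    "id": stage_id,
    "project": stage_project,
    "fit": stage_fit,
    "correlate": stage_correlate,
    "enrich": stage_enrich,
    "report": stage_report,
}

Stage = str


def run_all(cfg: RunConfig, simulate: bool | None = None) -> Path:
    """Run the full chain; returns the report path.

    ``simulate`` defaults to True when no catalog exists in ``data_dir`` yet.
    """
    if simulate is None:
        simulate = not (cfg.data_path / "catalog.tsv").exists()
    order = (["simulate"] if simulate else []) + [
        "filter", "ed", "id", "project", "fit", "correlate", "enrich", "report",
    ]
    for name in order:
        log.info("stage %s", name)
        STAGES[name](cfg)
    return Path(cfg.out_dir) / "report.txt"
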