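"""Run the whole pipeline — simulate through report — from one config.

Equivalent to `dupdiverge --seed 11 --outdir scratch/pipeline_run all` with a
generator section in the YAML config.
"""

from dupdiverge.pipeline import RunConfig, run_all

cfg = RunConfig(
    out_dir="scratch/pipeline_run",
    seed=11,
    generator=dict(
        n_species=3, n_families=300, n_block_pairs=100, n_tandem_pairs=100,
        n_unclassified_pairs=10, ppi_asymptote_factor=0.7,
    ),
)
report = run_all(cfg)
print(f"report written to {report}\n")
print(report.read_text()[:2000])
# The run directory also holds every intermediate table (ed.tsv, id.tsv,
# fits.tsv, comparisons.tsv, ...) plus manifest.json with input hashes.
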