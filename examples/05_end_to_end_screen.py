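"""Full screen: simulate a dataset with a planted theme, run both tests.

The planted theme's genes jointly carry survival-linked expression beyond
the mild global axis; the screen should rank it first by p2.
"""

import tempfile
from pathlib import Path

import themesurv as ts

spec = ts.SimulationSpec(
    n_genes=2000, n_samples=60, fraction_affected=0.2, shift=0.2,
    hazard_ratio=4.0, planted_theme_size=30, planted_theme_shift=1.5, seed=12,
)

with tempfile.TemporaryDirectory() as tmp:
    data_dir = Path(tmp) / "data"
    ts.simulate_to_files(spec, data_dir, n_sets=30, set_sizes=(10, 20, 50))
    config = ts.RunConfig(
        expression_path=str(data_dir / "expression.tsv"),
        clinical_path=str(data_dir / "clinical.tsv"),
        gmt_path=str(data_dir / "collection.gmt"),
        probe_map_path=str(data_dir / "probe_map.tsv"),
        output_dir=str(Path(tmp) / "out"),
        collection_name="random_collection",
        pipeline=ts.PipelineConfig(B=500, seed=13),
    )
    result = ts.run_screen(config)

print(f"{'rank':<6}{'geneset':<16}{'p1':>10}{'p2':>8}{'FDR2':>8}")
ok = [r for r in result.records if r.status == "ok"]
for rank, r in enumerate(ok[:5], start=1):
    print(f"{rank:<6}{r.geneset_name:<16}{r.p1:>10.3g}{r.p2:>8.3f}{r.fdr2:>8.3f}")
print("\nthe planted theme should sit at rank 1 with p2 near 0: its genes are")
print("more prognostic than random genesets from the same universe, which is")
print("exactly what the competitive test certifies.")
print("\nsummary:", {k: result.summary[k] for k in
      ("n_tested", "p1_significant", "p2_significant", "p2_fdr_significant")})
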