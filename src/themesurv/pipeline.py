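"""End-to-end orchestration of the two-null-hypothesis screen.

``run_screen`` is the library entry point the CLI wraps: preprocess the
matrix, run every geneset through the first test, build (or reload) the
collection's empirical null, attach p2 and the two FDR vectors, and write
a sorted results table plus a summary of significant counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .cluster import DEFAULT_EVENNESS_MIN_FRACTION, first_test_prepared, prepare_dataset
from .formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeMap,
    ResultRecord,
)
from .null_model import (
    EmpiricalNull,
    PipelineConfig,
    SizeSampler,
    build_empirical_null,
    load_empirical_null,
    make_size_sampler,
    save_empirical_null,
    second_test,
    size_effect_scan,
    stability_analysis,
    summarize_results,
    uniformity_diagnostics,
)
from .preprocess import PreprocessConfig, preprocess_matrix
from .simulate import (
    SimulationSpec,
    SyntheticDataset,
    gen_confounded_dataset,
    gen_null_dataset,
    gen_random_collection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ScreenResult",
    "run_screen",
    "diagnose",
    "simulate_to_files",
    "dataset_hash",
]


@dataclass
class RunConfig:
    """Everything one reproducible screen needs."""

    expression_path: str
    clinical_path: str
    gmt_path: str
    probe_map_path: str
    output_dir: str
    endpoint: str = "OS"
    time_col: str = "time"
    event_col: str = "event"
    collection_name: str = "collection"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION
    size_mode: str = "pooled"          # pooled | exact
    null_cache: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "pipeline" in d and isinstance(d["pipeline"], dict):
            d["pipeline"] = PipelineConfig(**d["pipeline"])
        return cls(**d)


@dataclass
class ScreenResult:
    records: list[ResultRecord]
    summary: dict
    null: EmpiricalNull


def dataset_hash(m: ExpressionMatrix, clin: ClinicalTable) -> str:
    """Content hash of the preprocessed matrix + clinical table (cache key)."""
    h = hashlib.md5()
    h.update(np.ascontiguousarray(m.values).tobytes())
    h.update("|".join(m.probe_ids).encode())
    h.update("|".join(m.sample_ids).encode())
    h.update(clin.times.tobytes())
    h.update(clin.events.tobytes())
    return h.hexdigest()


def _null_cache_valid(base: Path, expected: dict) -> bool:
    sidecar = base.with_suffix(".json")
    if not sidecar.exists() or not base.with_suffix(".tsv").exists():
        return False
    meta = json.loads(sidecar.read_text())
    return all(meta.get(k) == v for k, v in expected.items())


def run_screen(config: RunConfig) -> ScreenResult:
    """Run the full two-test screen and write results under ``output_dir``.

    Writes ``results.tsv`` (one row per geneset, sorted by p2 then p1,
    discarded sets last) and ``summary.json`` with the counts significant
    at (p1 < alpha), (p1 < alpha & FDR1 < threshold), (p2 < alpha),
    (p2 < alpha & FDR2 < threshold), plus seed, B and discard tallies.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    m = formats.read_expression_matrix(config.expression_path)
    clin = formats.read_clinical_table(
        config.clinical_path, config.endpoint, config.time_col, config.event_col
    )
    collection = formats.read_gmt(config.gmt_path, config.collection_name)
    pm = formats.read_probe_map(config.probe_map_path)

    m = preprocess_matrix(m, config.preprocess)
    prep = prepare_dataset(m, pm, clin, config.preprocess, config.evenness_min_fraction)

    first = [first_test_prepared(prep, gs.name, gs.genes, gs.collection) for gs in collection]
    ok = [r for r in first if r.ok]
    logger.info("first test: %d ok, %d discarded of %d genesets", len(ok), len(first) - len(ok), len(first))
    if not ok:
        raise RuntimeError("every geneset was discarded before the first test")

    if config.size_mode == "exact":
        if len({r.n_genes for r in ok}) != 1:
            raise ValueError("exact size mode needs a single tested geneset size")
        sampler = SizeSampler(np.array([ok[0].n_genes]))
    else:
        sampler = make_size_sampler(collection, [r.n_genes for r in ok])

    cache_key = {
        "collection_tag": config.collection_name,
        "endpoint_tag": config.endpoint,
        "B": config.pipeline.B,
        "seed": config.pipeline.seed,
        "size_mode": sampler.size_mode,
        "dataset_hash": dataset_hash(m, clin),
    }
    null: EmpiricalNull | None = None
    cache_base = Path(config.null_cache) if config.null_cache else out_dir / "null_cache"
    if _null_cache_valid(cache_base, cache_key):
        logger.info("reusing cached empirical null at %s", cache_base)
        null = load_empirical_null(cache_base)
    if null is None:
        null = build_empirical_null(
            collection.universe, sampler, prep,
            B=config.pipeline.B, seed=config.pipeline.seed,
            collection_tag=config.collection_name, endpoint_tag=config.endpoint,
            evenness_min_fraction=config.evenness_min_fraction,
        )
        save_empirical_null(null, cache_base, extra_meta={"dataset_hash": cache_key["dataset_hash"]})

    records = second_test(first, null, config.pipeline,
                          collection_tag=config.collection_name, endpoint_tag=config.endpoint)

    def sort_key(r: ResultRecord):
        if r.status != "ok":
            return (1, 1.0, 1.0, r.geneset_name)
        return (0, r.p2, r.p1, r.geneset_name)

    records = sorted(records, key=sort_key)
    formats.write_results(records, out_dir / "results.tsv")

    summary = summarize_results(records, config.pipeline)
    summary.update(
        {
            "endpoint": config.endpoint,
            "collection": config.collection_name,
            "B": null.B,
            "seed": config.pipeline.seed,
            "alpha": config.pipeline.alpha,
            "fdr_threshold": config.pipeline.fdr_threshold,
            "null_discarded_draws": null.n_discarded,
            "size_mode": null.size_mode,
        }
    )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("screen summary: %s", summary)
    return ScreenResult(records=records, summary=summary, null=null)


def diagnose(
    config: RunConfig,
    *,
    sizes: tuple[int, ...] = (20, 75, 150, 300, 500),
    reps_per_size: int = 10_000,
    B_list: tuple[int, ...] = (1_000, 10_000, 50_000, 100_000),
    run_size_effect: bool = True,
    run_stability: bool = True,
) -> dict:
    """Uniformity, size-effect and stability diagnostics for one dataset.

    Writes ``null_density.tsv``, ``null_qq.tsv``, ``uniformity.json`` and,
    when enabled, ``size_effect.tsv`` and ``stability.tsv`` under the
    output directory.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    m = formats.read_expression_matrix(config.expression_path)
    clin = formats.read_clinical_table(
        config.clinical_path, config.endpoint, config.time_col, config.event_col
    )
    collection = formats.read_gmt(config.gmt_path, config.collection_name)
    pm = formats.read_probe_map(config.probe_map_path)
    m = preprocess_matrix(m, config.preprocess)
    prep = prepare_dataset(m, pm, clin, config.preprocess, config.evenness_min_fraction)

    tested_sizes = []
    for gs in collection:
        r = first_test_prepared(prep, gs.name, gs.genes)
        if r.ok:
            tested_sizes.append(r.n_genes)
    if not tested_sizes:
        raise RuntimeError("no geneset survives the filters; cannot diagnose")
    sampler = make_size_sampler(collection, tested_sizes)

    null = build_empirical_null(
        collection.universe, sampler, prep,
        B=config.pipeline.B, seed=config.pipeline.seed,
        collection_tag=config.collection_name, endpoint_tag=config.endpoint,
        evenness_min_fraction=config.evenness_min_fraction,
    )
    diag = uniformity_diagnostics(null)
    diag.density.to_csv(out_dir / "null_density.tsv", sep="\t", index=False)
    diag.qq.to_csv(out_dir / "null_qq.tsv", sep="\t", index=False)
    uniformity = {
        "ks_statistic": diag.ks_statistic,
        "ks_pvalue": diag.ks_pvalue,
        "uniform_rejected_at_0.01": diag.uniform_rejected,
        "B": null.B,
        "n_discarded": null.n_discarded,
    }
    (out_dir / "uniformity.json").write_text(json.dumps(uniformity, indent=2) + "\n")

    out: dict = {"uniformity": uniformity}
    if run_size_effect:
        table, discards = size_effect_scan(
            collection.universe, prep,
            sizes=sizes, reps_per_size=reps_per_size, seed=config.pipeline.seed,
            evenness_min_fraction=config.evenness_min_fraction,
        )
        table.to_csv(out_dir / "size_effect.tsv", sep="\t", index=False)
        out["size_effect_discards"] = discards
    if run_stability:
        stab = stability_analysis(
            collection.universe, sampler, prep,
            B_list=B_list, genesets=list(collection), seed=config.pipeline.seed,
            evenness_min_fraction=config.evenness_min_fraction,
        )
        stab.to_csv(out_dir / "stability.tsv", sep="\t", index=False)
        out["stability"] = stab
    return out


def simulate_to_files(
    spec: SimulationSpec,
    out_dir: str | Path,
    *,
    n_sets: int = 0,
    set_sizes: tuple[int, ...] = (10, 20, 50),
    collection_seed: int | None = None,
) -> SyntheticDataset:
    """Generate a synthetic dataset and write it in the pipeline's formats.

    Writes ``expression.tsv``, ``clinical.tsv``, ``probe_map.tsv`` and
    ``truth.json``; with ``n_sets`` > 0 also a random geneset collection
    ``collection.gmt`` over the synthetic universe (with the planted theme
    appended when the spec defines one).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = gen_confounded_dataset(spec) if spec.fraction_affected > 0 else gen_null_dataset(spec)
    formats.write_expression_matrix(ds.expression, out_dir / "expression.tsv")
    formats.write_clinical_table(ds.clinical, out_dir / "clinical.tsv")
    formats.write_probe_map(ds.probe_map, out_dir / "probe_map.tsv")
    truth = dict(ds.truth)
    truth["spec"] = dataclasses.asdict(spec)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    if n_sets > 0:
        coll = gen_random_collection(
            spec.n_genes, n_sets, set_sizes,
            seed=spec.seed + 1 if collection_seed is None else collection_seed,
        )
        sets = list(coll.sets)
        theme = ds.theme
        if theme is not None:
            sets.append(theme)
        coll = GeneSetCollection(name=coll.name, sets=sets, universe=coll.universe)
        formats.write_gmt(coll, out_dir / "collection.gmt")
    return ds
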