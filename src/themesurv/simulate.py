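"""Synthetic expression-survival datasets with the structure the method assumes.

The generators emulate what the pipeline actually consumes: a probe x
sample log-ratio matrix with missing entries and replicate probe rows, a
clinical table of exponential survival times with independent exponential
censoring, and a gene -> probe map.

Two regimes matter:

* the *null* regime — expression independent of survival — under which
  random-geneset first-test p-values should be uniform; and
* the *confounded* regime — a latent binary patient group shifts a
  fraction of genes AND multiplies the event hazard — under which random
  genesets cluster patients prognostically and their p-values pile up near
  zero.  This is the global-prognostic-axis situation that makes the
  competitive second test necessary.

An optional planted "theme" geneset receives an extra expression shift so
that recovery of a genuinely theme-linked set can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .formats import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection, ProbeMap

__all__ = [
    "SimulationSpec",
    "SyntheticDataset",
    "gen_null_dataset",
    "gen_confounded_dataset",
    "gen_random_collection",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the expression-survival simulation.

    Defaults model a desk-scale cDNA-style cohort: 2,000 genes, 60
    patients (the cohorts this style of screen is run on hold 50-70),
    10% missing measurements, 5% of genes spotted twice, and exponential
    survival with event rate 1.0 and censoring rate 0.5 per unit time, so
    about two thirds of patients have an observed event.

    ``fraction_affected``, ``shift`` (log2 units) and ``hazard_ratio``
    define the confounding axis: a balanced latent group z shifts the
    affected genes by +-shift and multiplies the event hazard by
    ``hazard_ratio`` for z = 1.  ``planted_theme_size`` /
    ``planted_theme_shift`` add a geneset whose genes receive an extra
    shift along z on top of whatever the confounder does.
    """

    n_genes: int = 2000
    n_samples: int = 60
    missing_rate: float = 0.10
    replicate_rate: float = 0.05
    event_rate: float = 1.0
    censor_rate: float = 0.5
    fraction_affected: float = 0.0
    shift: float = 0.0
    hazard_ratio: float = 1.0
    planted_theme_size: int = 0
    planted_theme_shift: float = 0.0
    group_fraction: float = 0.5
    endpoint: str = "OS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.replicate_rate < 1):
            raise ValueError("replicate_rate must be in [0, 1)")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not (0 <= self.fraction_affected <= 1):
            raise ValueError("fraction_affected must be in [0, 1]")
        if self.shift < 0 or self.planted_theme_shift < 0:
            raise ValueError("shifts must be >= 0")
        if self.hazard_ratio < 1:
            raise ValueError("hazard_ratio must be >= 1")
        if not (0 < self.group_fraction < 1):
            raise ValueError("group_fraction must be in (0, 1)")
        if self.planted_theme_size > self.n_genes:
            raise ValueError("planted theme larger than the gene pool")


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth used to build it."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    probe_map: ProbeMap
    truth: dict[str, Any]

    @property
    def theme(self) -> GeneSet | None:
        genes = self.truth.get("theme_genes")
        if not genes:
            return None
        return GeneSet(name="planted_theme", collection="truth", genes=frozenset(genes))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _generate(spec: SimulationSpec) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    G, n = spec.n_genes, spec.n_samples
    genes = _gene_ids(G)
    samples = [f"s{i:03d}" for i in range(1, n + 1)]

    # latent patient group (confounding axis), balanced by default
    n_group1 = int(round(spec.group_fraction * n))
    z = np.zeros(n, dtype=int)
    z[rng.permutation(n)[:n_group1]] = 1

    # per-gene deterministic shift along z
    shift = np.zeros(G)
    n_affected = int(round(spec.fraction_affected * G))
    affected = np.sort(rng.choice(G, size=n_affected, replace=False)) if n_affected else np.empty(0, dtype=int)
    if n_affected:
        signs = rng.choice([-1.0, 1.0], size=n_affected)
        shift[affected] = signs * spec.shift
    theme_idx = np.empty(0, dtype=int)
    theme_shift = np.zeros(G)
    if spec.planted_theme_size:
        theme_idx = np.sort(rng.choice(G, size=spec.planted_theme_size, replace=False))
        theme_signs = rng.choice([-1.0, 1.0], size=spec.planted_theme_size)
        theme_shift[theme_idx] = theme_signs * spec.planted_theme_shift

    def gene_signal(idx: np.ndarray) -> np.ndarray:
        return (shift[idx, None] + theme_shift[idx, None]) * z[None, :]

    base = rng.standard_normal((G, n)) + gene_signal(np.arange(G))

    # replicate spots: extra rows with the SAME probe id, independent noise
    n_rep = int(round(spec.replicate_rate * G))
    rep_genes = np.sort(rng.choice(G, size=n_rep, replace=False)) if n_rep else np.empty(0, dtype=int)
    if n_rep:
        rep_rows = rng.standard_normal((n_rep, n)) + gene_signal(rep_genes)
        values = np.vstack([base, rep_rows])
        probe_ids = [f"p_{g}" for g in genes] + [f"p_{genes[i]}" for i in rep_genes]
    else:
        values = base
        probe_ids = [f"p_{g}" for g in genes]

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    expr = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=samples))
    pm = ProbeMap({g: frozenset({f"p_{g}"}) for g in genes})

    # exponential survival with independent exponential censoring
    hazard = spec.event_rate * np.where(z == 1, spec.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_censor = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    clin = ClinicalTable(
        endpoint=spec.endpoint,
        data=pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample_id")),
    )

    truth = {
        "spec": spec,
        "z": z.tolist(),
        "affected_genes": [genes[i] for i in affected],
        "theme_genes": [genes[i] for i in theme_idx],
        "event_fraction": float(event.mean()),
    }
    return SyntheticDataset(expression=expr, clinical=clin, probe_map=pm, truth=truth)


def gen_null_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Expression independent of survival (no confounding axis).

    Entries are i.i.d. standard normal; survival is exponential with
    independent censoring.  Random-geneset first-test p-values on this
    data should be approximately uniform.
    """
    if spec.fraction_affected != 0 or spec.shift != 0 or spec.hazard_ratio != 1:
        raise ValueError("null dataset requires fraction_affected=0, shift=0, hazard_ratio=1")
    return _generate(spec)


def gen_confounded_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Dataset with a global prognostic expression axis.

    A balanced latent group shifts ``fraction_affected`` of genes and
    multiplies the event hazard, so random genesets cluster patients into
    prognostically distinct groups and their first-test p-values are
    non-uniform.
    """
    if spec.fraction_affected <= 0:
        raise ValueError("confounded dataset requires fraction_affected > 0")
    return _generate(spec)


def gen_random_collection(
    universe_size: int,
    n_sets: int,
    size_distribution,
    seed: int = 0,
    name: str = "random_collection",
) -> GeneSetCollection:
    """A collection of random genesets over a synthetic gene universe.

    ``size_distribution`` is a sequence of candidate sizes sampled
    uniformly (a point mass reproduces fixed-size collections).  Member
    genes are drawn uniformly from the universe; sets may overlap.  The
    collection's universe is the full synthetic gene pool, matching
    annotation files in which more genes are annotated than appear in any
    retained set.
    """
    sizes = np.asarray(list(size_distribution), dtype=int)
    if sizes.size == 0:
        raise ValueError("empty size distribution")
    if sizes.max() > universe_size:
        raise ValueError("geneset size exceeds universe")
    if sizes.min() < 1:
        raise ValueError("geneset sizes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(universe_size)
    width = max(4, len(str(n_sets)))
    sets = []
    for k in range(n_sets):
        size = int(sizes[rng.integers(sizes.size)])
        idx = rng.choice(universe_size, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"set_{k + 1:0{width}d}",
                collection=name,
                genes=frozenset(genes[i] for i in idx),
            )
        )
    return GeneSetCollection(name=name, sets=sets, universe=frozenset(genes))
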