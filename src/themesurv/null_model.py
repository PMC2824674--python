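"""Second-hypothesis test: empirical nulls from random genesets.

A geneset's first-test p-value p1 answers the self-contained question —
does this set of genes stratify patients prognostically?  It does not say
whether *random* genes would do as well.  Under widespread survival-linked
expression structure, random genesets yield non-uniform p1 distributions,
so a small p1 alone cannot support a claim about the geneset's theme.

This module builds, per (collection, endpoint), an empirical distribution
of first-test p-values from B random genesets drawn from the collection's
gene universe with sizes matched to the tested sets, and computes for each
geneset the competitive empirical p-value

    p2 = b / B,   b = #{random genesets with p1' <= p1}.

Benjamini-Hochberg FDR is applied separately to the p1 and p2 vectors.
Diagnostics cover uniformity of the null (KS test, density, QQ tables),
the geneset-size effect, and stability of p2 in the number of draws B.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .cluster import (
    DEFAULT_EVENNESS_MIN_FRACTION,
    FirstTestResult,
    PreparedDataset,
    first_test_prepared,
    prepare_dataset,
)
from .formats import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection, ProbeMap, ResultRecord
from .preprocess import PreprocessConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "EmpiricalNull",
    "SizeSampler",
    "draw_random_geneset",
    "make_size_sampler",
    "build_empirical_null",
    "empirical_p2",
    "bh_fdr",
    "second_test",
    "summarize_results",
    "UniformityDiagnostics",
    "uniformity_diagnostics",
    "size_effect_scan",
    "stability_analysis",
    "save_empirical_null",
    "load_empirical_null",
    "expected_outperformance",
    "expected_exceedance",
    "expected_false_positives",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Significance thresholds and null size.

    ``alpha`` is applied to both p1 and p2; ``fdr_threshold`` to FDR1 and
    FDR2 (a permissive value suits screening studies with unstable feature
    rankings).  ``B`` random genesets per empirical null.
    """

    alpha: float = 0.01
    fdr_threshold: float = 0.30
    B: int = 100_000
    seed: int = 0
    pseudocount: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class EmpiricalNull:
    """B first-test p-values of random genesets for one (collection, endpoint)."""

    collection_tag: str
    endpoint_tag: str
    null_p1: np.ndarray
    sizes: np.ndarray
    n_discarded: int
    seed: int
    size_mode: str = "pooled"
    _sorted: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.null_p1 = np.asarray(self.null_p1, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.null_p1.shape != self.sizes.shape:
            raise ValueError("null_p1 and sizes length mismatch")
        if self.null_p1.size and (self.null_p1.min() < 0 or self.null_p1.max() > 1):
            raise ValueError("null p-values outside [0, 1]")
        if self.size_mode not in ("pooled", "exact"):
            raise ValueError(f"bad size_mode {self.size_mode!r}")

    @property
    def B(self) -> int:
        return int(self.null_p1.size)

    @property
    def sorted_p1(self) -> np.ndarray:
        if self._sorted is None or self._sorted.size != self.null_p1.size:
            self._sorted = np.sort(self.null_p1)
        return self._sorted

    def prefix(self, B: int) -> "EmpiricalNull":
        """First B retained draws — nested because one seeded stream is used."""
        if B > self.B:
            raise ValueError(f"prefix {B} exceeds available {self.B}")
        return EmpiricalNull(
            self.collection_tag, self.endpoint_tag,
            self.null_p1[:B].copy(), self.sizes[:B].copy(),
            self.n_discarded, self.seed, self.size_mode,
        )


@dataclass
class SizeSampler:
    """Draws geneset sizes from the tested collection's size multiset.

    Sampling sizes in proportion to the original sets' sizes makes the
    empirical null size-matched; a single-size multiset gives the
    exact-size mode used for single signatures.
    """

    sizes_multiset: np.ndarray

    def __post_init__(self) -> None:
        self.sizes_multiset = np.asarray(self.sizes_multiset, dtype=int)
        if self.sizes_multiset.size == 0:
            raise ValueError("empty size multiset")
        if (self.sizes_multiset < 1).any():
            raise ValueError("geneset sizes must be >= 1")

    def draw(self, rng: np.random.Generator) -> int:
        return int(self.sizes_multiset[rng.integers(self.sizes_multiset.size)])

    @property
    def size_mode(self) -> str:
        return "exact" if np.unique(self.sizes_multiset).size == 1 else "pooled"


def make_size_sampler(
    collection: GeneSetCollection | None,
    tested_sets: Sequence[GeneSet] | Sequence[int],
) -> SizeSampler:
    """Size sampler over the post-filter genesets' gene counts."""
    if len(tested_sets) == 0:
        raise ValueError("no tested genesets to match sizes against")
    sizes = [len(t.genes) if isinstance(t, GeneSet) else int(t) for t in tested_sets]
    return SizeSampler(np.asarray(sizes, dtype=int))


def draw_random_geneset(
    universe: Iterable[str], size: int, rng: np.random.Generator,
    name: str = "random", collection: str = "random",
) -> GeneSet:
    """Uniform sample of ``size`` unique genes from the universe."""
    pool = universe if isinstance(universe, (list, tuple)) else sorted(universe)
    if size > len(pool):
        raise ValueError(f"size {size} exceeds universe of {len(pool)} genes")
    idx = rng.choice(len(pool), size=size, replace=False)
    return GeneSet(name=name, collection=collection, genes=frozenset(pool[i] for i in idx))


def _as_prepared(
    m, pm=None, clin=None, cfg=None,
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION,
) -> PreparedDataset:
    if isinstance(m, PreparedDataset):
        return m
    return prepare_dataset(m, pm, clin, cfg, evenness_min_fraction)


def build_empirical_null(
    universe: Iterable[str],
    sampler: SizeSampler,
    m: ExpressionMatrix | PreparedDataset,
    pm: ProbeMap | None = None,
    clin: ClinicalTable | None = None,
    cfg: PreprocessConfig | None = None,
    *,
    B: int,
    seed: int,
    collection_tag: str = "",
    endpoint_tag: str = "",
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION,
    max_discard_fraction: float = 0.99,
) -> EmpiricalNull:
    """Collect B valid first-test p-values of random genesets.

    Draws alternate size then membership from one seeded stream; draws that
    the pipeline discards (size/probe filters, undefined distances, uneven
    clusters) are counted and redrawn, so the null holds exactly B assessed
    random genesets and is nested in any longer run with the same seed.
    Aborts if the discard rate over a 1,000-draw window exceeds
    ``max_discard_fraction`` — the dataset/universe cannot support the null.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    prep = _as_prepared(m, pm, clin, cfg, evenness_min_fraction)
    pool = sorted(universe)
    rng = np.random.default_rng(seed)
    p1s = np.empty(B, dtype=float)
    sizes = np.empty(B, dtype=int)
    n_valid = 0
    n_discarded = 0
    window_draws = window_discards = 0
    while n_valid < B:
        size = sampler.draw(rng)
        idx = rng.choice(len(pool), size=size, replace=False)
        genes = [pool[i] for i in idx]
        res = first_test_prepared(prep, "random", genes)
        window_draws += 1
        if res.ok:
            p1s[n_valid] = res.p1
            sizes[n_valid] = size
            n_valid += 1
        else:
            n_discarded += 1
            window_discards += 1
        if window_draws >= 1000:
            if window_discards / window_draws > max_discard_fraction:
                raise RuntimeError(
                    f"empirical null aborted: {window_discards}/{window_draws} random "
                    "genesets discarded in the last window; check filters/universe"
                )
            window_draws = window_discards = 0
        if n_valid and n_valid % 10_000 == 0 and window_draws == 0:
            logger.info("empirical null: %d/%d draws retained (%d discarded)", n_valid, B, n_discarded)
    return EmpiricalNull(
        collection_tag=collection_tag,
        endpoint_tag=endpoint_tag,
        null_p1=p1s,
        sizes=sizes,
        n_discarded=n_discarded,
        seed=seed,
        size_mode=sampler.size_mode,
    )


def empirical_p2(p1: float, null: EmpiricalNull, pseudocount: bool = False) -> float:
    """Competitive empirical p-value: fraction of null p1 values <= p1.

    Ties count (<=, inclusive).  With ``pseudocount`` the estimate is
    (b + 1) / (B + 1), which never returns exactly 0.
    """
    if not (0 <= p1 <= 1):
        raise ValueError("p1 must lie in [0, 1]")
    b = int(np.searchsorted(null.sorted_p1, p1, side="right"))
    if pseudocount:
        return (b + 1) / (null.B + 1)
    return b / null.B


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-aligned with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def second_test(
    results: Sequence[FirstTestResult],
    null: EmpiricalNull,
    cfg: PipelineConfig,
    collection_tag: str | None = None,
    endpoint_tag: str | None = None,
) -> list[ResultRecord]:
    """Attach p2, FDR1 and FDR2 to a collection's first-test results.

    FDR is computed over the ok genesets only (discarded sets were never
    tested).  Tags, when given, must match the null they were built for.
    """
    if collection_tag is not None and collection_tag != null.collection_tag:
        raise ValueError(f"null built for collection {null.collection_tag!r}, not {collection_tag!r}")
    if endpoint_tag is not None and endpoint_tag != null.endpoint_tag:
        raise ValueError(f"null built for endpoint {null.endpoint_tag!r}, not {endpoint_tag!r}")
    ok = [r for r in results if r.ok]
    p1s = np.array([r.p1 for r in ok], dtype=float)
    p2s = np.array([empirical_p2(p, null, cfg.pseudocount) for p in p1s], dtype=float)
    fdr1 = bh_fdr(p1s) if ok else np.empty(0)
    fdr2 = bh_fdr(p2s) if ok else np.empty(0)
    by_name = {r.geneset_name: i for i, r in enumerate(ok)}
    records: list[ResultRecord] = []
    for r in results:
        if r.ok:
            i = by_name[r.geneset_name]
            records.append(
                ResultRecord(
                    geneset_name=r.geneset_name, n_genes=r.n_genes, n_probes=r.n_probes,
                    cluster_sizes=r.cluster_sizes,
                    p1=float(p1s[i]), fdr1=float(fdr1[i]),
                    p2=float(p2s[i]), fdr2=float(fdr2[i]),
                )
            )
        else:
            records.append(
                ResultRecord(
                    geneset_name=r.geneset_name, n_genes=r.n_genes, n_probes=r.n_probes,
                    cluster_sizes=r.cluster_sizes,
                    status="discarded", discard_reason=r.discard_reason,
                )
            )
    return records


def summarize_results(records: Sequence[ResultRecord], cfg: PipelineConfig) -> dict[str, int]:
    """Counts of significant genesets under each test and its FDR filter."""
    ok = [r for r in records if r.status == "ok"]
    return {
        "n_tested": len(ok),
        "n_discarded": len(records) - len(ok),
        "p1_significant": sum(r.p1 < cfg.alpha for r in ok),
        "p1_fdr_significant": sum(r.p1 < cfg.alpha and r.fdr1 < cfg.fdr_threshold for r in ok),
        "p2_significant": sum(r.p2 is not None and r.p2 < cfg.alpha for r in ok),
        "p2_fdr_significant": sum(
            r.p2 is not None and r.p2 < cfg.alpha and r.fdr2 < cfg.fdr_threshold for r in ok
        ),
    }


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class UniformityDiagnostics:
    """Is the empirical null uniform on [0, 1]?

    ``ks_statistic``/``ks_pvalue`` — one-sample Kolmogorov-Smirnov test
    against Uniform(0,1).  ``density`` — histogram density over [0, 1] at
    the given bandwidth (a uniform null would be flat at 1).  ``qq`` —
    sorted null p1 against uniform quantiles i/(B+1), with -log10 columns
    for the small-p tail.
    """

    ks_statistic: float
    ks_pvalue: float
    bandwidth: float
    density: pd.DataFrame
    qq: pd.DataFrame

    @property
    def uniform_rejected(self) -> bool:
        return self.ks_pvalue < 0.01


def uniformity_diagnostics(null: EmpiricalNull, bandwidth: float = 0.01) -> UniformityDiagnostics:
    """KS uniformity test plus density and QQ tables for an empirical null."""
    if null.B < 10:
        raise ValueError("need at least 10 null draws for diagnostics")
    p = null.sorted_p1
    ks = kstest(p, "uniform")
    edges = np.arange(0.0, 1.0 + bandwidth / 2, bandwidth)
    counts, edges = np.histogram(p, bins=edges)
    density = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "density": counts / (null.B * bandwidth),
        }
    )
    uq = np.arange(1, null.B + 1) / (null.B + 1)
    with np.errstate(divide="ignore"):
        qq = pd.DataFrame(
            {
                "null_p1": p,
                "uniform_quantile": uq,
                "neg_log10_null_p1": -np.log10(np.maximum(p, np.finfo(float).tiny)),
                "neg_log10_uniform_quantile": -np.log10(uq),
            }
        )
    return UniformityDiagnostics(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        bandwidth=bandwidth,
        density=density,
        qq=qq,
    )


def size_effect_scan(
    universe: Iterable[str],
    m: ExpressionMatrix | PreparedDataset,
    pm: ProbeMap | None = None,
    clin: ClinicalTable | None = None,
    cfg: PreprocessConfig | None = None,
    *,
    sizes: Sequence[int] = (20, 75, 150, 300, 500),
    reps_per_size: int = 10_000,
    seed: int = 0,
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Association between random-geneset size and first-test significance.

    For each size, ``reps_per_size`` random genesets run through the first
    test; valid p1 values are returned with a -log10 column.  Sizes larger
    than the universe are skipped with a warning (too small a gene pool).
    Returns (table of size/p1 rows, per-size discard counts).
    """
    prep = _as_prepared(m, pm, clin, cfg, evenness_min_fraction)
    pool = sorted(universe)
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, float]] = []
    discards: dict[int, int] = {}
    for size in sizes:
        if size > len(pool):
            logger.warning("size %d exceeds universe of %d genes; skipped", size, len(pool))
            continue
        discards[size] = 0
        for _ in range(reps_per_size):
            idx = rng.choice(len(pool), size=size, replace=False)
            res = first_test_prepared(prep, "random", [pool[i] for i in idx])
            if res.ok:
                rows.append((size, res.p1))
            else:
                discards[size] += 1
    table = pd.DataFrame(rows, columns=["size", "p1"])
    table["neg_log10_p1"] = -np.log10(np.maximum(table["p1"].to_numpy(), np.finfo(float).tiny))
    return table, discards


def stability_analysis(
    universe: Iterable[str],
    sampler: SizeSampler,
    m: ExpressionMatrix | PreparedDataset,
    pm: ProbeMap | None = None,
    clin: ClinicalTable | None = None,
    cfg: PreprocessConfig | None = None,
    *,
    B_list: Sequence[int] = (1_000, 10_000, 50_000, 100_000, 200_000),
    reference_B: int | None = None,
    genesets: Sequence[GeneSet] = (),
    seed: int = 0,
    pipeline_cfg: PipelineConfig | None = None,
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION,
) -> pd.DataFrame:
    """How many random genesets are enough for stable p2 values?

    One null of max(B_list) draws is built from a single seeded stream;
    each smaller B reuses its first B draws (nested prefixes), so the
    comparison isolates the effect of B.  For every tested geneset, p2 is
    computed under each B and compared against the reference via Pearson r
    of -log10 p2 (p2 clamped to 1/(2B) for the log) and max |delta p2|.
    """
    B_list = sorted(set(int(b) for b in B_list))
    if reference_B is None:
        reference_B = B_list[-1]
    if reference_B not in B_list:
        raise ValueError("reference_B must be in B_list")
    if not genesets:
        raise ValueError("stability analysis needs tested genesets")
    pcfg = pipeline_cfg or PipelineConfig(B=B_list[-1], seed=seed)
    prep = _as_prepared(m, pm, clin, cfg, evenness_min_fraction)
    full = build_empirical_null(
        universe, sampler, prep, B=B_list[-1], seed=seed,
        evenness_min_fraction=evenness_min_fraction,
    )
    p1s = []
    for gs in genesets:
        res = first_test_prepared(prep, gs.name, gs.genes)
        if res.ok:
            p1s.append(res.p1)
    if not p1s:
        raise ValueError("all tested genesets were discarded")
    p1s = np.asarray(p1s)
    p2_by_B: dict[int, np.ndarray] = {}
    for B in B_list:
        nb = full.prefix(B)
        p2_by_B[B] = np.array([empirical_p2(p, nb, pcfg.pseudocount) for p in p1s])
    ref = p2_by_B[reference_B]
    rows = []
    for B in B_list:
        cur = p2_by_B[B]
        lo_cur = -np.log10(np.maximum(cur, 1 / (2 * B)))
        lo_ref = -np.log10(np.maximum(ref, 1 / (2 * reference_B)))
        if np.std(lo_cur) > 0 and np.std(lo_ref) > 0:
            r = float(np.corrcoef(lo_cur, lo_ref)[0, 1])
        else:
            r = 1.0 if np.allclose(cur, ref) else float("nan")
        rows.append(
            {
                "B": B,
                "reference_B": reference_B,
                "pearson_r_neglog10_p2": r,
                "max_abs_delta_p2": float(np.max(np.abs(cur - ref))),
                "n_genesets": int(p1s.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization


def save_empirical_null(
    null: EmpiricalNull, base_path: str | Path, extra_meta: dict | None = None
) -> None:
    """Write ``<base>.tsv`` (p1, size) plus a ``<base>.json`` sidecar.

    ``extra_meta`` entries (e.g. a dataset content hash) are merged into
    the sidecar so cached nulls can be validated before reuse.
    """
    base = Path(base_path)
    pd.DataFrame({"p1": null.null_p1, "size": null.sizes}).to_csv(
        base.with_suffix(".tsv"), sep="\t", index=False
    )
    meta = {
        "collection_tag": null.collection_tag,
        "endpoint_tag": null.endpoint_tag,
        "B": null.B,
        "seed": null.seed,
        "n_discarded": null.n_discarded,
        "size_mode": null.size_mode,
    }
    if extra_meta:
        meta.update(extra_meta)
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_empirical_null(base_path: str | Path) -> EmpiricalNull:
    base = Path(base_path)
    tab = pd.read_csv(base.with_suffix(".tsv"), sep="\t", float_precision="round_trip")
    meta = json.loads(base.with_suffix(".json").read_text())
    return EmpiricalNull(
        collection_tag=meta["collection_tag"],
        endpoint_tag=meta["endpoint_tag"],
        null_p1=tab["p1"].to_numpy(),
        sizes=tab["size"].to_numpy(),
        n_discarded=int(meta["n_discarded"]),
        seed=int(meta["seed"]),
        size_mode=meta["size_mode"],
    )


# ---------------------------------------------------------------------------
# closed-form arithmetic of the competitive test


def expected_outperformance(p1: float, n: int) -> float:
    """Expected number of n uniform random genesets a geneset with p-value
    ``p1`` outperforms: (1 - p1) * n."""
    return (1.0 - p1) * n


def expected_exceedance(p1: float, n: int) -> float:
    """Expected number of n uniform random genesets at least as significant
    as a geneset with p-value ``p1``: p1 * n."""
    return p1 * n


def expected_false_positives(n_tests: int, alpha: float) -> float:
    """Expected significant calls among n independent true-null tests."""
    return n_tests * alpha
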