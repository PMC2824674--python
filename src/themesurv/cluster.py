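"""First-hypothesis test: cluster patients on a geneset, compare survival.

For a geneset's probes, samples are clustered by average-linkage (UPGMA)
hierarchical clustering on the correlation distance d_xy = 1 - rho_xy,
where rho_xy is the Pearson correlation of two samples' expression
profiles over the geneset probes (pairwise-complete in the presence of
missing values).  The dendrogram's root split defines two patient groups,
groups smaller than a minimum fraction of samples are discarded, and a
two-sample log-rank test yields the first-test p-value p1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from .formats import ClinicalTable, ExpressionMatrix, GeneSet, ProbeMap
from .preprocess import GenesetExclusion, PreprocessConfig, map_geneset_to_probes

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "FirstTestResult",
    "correlation_distance",
    "pairwise_correlation_distance",
    "average_linkage_two_way_split",
    "logrank_test",
    "first_test",
    "PreparedDataset",
    "prepare_dataset",
]

#: minimum number of complete probe pairs for a sample-pair correlation
MIN_COMPLETE_PAIRS = 3

#: default evenness rule: discard when the smaller cluster holds < 10% of samples
DEFAULT_EVENNESS_MIN_FRACTION = 0.10


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, equal_nan=False):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if np.isnan(self.d).any():
            raise ValueError("distance matrix contains missing values")
        if self.d.min() < -1e-9 or self.d.max() > 2 + 1e-9:
            raise ValueError("distances outside [0, 2]")


@dataclass
class FirstTestResult:
    geneset_name: str
    n_genes: int
    n_probes: int | None = None
    labels: np.ndarray | None = None
    cluster_sizes: tuple[int, int] | None = None
    logrank_statistic: float | None = None
    p1: float | None = None
    status: str = "ok"
    discard_reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def pairwise_correlation_distance(
    values: np.ndarray, min_pairs: int = MIN_COMPLETE_PAIRS
) -> np.ndarray:
    """Pairwise-complete correlation distance between columns of ``values``.

    ``values`` is a probes x samples float array with NaN for missing.  For
    each sample pair, Pearson's rho is computed over the probes observed in
    both; d = 1 - rho.  Entries are NaN where fewer than ``min_pairs``
    complete pairs exist or either sample has zero variance over them.
    """
    X = np.asarray(values, dtype=float)
    M = np.isfinite(X)
    Z = np.where(M, X, 0.0)
    Mf = M.astype(float)
    # sums restricted to rows observed in BOTH columns of each pair
    N = Mf.T @ Mf
    Sx = Z.T @ Mf          # Sx[i, j] = sum of x_i over rows where both i, j present
    Sxy = Z.T @ Z
    Sxx = (Z * Z).T @ Mf
    cov = N * Sxy - Sx * Sx.T
    varx = N * Sxx - Sx**2
    vary = varx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(varx * vary)
        rho = cov / denom
    bad = (N < min_pairs) | (varx <= 0) | (vary <= 0)
    rho[bad] = np.nan
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    # numerical guard: |rho| can exceed 1 by float error
    np.clip(d, 0.0, 2.0, out=d)
    return 0.5 * (d + d.T)


def correlation_distance(
    submatrix: ExpressionMatrix, min_pairs: int = MIN_COMPLETE_PAIRS
) -> DistanceMatrix | GenesetExclusion:
    """Correlation distance over a geneset's probes, or an exclusion.

    A geneset whose data would leave any sample pair without a defined
    correlation (too many missing values, or zero variance) cannot be
    clustered and is excluded as ``undefined_distance``.
    """
    if submatrix.n_samples < 2 or submatrix.n_probes < 2:
        return GenesetExclusion("", "undefined_distance", 0, submatrix.n_probes)
    d = pairwise_correlation_distance(submatrix.values, min_pairs=min_pairs)
    if np.isnan(d).any():
        return GenesetExclusion("", "undefined_distance", 0, submatrix.n_probes)
    return DistanceMatrix(sample_ids=submatrix.sample_ids, d=d)


def _root_split_labels(Z: np.ndarray, n: int) -> np.ndarray:
    """Labels in {1, 2} from the two subtrees of the dendrogram root.

    Label 1 is the subtree containing the first sample (input order), a
    determinism convention.
    """
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k in range(Z.shape[0] - 1):
        x, y = int(Z[k, 0]), int(Z[k, 1])
        members[n + k] = members.pop(x) + members.pop(y)
    side_a, side_b = members[a], members[b]
    labels = np.empty(n, dtype=int)
    if 0 in side_a:
        labels[side_a], labels[side_b] = 1, 2
    else:
        labels[side_a], labels[side_b] = 2, 1
    return labels


def average_linkage_two_way_split(dm: DistanceMatrix | np.ndarray) -> np.ndarray:
    """UPGMA clustering; cut at the first bifurcation (the root merge).

    Returns per-sample labels in {1, 2}; label 1 marks the root subtree
    containing the first sample.
    """
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to split")
    if n == 2:
        return np.array([1, 2])
    Z = linkage(squareform(d, checks=False), method="average")
    return _root_split_labels(Z, n)


def logrank_test(
    labels: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """Two-sample log-rank test.

    At each distinct event time the observed minus expected event count in
    group 1 is accumulated with its hypergeometric variance; the statistic
    (sum(O-E))^2 / sum(V) is referred to a chi-square with 1 df.

    ``labels`` must contain both groups; with no events at all the
    statistic is 0 and p = 1 (with a warning).
    """
    labels = np.asarray(labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("log-rank test needs exactly two non-empty groups")
    g1 = labels == uniq[0]
    if events.sum() == 0:
        logger.warning("no events in either group; log-rank statistic is 0")
        return 0.0, 1.0
    event_times = np.unique(times[events == 1])
    at_risk = event_times[:, None] <= times[None, :]          # T x n
    dying = (times[None, :] == event_times[:, None]) & (events[None, :] == 1)
    n = at_risk.sum(axis=1).astype(float)
    n1 = (at_risk & g1[None, :]).sum(axis=1).astype(float)
    d = dying.sum(axis=1).astype(float)
    d1 = (dying & g1[None, :]).sum(axis=1).astype(float)
    expected = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    var = np.where(n > 1, var, 0.0)
    O_minus_E = float((d1 - expected).sum())
    V = float(np.nansum(var))
    if V <= 0:
        return 0.0, 1.0
    stat = O_minus_E**2 / V
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PreparedDataset:
    """Expression + clinical data pre-aligned for repeated first tests.

    Building this once and reusing it across many genesets (notably the
    100,000-draw empirical null) avoids re-aligning pandas objects in the
    inner loop.
    """

    values: np.ndarray                      # probes x samples, NaN = missing
    probe_row: dict[str, int]
    gene_rows: dict[str, np.ndarray]        # gene -> sorted row indices in matrix
    sample_ids: list[str]
    clin_mask: np.ndarray                   # samples with clinical data
    times: np.ndarray                       # aligned to samples[clin_mask]
    events: np.ndarray
    cfg: PreprocessConfig
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION


def prepare_dataset(
    m: ExpressionMatrix,
    pm: ProbeMap,
    clin: ClinicalTable,
    cfg: PreprocessConfig,
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION,
) -> PreparedDataset:
    """Index the matrix, probe map, and clinical table for fast first tests.

    ``m`` must already be preprocessed (unique probes).  Clustering uses all
    matrix samples; survival analysis uses the subset with clinical data.
    """
    if m.has_duplicate_probes():
        raise ValueError("matrix has replicate probes; run preprocess_matrix first")
    probe_row = {p: i for i, p in enumerate(m.probe_ids)}
    gene_rows: dict[str, np.ndarray] = {}
    for gene, probes in pm.mapping.items():
        rows = sorted(probe_row[p] for p in probes if p in probe_row)
        if rows:
            gene_rows[gene] = np.asarray(rows, dtype=np.intp)
    sample_ids = m.sample_ids
    clin_index = {s: i for i, s in enumerate(clin.sample_ids)}
    clin_mask = np.array([s in clin_index for s in sample_ids])
    if not clin_mask.any():
        raise ValueError("no overlap between matrix samples and clinical table")
    order = [clin_index[s] for s in sample_ids if s in clin_index]
    return PreparedDataset(
        values=m.values,
        probe_row=probe_row,
        gene_rows=gene_rows,
        sample_ids=sample_ids,
        clin_mask=clin_mask,
        times=clin.times[order],
        events=clin.events[order],
        cfg=cfg,
        evenness_min_fraction=evenness_min_fraction,
    )


def _gene_set_rows(prep: PreparedDataset, genes) -> np.ndarray:
    parts = [prep.gene_rows[g] for g in genes if g in prep.gene_rows]
    if not parts:
        return np.empty(0, dtype=np.intp)
    return np.unique(np.concatenate(parts))


def first_test_prepared(
    prep: PreparedDataset, name: str, genes, collection: str = ""
) -> FirstTestResult:
    """Run the first-hypothesis test on a prepared dataset (fast path)."""
    cfg = prep.cfg
    n_genes = len(genes)
    if n_genes < cfg.min_genes:
        return FirstTestResult(name, n_genes, status="discarded", discard_reason="too_few_genes")
    if n_genes > cfg.max_genes:
        return FirstTestResult(name, n_genes, status="discarded", discard_reason="too_many_genes")
    rows = _gene_set_rows(prep, genes)
    n_probes = len(rows)
    if n_probes < cfg.min_probes:
        return FirstTestResult(name, n_genes, n_probes, status="discarded", discard_reason="too_few_probes")
    if n_probes > cfg.max_probes:
        return FirstTestResult(name, n_genes, n_probes, status="discarded", discard_reason="too_many_probes")
    sub = prep.values[rows]
    d = pairwise_correlation_distance(sub)
    if np.isnan(d).any():
        return FirstTestResult(name, n_genes, n_probes, status="discarded", discard_reason="undefined_distance")
    labels = average_linkage_two_way_split(d)
    sizes = (int((labels == 1).sum()), int((labels == 2).sum()))
    if min(sizes) / labels.size < prep.evenness_min_fraction:
        return FirstTestResult(
            name, n_genes, n_probes, labels=labels, cluster_sizes=sizes,
            status="discarded", discard_reason="uneven_clusters",
        )
    lab_clin = labels[prep.clin_mask]
    stat, p1 = logrank_test(lab_clin, prep.times, prep.events)
    return FirstTestResult(
        name, n_genes, n_probes, labels=labels, cluster_sizes=sizes,
        logrank_statistic=stat, p1=p1,
    )


def first_test(
    g: GeneSet,
    m: ExpressionMatrix,
    pm: ProbeMap,
    clin: ClinicalTable,
    cfg: PreprocessConfig,
    evenness_min_fraction: float = DEFAULT_EVENNESS_MIN_FRACTION,
) -> FirstTestResult:
    """Map a geneset to probes, cluster samples, and log-rank test survival.

    Returns an ok result carrying the statistic and p1, or a discarded
    result with the first applicable reason (size filters, undefined
    distance, uneven clusters).  Deterministic: identical inputs give
    identical results.
    """
    prep = prepare_dataset(m, pm, clin, cfg, evenness_min_fraction)
    return first_test_prepared(prep, g.name, g.genes, g.collection)
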