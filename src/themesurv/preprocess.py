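"""Dataset preprocessing for cDNA-style log-ratio matrices.

The pipeline mirrors the standard preparation of two-channel microarray
data for geneset survival screens: recode categorical vital status to a
binary event, drop probes measured in too few samples, collapse replicate
spots of the same clone to one averaged row, median-centre each probe, and
map genesets onto matrix probes with size filters.

Order of operations is fixed: completeness filter -> replicate averaging ->
median centering, so that centering acts on the final probe rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix, GeneSet, ProbeMap

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "GenesetExclusion",
    "recode_event_status",
    "filter_probes_by_completeness",
    "average_replicate_probes",
    "median_center_rows",
    "preprocess_matrix",
    "map_geneset_to_probes",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Probe completeness and geneset size thresholds.

    ``min_complete_fraction`` — minimum fraction of samples a probe must be
    measured in (0.60 suits multi-batch arrays with partially disjoint probe
    sets; 0.80 suits single-design arrays).  Size filters are strict on both
    ends: genesets with < ``min_genes`` or > ``max_genes`` members, or
    mapping to < ``min_probes`` or > ``max_probes`` matrix probes, are
    excluded as of limited biological utility.
    """

    min_complete_fraction: float = 0.60
    min_genes: int = 5
    max_genes: int = 1000
    min_probes: int = 5
    max_probes: int = 2500

    def __post_init__(self) -> None:
        if not (0 < self.min_complete_fraction <= 1):
            raise ValueError("min_complete_fraction must be in (0, 1]")
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if self.min_probes > self.max_probes:
            raise ValueError("min_probes > max_probes")


@dataclass(frozen=True)
class GenesetExclusion:
    """A geneset filtered out before testing; carried as a value, not raised."""

    geneset_name: str
    reason: str
    n_genes: int
    n_probes: int | None = None


def recode_event_status(
    raw_status: Sequence,
    event_codes: Iterable,
    known_codes: Iterable | None = None,
) -> np.ndarray:
    """Collapse categorical vital-status codes to a binary event indicator.

    Each raw code becomes 1 iff it is in ``event_codes`` (e.g. dead of
    disease), else 0 (no evidence of disease, alive with disease, dead of
    other causes, ...).  When ``known_codes`` is given, any code outside
    ``event_codes | known_codes`` is rejected rather than silently mapped
    to 0.
    """
    event_codes = set(event_codes)
    if known_codes is not None:
        known = set(known_codes) | event_codes
        unknown = sorted({str(c) for c in raw_status if c not in known})
        if unknown:
            raise ValueError(f"unknown status codes: {unknown}")
    return np.fromiter(
        (1 if code in event_codes else 0 for code in raw_status),
        dtype=int,
        count=len(raw_status),
    )


def filter_probes_by_completeness(
    m: ExpressionMatrix, min_complete_fraction: float
) -> ExpressionMatrix:
    """Keep probes measured in at least the given fraction of samples (>=)."""
    if not (0 < min_complete_fraction <= 1):
        raise ValueError("min_complete_fraction must be in (0, 1]")
    frac = m.data.notna().sum(axis=1) / m.n_samples
    keep = frac >= min_complete_fraction
    return ExpressionMatrix(m.data.loc[keep.to_numpy()])


def average_replicate_probes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse rows sharing a probe id to their per-sample mean.

    The mean is taken over non-missing replicate values; a cell is missing
    in the output only when every replicate is missing there.  Row order
    follows first appearance of each probe id.
    """
    if not m.has_duplicate_probes():
        return ExpressionMatrix(m.data.copy())
    order = m.data.index.drop_duplicates()
    collapsed = m.data.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed.loc[order])


def median_center_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe's non-missing median from its row.

    Corrects the per-probe systematic bias of unequal reference-channel
    amounts.  All-missing rows are left unchanged with a warning.
    """
    values = m.values
    medians = np.full(values.shape[0], np.nan)
    has_data = np.isfinite(values).any(axis=1)
    if has_data.any():
        medians[has_data] = np.nanmedian(values[has_data], axis=1)
    all_missing = np.isnan(medians)
    if all_missing.any():
        logger.warning("%d all-missing probe rows left uncentered", int(all_missing.sum()))
        medians = np.where(all_missing, 0.0, medians)
    centered = values - medians[:, None]
    return ExpressionMatrix(pd.DataFrame(centered, index=m.data.index, columns=m.data.columns))


def preprocess_matrix(m: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Completeness filter -> replicate averaging -> median centering."""
    m = filter_probes_by_completeness(m, cfg.min_complete_fraction)
    m = average_replicate_probes(m)
    return median_center_rows(m)


def map_geneset_to_probes(
    g: GeneSet,
    pm: ProbeMap,
    m: ExpressionMatrix,
    cfg: PreprocessConfig,
) -> list[str] | GenesetExclusion:
    """Resolve a geneset to matrix probe ids, or exclude it by size.

    Probes are the union of the member genes' mapped probes intersected
    with the matrix, deduplicated, in matrix row order.  Exclusions (gene
    count outside [min_genes, max_genes], probe count outside
    [min_probes, max_probes]) are returned as values.
    """
    n_genes = len(g.genes)
    if n_genes < cfg.min_genes:
        return GenesetExclusion(g.name, "too_few_genes", n_genes)
    if n_genes > cfg.max_genes:
        return GenesetExclusion(g.name, "too_many_genes", n_genes)
    mapped = pm.probes_for(g.genes)
    probe_order = m.data.index
    probes = [p for p in probe_order.drop_duplicates() if p in mapped]
    n_probes = len(probes)
    if n_probes < cfg.min_probes:
        return GenesetExclusion(g.name, "too_few_probes", n_genes, n_probes)
    if n_probes > cfg.max_probes:
        return GenesetExclusion(g.name, "too_many_probes", n_genes, n_probes)
    return probes
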