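"""Tabular and GMT input/output for the geneset survival pipeline.

All on-disk formats are plain text: tab-separated tables for expression,
clinical and probe-map data, standard GMT for geneset collections, and a
tab-separated results table.  Missing values are written as ``NA``; both
``NA`` and the empty string are accepted on read.

This module does no statistics — only parsing, validation and round-trip
serialisation of the domain types the rest of the package computes on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSet",
    "GeneSetCollection",
    "ProbeMap",
    "ResultRecord",
    "DISCARD_REASONS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "write_probe_map",
    "write_results",
    "read_results",
]

DISCARD_REASONS = (
    "too_few_genes",
    "too_many_genes",
    "too_few_probes",
    "too_many_probes",
    "undefined_distance",
    "uneven_clusters",
)


@dataclass
class ExpressionMatrix:
    """Probe x sample grid of log2 expression ratios.

    ``data`` is a float DataFrame whose index holds probe identifiers and
    whose columns hold sample identifiers; NaN marks a missing measurement.
    Sample identifiers must be unique.  Probe identifiers may repeat before
    replicate averaging (the same spotted clone printed more than once).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.data.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if np.isinf(values).any():
            raise ValueError("expression matrix contains infinite values")

    @property
    def probe_ids(self) -> list[str]:
        return [str(p) for p in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def has_duplicate_probes(self) -> bool:
        return bool(self.data.index.duplicated().any())


@dataclass
class ClinicalTable:
    """Per-sample survival time and binary event status for one endpoint.

    ``data`` is indexed by sample identifier with float columns ``time``
    (>= 0, in whatever unit the study used) and ``event`` (1 = event
    observed, 0 = censored).
    """

    endpoint: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in clinical table")
        if (self.data["time"] < 0).any():
            bad = self.data.index[self.data["time"] < 0][0]
            raise ValueError(f"negative survival time for sample {bad!r}")
        events = set(self.data["event"].unique())
        if not events <= {0, 1}:
            raise ValueError(
                f"event status must be 0/1, found {sorted(events - {0, 1})}; "
                "recode categorical status first (see preprocess.recode_event_status)"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


@dataclass(frozen=True)
class GeneSet:
    name: str
    collection: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"geneset {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named genesets plus the collection's gene universe.

    The universe defaults to the union of all member genes; passing an
    explicit (larger) universe models annotation files in which some
    annotated genes belong to no retained set.
    """

    name: str
    sets: list[GeneSet]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        members: set[str] = set()
        for gs in self.sets:
            members |= gs.genes
        if not self.universe:
            self.universe = frozenset(members)
        elif not members <= self.universe:
            missing = sorted(members - self.universe)[:5]
            raise ValueError(f"geneset members outside universe, e.g. {missing}")
        names = [gs.name for gs in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate geneset names in collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class ProbeMap:
    """Many-to-many gene -> probe mapping (e.g. Entrez gene -> IMAGE clones)."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, probes in self.mapping.items():
            if not probes:
                raise ValueError(f"gene {gene!r} maps to an empty probe set")

    def probes_for(self, genes: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for g in genes:
            out |= self.mapping.get(g, frozenset())
        return out

    def __len__(self) -> int:
        return len(self.mapping)


RESULT_COLUMNS = [
    "geneset_name",
    "n_genes",
    "n_probes",
    "cluster_size_1",
    "cluster_size_2",
    "p1",
    "fdr1",
    "p2",
    "fdr2",
    "status",
    "discard_reason",
]


@dataclass
class ResultRecord:
    """One geneset's outcome across both hypothesis tests."""

    geneset_name: str
    n_genes: int
    n_probes: int | None = None
    cluster_sizes: tuple[int, int] | None = None
    p1: float | None = None
    fdr1: float | None = None
    p2: float | None = None
    fdr2: float | None = None
    status: str = "ok"
    discard_reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("ok", "discarded"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "discarded":
            if self.discard_reason not in DISCARD_REASONS:
                raise ValueError(
                    f"discarded record needs a valid reason, got {self.discard_reason!r}"
                )
            if self.p1 is not None or self.p2 is not None:
                raise ValueError("discarded record must not carry p-values")
        elif self.discard_reason:
            raise ValueError("ok record must not carry a discard reason")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probe x sample TSV of log ratios.

    First column: probe ids (duplicates allowed — replicate spots); header
    row: sample ids (must be unique).  Empty cells and ``NA`` are missing.
    Any other non-numeric cell is a hard error naming its row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample identifiers {dups}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    df.columns = header
    raw = df.to_numpy()
    stripped = np.char.strip(raw.astype(str))
    missing = (stripped == "") | (stripped == NA_TOKEN)
    numeric = np.asarray(
        pd.to_numeric(stripped.ravel(), errors="coerce"), dtype=float
    ).reshape(raw.shape)
    bad = np.isnan(numeric) & ~missing
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric value {stripped[i, j]!r} at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    numeric[missing] = np.nan
    return ExpressionMatrix(pd.DataFrame(numeric, index=df.index.astype(str), columns=list(df.columns)))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="probe_id")


def read_clinical_table(
    path: str | Path,
    endpoint: str,
    time_col: str = "time",
    event_col: str = "event",
    sample_col: str | None = None,
) -> ClinicalTable:
    """Read a clinical TSV; rows with missing time or event are dropped.

    ``sample_col`` defaults to the first column.  Event values must already
    be binary; categorical codes should go through
    :func:`themesurv.preprocess.recode_event_status` first.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str} if sample_col is None else None)
    if sample_col is None:
        sample_col = df.columns[0]
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df[[sample_col, time_col, event_col]].copy()
    df.columns = ["sample_id", "time", "event"]
    n_before = len(df)
    df = df.dropna(subset=["time", "event"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d samples with missing time/event", path, n_dropped)
    df["sample_id"] = df["sample_id"].astype(str)
    df["time"] = df["time"].astype(float)
    events = df["event"].astype(float)
    if not set(events.unique()) <= {0.0, 1.0}:
        bad = sorted(set(events.unique()) - {0.0, 1.0})
        raise ValueError(
            f"{path}: event column contains non-binary values {bad}; "
            "recode with preprocess.recode_event_status"
        )
    df["event"] = events.astype(int)
    df = df.set_index("sample_id")
    return ClinicalTable(endpoint=endpoint, data=df)


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="sample_id")


def read_gmt(path: str | Path, collection_name: str) -> GeneSetCollection:
    """Read a GMT file: one geneset per line (name, description, members...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate geneset name {name!r}")
        seen.add(name)
        members = [g for g in fields[2:] if g]
        unique = frozenset(members)
        if len(unique) < len(members):
            logger.warning("%s:%d: duplicate genes within geneset %s deduplicated", path, lineno, name)
        sets.append(GeneSet(name=name, collection=collection_name, genes=unique))
    return GeneSetCollection(name=collection_name, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection.sets:
            fh.write("\t".join([gs.name, gs.collection, *sorted(gs.genes)]) + "\n")


def read_probe_map(path: str | Path) -> ProbeMap:
    """Read a two-column gene_id TAB probe_id table; repeated genes accumulate."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed probe-map line {line!r}")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return ProbeMap({g: frozenset(p) for g, p in mapping.items()})


def write_probe_map(pm: ProbeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(pm.mapping):
            for probe in sorted(pm.mapping[gene]):
                fh.write(f"{gene}\t{probe}\n")


def _fmt(x) -> str:
    if x is None:
        return NA_TOKEN
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_results(results: Sequence[ResultRecord], path: str | Path) -> None:
    """Write one header row plus one TSV row per record; missing cells as NA."""
    if not results:
        raise ValueError("no results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            cs = r.cluster_sizes or (None, None)
            row = [
                r.geneset_name,
                str(r.n_genes),
                _fmt(r.n_probes),
                _fmt(cs[0]),
                _fmt(cs[1]),
                _fmt(r.p1),
                _fmt(r.fdr1),
                _fmt(r.p2),
                _fmt(r.fdr2),
                r.status,
                r.discard_reason or NA_TOKEN,
            ]
            fh.write("\t".join(row) + "\n")


def read_results(path: str | Path) -> list[ResultRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"geneset_name": str},
        na_values=[NA_TOKEN], keep_default_na=False, float_precision="round_trip",
    )
    out: list[ResultRecord] = []

    def _opt_float(v):
        return None if pd.isna(v) else float(v)

    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    for _, row in df.iterrows():
        c1, c2 = _opt_int(row["cluster_size_1"]), _opt_int(row["cluster_size_2"])
        out.append(
            ResultRecord(
                geneset_name=row["geneset_name"],
                n_genes=int(row["n_genes"]),
                n_probes=_opt_int(row["n_probes"]),
                cluster_sizes=(c1, c2) if c1 is not None else None,
                p1=_opt_float(row["p1"]),
                fdr1=_opt_float(row["fdr1"]),
                p2=_opt_float(row["p2"]),
                fdr2=_opt_float(row["fdr2"]),
                status=row["status"],
                discard_reason="" if pd.isna(row["discard_reason"]) else str(row["discard_reason"]),
            )
        )
    return out
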