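"""Readers, writers and containers for the pipeline's file formats.

Formats handled here: wide TSV/CSV protein quantification tables (one
abundance column per condition), GMT gene-set collections, long-format
grouped measurement tables, tab-separated results tables and a YAML run
configuration.  Parsers reject invariant violations with located errors;
they never silently drop rows — exclusions happen downstream and are
logged there.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "ConfigError",
    "QuantTable",
    "GeneSet",
    "GeneSetCollection",
    "GroupedData",
    "RunConfig",
    "read_quant_table",
    "write_quant_table",
    "read_gmt",
    "write_gmt",
    "read_grouped_table",
    "write_grouped_table",
    "write_results",
    "load_run_config",
]

#: tokens that denote a missing abundance (case-insensitive), chosen to
#: cover common text exports including Proteome Discoverer dialects
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: printf-style format for floating-point results columns; 12 significant
#: digits so that write → read round-trips are lossless at that precision
FLOAT_FMT = "%.12g"
PVALUE_FMT = "%.12e"


class ParseError(ValueError):
    """A malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(ValueError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# quantification tables


@dataclass
class QuantTable:
    """Protein abundances per condition.

    ``data`` is indexed by protein id with one float column per condition;
    NaN encodes a missing (unquantified) abundance.  Zero is a valid stored
    abundance — the zero-vs-missing distinction is preserved here and only
    collapsed downstream when ratios are formed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ParseError(f"duplicate protein id {dup!r}")
        if self.data.shape[1] < 2:
            raise ParseError("need at least 2 condition columns")
        values = self.data.to_numpy(dtype=float)
        present = ~np.isnan(values)
        if not np.all(np.isfinite(values[present])):
            raise ParseError("abundances must be finite")
        if np.any(values[present] < 0):
            raise ParseError("abundances must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def _open_source(source: str | os.PathLike | TextIO) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return open(path, "r", newline=""), True


def read_quant_table(source: str | os.PathLike | TextIO,
                     dialect: str = "tsv") -> QuantTable:
    """Parse a wide quantification table.

    The first row is the header; the first column holds protein ids and
    every remaining column is one condition.  Cells that are empty, ``NA``
    or ``NaN`` (case-insensitive) become missing values; any other
    non-numeric cell is a :class:`ParseError` with its line number.
    """
    if dialect not in ("tsv", "csv"):
        raise ConfigError("dialect", f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    stream, owned = _open_source(source)
    try:
        reader = csv.reader(stream, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty input: missing header row", line=1)
        if len(header) < 3:
            raise ParseError(
                f"need an id column plus >= 2 condition columns, got {len(header)}",
                line=1)
        conditions = [c.strip() for c in header[1:]]
        ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(row)}", line=lineno)
            pid = row[0].strip()
            if pid in seen:
                raise ParseError(f"duplicate protein id {pid!r}", line=lineno)
            seen.add(pid)
            parsed: list[float] = []
            for cond, cell in zip(conditions, row[1:]):
                token = cell.strip()
                if token.lower() in MISSING_TOKENS:
                    parsed.append(math.nan)
                    continue
                try:
                    value = float(token)
                except ValueError:
                    raise ParseError(
                        f"non-numeric abundance {token!r} for protein "
                        f"{pid!r}, condition {cond!r}", line=lineno) from None
                parsed.append(value)
            ids.append(pid)
            rows.append(parsed)
        data = pd.DataFrame(rows, index=pd.Index(ids, name="protein_id"),
                            columns=conditions, dtype=float)
        return QuantTable(data)
    finally:
        if owned:
            stream.close()


def write_quant_table(table: QuantTable, path: str | os.PathLike) -> None:
    """Write a quantification table as TSV; missing cells become empty."""
    table.data.to_csv(path, sep="\t", na_rep="", float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    category_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ParseError(f"category {self.category_id!r} has no members")


@dataclass
class GeneSetCollection:
    """An ordered collection of named identifier sets (GO stand-in)."""

    categories: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [c.category_id for c in self.categories]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ParseError(f"duplicate category id {dup!r}")

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def get(self, category_id: str) -> GeneSet:
        for cat in self.categories:
            if cat.category_id == category_id:
                return cat
        raise KeyError(category_id)


def _dedup(items: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return tuple(out)


def read_gmt(source: str | os.PathLike | TextIO) -> GeneSetCollection:
    """Parse the standard GMT dialect: ``id<TAB>description<TAB>member...``.

    Members are deduplicated preserving first occurrence; blank lines are
    skipped; a line with fewer than three fields is a located error.
    """
    stream, owned = _open_source(source)
    try:
        categories: list[GeneSet] = []
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line needs >= 3 tab-separated fields, got {len(fields)}",
                    line=lineno)
            members = _dedup(f.strip() for f in fields[2:] if f.strip())
            if not members:
                raise ParseError(
                    f"category {fields[0]!r} has no non-empty members", line=lineno)
            categories.append(GeneSet(fields[0], fields[1], members))
        return GeneSetCollection(categories)
    finally:
        if owned:
            stream.close()


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for cat in collection:
            fh.write("\t".join([cat.category_id, cat.description, *cat.members]))
            fh.write("\n")


# ---------------------------------------------------------------------------
# grouped measurements


@dataclass
class GroupedData:
    """Labeled numeric groups for the normality-gated comparisons."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ParseError(f"group {label!r} must be a non-empty 1-d vector")
            if not np.all(np.isfinite(arr)):
                raise ParseError(f"group {label!r} contains non-finite values")
            clean[label] = arr
        self.groups = clean

    @property
    def labels(self) -> list[str]:
        return list(self.groups.keys())

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.groups[label]

    def items(self):
        return self.groups.items()


def read_grouped_table(source: str | os.PathLike | TextIO) -> GroupedData:
    """Read long-format measurements: a TSV with ``group`` and ``value`` columns."""
    stream, owned = _open_source(source)
    try:
        df = pd.read_csv(stream, sep="\t")
    finally:
        if owned:
            stream.close()
    missing = {"group", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"grouped table missing column(s): {sorted(missing)}")
    groups = {str(label): sub["value"].to_numpy(dtype=float)
              for label, sub in df.groupby("group", sort=False)}
    return GroupedData(groups)


def write_grouped_table(data: GroupedData, path: str | os.PathLike) -> None:
    records = [(label, v) for label, values in data.items() for v in values]
    pd.DataFrame(records, columns=["group", "value"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# results writing


def _format_results(df: pd.DataFrame, pvalue_cols: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        fmt = PVALUE_FMT if col in pvalue_cols else FLOAT_FMT
        out[col] = [fmt % v if np.isfinite(v) else "" for v in out[col]]
    return out


def write_results(scores: pd.DataFrame | None,
                  enrichment: pd.DataFrame | None,
                  sink: str | os.PathLike) -> dict[str, int]:
    """Write the annotated protein scores and the enrichment table.

    Proteins are ordered by ascending significance-A p then id; categories
    by ascending raw p then id.  Returns a manifest mapping each written
    file name to its row count.  Column order is fixed so two runs on the
    same inputs are byte-identical.
    """
    sink = Path(sink)
    sink.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    if scores is not None:
        ordered = scores.sort_values(["p", "protein_id"], kind="mergesort")
        path = sink / "differential_proteins.tsv"
        _format_results(ordered, ["p", "q_bh"]).to_csv(path, sep="\t", index=False)
        manifest[path.name] = len(ordered)
    if enrichment is not None:
        ordered = enrichment.sort_values(["p_raw", "category_id"], kind="mergesort")
        path = sink / "enrichment.tsv"
        _format_results(ordered, ["p_raw", "p_adj"]).to_csv(path, sep="\t", index=False)
        manifest[path.name] = len(ordered)
    return manifest


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration for an end-to-end differential-abundance run.

    When ``quant_table`` is None the pipeline simulates its input; when
    ``gene_sets`` is None a collection with one planted category (the true
    differential set) is simulated alongside.
    """

    outdir: str
    quant_table: str | None = None
    gene_sets: str | None = None
    treated: str = "treated"
    control: str = "control"
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_category_size: int = 5
    seed: int = 0
    simulation: Mapping | None = None

    def __post_init__(self) -> None:
        if not self.outdir:
            raise ConfigError("outdir", "output directory is required")
        if not (self.fc_threshold >= 1):
            raise ConfigError("fc_threshold", f"must be >= 1, got {self.fc_threshold}")
        if not (0 < self.p_threshold):
            raise ConfigError("p_threshold", f"must be > 0, got {self.p_threshold}")
        if self.min_category_size < 1:
            raise ConfigError("min_category_size",
                              f"must be >= 1, got {self.min_category_size}")
        if self.treated == self.control:
            raise ConfigError("treated", "treated and control must differ")

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config", "YAML config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown configuration key")
    return RunConfig(**raw)
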