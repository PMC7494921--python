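"""Tabular I/O for expression layers, sample annotations and result tables.

An expression layer is a features-by-samples real matrix with unique text
identifiers on both axes.  Two dialects are read: plain TSV (header row of
sample IDs, one feature per line) and the GEO series-matrix dialect (metadata
lines prefixed with ``!`` and a delimited data block), with gzip handled
transparently.  Result tables are written as TSV with full-precision floats so
that writing and re-reading a matrix is lossless.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens treated as missing values when parsing expression files
_NA_TOKENS = {"", "null", "na", "nan"}

# full round-trip precision for float64
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass
class ExpressionMatrix:
    """One omics layer: ``values[i, j]`` is feature ``feature_ids[i]`` in
    sample ``sample_ids[j]``.

    Parameters
    ----------
    layer_name : str
        Free-text tag, conventionally ``"mRNA"`` or ``"miRNA"``.
    feature_ids, sample_ids : sequence of str
        Unique row and column identifiers.
    values : ndarray, shape (n_features, n_samples)
    """

    layer_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature IDs but {n} rows"
            )
        if m != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample IDs but {m} columns")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} IDs: {dupes[:5]}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer_name: str) -> "ExpressionMatrix":
        return cls(
            layer_name=layer_name,
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_features(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        """Restrict to the given features.  ``keep`` is either a boolean mask
        over rows or an ordered list of feature IDs."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            missing = [f for f in keep if f not in pos]
            if missing:
                raise KeyError(f"unknown feature IDs: {missing[:5]}")
            idx = np.array([pos[f] for f in keep], dtype=int)
        return ExpressionMatrix(
            layer_name=self.layer_name,
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
        )

    def select_samples(self, order: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in order if s not in pos]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        idx = [pos[s] for s in order]
        return ExpressionMatrix(
            layer_name=self.layer_name,
            feature_ids=list(self.feature_ids),
            sample_ids=list(order),
            values=self.values[:, idx],
        )


@dataclass
class SampleAnnotation:
    """Mapping from sample ID to a binary class label (e.g. tumor/normal)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def binary_masks(
        self, sample_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray, str, str]:
        """Boolean masks over ``sample_ids`` for the two classes.

        Returns ``(mask_a, mask_b, label_a, label_b)`` with labels in sorted
        order.  Raises if any sample is unannotated or the annotation does not
        define exactly two classes among the given samples.
        """
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without annotation: {missing[:10]}")
        lab = np.array([self.labels[s] for s in sample_ids])
        classes = sorted(set(lab))
        if len(classes) != 2:
            raise ValueError(
                f"need exactly 2 classes among samples, found {classes}"
            )
        return lab == classes[0], lab == classes[1], classes[0], classes[1]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleAnnotation":
        """Read a two-column ``sample_id<TAB>label`` file; an optional header
        line starting with ``sample_id`` is skipped."""
        labels: dict[str, str] = {}
        with _open_text(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n").rstrip("\r")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: line {ln}: expected 2 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                if ln == 1 and parts[0].lower() in {"sample_id", "sample", "id"}:
                    continue
                if parts[0] in labels:
                    raise FormatError(f"{path}: duplicate sample ID {parts[0]!r}")
                labels[parts[0]] = parts[1]
        if not labels:
            raise FormatError(f"{path}: empty annotation")
        return cls(labels)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tlabel\n")
            for s, lab in self.labels.items():
                fh.write(f"{s}\t{lab}\n")


@dataclass
class ConfusionTable:
    """2x2 cross-dataset selection-overlap counts.

    ``a`` neither selected, ``b`` selected in B only, ``c`` selected in A
    only, ``d`` selected in both.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a nonnegative integer")
            setattr(self, name, int(v))

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_array(),
            index=pd.Index(["not selected", "selected"], name="A"),
            columns=pd.Index(["not selected", "selected"], name="B"),
        )


def _open_text(path: str | Path):
    """Open plain or gzipped text transparently."""
    path = Path(path)
    with open(path, "rb") as raw:
        magic = raw.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _parse_cell(token: str, path, ln: int, col: str) -> float:
    t = token.strip().strip('"')
    if t.lower() in _NA_TOKENS:
        return math.nan
    try:
        return float(t)
    except ValueError:
        raise FormatError(
            f"{path}: line {ln}, column {col!r}: non-numeric value {token!r}"
        ) from None


def read_matrix_tsv(path: str | Path, layer_name: str) -> ExpressionMatrix:
    """Read a features-by-samples TSV expression matrix.

    The first line is a header whose first field names the feature-ID column
    and whose remaining fields are sample IDs; each following line is a
    feature ID plus one numeric field per sample.  Missing-value tokens
    (empty, ``null``, ``NA``, ``NaN``) load as non-finite and are handled by
    :func:`tensorfe.preprocess.filter_features`.
    """
    path = Path(path)
    with _open_text(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        sample_ids = [h.strip().strip('"') for h in header[1:]]
        if not sample_ids:
            raise FormatError(f"{path}: header has no sample columns")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for ln, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue  # ignore blank lines
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}: line {ln}: expected {len(sample_ids) + 1} fields,"
                    f" got {len(fields)} (ragged row)"
                )
            feature_ids.append(fields[0].strip().strip('"'))
            rows.append(
                [
                    _parse_cell(tok, path, ln, sample_ids[j])
                    for j, tok in enumerate(fields[1:])
                ]
            )
    if not rows:
        raise FormatError(f"{path}: empty matrix (header only)")
    return ExpressionMatrix(
        layer_name=layer_name,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
    )


def read_geo_series_matrix(path: str | Path, layer_name: str) -> ExpressionMatrix:
    """Read the data block of a GEO series-matrix file.

    Metadata lines (prefix ``!``) are ignored; only the block delimited by
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` is parsed.
    The first block row carries the sample accessions (GSM IDs).  Gzipped
    files are handled transparently.
    """
    path = Path(path)
    in_block = False
    saw_begin = saw_end = False
    block_lines: list[tuple[int, str]] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if stripped.startswith("!series_matrix_table_begin"):
                saw_begin, in_block = True, True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                saw_end, in_block = True, False
                continue
            if in_block and stripped:
                block_lines.append((ln, stripped))
    if not (saw_begin and saw_end):
        missing = []
        if not saw_begin:
            missing.append("!series_matrix_table_begin")
        if not saw_end:
            missing.append("!series_matrix_table_end")
        raise FormatError(f"{path}: missing delimiter(s) {missing}")
    if len(block_lines) < 2:
        raise FormatError(f"{path}: empty series-matrix data block")

    hdr_ln, hdr = block_lines[0]
    sample_ids = [t.strip().strip('"') for t in hdr.split("\t")[1:]]
    if not sample_ids:
        raise FormatError(f"{path}: line {hdr_ln}: no sample columns in block")
    feature_ids, rows = [], []
    for ln, line in block_lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}: line {ln}: expected {len(sample_ids) + 1} fields, "
                f"got {len(fields)} (ragged row)"
            )
        feature_ids.append(fields[0].strip().strip('"'))
        rows.append(
            [
                _parse_cell(tok, path, ln, sample_ids[j])
                for j, tok in enumerate(fields[1:])
            ]
        )
    return ExpressionMatrix(
        layer_name=layer_name,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
    )


def align_layers(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both layers to their shared samples, columns sorted
    lexicographically (deterministic across runs).  Idempotent."""
    shared = sorted(set(a.sample_ids) & set(b.sample_ids))
    if not shared:
        raise ValueError("no shared samples between layers")
    for layer in (a, b):
        dropped = layer.n_samples - len(shared)
        if dropped:
            logger.info(
                "align_layers: dropping %d of %d samples from layer %r",
                dropped, layer.n_samples, layer.layer_name,
            )
    return a.select_samples(shared), b.select_samples(shared)


def write_results(table, path: str | Path) -> None:
    """Write a result object as TSV: one header line, stable column order,
    floats at full precision (P-values in scientific notation survive a
    round-trip)."""
    path = Path(path)
    try:
        if isinstance(table, ExpressionMatrix):
            _write_expression_matrix(table, path)
        elif isinstance(table, ConfusionTable):
            table.to_frame().to_csv(path, sep="\t")
        elif isinstance(table, pd.DataFrame):
            table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        else:
            raise TypeError(f"cannot write object of type {type(table).__name__}")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc


def _write_expression_matrix(x: ExpressionMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(x.sample_ids) + "\n")
        for i, fid in enumerate(x.feature_ids):
            vals = "\t".join(_FLOAT_FMT % v for v in x.values[i])
            fh.write(f"{fid}\t{vals}\n")
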