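"""Reading, writing and structural parsing of wide expression matrices.

An expression atlas is distributed as a wide delimited text file: one row per
probe(set), one column per hybridization, a single header row, probe
identifiers in the first column.  Column headers encode the sample name plus a
replicate index (``Root_A17_control_1`` is replicate 1 of sample
``Root_A17_control``); columns without a replicate suffix stand for samples
measured once.  This module parses that layout strictly (no silent coercion of
malformed cells) and recovers the sample/replicate structure from the headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleGroup",
    "DEFAULT_REPLICATE_PATTERN",
    "read_matrix",
    "write_matrix",
    "parse_replicate_groups",
    "detect_duplicate_names",
]

#: Default rule for splitting a column header into sample name and replicate
#: index: a trailing ``_<integer>``. Configurable because atlases are not
#: perfectly consistent in how they label replicates.
DEFAULT_REPLICATE_PATTERN = r"^(?P<sample>.+)_(?P<rep>\d+)$"

SCALE_LINEAR = "linear"
SCALE_SUSPECTED_LOG = "suspected-log"
_VALID_SCALES = frozenset({SCALE_LINEAR, SCALE_SUSPECTED_LOG})


@dataclass
class ExpressionMatrix:
    """A probes x hybridizations matrix of non-negative expression values.

    Parameters
    ----------
    probe_ids:
        Ordered, unique probe identifiers (matrix rows).
    column_labels:
        Ordered hybridization headers.  Duplicate labels are permitted here
        (they are one of the data-entry defects this package detects and
        repairs), which is why the matrix is not simply a DataFrame indexed by
        label.
    values:
        Float array of shape ``(len(probe_ids), len(column_labels))``; all
        entries finite and >= 0.
    scale_tags:
        Per-column scale annotation, ``"linear"`` or ``"suspected-log"``.
    """

    probe_ids: list[str]
    column_labels: list[str]
    values: np.ndarray
    scale_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.column_labels = [str(c) for c in self.column_labels]
        self.values = np.asarray(self.values, dtype=float)
        if not self.scale_tags:
            self.scale_tags = [SCALE_LINEAR] * len(self.column_labels)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_probes, n_cols = self.values.shape
        if n_probes != len(self.probe_ids):
            raise ValueError(
                f"{len(self.probe_ids)} probe ids but {n_probes} value rows"
            )
        if n_cols != len(self.column_labels):
            raise ValueError(
                f"{len(self.column_labels)} column labels but {n_cols} value columns"
            )
        if len(self.scale_tags) != n_cols:
            raise ValueError("one scale tag per column required")
        bad_tags = set(self.scale_tags) - _VALID_SCALES
        if bad_tags:
            raise ValueError(f"invalid scale tags: {sorted(bad_tags)}")
        seen: set[str] = set()
        for p in self.probe_ids:
            if p in seen:
                raise ValueError(f"duplicate probe id: {p!r}")
            seen.add(p)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe id not in matrix: {probe_id!r}") from None

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_index(probe_id)]

    def subset_columns(self, indices: Sequence[int]) -> "ExpressionMatrix":
        """New matrix restricted to ``indices``, preserving the given order."""
        idx = list(indices)
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            column_labels=[self.column_labels[i] for i in idx],
            values=self.values[:, idx].copy(),
            scale_tags=[self.scale_tags[i] for i in idx],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            column_labels=list(self.column_labels),
            values=self.values.copy(),
            scale_tags=list(self.scale_tags),
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view (probe ids as index; duplicate headers preserved)."""
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probeset"),
            columns=self.column_labels,
        )


@dataclass
class SampleGroup:
    """A named sample and the ordered hybridization columns measuring it."""

    sample_name: str
    member_columns: list[int]
    replicate_labels: list[str]

    @property
    def n_replicates(self) -> int:
        return len(self.member_columns)

    @property
    def is_singleton(self) -> bool:
        return len(self.member_columns) == 1


def read_matrix(
    path: str | Path,
    delimiter: str = "\t",
    probe_column: int = 0,
) -> ExpressionMatrix:
    """Read a wide expression matrix from delimited text.

    The first row is the header; ``probe_column`` holds probe identifiers and
    every other column holds expression values.  Parsing is strict: ragged
    rows, non-numeric cells, non-finite or negative values and duplicate probe
    ids are hard errors that name the offending location.  Numbers use the dot
    decimal convention regardless of locale.
    """
    path = Path(path)
    # the header is read by hand: pandas silently renames duplicate column
    # names, which would destroy exactly the header-collision defect this
    # package detects
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\r\n")
    header = first.split(delimiter)
    try:
        raw = pd.read_csv(
            path, sep=delimiter, header=None, skiprows=1, dtype=str,
            keep_default_na=False, na_filter=False, engine="c",
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if raw.shape[1] != len(header):
        raise ValueError(
            f"{path}: header has {len(header)} fields but rows have "
            f"{raw.shape[1]}"
        )
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need a probe column plus >= 1 value column")
    if not 0 <= probe_column < raw.shape[1]:
        raise ValueError(f"probe_column {probe_column} out of range")
    probe_ids = raw.iloc[:, probe_column].astype(str).tolist()
    value_cols = [j for j in range(raw.shape[1]) if j != probe_column]
    column_labels = [header[j] for j in value_cols]

    n = len(probe_ids)
    values = np.empty((n, len(value_cols)), dtype=float)
    for out_j, j in enumerate(value_cols):
        col = raw.iloc[:, j].to_numpy()
        try:
            # numpy's string conversion is correctly rounded, so values
            # written with a round-tripping repr parse back bit-identically
            parsed = col.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(col):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at row "
                        f"{probe_ids[i]!r} (line {i + 2}), column {header[j]!r}"
                    ) from None
            raise
        bad = ~np.isfinite(parsed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-finite value {col[i]!r} at row "
                f"{probe_ids[i]!r} (line {i + 2}), column {header[j]!r}"
            )
        neg = parsed < 0
        if neg.any():
            i = int(np.flatnonzero(neg)[0])
            raise ValueError(
                f"{path}: negative value {parsed[i]!r} at row {probe_ids[i]!r} "
                f"(line {i + 2}), column {header[j]!r}"
            )
        values[:, out_j] = parsed

    return ExpressionMatrix(
        probe_ids=probe_ids, column_labels=column_labels, values=values
    )


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    delimiter: str = "\t",
    probe_header: str = "probeset",
) -> None:
    """Write the matrix in the same wide layout ``read_matrix`` consumes.

    Values are written with Python's shortest round-tripping float repr, so a
    read -> write -> read cycle reproduces the parsed doubles exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join([probe_header, *matrix.column_labels]) + "\n")
        for i, probe in enumerate(matrix.probe_ids):
            row = matrix.values[i]
            fh.write(probe)
            for v in row:
                fh.write(delimiter + repr(float(v)))
            fh.write("\n")


def parse_replicate_groups(
    column_labels: Sequence[str],
    pattern: str = DEFAULT_REPLICATE_PATTERN,
) -> list[SampleGroup]:
    """Partition columns into sample groups via the replicate-suffix rule.

    A header matching ``pattern`` (default: trailing ``_<integer>``) is
    assigned to the sample named by its ``sample`` capture group; a header
    without the suffix forms a singleton group under its full name.  Groups
    are returned in first-appearance order and partition the columns: every
    column belongs to exactly one group.
    """
    if len(column_labels) == 0:
        raise ValueError("column_labels must be non-empty")
    rx = re.compile(pattern)
    groups: dict[str, SampleGroup] = {}
    order: list[str] = []
    for idx, label in enumerate(column_labels):
        m = rx.match(label)
        sample = m.group("sample") if m else label
        if sample not in groups:
            groups[sample] = SampleGroup(sample, [], [])
            order.append(sample)
        groups[sample].member_columns.append(idx)
        groups[sample].replicate_labels.append(label)
    return [groups[s] for s in order]


def detect_duplicate_names(column_labels: Sequence[str]) -> list[list[int]]:
    """Groups of column indices sharing an identical full header.

    Duplicate headers are a data-entry defect (the same sample block pasted
    twice shifts every later column's identity), so they are reported for
    repair rather than silently disambiguated.  Only groups of size >= 2 are
    returned, in order of first appearance.
    """
    by_label: dict[str, list[int]] = {}
    for idx, label in enumerate(column_labels):
        by_label.setdefault(label, []).append(idx)
    return [idxs for idxs in by_label.values() if len(idxs) >= 2]
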