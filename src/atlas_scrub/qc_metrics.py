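"""Quality indices and anomaly detectors for expression-atlas columns.

Two cheap indices catch most defective hybridizations in a public atlas:

* the **column sum** — total expression over all probes.  Healthy full-size
  arrays (~50,900 probesets) sum to roughly 2.0e7; columns that were uploaded
  on a log scale, or that lost signal to amplification artifacts, fall orders
  of magnitude below that;
* the **replicate-pair Pearson correlation** — replicates of the same tissue
  should agree almost perfectly across the transcriptome, so any pair below
  ~0.9 marks a corrupted measurement.

On top of these sit three structural detectors: value-identical columns pasted
under different sample names, identical header names (a paste error that
shifts later column identities), and whole studies inserted after log
transformation (confirmed by matching the antilog's per-sample means against
the deposited sample-mean matrix).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix_io import (
    ExpressionMatrix,
    SampleGroup,
    detect_duplicate_names,
    parse_replicate_groups,
)

__all__ = [
    "DEFAULT_SUM_THRESHOLD",
    "DEFAULT_R_THRESHOLD",
    "ReplicatePair",
    "LogInsertionCall",
    "QCReport",
    "column_sums",
    "flag_low_sum",
    "replicate_correlations",
    "detect_duplicate_columns",
    "detect_log_inserted",
    "compute_qc",
]

#: Low-sum threshold for a full-size (50,900 probe) array; scale by
#: n_probes/50900 for reduced matrices.
DEFAULT_SUM_THRESHOLD = 1e6
#: Minimum acceptable replicate-pair Pearson correlation.
DEFAULT_R_THRESHOLD = 0.90
#: Candidate logarithm bases tried by the log-insertion detector.
DEFAULT_LOG_BASES = (2.0, math.e, 10.0)


@dataclass
class ReplicatePair:
    """Pearson correlation between two replicate columns of one sample."""

    sample_name: str
    col_i: int
    col_j: int
    label_i: str
    label_j: str
    r: float  # NaN when undefined (zero-variance column)


@dataclass
class LogInsertionCall:
    """Log-insertion verdict for one sample group.

    ``status`` is ``"confirmed"`` when the antilog test against a sample-means
    matrix succeeded (``base`` then holds the recovered base), ``"suspected"``
    when the group is low-sum but no means column was available to test, and
    ``"clear"`` otherwise.
    """

    sample_name: str
    status: str  # confirmed | suspected | clear
    base: float | None = None
    agree_fraction: float | None = None

    @property
    def flagged(self) -> bool:
        return self.status in ("confirmed", "suspected")


@dataclass
class QCReport:
    """All per-column and per-group QC results for one matrix."""

    column_labels: list[str]
    column_sum: np.ndarray
    sum_threshold: float
    low_sum_flags: np.ndarray  # bool per column
    replicate_pairs: list[ReplicatePair]
    duplicate_column_groups: list[list[int]]
    duplicate_name_groups: list[list[int]]
    log_insertion: list[LogInsertionCall]
    singleton_flags: dict[str, bool]  # per sample group

    def to_dict(self) -> dict:
        return {
            "sum_threshold": self.sum_threshold,
            "columns": [
                {
                    "index": i,
                    "label": lab,
                    "sum": float(self.column_sum[i]),
                    "low_sum": bool(self.low_sum_flags[i]),
                }
                for i, lab in enumerate(self.column_labels)
            ],
            "replicate_pairs": [
                {
                    "sample": p.sample_name,
                    "labels": [p.label_i, p.label_j],
                    "r": None if np.isnan(p.r) else float(p.r),
                }
                for p in self.replicate_pairs
            ],
            "duplicate_column_groups": [list(g) for g in self.duplicate_column_groups],
            "duplicate_name_groups": [list(g) for g in self.duplicate_name_groups],
            "log_insertion": [
                {
                    "sample": c.sample_name,
                    "status": c.status,
                    "base": c.base,
                    "agree_fraction": c.agree_fraction,
                }
                for c in self.log_insertion
            ],
            "singleton_samples": sorted(
                s for s, flag in self.singleton_flags.items() if flag
            ),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def column_sums(matrix: ExpressionMatrix) -> np.ndarray:
    """Total expression over all probes, per hybridization column."""
    return matrix.values.sum(axis=0)


def flag_low_sum(sums: np.ndarray, threshold: float = DEFAULT_SUM_THRESHOLD) -> np.ndarray:
    """True where the column sum is strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(sums) < threshold


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, NaN (not 0) when either vector has zero variance."""
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float((xc @ yc) / math.sqrt(vx * vy))


def replicate_correlations(
    matrix: ExpressionMatrix,
    groups: Sequence[SampleGroup] | None = None,
) -> list[ReplicatePair]:
    """Pearson r for every unordered replicate pair within each sample.

    Computed across all probes on the values as stored (linear scale by
    convention).  Groups with a single member yield no pairs.  A
    zero-variance column produces an undefined correlation, reported as NaN
    with a warning; downstream rules treat NaN as below any threshold since
    such a column cannot demonstrate concordance.
    """
    if groups is None:
        groups = parse_replicate_groups(matrix.column_labels)
    pairs: list[ReplicatePair] = []
    for g in groups:
        members = g.member_columns
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                r = _pearson(matrix.values[:, i], matrix.values[:, j])
                if np.isnan(r):
                    warnings.warn(
                        f"undefined replicate correlation (zero variance) for "
                        f"{matrix.column_labels[i]!r} vs {matrix.column_labels[j]!r}",
                        stacklevel=2,
                    )
                pairs.append(
                    ReplicatePair(
                        g.sample_name, i, j,
                        matrix.column_labels[i], matrix.column_labels[j], r,
                    )
                )
    return pairs


class _DSU:
    """Union-find over column indices for duplicate-group closure."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def detect_duplicate_columns(
    matrix: ExpressionMatrix, tol: float = 0.0
) -> list[list[int]]:
    """Groups of columns whose value vectors are elementwise equal within ``tol``.

    Detection works directly on the stored values rather than on the
    correlation symptom (pairs of replicate correlations repeating digit for
    digit) that usually reveals pasted columns.  ``tol`` is relative
    (``|a-b| <= tol * max(|a|,|b|)`` per element); the default 0 means exact
    equality of the parsed values, appropriate for text exports where a pasted
    column is bit-identical.  Equality within a positive tolerance is not
    transitive, so groups are the union-find closure of the pairwise relation.
    Only groups of size >= 2 are returned, ordered by their smallest column
    index.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    n = matrix.n_columns
    if tol == 0.0:
        by_bytes: dict[bytes, list[int]] = {}
        for j in range(n):
            by_bytes.setdefault(matrix.values[:, j].tobytes(), []).append(j)
        groups = [g for g in by_bytes.values() if len(g) >= 2]
        return sorted(groups, key=lambda g: g[0])

    dsu = _DSU(n)
    sums = matrix.values.sum(axis=0)
    order = np.argsort(sums, kind="stable")
    # two near-equal columns have near-equal sums; prune by a sliding window
    vals = matrix.values
    for ai in range(n):
        a = int(order[ai])
        for bi in range(ai + 1, n):
            b = int(order[bi])
            if sums[b] - sums[a] > tol * max(abs(sums[a]), abs(sums[b]), 1.0) * vals.shape[0]:
                break
            va, vb = vals[:, a], vals[:, b]
            scale = np.maximum(np.abs(va), np.abs(vb))
            if np.all(np.abs(va - vb) <= tol * scale):
                dsu.union(a, b)
    by_root: dict[int, list[int]] = {}
    for j in range(n):
        by_root.setdefault(dsu.find(j), []).append(j)
    groups = [g for g in by_root.values() if len(g) >= 2]
    return sorted(groups, key=lambda g: g[0])


def detect_log_inserted(
    matrix: ExpressionMatrix,
    groups: Sequence[SampleGroup] | None = None,
    means_matrix: ExpressionMatrix | None = None,
    bases: Sequence[float] = DEFAULT_LOG_BASES,
    rel_tol: float = 0.01,
    min_agree_fraction: float = 0.99,
    sum_threshold: float = DEFAULT_SUM_THRESHOLD,
) -> list[LogInsertionCall]:
    """Flag sample groups whose values were uploaded after log transformation.

    A log-inserted study betrays itself twice: its column sums collapse to a
    few orders of magnitude below healthy columns, and — decisively — taking
    the antilog of its values and averaging over replicates reproduces the
    per-sample means deposited alongside the atlas (the means having been
    computed from the original, untransformed values).

    For each low-sum group (any member below ``sum_threshold``) with a column
    in ``means_matrix``, every candidate base ``b`` is tried: the group is
    confirmed if ``mean over replicates of b**value`` matches the means column
    within ``rel_tol`` relative deviation for at least ``min_agree_fraction``
    of the probes with positive deposited mean.  The best-agreeing base is
    reported.  Overflow during the antilog simply disqualifies that base.
    Without a means matrix the verdict stays ``"suspected"`` (low sum only).
    """
    if groups is None:
        groups = parse_replicate_groups(matrix.column_labels)
    sums = column_sums(matrix)
    calls: list[LogInsertionCall] = []

    means_lookup: dict[str, np.ndarray] = {}
    if means_matrix is not None:
        if means_matrix.probe_ids != matrix.probe_ids:
            # align by probe id; means matrices ship in the same probe order
            # but we do not rely on it
            pos = {p: i for i, p in enumerate(means_matrix.probe_ids)}
            try:
                idx = np.array([pos[p] for p in matrix.probe_ids])
            except KeyError as exc:
                raise ValueError(
                    f"means matrix is missing probe {exc.args[0]!r}"
                ) from None
            aligned = means_matrix.values[idx, :]
        else:
            aligned = means_matrix.values
        for j, lab in enumerate(means_matrix.column_labels):
            means_lookup[lab] = aligned[:, j]

    for g in groups:
        if not any(sums[i] < sum_threshold for i in g.member_columns):
            calls.append(LogInsertionCall(g.sample_name, "clear"))
            continue
        ref = means_lookup.get(g.sample_name)
        if ref is None:
            calls.append(LogInsertionCall(g.sample_name, "suspected"))
            continue
        block = matrix.values[:, g.member_columns]
        vmax = float(block.max()) if block.size else 0.0
        positive = ref > 0
        n_pos = int(positive.sum())
        best_base: float | None = None
        best_frac = 0.0
        for b in bases:
            if vmax * math.log(b) > 700.0:  # antilog would overflow float64
                continue
            with np.errstate(over="ignore"):
                anti_mean = np.power(b, block).mean(axis=1)
            if not np.all(np.isfinite(anti_mean)):
                continue
            if n_pos == 0:
                continue
            agree = np.abs(anti_mean[positive] - ref[positive]) <= rel_tol * ref[positive]
            frac = float(agree.mean())
            if frac > best_frac:
                best_frac, best_base = frac, b
        if best_base is not None and best_frac >= min_agree_fraction:
            calls.append(
                LogInsertionCall(g.sample_name, "confirmed", best_base, best_frac)
            )
        else:
            calls.append(
                LogInsertionCall(g.sample_name, "suspected", None, best_frac or None)
            )
    return calls


def compute_qc(
    matrix: ExpressionMatrix,
    groups: Sequence[SampleGroup] | None = None,
    sum_threshold: float = DEFAULT_SUM_THRESHOLD,
    means_matrix: ExpressionMatrix | None = None,
    duplicate_tol: float = 0.0,
) -> QCReport:
    """Run every detector and bundle the results into a :class:`QCReport`."""
    if groups is None:
        groups = parse_replicate_groups(matrix.column_labels)
    sums = column_sums(matrix)
    return QCReport(
        column_labels=list(matrix.column_labels),
        column_sum=sums,
        sum_threshold=sum_threshold,
        low_sum_flags=flag_low_sum(sums, sum_threshold),
        replicate_pairs=replicate_correlations(matrix, groups),
        duplicate_column_groups=detect_duplicate_columns(matrix, duplicate_tol),
        duplicate_name_groups=detect_duplicate_names(matrix.column_labels),
        log_insertion=detect_log_inserted(
            matrix, groups, means_matrix, sum_threshold=sum_threshold
        ),
        singleton_flags={g.sample_name: g.is_singleton for g in groups},
    )
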