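"""Removal of defective hybridization columns with an auditable ledger.

Cleaning applies five rules in a fixed priority order; each removed column is
charged to exactly one category (the first rule that catches it):

1. ``duplicate_name``   — repair identical headers (keep the first occurrence);
2. ``duplicate_data``   — drop value-identical columns pasted under different
   sample names (both copies by default, since provenance is ambiguous);
3. ``low_sum``          — drop *whole* sample groups containing any column whose
   expression sum falls below the threshold (such groups are systematically
   corrupted, typically log-inserted studies);
4. ``singleton``        — drop samples measured once: with no replicate there is
   no concordance evidence to retain them on;
5. ``low_correlation_replicate`` — apply the four-case replicate rule (below)
   to the surviving groups.

The replicate rule, at the default Pearson threshold 0.90: with two
replicates, keep both if their correlation clears the threshold, otherwise
drop both; with three, keep all three when every pair clears it, keep exactly
the best-passing pair when some but not all pairs do, and drop all three when
none does.

The priority order is a design choice — cheap structural defects are settled
before any correlation-based decision — and with non-overlapping defects it
does not affect the totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import (
    ExpressionMatrix,
    SampleGroup,
    detect_duplicate_names,
    parse_replicate_groups,
)
from .qc_metrics import (
    DEFAULT_R_THRESHOLD,
    DEFAULT_SUM_THRESHOLD,
    QCReport,
    _pearson,
    column_sums,
    detect_duplicate_columns,
)

__all__ = [
    "CATEGORIES",
    "CleaningConfig",
    "RemovalEntry",
    "RemovalLedger",
    "resolve_replicate_rule",
    "clean",
]

CATEGORIES = (
    "duplicate_name",
    "duplicate_data",
    "low_sum",
    "singleton",
    "low_correlation_replicate",
)


@dataclass
class CleaningConfig:
    """Thresholds and policies for :func:`clean`.

    ``r_min`` is the minimum acceptable replicate-pair Pearson correlation
    (default 0.90) and ``sum_min`` the low-sum cutoff (default 1e6, calibrated
    for full-size ~50,900-probe arrays whose healthy columns sum to ~2e7;
    scale it by ``n_probes / 50900`` for reduced matrices).
    """

    r_min: float = DEFAULT_R_THRESHOLD
    sum_min: float = DEFAULT_SUM_THRESHOLD
    drop_singletons: bool = True
    duplicate_policy: str = "remove_all"  # or "keep_first"
    name_duplicate_policy: str = "keep_first"  # or "remove_all"
    duplicate_tol: float = 0.0
    replicate_pattern: str | None = None  # None -> matrix_io default

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError("r_min must be in [0, 1]")
        if self.sum_min <= 0:
            raise ValueError("sum_min must be positive")
        if self.duplicate_policy not in ("remove_all", "keep_first"):
            raise ValueError(f"invalid duplicate_policy {self.duplicate_policy!r}")
        if self.name_duplicate_policy not in ("remove_all", "keep_first"):
            raise ValueError(
                f"invalid name_duplicate_policy {self.name_duplicate_policy!r}"
            )


@dataclass
class RemovalEntry:
    column_index: int
    column_label: str
    category: str
    detail: str


@dataclass
class RemovalLedger:
    """Accounting of one cleaning run: every input column is either removed
    under exactly one category or kept."""

    entries: list[RemovalEntry] = field(default_factory=list)
    kept_indices: list[int] = field(default_factory=list)
    kept_labels: list[str] = field(default_factory=list)

    @property
    def removed_indices(self) -> list[int]:
        return [e.column_index for e in self.entries]

    @property
    def counts(self) -> dict[str, int]:
        c = {cat: 0 for cat in CATEGORIES}
        for e in self.entries:
            c[e.category] += 1
        return c

    @property
    def n_removed(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "column_index": e.column_index,
                    "column_label": e.column_label,
                    "category": e.category,
                    "detail": e.detail,
                }
                for e in self.entries
            ],
            columns=["column_index", "column_label", "category", "detail"],
        )

    def summary(self) -> dict:
        return {
            "n_input": len(self.entries) + len(self.kept_indices),
            "n_removed": self.n_removed,
            "n_kept": len(self.kept_indices),
            "counts": self.counts,
        }


def resolve_replicate_rule(
    members: Sequence[int],
    pair_r: Mapping[tuple[int, int], float],
    r_min: float = DEFAULT_R_THRESHOLD,
) -> tuple[list[int], list[int]]:
    """Decide which replicates of one sample survive the concordance rule.

    ``members`` are the group's column indices and ``pair_r`` maps each
    unordered pair (as a sorted tuple) to its Pearson r; an undefined (NaN)
    correlation counts as below any threshold.

    Two replicates: keep both iff r >= ``r_min``, else drop both.  Three
    replicates: keep all when every pair passes; when at least one but not
    every pair passes, keep exactly the two columns of the highest-r passing
    pair (ties broken toward the pair with the lowest column indices) and drop
    the third; when no pair passes, drop all.  More than three replicates
    (beyond the classical two-to-three design) are handled by greedy
    elimination: repeatedly drop the member with the lowest mean correlation
    to the rest until every remaining pair passes, or fewer than two remain,
    in which case all are dropped.

    Returns ``(kept, dropped)`` in original member order.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("replicate rule requires a group with >= 2 members")

    def get_r(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        try:
            return float(pair_r[key])
        except KeyError:
            raise KeyError(f"missing pair correlation for columns {key}") from None

    def passes(r: float) -> bool:
        return not np.isnan(r) and r >= r_min

    def split(kept: list[int]) -> tuple[list[int], list[int]]:
        kept_set = set(kept)
        return (
            [m for m in members if m in kept_set],
            [m for m in members if m not in kept_set],
        )

    if len(members) == 2:
        return split(members if passes(get_r(*members)) else [])

    if len(members) == 3:
        pairs = list(combinations(members, 2))
        passing = [(a, b) for a, b in pairs if passes(get_r(a, b))]
        if len(passing) == len(pairs):
            return split(members)
        if passing:
            best = max(passing, key=lambda p: (get_r(*p), (-p[0], -p[1])))
            return split(list(best))
        return split([])

    remaining = list(members)
    while True:
        failing = [
            (a, b)
            for a, b in combinations(remaining, 2)
            if not passes(get_r(a, b))
        ]
        if not failing:
            return split(remaining)
        if len(remaining) <= 2:
            return split([])

        def mean_r(m: int) -> float:
            rs = [get_r(m, o) for o in remaining if o != m]
            return float(np.mean([-1.0 if np.isnan(r) else r for r in rs]))

        worst = min(remaining, key=lambda m: (mean_r(m), -m))
        remaining.remove(worst)


def clean(
    matrix: ExpressionMatrix,
    groups: Sequence[SampleGroup] | None = None,
    qc_report: QCReport | None = None,
    config: CleaningConfig | None = None,
) -> tuple[ExpressionMatrix, RemovalLedger]:
    """Apply all removal rules; return the cleaned matrix and its ledger.

    Columns are examined in the priority order described in the module
    docstring; a column removed at one step is not re-examined later, so its
    ledger category is the first rule that triggered.  The cleaned matrix
    preserves the original order of the kept columns.  Pair correlations and
    duplicate groups are taken from ``qc_report`` when supplied (it must have
    been computed on this matrix) and computed on the fly otherwise.
    """
    config = config or CleaningConfig()
    if groups is None:
        pattern = config.replicate_pattern
        if pattern is None:
            groups = parse_replicate_groups(matrix.column_labels)
        else:
            groups = parse_replicate_groups(matrix.column_labels, pattern)

    n = matrix.n_columns
    entries: list[RemovalEntry] = []
    removed: set[int] = set()

    def remove(idx: int, category: str, detail: str) -> None:
        entries.append(
            RemovalEntry(idx, matrix.column_labels[idx], category, detail)
        )
        removed.add(idx)

    # 1. duplicate header names
    name_groups = (
        qc_report.duplicate_name_groups
        if qc_report is not None
        else detect_duplicate_names(matrix.column_labels)
    )
    for grp in name_groups:
        victims = grp if config.name_duplicate_policy == "remove_all" else grp[1:]
        for idx in victims:
            remove(
                idx, "duplicate_name",
                f"header {matrix.column_labels[idx]!r} occurs {len(grp)} times",
            )

    # 2. value-identical columns under different names
    dup_groups = (
        qc_report.duplicate_column_groups
        if qc_report is not None
        else detect_duplicate_columns(matrix, config.duplicate_tol)
    )
    for grp in dup_groups:
        alive = [i for i in grp if i not in removed]
        if len(alive) < 2:
            continue
        victims = alive if config.duplicate_policy == "remove_all" else alive[1:]
        labels = ", ".join(matrix.column_labels[i] for i in alive)
        for idx in victims:
            remove(idx, "duplicate_data", f"identical values among: {labels}")

    # 3. low-sum sample groups (removed whole: a group with any collapsed
    # column is systematically corrupted)
    sums = (
        qc_report.column_sum if qc_report is not None else column_sums(matrix)
    )
    for g in groups:
        alive = [i for i in g.member_columns if i not in removed]
        if not alive:
            continue
        low = [i for i in alive if sums[i] < config.sum_min]
        if low:
            min_sum = min(sums[i] for i in low)
            for idx in alive:
                remove(
                    idx, "low_sum",
                    f"sample {g.sample_name!r} min column sum {min_sum:.4g} "
                    f"< {config.sum_min:.4g}",
                )

    # 4. singletons (one surviving column: no concordance evidence)
    if config.drop_singletons:
        for g in groups:
            alive = [i for i in g.member_columns if i not in removed]
            if len(alive) == 1:
                remove(
                    alive[0], "singleton",
                    f"sample {g.sample_name!r} has a single hybridization",
                )

    # 5. replicate concordance rule on the surviving groups
    pair_r_cache: dict[tuple[int, int], float] = {}
    if qc_report is not None:
        for p in qc_report.replicate_pairs:
            key = (p.col_i, p.col_j) if p.col_i < p.col_j else (p.col_j, p.col_i)
            pair_r_cache[key] = p.r
    for g in groups:
        alive = [i for i in g.member_columns if i not in removed]
        if len(alive) < 2:
            continue
        for a, b in combinations(alive, 2):
            key = (a, b) if a < b else (b, a)
            if key not in pair_r_cache:
                pair_r_cache[key] = _pearson(
                    matrix.values[:, key[0]], matrix.values[:, key[1]]
                )
        kept, dropped = resolve_replicate_rule(alive, pair_r_cache, config.r_min)
        for idx in dropped:
            rs = ", ".join(
                f"{pair_r_cache[(min(idx, o), max(idx, o))]:.3f}"
                for o in alive
                if o != idx
            )
            remove(
                idx, "low_correlation_replicate",
                f"sample {g.sample_name!r} pair r vs siblings: [{rs}] "
                f"(threshold {config.r_min})",
            )

    kept_indices = [i for i in range(n) if i not in removed]
    if not kept_indices:
        warnings.warn("cleaning removed every column", stacklevel=2)
    ledger = RemovalLedger(
        entries=sorted(entries, key=lambda e: e.column_index),
        kept_indices=kept_indices,
        kept_labels=[matrix.column_labels[i] for i in kept_indices],
    )
    cleaned = matrix.subset_columns(kept_indices)
    return cleaned, ledger
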