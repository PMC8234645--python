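"""Probe-probe correlation analysis across hybridizations.

Correlation between two probes' expression profiles, taken across all columns
of the atlas, is the workhorse for guilt-by-association function prediction.
Three coefficients are supported:

* **Pearson** on linear values — dominated by high-expression columns, hence
  very sensitive to the defective hybridizations that cleaning removes;
* **Pearson on log values** (``log2(x + pseudocount)``) — reveals correlations
  that also hold at low expression; the base is irrelevant to Pearson (bases
  differ by a positive scalar), the pseudocount guards zeros;
* **Spearman / Kendall tau-b** — rank coefficients, invariant under strictly
  monotone transforms and therefore largely insensitive both to the log/linear
  choice and to a handful of outlier columns.

On top of the pairwise engine sit a one-vs-all ranking (top-k correlator
lists, k = 49 by convention), differential tables (cleaned minus original,
quantifying the false positives and negatives the cleaning removed) and a
heatmap-ready TSV export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import ExpressionMatrix

__all__ = [
    "CorrelationTable",
    "RankedCorrelators",
    "DifferentialTable",
    "correlate",
    "one_vs_all",
    "differential_table",
    "export_heatmap_data",
]

METHODS = ("pearson", "spearman", "kendall")
SCALES = ("linear", "log")
DEFAULT_TOP_K = 49
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class CorrelationTable:
    """Correlation coefficients between two probe lists.

    ``values[i, j]`` is the coefficient between ``row_probes[i]`` and
    ``col_probes[j]``; NaN marks an undefined coefficient (zero-variance
    probe).  ``note`` records caveats such as a scale argument being ignored
    by a rank method.
    """

    row_probes: list[str]
    col_probes: list[str]
    method: str
    scale: str
    values: np.ndarray
    n_columns_used: int
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_probes, columns=self.col_probes
        )

    @property
    def is_square(self) -> bool:
        return self.row_probes == self.col_probes


@dataclass
class RankedCorrelators:
    """Full descending ranking of correlators of one query probe.

    Probes with undefined correlation are excluded rather than ranked last.
    ``top(k)`` is a view of the first ``k`` entries (default 49, the
    conventional list length for enrichment follow-up).
    """

    query_probe: str
    probes: list[str]
    r: np.ndarray
    method: str
    scale: str
    k: int = DEFAULT_TOP_K

    def top(self, k: int | None = None) -> list[tuple[str, float]]:
        k = self.k if k is None else k
        return [(p, float(v)) for p, v in zip(self.probes[:k], self.r[:k])]

    def to_frame(self, k: int | None = None) -> pd.DataFrame:
        rows = self.top(k)
        return pd.DataFrame(rows, columns=["probe", "r"])


@dataclass
class DifferentialTable:
    """Elementwise difference of two correlation tables (cleaned - original).

    ``mean_difference`` averages the off-diagonal cells (NaN-aware) when the
    table is square on identical axes, all cells otherwise.
    """

    row_probes: list[str]
    col_probes: list[str]
    method: str
    scale: str
    values: np.ndarray
    mean_difference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_probes, columns=self.col_probes
        )


def _log_transform(block: np.ndarray, pseudocount: float) -> np.ndarray:
    return np.log2(block + pseudocount)


def _pearson_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson between every row of ``a`` and every row of ``b``.

    Zero-variance rows yield NaN, not 0: an uninformative coefficient must not
    masquerade as evidence of independence.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((ac * ac).sum(axis=1))
    bn = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ bc.T) / np.outer(an, bn)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _rank_rows(block: np.ndarray) -> np.ndarray:
    """Fractional ranks (ties -> average rank) along each row."""
    return np.apply_along_axis(stats.rankdata, 1, block)


def _kendall_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            if np.ptp(a[i]) == 0 or np.ptp(b[j]) == 0:
                out[i, j] = np.nan
                continue
            out[i, j] = stats.kendalltau(a[i], b[j]).statistic  # tau-b
    return out


def correlate(
    matrix: ExpressionMatrix,
    probes_a: Sequence[str],
    probes_b: Sequence[str] | None = None,
    method: str = "pearson",
    scale: str = "linear",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CorrelationTable:
    """Correlation table between two probe lists across all hybridizations.

    ``scale="log"`` applies ``log2(x + pseudocount)`` before a Pearson
    correlation; Spearman and Kendall are invariant under that (strictly
    monotone) transform, so for them the scale argument is ignored and noted
    in the output.  Requires at least 3 columns.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    if matrix.n_columns < 3:
        raise ValueError(
            f"need >= 3 hybridizations to correlate, got {matrix.n_columns}"
        )
    probes_a = list(probes_a)
    probes_b = probes_a if probes_b is None else list(probes_b)
    ia = [matrix.probe_index(p) for p in probes_a]
    ib = [matrix.probe_index(p) for p in probes_b]
    a = matrix.values[ia, :].astype(float)
    b = matrix.values[ib, :].astype(float)

    note = ""
    if method == "pearson":
        if scale == "log":
            a = _log_transform(a, pseudocount)
            b = _log_transform(b, pseudocount)
        vals = _pearson_block(a, b)
    elif method == "spearman":
        note = "rank method: scale argument has no effect"
        vals = _pearson_block(_rank_rows(a), _rank_rows(b))
    else:
        note = "rank method: scale argument has no effect"
        vals = _kendall_block(a, b)

    if np.isnan(vals).any():
        warnings.warn(
            "undefined correlations (zero-variance probes) reported as NaN",
            stacklevel=2,
        )
    return CorrelationTable(
        row_probes=probes_a,
        col_probes=probes_b,
        method=method,
        scale=scale,
        values=vals,
        n_columns_used=matrix.n_columns,
        note=note,
    )


def one_vs_all(
    matrix: ExpressionMatrix,
    query_probe: str,
    method: str = "pearson",
    scale: str = "linear",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    k: int = DEFAULT_TOP_K,
) -> RankedCorrelators:
    """Rank every other probe by its correlation with ``query_probe``.

    Returns the full descending ranking (``top(k)`` is a view); ties are
    broken by probe id so the ordering is deterministic.  Probes with an
    undefined coefficient are excluded.  Other probes targeting the same gene
    are deliberately *not* excluded — a sibling probe ranking first is the
    natural positive control.
    """
    table = correlate(
        matrix, [query_probe], matrix.probe_ids, method, scale, pseudocount
    )
    r = table.values[0]
    order = []
    for j, probe in enumerate(matrix.probe_ids):
        if probe == query_probe or np.isnan(r[j]):
            continue
        order.append((probe, float(r[j])))
    order.sort(key=lambda t: (-t[1], t[0]))
    return RankedCorrelators(
        query_probe=query_probe,
        probes=[p for p, _ in order],
        r=np.array([v for _, v in order]),
        method=method,
        scale=scale,
        k=k,
    )


def differential_table(
    table_cleaned: CorrelationTable,
    table_original: CorrelationTable,
) -> DifferentialTable:
    """Cleaned-minus-original correlation differences on identical axes.

    A positive cell means cleaning *strengthened* the correlation (a false
    negative removed); a negative cell means it weakened one (a false positive
    removed).
    """
    if table_cleaned.row_probes != table_original.row_probes or (
        table_cleaned.col_probes != table_original.col_probes
    ):
        raise ValueError("differential table requires identical probe axes")
    if table_cleaned.method != table_original.method:
        raise ValueError("differential table requires matching methods")
    if table_cleaned.scale != table_original.scale:
        raise ValueError("differential table requires matching scales")
    diff = table_cleaned.values - table_original.values
    if table_cleaned.is_square and diff.shape[0] == diff.shape[1]:
        mask = ~np.eye(diff.shape[0], dtype=bool)
        cells = diff[mask]
    else:
        cells = diff.ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slice
        mean_diff = float(np.nanmean(cells)) if cells.size else float("nan")
    return DifferentialTable(
        row_probes=list(table_cleaned.row_probes),
        col_probes=list(table_cleaned.col_probes),
        method=table_cleaned.method,
        scale=table_cleaned.scale,
        values=diff,
        mean_difference=mean_diff,
    )


def export_heatmap_data(
    table: CorrelationTable | DifferentialTable,
    path: str | Path,
    image_path: str | Path | None = None,
) -> None:
    """Write a square table as heatmap-ready TSV; optionally render a PNG.

    The numeric TSV is the contract; rendering (requires matplotlib) is
    best-effort and a failure there only warns.
    """
    if table.row_probes != table.col_probes:
        raise ValueError("heatmap export requires a square table")
    frame = table.to_frame()
    frame.index.name = "probe"
    frame.to_csv(path, sep="\t")
    if image_path is not None:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(
                figsize=(max(4, len(table.row_probes) * 0.15),) * 2
            )
            im = ax.imshow(table.values, vmin=-1, vmax=1, cmap="RdBu_r")
            fig.colorbar(im, ax=ax, shrink=0.8)
            ax.set_xticks([])
            ax.set_yticks([])
            fig.savefig(image_path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        except Exception as exc:  # rendering is best-effort
            warnings.warn(f"heatmap rendering failed: {exc}", stacklevel=2)
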