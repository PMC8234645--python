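"""Singular enrichment analysis (SEA) of a probe list against a background.

Given a query list (typically the top-k correlators of a gene), a probe→term
annotation and a background universe of N probes, each term annotating K
background probes and k of the n query probes is scored with the one-sided
hypergeometric upper tail

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

(equivalently Fisher's exact test, enrichment side), followed by
Benjamini-Hochberg FDR control across the tested terms.  Unannotated probes
count toward N but toward no K.  Terms absent from the query (k = 0) are not
reported; their p-value is ~1 and carries no enrichment information.

Term propagation up an ontology DAG is off by default — the annotation is
taken as given — but can be enabled when an OBO file is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "read_annotation",
    "load_ontology",
    "propagate_annotation",
    "enrich",
]


@dataclass
class AnnotationMap:
    """Probe → term-set mapping plus an optional term metadata table."""

    probe_to_terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_to_terms = {
            str(p): frozenset(ts) for p, ts in self.probe_to_terms.items()
        }
        for probe, terms in self.probe_to_terms.items():
            if not probe:
                raise ValueError("empty probe id in annotation")
            for t in terms:
                if not t:
                    raise ValueError(f"empty term id annotating probe {probe!r}")

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.probe_to_terms.values():
            out |= ts
        return out

    def terms_of(self, probe: str) -> frozenset[str]:
        return self.probe_to_terms.get(probe, frozenset())


@dataclass
class EnrichmentResult:
    """Per-term enrichment statistics, sorted by p ascending.

    ``table`` columns: term, name, N, K, n, k, p, q, significant.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def significant_terms(self) -> list[str]:
        return self.table.loc[self.table["significant"], "term"].tolist()


def read_annotation(path: str | Path, delimiter: str = "\t") -> AnnotationMap:
    """Read a two-column (probe, term id) TSV; extra columns are ignored."""
    frame = pd.read_csv(
        path, sep=delimiter, header=None, dtype=str, comment="#",
        keep_default_na=False,
    )
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (probe, term)")
    mapping: dict[str, set[str]] = {}
    for probe, term in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        mapping.setdefault(probe, set()).add(term)
    return AnnotationMap({p: frozenset(ts) for p, ts in mapping.items()})


def load_ontology(path: str | Path):
    """Load an OBO ontology as a directed graph (child → parent edges)."""
    import obonet

    return obonet.read_obo(str(path))


def propagate_annotation(annotation: AnnotationMap, ontology) -> AnnotationMap:
    """Extend each probe's terms with all ancestors in the ontology DAG."""
    import networkx as nx

    ancestor_cache: dict[str, frozenset[str]] = {}

    def ancestors(term: str) -> frozenset[str]:
        if term not in ancestor_cache:
            if term in ontology:
                # obonet edges point child -> parent, so ancestors are the
                # graph-theoretic descendants of the term node
                ancestor_cache[term] = frozenset(nx.descendants(ontology, term))
            else:
                ancestor_cache[term] = frozenset()
        return ancestor_cache[term]

    names = dict(annotation.term_names)
    namespaces = dict(annotation.term_namespaces)
    new_map: dict[str, frozenset[str]] = {}
    for probe, terms in annotation.probe_to_terms.items():
        expanded = set(terms)
        for t in terms:
            expanded |= ancestors(t)
        new_map[probe] = frozenset(expanded)
    for term in set().union(*new_map.values()) if new_map else set():
        if term in getattr(ontology, "nodes", {}):
            data = ontology.nodes[term]
            names.setdefault(term, data.get("name", ""))
            namespaces.setdefault(term, data.get("namespace", ""))
    return AnnotationMap(new_map, names, namespaces)


def enrich(
    query_probes: Sequence[str],
    annotation: AnnotationMap,
    background_probes: Iterable[str],
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> EnrichmentResult:
    """Hypergeometric over-representation of terms in ``query_probes``.

    ``query_probes`` must be a subset of ``background_probes``; a violation is
    an error naming the first offending probe (a query drawn from a different
    universe would silently bias every K and N).  Probes without annotation
    are legitimate members of the background (they inflate N only).
    """
    query = list(dict.fromkeys(str(p) for p in query_probes))
    if not query:
        raise ValueError("query probe list is empty")
    background = list(dict.fromkeys(str(p) for p in background_probes))
    bg_set = set(background)
    for p in query:
        if p not in bg_set:
            raise ValueError(f"query probe {p!r} is not in the background")

    N = len(background)
    n = len(query)

    bg_count: dict[str, int] = {}
    for p in background:
        for t in annotation.terms_of(p):
            bg_count[t] = bg_count.get(t, 0) + 1
    q_count: dict[str, int] = {}
    for p in query:
        for t in annotation.terms_of(p):
            q_count[t] = q_count.get(t, 0) + 1

    rows = []
    for term, k in sorted(q_count.items()):
        K = bg_count[term]
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p_val = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, ""),
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": min(p_val, 1.0),
            }
        )
    if not rows:
        table = pd.DataFrame(
            columns=["term", "name", "N", "K", "n", "k", "p", "q", "significant"]
        )
        return EnrichmentResult(table=table, alpha=alpha)

    table = pd.DataFrame(rows)
    reject, q_vals, _, _ = multipletests(
        table["p"].to_numpy(), alpha=alpha, method=correction
    )
    table["q"] = q_vals
    table["significant"] = reject
    table = table.sort_values(
        ["p", "term"], kind="stable", ignore_index=True
    )
    return EnrichmentResult(table=table, alpha=alpha)
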