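"""Edge classification: literature-known, anatomically confirmed new, putative new.

Per-line binary connectomes are combined per cell-type category (wild,
excitatory, inhibitory, uncategorized) with an elementwise OR, and the union
over categories forms the summary map.  Each detected edge is then assigned a
status:

known
    present in the curated literature list;
confirmed_new
    not in the literature, but backed by at least one ≥75 %-specificity
    experiment at its source (the anatomical-confirmation tier);
putative_new
    detected but lacking confirmation support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import BinaryConnectome
from .errors import ConfigError, DimensionError
from .ontology import LineCategoryTable

logger = logging.getLogger(__name__)

STATUSES = ("known", "confirmed_new", "putative_new")


@dataclass(frozen=True)
class EdgeInfo:
    status: str
    categories: frozenset[str]


@dataclass
class ClassifiedConnectome:
    """Directed binary map with per-edge status and cell-type support."""

    nodes: list[str]
    edges: dict[tuple[str, str], EdgeInfo] = field(default_factory=dict)
    measured: np.ndarray | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (s, t), info in self.edges.items():
            if s == t:
                raise ConfigError(f"self-edge ({s}, {t}) not allowed")
            if s not in node_set or t not in node_set:
                raise ConfigError(f"edge ({s}, {t}) outside node panel")
            if info.status not in STATUSES:
                raise ConfigError(f"edge ({s}, {t}): unknown status {info.status!r}")
            if not info.categories:
                raise ConfigError(f"edge ({s}, {t}): empty category support")
        if self.measured is None:
            self.measured = np.ones(len(self.nodes), dtype=bool)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.nodes)}
        a = np.zeros((self.n, self.n), dtype=int)
        for s, t in self.edges:
            a[idx[s], idx[t]] = 1
        return a

    def status_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STATUSES}
        for info in self.edges.values():
            counts[info.status] += 1
        return counts


def combine_categories(
    per_line: dict[str, BinaryConnectome], cats: LineCategoryTable
) -> dict[str, BinaryConnectome]:
    """OR the per-line maps within each category; add the union map "all".

    A structure counts as measured for a category if any line of that category
    measured it.  Every line id must appear in the category table.
    """
    if not per_line:
        raise ConfigError("no per-line connectomes to combine")
    nodes = None
    for line_id, bc in per_line.items():
        if line_id not in cats:
            raise ConfigError(f"line {line_id!r} missing from category table")
        if nodes is None:
            nodes = bc.nodes
        elif bc.nodes != nodes:
            raise DimensionError("per-line connectomes disagree on node panel")
    assert nodes is not None
    n = len(nodes)

    out: dict[str, BinaryConnectome] = {}
    for cat in LineCategoryTable.CATEGORIES:
        adj = np.zeros((n, n), dtype=int)
        meas = np.zeros(n, dtype=bool)
        found = False
        for line_id, bc in per_line.items():
            if cats.category(line_id) != cat:
                continue
            found = True
            adj |= bc.adjacency
            meas |= bc.measured
        if found:
            out[cat] = BinaryConnectome(nodes=list(nodes), adjacency=adj, measured=meas)
    all_adj = np.zeros((n, n), dtype=int)
    all_meas = np.zeros(n, dtype=bool)
    for bc in out.values():
        all_adj |= bc.adjacency
        all_meas |= bc.measured
    out["all"] = BinaryConnectome(nodes=list(nodes), adjacency=all_adj, measured=all_meas)
    return out


def classify_edges(
    all_map: BinaryConnectome,
    literature: set[tuple[str, str]] | "object",
    confirmed_support: set[tuple[str, str]],
    category_maps: dict[str, BinaryConnectome] | None = None,
) -> ClassifiedConnectome:
    """Assign a status to every detected off-diagonal edge.

    ``literature`` is the curated set of previously reported connections
    (anything iterable over (source, target) pairs).  ``confirmed_support``
    holds edges backed by a ≥75 %-specificity experiment.  ``category_maps``
    (as from :func:`combine_categories`) supplies per-edge cell-type support;
    without it every edge is attributed to the "wild" category.
    """
    lit = set(tuple(p) for p in literature)
    detected = set(all_map.edges())
    orphans = set(confirmed_support) - detected
    if orphans:
        logger.warning(
            "confirmation support for %d undetected edge(s): %s",
            len(orphans),
            sorted(orphans)[:5],
        )
    edges: dict[tuple[str, str], EdgeInfo] = {}
    for e in sorted(detected):
        if e in lit:
            status = "known"
        elif e in confirmed_support:
            status = "confirmed_new"
        else:
            status = "putative_new"
        if category_maps:
            support = frozenset(
                cat
                for cat, bc in category_maps.items()
                if cat != "all" and e in set(bc.edges())
            )
        else:
            support = frozenset({"wild"})
        edges[e] = EdgeInfo(status=status, categories=support or frozenset({"wild"}))
    return ClassifiedConnectome(
        nodes=list(all_map.nodes), edges=edges, measured=all_map.measured.copy()
    )


def _truncate1(x: float) -> float:
    """One-decimal display truncation toward zero (48.456 → 48.4)."""
    return math.trunc(x * 10) / 10


def count_report(c: ClassifiedConnectome) -> dict:
    """Summary counts and coverage for a classified connectome.

    Coverage is reported against |nodes|² possible ordered pairs (the field's
    customary denominator, which includes self-pairs even though self-edges
    are never counted as connections); the off-diagonal-only figure is emitted
    alongside.  Display percentages are truncated to one decimal.
    """
    counts = c.status_counts()
    total = len(c.edges)
    n = c.n
    per_category = {
        cat: sum(1 for info in c.edges.values() if cat in info.categories)
        for cat in LineCategoryTable.CATEGORIES
    }
    coverage = 100.0 * total / (n * n) if n else 0.0
    coverage_offdiag = 100.0 * total / (n * (n - 1)) if n > 1 else 0.0
    return {
        "total": total,
        "known": counts["known"],
        "confirmed_new": counts["confirmed_new"],
        "putative_new": counts["putative_new"],
        "per_category": per_category,
        "possible_pairs": n * n,
        "coverage_percent": _truncate1(coverage),
        "coverage_percent_raw": coverage,
        "coverage_offdiagonal_percent": _truncate1(coverage_offdiag),
    }
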