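"""Top-k centrality ranking, union ("vital genes") and origin labelling.

For each of the four centrality metrics the genes are sorted by value
descending and the top k kept (ties at the boundary broken by gene
symbol, so each list has exactly k entries and is deterministic).  The
union of the four lists is the vital-gene set; each member carries the
metrics it appears in and the best rank it attains, and is labelled
``driver`` or ``selected`` against the anchor driver list.

A small alias map canonicalizes misprinted or synonymous symbols before
the union (the bundled map resolves the published REBBP misprint to
CREBBP); substitutions are always logged.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

METRICS = ("dc", "cc", "bc", "ec")
_METRIC_ALIASES = {
    "dc": "dc", "degree": "dc",
    "cc": "cc", "closeness": "cc",
    "bc": "bc", "betweenness": "bc",
    "ec": "ec", "eigenvector": "ec",
}


def _canon_metric(name: str) -> str:
    try:
        return _METRIC_ALIASES[name.strip().lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown metric {name!r}; expected one of DC, CC, BC, EC") from None


def rank_top_k(table: pd.DataFrame, metric: str, k: int) -> list[str]:
    """Top-k genes by one metric, value descending, symbol-ascending ties."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if table.empty:
        raise ConfigurationError("empty centrality table")
    col = _canon_metric(metric)
    ordered = table.sort_values([col, "gene"], ascending=[False, True],
                                kind="mergesort")
    return list(ordered["gene"].head(k))


def normalize_symbols(genes: Sequence[str], alias_map: Mapping[str, str]
                      ) -> list[str]:
    """Map every symbol through the alias map; unmapped symbols unchanged."""
    out = []
    for g in genes:
        canonical = alias_map.get(g, g)
        if canonical != g:
            logger.info("symbol alias: %s -> %s", g, canonical)
        out.append(canonical)
    return out


@dataclass
class VitalGeneReport:
    """Union of the per-metric top-k lists with membership and origin."""

    k: int
    top_lists: dict[str, list[str]]
    members: pd.DataFrame = field(repr=False)
    # members columns: gene, in_dc, in_cc, in_bc, in_ec, best_rank[, origin]

    @property
    def union(self) -> list[str]:
        return list(self.members["gene"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "top_lists": self.top_lists,
            "members": self.members.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def vital_union(lists: Mapping[str, Sequence[str]], k: int | None = None
                ) -> VitalGeneReport:
    """Union of four per-metric ordered lists into one vital-gene report.

    ``lists`` maps metric name -> ordered top-k genes.  ``best_rank`` is
    1-based.  Members are ordered by best rank, then symbol.
    """
    canon = {_canon_metric(m): list(genes) for m, genes in lists.items()}
    missing = set(METRICS) - set(canon)
    if missing:
        raise ConfigurationError(f"missing metric list(s): {sorted(missing)}")
    if k is None:
        k = max(len(v) for v in canon.values())
    best: dict[str, int] = {}
    membership: dict[str, set[str]] = {}
    for m in METRICS:
        for rank, g in enumerate(canon[m], start=1):
            membership.setdefault(g, set()).add(m)
            best[g] = min(best.get(g, rank), rank)
    genes = sorted(best, key=lambda g: (best[g], g))
    members = pd.DataFrame({
        "gene": genes,
        **{f"in_{m}": [m in membership[g] for g in genes] for m in METRICS},
        "best_rank": [best[g] for g in genes],
    })
    return VitalGeneReport(k=k, top_lists=canon, members=members)


def classify_origin(report: VitalGeneReport, drivers: Sequence[str]
                    ) -> tuple[int, int]:
    """Label union members driver/selected; returns (n_driver, n_selected)."""
    driver_set = set(drivers)
    origin = ["driver" if g in driver_set else "selected"
              for g in report.members["gene"]]
    report.members = report.members.assign(origin=origin)
    n_driver = sum(o == "driver" for o in origin)
    return n_driver, len(origin) - n_driver


def extract_vital_genes(table: pd.DataFrame, k: int,
                        drivers: Sequence[str] = (),
                        alias_map: Mapping[str, str] | None = None
                        ) -> VitalGeneReport:
    """Rank, canonicalize, union and label in one call."""
    alias_map = alias_map or {}
    lists = {m: normalize_symbols(rank_top_k(table, m, k), alias_map)
             for m in METRICS}
    report = vital_union(lists, k=k)
    if drivers:
        classify_origin(report, drivers)
    return report


# ---------------------------------------------------------------------------
# bundled published lists (shipped as plain text, one metric per line)
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("drivernet").joinpath("data", name).read_text()


def load_alias_map() -> dict[str, str]:
    """Bundled symbol-alias map (misprint/synonym -> canonical)."""
    out = {}
    for line in _data_text("symbol_aliases.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        src, dst = line.split("\t")
        out[src] = dst
    return out


def load_published_top_lists(k: int) -> dict[str, list[str]]:
    """The published per-metric top-10 or top-20 gene rows, as printed.

    Symbols are split on commas and whitespace (the printed top-20 degree
    row runs two symbols together without a comma) and are NOT alias-
    canonicalized here; pass through :func:`normalize_symbols` with
    :func:`load_alias_map` to resolve known misprints.
    """
    if k not in (10, 20):
        raise ConfigurationError(f"published lists exist for k=10 and k=20, not {k}")
    lists: dict[str, list[str]] = {}
    for line in _data_text(f"published_top{k}.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        metric, row = line.split("\t", 1)
        genes = [g for g in re.split(r"[,\s]+", row.strip()) if g]
        lists[_canon_metric(metric)] = genes
    return lists
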