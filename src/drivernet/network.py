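"""PPI graph construction and the four node-centrality metrics.

The graph is an undirected simple graph over gene symbols, induced on
the relevant-gene whitelist from a STRING-export edge list (two protein
columns plus an integer ``combined_score`` in [0, 1000]).

Centralities follow these conventions:

* degree centrality  DC_i = k_i / (N - 1), N the node count;
* closeness          CC_i = N_c / sum_j d_ij summed over nodes reachable
  from i, with N_c the size of i's connected component (numerator N_c,
  not the conventional N_c - 1; the conventional variant is available
  via ``conventional=True``); isolated nodes get 0;
* betweenness        BC_i = sum over unordered pairs {s,t}, s != i != t,
  of the fraction of shortest s-t paths through i, unnormalized;
* eigenvector        the principal eigenvector of the adjacency matrix
  of the largest connected component, non-negative, unit Euclidean norm,
  found by power iteration on A + I (the shift guards bipartite
  degeneracy); nodes outside that component get 0.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConvergenceError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_SCORE_MIN = 400  # STRING "medium confidence" convention

EDGE_COLUMNS = ("protein1", "protein2", "combined_score")


def read_string_edges(path: str | Path, score_min: int = DEFAULT_SCORE_MIN
                      ) -> pd.DataFrame:
    """Read a STRING-dialect edge list, filter by score, collapse duplicates.

    Rows with ``combined_score`` below ``score_min`` are discarded;
    A-B/B-A duplicates are collapsed keeping the maximum score;
    self-loops are logged and skipped.  Malformed rows raise
    ``FormatError`` naming the line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path} is empty")
        sep = "\t" if "\t" in header else None
        cols = header.split(sep)
        if len(cols) < 3:
            raise FormatError("expected at least 3 columns "
                              f"(protein1, protein2, combined_score)", line=1)
        seen: dict[tuple[str, str], int] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) < 3:
                raise FormatError(f"expected 3+ fields, got {len(parts)}",
                                  line=lineno)
            a, b, raw = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if not a or not b:
                raise FormatError("empty protein symbol", line=lineno)
            try:
                score = int(float(raw))
            except ValueError:
                raise FormatError(f"non-numeric combined_score {raw!r}",
                                  line=lineno) from None
            if not (0 <= score <= 1000):
                raise FormatError(f"combined_score {score} outside [0, 1000]",
                                  line=lineno)
            if a == b:
                logger.warning("line %d: self-loop %s-%s skipped", lineno, a, b)
                continue
            key = (a, b) if a < b else (b, a)
            if key not in seen or score > seen[key]:
                seen[key] = score
    kept = sorted((k, s) for k, s in seen.items() if s >= score_min)
    return pd.DataFrame({
        "protein1": [k[0] for k, _ in kept],
        "protein2": [k[1] for k, _ in kept],
        "combined_score": [s for _, s in kept],
    })


def build_network(edges: pd.DataFrame, node_whitelist: Iterable[str],
                  keep_isolated: bool = True) -> nx.Graph:
    """Undirected simple graph induced on the whitelist.

    Whitelist genes with no surviving edge are retained as isolated
    nodes unless ``keep_isolated=False``.
    """
    whitelist = set(map(str, node_whitelist))
    if not whitelist:
        raise ConfigurationError("node_whitelist must be non-empty")
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(sorted(whitelist))
    for a, b, s in edges[list(EDGE_COLUMNS)].itertuples(index=False):
        if a in whitelist and b in whitelist and a != b:
            g.add_edge(str(a), str(b), combined_score=int(s))
    if g.number_of_edges() == 0:
        logger.warning("induced network has no edges "
                       "(%d whitelist nodes)", len(whitelist))
    return g


# ---------------------------------------------------------------------------
# centrality metrics
# ---------------------------------------------------------------------------

def degree_centrality(net: nx.Graph) -> dict[str, float]:
    """DC_i = k_i / (N - 1)."""
    n = net.number_of_nodes()
    if n < 2:
        raise ConfigurationError("degree centrality needs at least 2 nodes")
    return {v: net.degree(v) / (n - 1) for v in net.nodes}


def closeness_centrality(net: nx.Graph, conventional: bool = False
                         ) -> dict[str, float]:
    """CC_i = N_c / sum_j d_ij within i's connected component.

    ``conventional=True`` uses the textbook (N_c - 1) numerator instead.
    Isolated nodes get 0.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(net):
        nc = len(comp)
        numer = (nc - 1) if conventional else nc
        for v in comp:
            if nc == 1:
                out[v] = 0.0
                continue
            total = sum(nx.single_source_shortest_path_length(net, v).values())
            out[v] = numer / total
    return out


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness over unordered pairs.

    Endpoints excluded (s != i != t); unreachable pairs contribute 0.
    """
    return {v: float(b) for v, b in
            nx.betweenness_centrality(net, normalized=False).items()}


def eigenvector_centrality(net: nx.Graph, tol: float = 1e-10,
                           max_iter: int = 10000) -> dict[str, float]:
    """Principal adjacency eigenvector of the largest component, unit norm.

    Power iteration on A + I; converges when the iterate moves by less
    than ``tol`` in relative Euclidean norm.  Nodes outside the largest
    component get 0.  When components tie in size the one containing the
    lexicographically smallest node is used.
    """
    if net.number_of_nodes() == 0:
        return {}
    comps = sorted(nx.connected_components(net),
                   key=lambda c: (-len(c), min(c)))
    comp = sorted(comps[0])
    out = {v: 0.0 for v in net.nodes}
    if len(comp) == 1:
        out[comp[0]] = 1.0
        return out
    a = nx.to_numpy_array(net, nodelist=comp)
    x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    for it in range(max_iter):
        x_new = a @ x + x  # A + I keeps the iteration aperiodic
        x_new /= np.linalg.norm(x_new)
        if np.linalg.norm(x_new - x) <= tol * np.linalg.norm(x_new):
            x = x_new
            break
        x = x_new
    else:
        raise ConvergenceError(
            f"eigenvector centrality did not converge in {max_iter} iterations")
    x = np.abs(x)  # principal vector of a connected graph is strictly positive
    x /= np.linalg.norm(x)
    out.update(zip(comp, x.tolist()))
    return out


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """All four metrics per gene plus a connected-component id.

    Components are numbered by decreasing size (ties by smallest member);
    rows are sorted by gene symbol.
    """
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    comp_id = {v: i for i, c in enumerate(comps) for v in c}
    dc = degree_centrality(net)
    cc = closeness_centrality(net)
    bc = betweenness_centrality(net)
    ec = eigenvector_centrality(net)
    genes = sorted(net.nodes)
    return pd.DataFrame({
        "gene": genes,
        "dc": [dc[g] for g in genes],
        "cc": [cc[g] for g in genes],
        "bc": [bc[g] for g in genes],
        "ec": [ec[g] for g in genes],
        "component": [comp_id[g] for g in genes],
    })


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = sorted((min(u, v), max(u, v), d.get("combined_score", ""))
                  for u, v, d in net.edges(data=True))
    pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(
        path, sep="\t", index=False)
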