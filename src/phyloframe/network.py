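"""Weighted functional-interaction networks and seed-set expansion.

Tissue-specific functional interaction networks (HumanBase-style) are
undirected gene graphs whose edge weights in [0, 1] are posterior
confidences that two genes act together in the tissue.  A disease
signature is propagated through such a network by collecting every gene
reachable from a seed gene along short paths whose edges all fall inside
a confidence window — by default first and second neighbors over edges
with weight in [0.2, 0.5].
"""

from __future__ import annotations

import dataclasses
import gzip
import itertools
import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "FunctionalNetwork",
    "NeighborhoodParams",
    "load_network",
    "load_id_map",
    "expand_neighborhood",
    "grid_search_params",
    "DEFAULT_GRID_E",
]

logger = logging.getLogger(__name__)

#: Minimum-edge-weight grid used by the neighborhood parameter search.
DEFAULT_GRID_E: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(11))


@dataclasses.dataclass
class FunctionalNetwork:
    """Undirected weighted gene graph (no self-loops, weights in [0, 1])."""

    graph: nx.Graph
    tissue: str = ""
    dropped_unmapped: int = 0
    dropped_self_loops: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b):
            return float(self.graph[a][b]["weight"])
        return None


@dataclasses.dataclass(frozen=True)
class NeighborhoodParams:
    """Expansion order (path length cap) and edge-confidence window.

    The pipeline default — order 2 with window [0.2, 0.5] — collects first
    and second neighbors connected through mid-confidence edges.
    """

    order: int = 2
    wmin: float = 0.2
    wmax: float = 0.5

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError(f"order must be in {{1,2,3}}, got {self.order}")
        if not (0.0 <= self.wmin <= self.wmax <= 1.0):
            raise ValueError(
                f"need 0 <= wmin <= wmax <= 1, got [{self.wmin}, {self.wmax}]"
            )


def load_id_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column (id, symbol) TSV into a mapping."""
    frame = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    return dict(zip(frame[0], frame[1]))


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_network(
    path: str | Path,
    id_map: Mapping[str, str] | None = None,
    tissue: str = "",
) -> FunctionalNetwork:
    """Load a 3-column (gene, gene, weight) edge list into a graph.

    Endpoints are optionally translated through ``id_map`` (e.g. Entrez id
    to gene symbol); edges with an unmappable endpoint are dropped and
    counted.  Duplicate pairs keep the maximum weight; self-loops (possibly
    created by the id mapping) are dropped and counted.

    Raises
    ------
    ValueError
        On a malformed row, a non-numeric weight, or a weight outside
        [0, 1] — the message carries the 1-based line number.
    """
    path = Path(path)
    graph = nx.Graph()
    dropped_unmapped = 0
    dropped_self = 0
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, w_raw = parts[0], parts[1], parts[2]
            try:
                w = float(w_raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {w_raw!r}") from exc
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    dropped_unmapped += 1
                    continue
                a, b = id_map[a], id_map[b]
            if a == b:
                dropped_self += 1
                continue
            if graph.has_edge(a, b):
                graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
            else:
                graph.add_edge(a, b, weight=w)
    return FunctionalNetwork(
        graph=graph,
        tissue=tissue,
        dropped_unmapped=dropped_unmapped,
        dropped_self_loops=dropped_self,
    )


def expand_neighborhood(
    net: FunctionalNetwork,
    seeds: Iterable[str],
    params: NeighborhoodParams | None = None,
) -> set[str]:
    """Seeds plus all genes reachable within ``order`` qualifying edges.

    A path qualifies only if *every* edge on it has weight inside
    ``[wmin, wmax]`` (breadth-first search over the window-restricted
    subgraph).  Seeds absent from the network contribute no neighbors but
    are always retained in the output.
    """
    params = params or NeighborhoodParams()
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = seeds - set(net.graph.nodes)
    if missing:
        logger.warning("%d seed gene(s) absent from the network", len(missing))

    result = set(seeds)
    frontier = seeds - missing
    g = net.graph
    for _ in range(params.order):
        nxt: set[str] = set()
        for node in frontier:
            for nbr, attrs in g[node].items():
                if params.wmin <= attrs["weight"] <= params.wmax and nbr not in result:
                    nxt.add(nbr)
        result |= nxt
        frontier = nxt
        if not frontier:
            break
    return result


def grid_search_params(
    train_batches: Sequence,
    eval_fn: Callable[[NeighborhoodParams, object], float],
    grid_N: Sequence[int] = (1, 2, 3),
    grid_E: Sequence[float] = DEFAULT_GRID_E,
) -> tuple[NeighborhoodParams, pd.DataFrame]:
    """Pick the (order, minimum edge weight) pair maximizing mean AUC.

    ``eval_fn(params, batch)`` must return the AUC of the model trained on
    that batch under those neighborhood parameters.  In grid mode each E
    value is a *minimum* edge weight (window [E, 1.0]).  The mean is taken
    over all supplied batches; ties are broken toward smaller order, then
    smaller E.  Returns the winning params and the full score table.
    """
    grid_N = list(grid_N)
    grid_E = list(grid_E)
    if not grid_N or not grid_E:
        raise ValueError("empty parameter grid")
    if not train_batches:
        raise ValueError("need at least one training batch")

    rows = []
    for n, e in itertools.product(grid_N, grid_E):
        params = NeighborhoodParams(order=n, wmin=e, wmax=1.0)
        scores = [eval_fn(params, batch) for batch in train_batches]
        rows.append({"order": n, "wmin": e, "mean_auc": float(pd.Series(scores).mean())})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_auc", "order", "wmin"], ascending=[False, True, True]
    ).iloc[0]
    return (
        NeighborhoodParams(order=int(best["order"]), wmin=float(best["wmin"]), wmax=1.0),
        table,
    )
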