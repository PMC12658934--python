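"""Least-cost dispersal corridors on an edge-density conductance surface.

A :class:`~beecorridors.landcover.ProportionGrid` (share of fine cells that
are seminatural LLS or forest edge) is read as a conductance surface: cells
rich in linear habitat are permeable, empty matrix is nearly impassable.
Movement is modelled on the 8-neighborhood grid graph; the conductance of a
step between neighboring cells is the arithmetic mean of the two cell
values divided by the center distance (1 or sqrt(2) cell units), and edge
*cost* is the reciprocal 1/x of that conductance, so costs blow up as the
proportion of linear habitat shrinks.  Zero proportions are floored at a
small ``eps`` so the graph stays connected and any positive-proportion
detour beats crossing empty matrix.

Two corridor metrics are reported per least-cost path (LCP): geometric
length of the center-to-center polyline, and accumulated travel cost, the
sum of (1 - x) over path cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from beecorridors.landcover import ProportionGrid

DEFAULT_EPS = 1e-6

#: 8-neighborhood offsets (row, col) — E, SE, S, SW paired with symmetry.
_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class ConductanceGraph:
    """Sparse 8-neighbor cost graph over a proportion grid.

    Node ``r * n_cols + c`` is cell ``(r, c)``; edge weights are
    ``d_ij / mean(x_i, x_j)`` with ``x`` floored at ``eps``.
    """

    costs: sparse.csr_matrix
    x: np.ndarray  # floored proportions, flattened
    shape: tuple[int, int]
    cell_size: float
    origin: tuple[float, float]
    eps: float

    def node(self, cell: tuple[int, int]) -> int:
        r, c = cell
        n_rows, n_cols = self.shape
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"cell {cell} out of bounds for {self.shape}")
        return r * n_cols + c

    def cell(self, node: int) -> tuple[int, int]:
        n_cols = self.shape[1]
        return divmod(int(node), n_cols)


@dataclass
class CorridorPath:
    """Ordered cell trace of a least-cost path.

    ``length`` is the meters of the polyline through cell centers,
    ``cost`` the sum of (1 - x) over the path's cells (endpoints
    included, each visited cell counted once), and ``graph_cost`` the sum
    of 1/conductance edge weights actually minimized.
    """

    cells: list[tuple[int, int]]
    length: float
    cost: float
    graph_cost: float


def build_graph(grid: ProportionGrid, eps: float = DEFAULT_EPS) -> ConductanceGraph:
    """Build the 8-neighbor conductance/cost graph from a proportion grid.

    Conductance between neighbors i, j is ``mean(x_i, x_j) / d_ij`` with
    ``d_ij`` in {1, sqrt(2)} cell units; the edge weight stored is the
    cost ``1 / conductance``.  Proportions are floored at ``eps`` before
    averaging, keeping all weights finite and the graph connected.
    """
    if not 0 < eps < 1:
        raise ValueError("eps must be in (0, 1)")
    n_rows, n_cols = grid.shape
    x = np.maximum(grid.values, eps).ravel()
    rows_i, rows_j, w = [], [], []
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    for dr, dc in _OFFSETS:
        src = idx[max(0, -dr) : n_rows - max(0, dr), max(0, -dc) : n_cols - max(0, dc)]
        dst = idx[max(0, dr) :, max(0, dc) :][: src.shape[0], : src.shape[1]]
        d = np.sqrt(dr * dr + dc * dc)
        cond = (x[src.ravel()] + x[dst.ravel()]) / 2.0 / d
        rows_i.append(src.ravel())
        rows_j.append(dst.ravel())
        w.append(1.0 / cond)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(w)
    n = n_rows * n_cols
    costs = sparse.csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    return ConductanceGraph(costs, x, (n_rows, n_cols), grid.cell_size, grid.origin, eps)


def _trace(predecessors: np.ndarray, src: int, dst: int) -> list[int]:
    path = [dst]
    while path[-1] != src:
        prev = int(predecessors[path[-1]])
        if prev < 0:
            raise RuntimeError("no path found (graph disconnected?)")
        path.append(prev)
    path.reverse()
    return path


def _path_from_nodes(graph: ConductanceGraph, nodes: list[int]) -> CorridorPath:
    cells = [graph.cell(n) for n in nodes]
    arr = np.asarray(cells, dtype=float)
    if len(cells) > 1:
        steps = np.hypot(*np.diff(arr, axis=0).T)
        length = float(steps.sum() * graph.cell_size)
        graph_cost = float(
            sum(graph.costs[a, b] for a, b in zip(nodes[:-1], nodes[1:]))
        )
    else:
        length = 0.0
        graph_cost = 0.0
    cost = float((1.0 - np.minimum(graph.x[nodes], 1.0)).sum())
    return CorridorPath(cells, length, cost, graph_cost)


def least_cost_path(
    graph: ConductanceGraph, src: tuple[int, int], dst: tuple[int, int]
) -> CorridorPath:
    """Dijkstra least-cost path between two cells.

    A degenerate ``src == dst`` query returns the single-cell path with
    zero length and cost ``1 - x_src``.
    """
    s, t = graph.node(src), graph.node(dst)
    if s == t:
        return _path_from_nodes(graph, [s])
    _, pred = dijkstra(
        graph.costs, directed=False, indices=s, return_predecessors=True
    )
    return _path_from_nodes(graph, _trace(pred, s, t))


def corridor_metrics(
    path: CorridorPath, grid: ProportionGrid
) -> tuple[float, float]:
    """(length_km, cost) of a corridor path on its grid.

    Length sums center-to-center steps (``cell_size`` for rook moves,
    ``sqrt(2) * cell_size`` diagonally); cost sums ``1 - x`` over the
    path's cells, endpoints included.
    """
    arr = np.asarray(path.cells, dtype=float)
    if len(path.cells) > 1:
        length_km = float(np.hypot(*np.diff(arr, axis=0).T).sum()) * grid.cell_size / 1000.0
    else:
        length_km = 0.0
    rows, cols = np.asarray(path.cells, dtype=int).T
    cost = float((1.0 - grid.values[rows, cols]).sum())
    return length_km, cost


def geographic_distance(site_i, site_j) -> float:
    """Euclidean distance in km between two sites with projected metric
    ``x``/``y`` attributes (or mappings)."""

    def _xy(s):
        if hasattr(s, "x"):
            return float(s.x), float(s.y)
        return float(s["x"]), float(s["y"])

    (xi, yi), (xj, yj) = _xy(site_i), _xy(site_j)
    return float(np.hypot(xi - xj, yi - yj) / 1000.0)


def pairwise_distances(
    sites: pd.DataFrame,
    grids: dict[str, ProportionGrid],
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Geographic and least-cost distances for all within-country site pairs.

    Parameters
    ----------
    sites
        Site table with columns ``id``, ``x``, ``y``, ``country``.
    grids
        Mapping of LLS map name (e.g. ``"lls"``, ``"forest"``) to its
        :class:`ProportionGrid`; one LCP length and cost column is emitted
        per map, named ``lcp_len_<name>_km`` / ``lcp_cost_<name>``.

    Returns
    -------
    DataFrame
        One row per unordered same-country pair (``site_i < site_j`` by
        table order) with ``geo_km`` and the per-map corridor metrics.
        Sites are snapped to the coarse cell containing them; corridor
        lengths are center-to-center.
    """
    sites = sites.reset_index(drop=True)
    graphs = {name: build_graph(g, eps=eps) for name, g in grids.items()}

    # snap each site once per grid; all grids normally share geometry
    snapped: dict[str, list[int]] = {}
    for name, g in grids.items():
        nodes = []
        for _, s in sites.iterrows():
            try:
                cell = g.cell_of(float(s["x"]), float(s["y"]))
            except ValueError as exc:
                raise ValueError(f"site {s['id']!r} lies outside raster {name!r}") from exc
            nodes.append(graphs[name].node(cell))
        snapped[name] = nodes

    records = []
    for country, group in sites.groupby("country", sort=False):
        order = group.index.to_list()
        # one Dijkstra sweep per source site per grid
        for name, graph in graphs.items():
            nodes = snapped[name]
            srcs = sorted({nodes[i] for i in order})
            dist_mat, pred_mat = dijkstra(
                graph.costs, directed=False, indices=srcs,
                return_predecessors=True,
            )
            src_row = {s: k for k, s in enumerate(srcs)}
            for a_pos, i in enumerate(order):
                for j in order[a_pos + 1 :]:
                    ni, nj = nodes[i], nodes[j]
                    if ni == nj:
                        path = _path_from_nodes(graph, [ni])
                    else:
                        node_seq = _trace(pred_mat[src_row[ni]], ni, nj)
                        path = _path_from_nodes(graph, node_seq)
                    length_km, cost = corridor_metrics(path, grids[name])
                    records.append(
                        {
                            "site_i": sites.loc[i, "id"],
                            "site_j": sites.loc[j, "id"],
                            "country": country,
                            f"lcp_len_{name}_km": length_km,
                            f"lcp_cost_{name}": cost,
                        }
                    )

    out = pd.DataFrame(records)
    out = out.groupby(["site_i", "site_j", "country"], sort=False, as_index=False).first()
    geo = []
    pos = {sid: k for k, sid in enumerate(sites["id"])}
    for _, row in out.iterrows():
        si = sites.loc[pos[row["site_i"]]]
        sj = sites.loc[pos[row["site_j"]]]
        geo.append(geographic_distance(si, sj))
    out.insert(3, "geo_km", geo)
    return out
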