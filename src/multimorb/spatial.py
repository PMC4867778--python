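"""Spatial adjacency structures, ICAR quadratic forms, and Moran's I.

Small-area disease mapping rests on a notion of which areas are neighbours.
This module holds the adjacency graph (binary contiguity by default, weighted
pairs accepted), generates regular lattices for synthetic studies, evaluates
the intrinsic conditional autoregressive (ICAR) joint log density in its
pairwise-difference form, and computes Moran's I spatial autocorrelation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "build_lattice_graph",
    "read_adjacency",
    "write_adjacency",
    "icar_log_density",
    "icar_quadratic",
    "morans_i",
    "sample_icar",
]


class AdjacencyParseError(ValueError):
    """Raised when an adjacency file is malformed; the message names the line."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric spatial interaction structure c_ab between areas.

    Areas are 0-based indices ``0 .. n_areas-1``.  ``edges`` holds unordered
    pairs ``(a, b)`` with ``a < b``; ``weights`` is parallel to ``edges``
    (binary contiguity uses weight 1 throughout).  Isolated areas are legal
    but flagged with a warning: the conditional ICAR variance kappa/degree is
    undefined there and such areas contribute nothing to the quadratic form.
    """

    n_areas: int
    edges: tuple[tuple[int, int], ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be a positive integer")
        canon = []
        seen = set()
        for e in self.edges:
            a, b = int(e[0]), int(e[1])
            if a == b:
                raise ValueError(f"self-loop at area {a}")
            if not (0 <= a < self.n_areas and 0 <= b < self.n_areas):
                raise ValueError(f"edge ({a},{b}) references area >= n_areas={self.n_areas}")
            pair = (min(a, b), max(a, b))
            if pair in seen:
                raise ValueError(f"duplicate edge {pair}")
            seen.add(pair)
            canon.append(pair)
        w = tuple(float(x) for x in (self.weights if self.weights else (1.0,) * len(canon)))
        if len(w) != len(canon):
            raise ValueError("weights must parallel edges")
        if any(x < 0 for x in w):
            raise ValueError("weights must be nonnegative")
        order = sorted(range(len(canon)), key=lambda i: canon[i])
        object.__setattr__(self, "edges", tuple(canon[i] for i in order))
        object.__setattr__(self, "weights", tuple(w[i] for i in order))
        iso = self.isolated_areas()
        if iso.size:
            logger.warning(
                "graph has %d isolated area(s) (e.g. %d): ICAR conditional "
                "variance undefined there; contribution set to 0",
                iso.size,
                int(iso[0]),
            )

    # -- derived structure ------------------------------------------------

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, w) arrays over unordered edges."""
        if not self.edges:
            return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
        ij = np.asarray(self.edges, dtype=int)
        return ij[:, 0], ij[:, 1], np.asarray(self.weights, dtype=float)

    def degrees(self) -> np.ndarray:
        """Weighted degree sum_b c_ab per area."""
        deg = np.zeros(self.n_areas)
        i, j, w = self.edge_arrays()
        np.add.at(deg, i, w)
        np.add.at(deg, j, w)
        return deg

    def isolated_areas(self) -> np.ndarray:
        return np.flatnonzero(self.degrees() == 0)

    def neighbor_lists(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per area: (array of neighbour indices, parallel weights)."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_areas)]
        wts: list[list[float]] = [[] for _ in range(self.n_areas)]
        for (a, b), w in zip(self.edges, self.weights):
            nbrs[a].append(b)
            wts[a].append(w)
            nbrs[b].append(a)
            wts[b].append(w)
        return [(np.asarray(n, int), np.asarray(w, float)) for n, w in zip(nbrs, wts)]

    def n_components(self) -> int:
        """Number of connected components (isolated areas count singly)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return nx.number_connected_components(g)

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric A x A weight matrix (small graphs / cross-checks)."""
        c = np.zeros((self.n_areas, self.n_areas))
        i, j, w = self.edge_arrays()
        c[i, j] = w
        c[j, i] = w
        return c


def build_lattice_graph(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """Rook-contiguity graph of a regular ``n_rows`` x ``n_cols`` grid.

    Areas are indexed row-major; cells sharing an edge (not a corner) are
    neighbours.  Stands in for real small-area contiguity in synthetic runs.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            a = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((a, a + 1))
            if r + 1 < n_rows:
                edges.append((a, a + n_cols))
    return AdjacencyGraph(n_rows * n_cols, tuple(edges))


# -- file dialects --------------------------------------------------------


def write_adjacency(graph: AdjacencyGraph, path, dialect: str = "edge-list-csv") -> None:
    """Write ``graph`` as an edge-list CSV (0-based ids) or GAL (1-based ids)."""
    if dialect == "edge-list-csv":
        with open(path, "w") as fh:
            fh.write(f"# n_areas={graph.n_areas}\n")
            fh.write("area_a,area_b,weight\n")
            for (a, b), w in zip(graph.edges, graph.weights):
                fh.write(f"{a},{b},{w:g}\n")
    elif dialect == "gal":
        nbrs = graph.neighbor_lists()
        with open(path, "w") as fh:
            fh.write(f"{graph.n_areas}\n")
            for a, (nn, _) in enumerate(nbrs):
                fh.write(f"{a + 1} {len(nn)}\n")
                fh.write(" ".join(str(int(b) + 1) for b in sorted(nn)) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_adjacency(path, dialect: str = "edge-list-csv", n_areas: int | None = None) -> AdjacencyGraph:
    """Read an adjacency graph; inverse of :func:`write_adjacency`.

    Edge-list CSV: optional ``# n_areas=A`` comment line, header
    ``area_a,area_b[,weight]``, one unordered 0-based pair per row.
    GAL: standard header + neighbour-list layout with 1-based ids.
    Malformed input raises :class:`AdjacencyParseError` naming the line.
    """
    if dialect == "edge-list-csv":
        return _read_edge_csv(path, n_areas)
    if dialect == "gal":
        return _read_gal(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_edge_csv(path, n_areas: int | None) -> AdjacencyGraph:
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_areas=" in line and n_areas is None:
                    try:
                        n_areas = int(line.split("n_areas=")[1].split()[0])
                    except ValueError as exc:
                        raise AdjacencyParseError(f"line {lineno}: bad n_areas comment") from exc
                continue
            parts = [p.strip() for p in line.split(",")]
            if not header_seen:
                header_seen = True
                if parts[0].lower() == "area_a":
                    continue
            try:
                a, b = int(parts[0]), int(parts[1])
            except (ValueError, IndexError) as exc:
                raise AdjacencyParseError(f"line {lineno}: expected 'area_a,area_b[,weight]'") from exc
            if a == b:
                raise AdjacencyParseError(f"line {lineno}: self-loop at area {a}")
            w = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
            edges.append((a, b))
            weights.append(w)
    if n_areas is None:
        n_areas = 1 + max((max(e) for e in edges), default=0)
    for lineno_free, (a, b) in enumerate(edges):
        if a >= n_areas or b >= n_areas:
            raise AdjacencyParseError(f"edge ({a},{b}) references unknown area id >= {n_areas}")
    try:
        return AdjacencyGraph(n_areas, tuple(edges), tuple(weights))
    except ValueError as exc:
        raise AdjacencyParseError(str(exc)) from exc


def _read_gal(path) -> AdjacencyGraph:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise AdjacencyParseError("line 1: empty GAL file")
    header = lines[0].split()
    # libpysal-style headers are "0 n file key"; plain headers are just "n"
    try:
        n = int(header[1]) if len(header) >= 2 else int(header[0])
    except ValueError as exc:
        raise AdjacencyParseError("line 1: cannot parse GAL header") from exc
    nbrs: dict[int, set[int]] = {}
    i = 1
    lineno = 2
    while i < len(lines):
        head = lines[i].split()
        if len(head) != 2:
            raise AdjacencyParseError(f"line {lineno}: expected 'area_id n_neighbours'")
        try:
            aid, k = int(head[0]), int(head[1])
        except ValueError as exc:
            raise AdjacencyParseError(f"line {lineno}: bad area/neighbour count") from exc
        if not (1 <= aid <= n):
            raise AdjacencyParseError(f"line {lineno}: area id {aid} outside 1..{n}")
        if k > 0:
            if i + 1 >= len(lines):
                raise AdjacencyParseError(f"line {lineno + 1}: missing neighbour list for area {aid}")
            try:
                ns = [int(t) for t in lines[i + 1].split()]
            except ValueError as exc:
                raise AdjacencyParseError(f"line {lineno + 1}: bad neighbour id") from exc
            if len(ns) != k:
                raise AdjacencyParseError(
                    f"line {lineno + 1}: area {aid} declares {k} neighbours, lists {len(ns)}"
                )
            for b in ns:
                if not (1 <= b <= n):
                    raise AdjacencyParseError(f"line {lineno + 1}: neighbour id {b} outside 1..{n}")
                if b == aid:
                    raise AdjacencyParseError(f"line {lineno + 1}: self-loop at area {aid}")
            nbrs[aid - 1] = set(x - 1 for x in ns)
            i += 2
            lineno += 2
        else:
            nbrs[aid - 1] = set()
            i += 1
            lineno += 1
    edges = set()
    for a, ns in nbrs.items():
        for b in ns:
            if a not in nbrs.get(b, set()):
                raise AdjacencyParseError(f"asymmetric input: {a + 1} lists {b + 1} but not conversely")
            edges.add((min(a, b), max(a, b)))
    return AdjacencyGraph(n, tuple(sorted(edges)))


# -- ICAR ----------------------------------------------------------------


def icar_quadratic(r: np.ndarray, graph: AdjacencyGraph) -> float:
    """Pairwise quadratic form sum_{(a,b) in edges} c_ab (r_a - r_b)^2."""
    i, j, w = graph.edge_arrays()
    if i.size == 0:
        return 0.0
    d = r[i] - r[j]
    return float(np.sum(w * d * d))


def icar_log_density(r: np.ndarray, graph: AdjacencyGraph, kappa: float) -> float:
    """Unnormalized joint ICAR log density -(1/(2 kappa)) sum c_ab (r_a - r_b)^2.

    This is the joint form of the conditional prior r_a | r_[a] ~
    N(mean of neighbours, kappa / degree); the improper normalizing constant
    is dropped, so the value is invariant to adding a constant to ``r``.
    """
    r = np.asarray(r, dtype=float)
    if r.shape != (graph.n_areas,):
        raise ValueError(f"r must have length n_areas={graph.n_areas}")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return -icar_quadratic(r, graph) / (2.0 * kappa)


def sample_icar(graph: AdjacencyGraph, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the ICAR prior under the sum-to-zero constraint.

    Uses the eigenbasis of the graph Laplacian: the ICAR precision is L/kappa,
    so a proper draw on the contrast space has covariance kappa * L^+.  Null
    directions (one per connected component) are excluded and the draw is
    centered.  O(A^3); intended for simulation at synthetic-study scale.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    c = graph.weight_matrix()
    lap = np.diag(c.sum(axis=1)) - c
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    z = rng.standard_normal(int(pos.sum()))
    x = evecs[:, pos] @ (z / np.sqrt(evals[pos])) * math.sqrt(kappa)
    return x - x.mean()


# -- Moran's I ------------------------------------------------------------


def morans_i(values: Sequence[float], graph: AdjacencyGraph, row_standardize: bool = False) -> float:
    """Classical Moran's I with the graph's weights.

    I = (A / S0) * sum_ab w_ab z_a z_b / sum_a z_a^2 with z the centered
    values and S0 the directed weight sum.  ``row_standardize=True`` divides
    each area's outgoing weights by its degree first (config switch; binary
    raw weights are the default).
    """
    z = np.asarray(values, dtype=float)
    if z.shape != (graph.n_areas,):
        raise ValueError(f"values must have length n_areas={graph.n_areas}")
    if not graph.edges:
        raise ValueError("Moran's I undefined on an edgeless graph")
    z = z - z.mean()
    denom = float(np.sum(z * z))
    if denom <= 0:
        raise ValueError("Moran's I undefined for zero-variance values")
    i, j, w = graph.edge_arrays()
    if row_standardize:
        deg = graph.degrees()
        wij = np.where(deg[i] > 0, w / deg[i], 0.0)
        wji = np.where(deg[j] > 0, w / deg[j], 0.0)
        cross = float(np.sum(wij * z[i] * z[j]) + np.sum(wji * z[j] * z[i]))
        s0 = float(np.sum(wij) + np.sum(wji))
    else:
        cross = 2.0 * float(np.sum(w * z[i] * z[j]))
        s0 = 2.0 * float(np.sum(w))
    return (graph.n_areas / s0) * cross / denom
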