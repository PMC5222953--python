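"""Grayordinate spaces, parcellations and connected-component machinery.

A *grayordinate space* is the set of spatial locations an analysis runs on —
cortical surface vertices plus subcortical voxels on real data (91,282 in the
standard dense space), a small 2D lattice in synthetic use.  Only the graph
structure matters downstream: adjacency drives cluster formation, coordinates
are used for smoothing kernels and bump placement in the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _csgraph_cc
from scipy.sparse.csgraph import dijkstra


@dataclass(frozen=True)
class GrayordinateSpace:
    """A set of n vertices with an undirected adjacency structure.

    Parameters
    ----------
    n
        Number of vertices.
    edges
        Integer array of shape (E, 2); unordered vertex pairs.  No self
        loops; endpoints must be < n.
    coordinates
        Optional (n, d) positions, used only for spatial kernels.
    lattice_shape
        Set when the space is a 2D lattice, as (height, width); lets the
        simulator use fast separable smoothing.
    """

    n: int
    edges: np.ndarray
    coordinates: np.ndarray | None = None
    lattice_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        if self.n < 1:
            raise ValueError("space must contain at least one vertex")
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n:
                raise ValueError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loop edges are not allowed")
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape[0] != self.n:
                raise ValueError("coordinates must have one row per vertex")
            object.__setattr__(self, "coordinates", coords)

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse adjacency matrix (0/1 weights)."""
        if not self.edges.size:
            return csr_matrix((self.n, self.n))
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        data = np.ones(i.size)
        return csr_matrix((data, (i, j)), shape=(self.n, self.n))


@dataclass(frozen=True)
class Parcellation:
    """Per-vertex parcel labels in 1..P; parcels are non-overlapping, cover
    the space, and are all non-empty."""

    labels: np.ndarray
    P: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1D array")
        if self.P < 1:
            raise ValueError("parcel count must be positive")
        present = np.unique(labels)
        if present.min() < 1 or present.max() > self.P:
            raise ValueError("labels must lie in 1..P")
        if present.size != self.P:
            missing = sorted(set(range(1, self.P + 1)) - set(present.tolist()))
            raise ValueError(f"empty parcels: {missing}")

    @property
    def n(self) -> int:
        return self.labels.size

    def vertices(self, p: int) -> np.ndarray:
        """Indices of the vertices in parcel p (1-based parcel id)."""
        return np.flatnonzero(self.labels == p)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.P + 1)[1:]


@dataclass(frozen=True)
class ClusterSet:
    """Disjoint connected clusters of vertices with their masses."""

    clusters: list
    masses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        if len(self.clusters) != self.masses.size:
            raise ValueError("one mass per cluster required")


def build_lattice_space(width: int, height: int) -> GrayordinateSpace:
    """A width x height 2D lattice with 4-neighbour adjacency.

    Vertex v = row * width + col; coordinates are (col, row) on the integer
    grid.  This is the synthetic stand-in for a cortical surface mesh.
    """
    if width < 1 or height < 1:
        raise ValueError("lattice dimensions must be positive")
    n = width * height
    idx = np.arange(n).reshape(height, width)
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    edges = np.concatenate([horiz, vert], axis=0) if n > 1 else np.empty((0, 2), int)
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    coords = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
    return GrayordinateSpace(n=n, edges=edges, coordinates=coords,
                             lattice_shape=(height, width))


def winner_takes_all(component_maps: np.ndarray) -> Parcellation:
    """Assign each vertex to the component with the largest value there.

    Ties are broken by the lowest component index.  Labels are 1-based.
    Raises if any component wins nowhere (empty parcel).
    """
    maps = np.asarray(component_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 1:
        raise ValueError("need a non-empty K x n array of component maps")
    labels = np.argmax(maps, axis=0) + 1
    return Parcellation(labels=labels, P=maps.shape[0])


def connected_components(space: GrayordinateSpace, active: np.ndarray) -> list:
    """Partition the active vertices into maximal connected sets.

    Connectivity is edge-sharing under the space's adjacency.  Returns a
    list of sorted integer arrays ordered by their smallest vertex.
    """
    active = np.asarray(active, dtype=bool)
    if active.size != space.n:
        raise ValueError("mask length must equal the number of vertices")
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    sub = space.adjacency()[idx][:, idx]
    n_comp, labels = _csgraph_cc(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def graph_ball(space: GrayordinateSpace, centre: int, radius: int) -> np.ndarray:
    """Boolean mask of vertices within graph distance `radius` of `centre`.

    A graph ball is always connected, which is what lesion masks require.
    """
    if not 0 <= centre < space.n:
        raise ValueError("centre out of range")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        mask = np.zeros(space.n, dtype=bool)
        mask[centre] = True
        return mask
    dist = dijkstra(space.adjacency(), directed=False, unweighted=True,
                    indices=centre, limit=radius)
    return np.isfinite(dist)


def write_parcellation(path, parcellation: Parcellation) -> None:
    """One label per line, 1-based, plain text."""
    np.savetxt(path, parcellation.labels, fmt="%d")


def read_parcellation(path) -> Parcellation:
    labels = np.loadtxt(path, dtype=np.int64, ndmin=1)
    return Parcellation(labels=labels, P=int(labels.max()))
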