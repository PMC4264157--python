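"""Plunge-needle electrode grid geometry.

A recording array is a set of transmural needles on a 2-D plane, each
carrying up to three recording layers (endocardial, midwall, epicardial).
Sites are (needle, layer) pairs; adjacency and geodesic distances over the
site graph drive both the synthetic wavefront generator and the mechanism
classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import InvalidArgumentError

#: Transmural layer labels, ordered from inside out.
LAYERS = ("endo", "mid", "epi")

#: Default number of needles in the full array.
DEFAULT_N_NEEDLES = 23

#: Default in-plane inter-needle spacing (mm); arrays use 6-10 mm.
DEFAULT_SPACING_MM = 8.0

#: Transmural distance between consecutive layers (mm).
DEFAULT_LAYER_DEPTH_MM = 4.0

#: Needles closer than this multiple of the spacing are in-plane neighbors.
ADJACENCY_FACTOR = 1.5


@dataclass(frozen=True, order=True)
class Site:
    """One recording site: a needle index and a transmural layer."""

    needle: int
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InvalidArgumentError(f"unknown layer {self.layer!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"N{self.needle}:{self.layer}"


@dataclass(frozen=True)
class ElectrodeGrid:
    """Needle positions plus the per-needle layer stack.

    Parameters
    ----------
    positions
        ``(n_needles, 2)`` array of in-plane needle coordinates in mm.
    layers
        Ordered layer labels shared by every needle (endo -> epi).
    spacing_mm
        Nominal inter-needle spacing used for the adjacency criterion.
    layer_depth_mm
        Transmural distance between consecutive layers.
    """

    positions: np.ndarray
    layers: tuple[str, ...] = LAYERS
    spacing_mm: float = DEFAULT_SPACING_MM
    layer_depth_mm: float = DEFAULT_LAYER_DEPTH_MM

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise InvalidArgumentError("positions must be a (n, 2) array with n >= 1")
        if self.spacing_mm <= 0:
            raise InvalidArgumentError("spacing must be positive")
        if not 1 <= len(self.layers) <= 3:
            raise InvalidArgumentError("each needle carries 1-3 layers")
        order = [LAYERS.index(l) for l in self.layers]
        if order != sorted(order) or len(set(order)) != len(order):
            raise InvalidArgumentError("layers must follow endo -> mid -> epi order")

    @property
    def n_needles(self) -> int:
        return self.positions.shape[0]

    @cached_property
    def sites(self) -> tuple[Site, ...]:
        """All sites, needle-major, layers inside-out."""
        return tuple(
            Site(n, layer)
            for n in range(self.n_needles)
            for layer in self.layers
        )

    @cached_property
    def site_index(self) -> dict[Site, int]:
        return {s: i for i, s in enumerate(self.sites)}

    @property
    def n_sites(self) -> int:
        return self.n_needles * len(self.layers)

    def site_position(self, site: Site) -> np.ndarray:
        """3-D position (mm): in-plane coordinates plus transmural depth."""
        x, y = self.positions[site.needle]
        depth = LAYERS.index(site.layer) * self.layer_depth_mm
        return np.array([x, y, depth])

    def needles_adjacent(self, a: int, b: int) -> bool:
        if a == b:
            return False
        d = float(np.hypot(*(self.positions[a] - self.positions[b])))
        return d <= ADJACENCY_FACTOR * self.spacing_mm

    def sites_adjacent(self, a: Site, b: Site) -> bool:
        """Layers on one needle are always adjacent; otherwise needles must
        be in-plane neighbors (within 1.5x spacing)."""
        if a == b:
            return False
        if a.needle == b.needle:
            return True
        return self.needles_adjacent(a.needle, b.needle)

    def neighbors(self, site: Site) -> list[Site]:
        return [s for s in self.sites if self.sites_adjacent(site, s)]

    @cached_property
    def geodesic_mm(self) -> np.ndarray:
        """All-pairs shortest-path distance over the site adjacency graph,
        edge weights = 3-D Euclidean distance between adjacent sites."""
        n = self.n_sites
        pos = np.array([self.site_position(s) for s in self.sites])
        rows, cols, vals = [], [], []
        for i, a in enumerate(self.sites):
            for j in range(i + 1, n):
                b = self.sites[j]
                if self.sites_adjacent(a, b):
                    w = float(np.linalg.norm(pos[i] - pos[j]))
                    rows += [i, j]
                    cols += [j, i]
                    vals += [w, w]
        graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
        return shortest_path(graph, method="D", directed=False)

    def distance_mm(self, a: Site, b: Site) -> float:
        """Geodesic (graph) distance between two sites in mm."""
        return float(self.geodesic_mm[self.site_index[a], self.site_index[b]])


def make_grid(
    n_needles: int = DEFAULT_N_NEEDLES,
    spacing_mm: float = DEFAULT_SPACING_MM,
    layers: tuple[str, ...] = LAYERS,
    layer_depth_mm: float = DEFAULT_LAYER_DEPTH_MM,
) -> ElectrodeGrid:
    """Build a deterministic rectangular needle layout.

    Needles fill a ``ceil(sqrt(n))``-wide rectangle row-major; the default
    23-needle array is a 5x5 lattice minus the last two cells.
    """
    if n_needles < 1:
        raise InvalidArgumentError("need at least one needle")
    if spacing_mm <= 0:
        raise InvalidArgumentError("spacing must be positive")
    width = math.ceil(math.sqrt(n_needles))
    positions = np.array(
        [((i % width) * spacing_mm, (i // width) * spacing_mm) for i in range(n_needles)]
    )
    return ElectrodeGrid(
        positions=positions,
        layers=tuple(layers),
        spacing_mm=float(spacing_mm),
        layer_depth_mm=float(layer_depth_mm),
    )
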