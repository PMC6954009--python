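"""Landscape construction: continuous diffusive grids and patchy networks.

Two idealized spatially extended ecosystems carry the local dynamics:

* a **continuous landscape** — a square domain (default 100 m x 100 m,
  discretized on a 50 x 50 lattice) over which the resource disperses by
  diffusion with rate ``D`` (m^2 day^-1);
* a **patchy landscape** — well-mixed 1 m^2 patches (default 100) linked
  by the edges of an Erdos-Renyi random graph (default 4% connectivity),
  exchanging biomass along edges at rate ``d`` (day^-1).

Spatial heterogeneity enters through the local maximum growth rate r:
on the grid, 25 equal blocks receive i.i.d. U[r_low, r_high] draws which
are then blended with a Gaussian smoothing kernel; on the network, each
patch draws its own rate from the same distribution.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from respulse.local_model import LocalParams

__all__ = [
    "ContinuousLandscape",
    "PatchyLandscape",
    "HeterogeneitySpec",
    "make_continuous",
    "make_patchy",
    "make_random_network",
    "heterogeneous_r_field",
    "patch_growth_rates",
    "select_focus_patch",
    "write_edge_list",
    "read_edge_list",
    "write_field",
    "read_field",
]

logger = logging.getLogger(__name__)

_MAX_NETWORK_ATTEMPTS = 10_000


@dataclass
class ContinuousLandscape:
    """Gridded biomass and growth-rate fields with diffusive dispersal.

    ``params.r`` is the reference growth rate; ``r_field`` holds the
    per-cell rates actually used (uniform for a homogeneous landscape).
    """

    biomass: np.ndarray          # (n_y, n_x), g m^-2
    r_field: np.ndarray          # (n_y, n_x), day^-1
    D: float                     # m^2 day^-1
    cell_size: float             # m
    params: LocalParams
    boundary: str = "zero-flux"  # or "periodic"

    def __post_init__(self) -> None:
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.r_field = np.asarray(self.r_field, dtype=float)
        if self.biomass.shape != self.r_field.shape:
            raise ValueError("biomass and r_field shapes differ")
        if self.biomass.ndim != 2:
            raise ValueError("fields must be 2-D")
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be non-negative")
        if np.any(self.r_field <= 0):
            raise ValueError("growth rates must be positive")
        if self.cell_size <= 0 or self.D < 0:
            raise ValueError("cell_size must be positive and D non-negative")
        if self.boundary not in ("zero-flux", "periodic"):
            raise ValueError(f"unknown boundary condition {self.boundary!r}")

    @property
    def n_y(self) -> int:
        return self.biomass.shape[0]

    @property
    def n_x(self) -> int:
        return self.biomass.shape[1]

    @property
    def n_sites(self) -> int:
        return self.biomass.size

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in metres."""
        return (self.n_x * self.cell_size, self.n_y * self.cell_size)

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    @property
    def total_area(self) -> float:
        return self.n_sites * self.cell_area

    def with_biomass(self, biomass: np.ndarray) -> "ContinuousLandscape":
        return replace(self, biomass=np.asarray(biomass, dtype=float))


@dataclass
class PatchyLandscape:
    """Well-mixed patches coupled along the edges of an undirected graph.

    All patches have unit area (1 m^2); the dispersal term for patch i is
    ``d * sum_j (N_j - N_i)`` over its graph neighbours j.
    """

    biomass: np.ndarray          # (n_patches,), g m^-2
    r_vec: np.ndarray            # (n_patches,), day^-1
    adjacency: sp.csr_matrix     # symmetric 0/1, zero diagonal
    d: float                     # day^-1
    params: LocalParams
    patch_area: float = 1.0      # m^2

    def __post_init__(self) -> None:
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.r_vec = np.asarray(self.r_vec, dtype=float)
        self.adjacency = sp.csr_matrix(self.adjacency)
        n = self.biomass.size
        if self.r_vec.size != n or self.adjacency.shape != (n, n):
            raise ValueError("biomass, r_vec and adjacency sizes disagree")
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be non-negative")
        if np.any(self.r_vec <= 0):
            raise ValueError("growth rates must be positive")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have zero diagonal (no self-links)")
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.d < 0:
            raise ValueError("dispersal rate must be non-negative")

    @property
    def n_patches(self) -> int:
        return self.biomass.size

    @property
    def n_sites(self) -> int:
        return self.biomass.size

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def neighbours(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i]:self.adjacency.indptr[i + 1]
        ]

    def with_biomass(self, biomass: np.ndarray) -> "PatchyLandscape":
        return replace(self, biomass=np.asarray(biomass, dtype=float))


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Spatial heterogeneity in the maximum growth rate r.

    The continuous landscape is split into ``block_grid x block_grid``
    equal squares; each block draws r ~ U[r_low, r_high] and the block
    field is smoothed with a Gaussian kernel of bandwidth ``sigma_m``
    (metres), truncated at 3 sigma and renormalized at the domain edges.
    """

    block_grid: int = 5
    r_low: float = 0.8
    r_high: float = 1.2
    sigma_m: float = 10.0
    truncate: float = 3.0

    def __post_init__(self) -> None:
        if self.r_low > self.r_high:
            raise ValueError("r_low must not exceed r_high")
        if self.r_low <= 0:
            raise ValueError("growth rates must be positive")
        if self.sigma_m <= 0:
            raise ValueError("smoothing bandwidth must be positive")
        if self.block_grid < 1:
            raise ValueError("block grid must be at least 1")


def make_continuous(
    D: float,
    params: LocalParams,
    n_x: int = 50,
    n_y: int = 50,
    cell_size: float = 2.0,
    r: float | np.ndarray | None = None,
    boundary: str = "zero-flux",
) -> ContinuousLandscape:
    """Build a continuous landscape with uniform (zero) initial biomass.

    ``r`` may be a scalar (broadcast to every cell) or a full (n_y, n_x)
    field; by default ``params.r`` is used.  Callers initialize biomass
    to the settled high state via :func:`respulse.dynamics.settle_to_equilibrium`.
    """
    if n_x < 1 or n_y < 1 or cell_size <= 0:
        raise ValueError("grid geometry must be positive")
    if D < 0:
        raise ValueError("diffusion rate must be non-negative")
    if r is None:
        r = params.r
    r_field = np.broadcast_to(np.asarray(r, dtype=float), (n_y, n_x)).copy()
    return ContinuousLandscape(
        biomass=np.zeros((n_y, n_x)),
        r_field=r_field,
        D=D,
        cell_size=cell_size,
        params=params,
        boundary=boundary,
    )


def make_patchy(
    d: float,
    params: LocalParams,
    adjacency: sp.spmatrix,
    r: float | np.ndarray | None = None,
) -> PatchyLandscape:
    """Build a patchy landscape on an existing adjacency structure."""
    adjacency = sp.csr_matrix(adjacency)
    n = adjacency.shape[0]
    if r is None:
        r = params.r
    r_vec = np.broadcast_to(np.asarray(r, dtype=float), (n,)).copy()
    return PatchyLandscape(
        biomass=np.zeros(n),
        r_vec=r_vec,
        adjacency=adjacency,
        d=d,
        params=params,
    )


def make_random_network(
    n_patches: int = 100,
    edge_probability: float = 0.04,
    rng: np.random.Generator | int | None = None,
    required_degree: int = 4,
) -> sp.csr_matrix:
    """Erdos-Renyi patch network, resampled until usable.

    Each unordered patch pair is linked independently with
    ``edge_probability``.  Draws are repeated (fresh substream each time)
    until the graph is connected and contains at least one node of
    ``required_degree`` — the focus-patch protocol needs both.  The number
    of regenerations is logged.
    """
    if not 0 < edge_probability <= 1:
        raise ValueError("edge probability must be in (0, 1]")
    rng = np.random.default_rng(rng)
    for attempt in range(1, _MAX_NETWORK_ATTEMPTS + 1):
        g = nx.fast_gnp_random_graph(
            n_patches, edge_probability,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        degrees = np.array([deg for _, deg in g.degree()])
        if nx.is_connected(g) and np.any(degrees == required_degree):
            if attempt > 1:
                logger.info("random network accepted after %d draws", attempt)
            adj = nx.to_scipy_sparse_array(g, format="csr", dtype=float)
            return sp.csr_matrix(adj)
    raise RuntimeError(
        f"no connected network with a degree-{required_degree} node in "
        f"{_MAX_NETWORK_ATTEMPTS} draws (n={n_patches}, p={edge_probability})"
    )


def heterogeneous_r_field(
    spec: HeterogeneitySpec,
    n_x: int = 50,
    n_y: int = 50,
    cell_size: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Blocky-then-smoothed growth-rate field for the continuous landscape.

    The grid must tile exactly into ``block_grid x block_grid`` squares
    (at defaults each 20 m block covers a 10 x 10 cell tile).  Smoothing
    uses a truncated Gaussian renormalized at the edges, so every output
    value is a convex combination of block draws and stays inside
    [r_low, r_high].
    """
    if n_x % spec.block_grid or n_y % spec.block_grid:
        raise ValueError(
            f"grid {n_x}x{n_y} does not tile into {spec.block_grid}x{spec.block_grid} blocks"
        )
    rng = np.random.default_rng(rng)
    blocks = rng.uniform(spec.r_low, spec.r_high, size=(spec.block_grid, spec.block_grid))
    field = np.kron(blocks, np.ones((n_y // spec.block_grid, n_x // spec.block_grid)))

    sigma_cells = spec.sigma_m / cell_size
    # constant-mode numerator / denominator: a truncated kernel renormalized
    # over the part overlapping the domain
    num = gaussian_filter(field, sigma=sigma_cells, mode="constant", cval=0.0,
                          truncate=spec.truncate)
    den = gaussian_filter(np.ones_like(field), sigma=sigma_cells, mode="constant",
                          cval=0.0, truncate=spec.truncate)
    return num / den


def patch_growth_rates(
    n_patches: int,
    r_low: float = 0.8,
    r_high: float = 1.2,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One i.i.d. U[r_low, r_high] growth rate per patch."""
    if r_low > r_high or r_low <= 0:
        raise ValueError("invalid growth-rate bounds")
    rng = np.random.default_rng(rng)
    return rng.uniform(r_low, r_high, size=n_patches)


def select_focus_patch(
    adjacency: sp.spmatrix,
    required_degree: int = 4,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Uniformly random patch with exactly the required degree."""
    adjacency = sp.csr_matrix(adjacency)
    degrees = np.asarray(adjacency.sum(axis=1)).ravel().astype(int)
    candidates = np.flatnonzero(degrees == required_degree)
    if candidates.size == 0:
        raise ValueError(f"no patch of degree {required_degree} in the network")
    rng = np.random.default_rng(rng)
    return int(rng.choice(candidates))


# ---------------------------------------------------------------------------
# plain-text I/O: edge-list CSV for networks, matrix CSV + JSON sidecar for
# fields


def write_edge_list(adjacency: sp.spmatrix, path: str | Path) -> None:
    adjacency = sp.coo_matrix(sp.csr_matrix(adjacency))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for i, j in zip(adjacency.row, adjacency.col):
            if i < j:
                w.writerow([int(i), int(j)])


def read_edge_list(path: str | Path, n_patches: int | None = None) -> sp.csr_matrix:
    edges = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            edges.append((int(row["source"]), int(row["target"])))
    if n_patches is None:
        n_patches = 1 + max(max(e) for e in edges)
    adj = sp.lil_matrix((n_patches, n_patches))
    for i, j in edges:
        adj[i, j] = 1.0
        adj[j, i] = 1.0
    return sp.csr_matrix(adj)


def write_field(field: np.ndarray, path: str | Path, cell_size: float) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(field), delimiter=",")
    meta = {"n_y": int(field.shape[0]), "n_x": int(field.shape[1]),
            "cell_size": float(cell_size)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_field(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    field = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return field, meta
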