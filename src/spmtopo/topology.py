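"""Simplicial representation of the search space and Euler characteristics.

The search space is either a regular lattice restricted to a binary mask
(1D chains, 2D pixel grids, 3D voxel grids) or an arbitrary triangle mesh.
Lattice masks are triangulated once and shared by every downstream
computation: Euler-characteristic (EC) counting, cluster labelling and
smoothness-based intrinsic-volume estimation all see the same topology.

Triangulation conventions
-------------------------
* 2D: every unit square whose 4 corners are in-mask is split into two
  triangles along one diagonal.
* 3D: every unit cube whose 8 corners are in-mask is split into 5
  tetrahedra (a central tetrahedron plus 4 corner tetrahedra).
* The diagonal of every square face joins the two corners whose lattice
  coordinate sum is even; equivalently, the central tetrahedron of every
  cube consists of its 4 even-parity corners.  This single parity rule
  makes neighbouring cubes/squares share identical face diagonals, so the
  decomposition is conforming and introduces no spurious topology.

Excursion sets use the closed (vertex-inclusion) rule: a simplex belongs to
the excursion set at threshold ``u`` iff *all* its vertices have value
``>= u``.  With this rule the EC at ``u -> -inf`` equals the EC of the full
search space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SimplicialComplex",
    "ECCurve",
    "build_complex",
    "mesh_complex",
    "euler_characteristic",
    "ec_curve",
    "count_clusters",
    "l0",
]


@dataclass
class LatticeInfo:
    """Lattice bookkeeping needed by the smoothness LKC estimator.

    ``squares`` stores, per axis pair, the 4 corners of every fully in-mask
    unit square in the fixed local order (00, 10, 01, 11) together with the
    parity of the base corner (which determines the diagonal split).
    ``cubes`` stores the 8 corners of every fully in-mask unit cube indexed
    by local bits ``ix + 2*iy + 4*iz``, plus base parity.
    """

    edges_by_axis: dict = field(default_factory=dict)   # axis -> (n, 2) int
    squares: dict = field(default_factory=dict)         # (a, b) -> dict(corners=(n,4), parity=(n,))
    cubes: np.ndarray | None = None                     # (n, 8) int
    cube_parity: np.ndarray | None = None               # (n,) 0/1


@dataclass
class SimplicialComplex:
    """Conforming simplicial decomposition of the search space.

    Attributes
    ----------
    dim : topological dimension D (simplices up to dimension D are stored).
    n_vertices : number of vertices.
    simplices : maps d -> integer array of shape (n_d, d+1); vertex indices
        within each simplex are sorted ascending.
    coords : optional (n_vertices, k) coordinate array (lattice indices for
        lattice-derived complexes).
    lattice : lattice bookkeeping, present only for lattice complexes.
    """

    dim: int
    n_vertices: int
    simplices: dict
    coords: np.ndarray | None = None
    lattice: LatticeInfo | None = None

    def n_simplices(self, d: int) -> int:
        s = self.simplices.get(d)
        return 0 if s is None else len(s)

    def min_values(self, values: np.ndarray, d: int) -> np.ndarray:
        """Per-simplex minimum of a vertex-valued field (closed-rule births).

        ``values`` may be (n_vertices,) or (n_fields, n_vertices); the
        result has the field axes first and one entry per d-simplex.
        """
        simp = self.simplices[d]
        if simp.size == 0:
            base = np.atleast_2d(values)
            return np.empty(base.shape[:-1] + (0,))
        return np.asarray(values)[..., simp].min(axis=-1)


@dataclass
class ECCurve:
    """Euler characteristic of excursion sets over a threshold grid."""

    thresholds: np.ndarray
    ec: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.ec = np.asarray(self.ec)
        if self.thresholds.shape != self.ec.shape:
            raise ValueError("thresholds and ec must have equal length")


def _axis_edges(mask: np.ndarray, idx: np.ndarray, axis: int) -> np.ndarray:
    lo = [slice(None)] * mask.ndim
    hi = [slice(None)] * mask.ndim
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    both = mask[tuple(lo)] & mask[tuple(hi)]
    v0 = idx[tuple(lo)][both]
    v1 = idx[tuple(hi)][both]
    return np.stack([v0, v1], axis=1)


def _full_squares(mask, idx, coord_sum, a, b):
    """Corners (00, 10, 01, 11 in local (a, b) offsets) of full unit squares."""
    nd = mask.ndim

    def sl(da, db):
        s = [slice(None)] * nd
        s[a] = slice(1, None) if da else slice(None, -1)
        s[b] = slice(1, None) if db else slice(None, -1)
        return tuple(s)

    full = mask[sl(0, 0)] & mask[sl(1, 0)] & mask[sl(0, 1)] & mask[sl(1, 1)]
    corners = np.stack(
        [idx[sl(0, 0)][full], idx[sl(1, 0)][full], idx[sl(0, 1)][full], idx[sl(1, 1)][full]],
        axis=1,
    )
    parity = coord_sum[sl(0, 0)][full] % 2
    return corners, parity


def square_triangles(corners: np.ndarray, parity: np.ndarray):
    """Split squares into 2 triangles along the even-parity diagonal.

    Returns (triangles (2n, 3), diagonals (n, 2)), unsorted vertex order.
    """
    c00, c10, c01, c11 = corners.T
    even = parity == 0
    diag = np.where(even[:, None], np.stack([c00, c11], 1), np.stack([c10, c01], 1))
    tri1 = np.where(even[:, None], np.stack([c00, c10, c11], 1), np.stack([c00, c10, c01], 1))
    tri2 = np.where(even[:, None], np.stack([c00, c01, c11], 1), np.stack([c10, c01, c11], 1))
    return np.concatenate([tri1, tri2], axis=0), diag


# Local cube corners by bit index ix + 2*iy + 4*iz.  Even-parity corners for
# a cube whose base corner has even coordinate sum:
_EVEN_CORNERS = np.array([0, 3, 5, 6])   # (0,0,0) (1,1,0) (1,0,1) (0,1,1)
_ODD_CORNERS = np.array([1, 2, 4, 7])    # (1,0,0) (0,1,0) (0,0,1) (1,1,1)
# cube-edge neighbours of each corner (bit flips)
_NEIGHBOURS = {c: [c ^ 1, c ^ 2, c ^ 4] for c in range(8)}


def _cube_tets(cubes: np.ndarray, parity: np.ndarray):
    """5-tetrahedra decomposition; central tet = even-parity corners.

    Returns (tets (5n, 4), central_tris (4n, 3)).
    """
    tets = []
    tris = []
    for par, central, outer in ((0, _EVEN_CORNERS, _ODD_CORNERS),
                                (1, _ODD_CORNERS, _EVEN_CORNERS)):
        sel = cubes[parity == par]
        if len(sel) == 0:
            continue
        tets.append(sel[:, central])
        for c in outer:
            tets.append(sel[:, [c] + _NEIGHBOURS[c]])
        for face in combinations(central, 3):
            tris.append(sel[:, list(face)])
    tets = np.concatenate(tets, axis=0) if tets else np.empty((0, 4), int)
    tris = np.concatenate(tris, axis=0) if tris else np.empty((0, 3), int)
    return tets, tris


def build_complex(mask: np.ndarray, dim: int | None = None) -> SimplicialComplex:
    """Triangulate a binary lattice mask into a conforming simplicial complex.

    Parameters
    ----------
    mask : boolean array of dimension 1, 2 or 3.
    dim : optional explicit dimension check.

    Vertices are the in-mask lattice sites in C (row-major) order — the same
    order produced by ``values[mask]`` — with 0-based unit-spacing
    coordinates.
    """
    mask = np.asarray(mask).astype(bool)
    if dim is not None and dim != mask.ndim:
        raise ValueError(f"mask has dimension {mask.ndim}, expected {dim}")
    D = mask.ndim
    if D not in (1, 2, 3):
        raise ValueError("only dimensions 1, 2 and 3 are supported")
    if not mask.any():
        raise ValueError("mask is empty")

    nv = int(mask.sum())
    idx = np.full(mask.shape, -1, dtype=np.int64)
    idx[mask] = np.arange(nv)
    coords = np.argwhere(mask)
    coord_sum = np.add.reduce(np.indices(mask.shape), axis=0)

    info = LatticeInfo()
    for a in range(D):
        info.edges_by_axis[a] = _axis_edges(mask, idx, a)
    edges = [info.edges_by_axis[a] for a in range(D)]
    triangles = []
    tets = None

    if D >= 2:
        for a, b in combinations(range(D), 2):
            corners, parity = _full_squares(mask, idx, coord_sum, a, b)
            info.squares[(a, b)] = {"corners": corners, "parity": parity}
            tris, diag = square_triangles(corners, parity)
            triangles.append(tris)
            edges.append(diag)
    if D == 3:
        sls = {}
        for bits in range(8):
            off = [(bits >> ax) & 1 for ax in range(3)]
            sls[bits] = tuple(
                slice(1, None) if o else slice(None, -1) for o in off
            )
        full = np.ones(tuple(s - 1 for s in mask.shape), dtype=bool)
        for bits in range(8):
            full &= mask[sls[bits]]
        cubes = np.stack([idx[sls[bits]][full] for bits in range(8)], axis=1)
        parity = coord_sum[sls[0]][full] % 2
        info.cubes, info.cube_parity = cubes, parity
        tets, central_tris = _cube_tets(cubes, parity)
        triangles.append(central_tris)

    simplices = {0: np.arange(nv, dtype=np.int64)[:, None]}
    simplices[1] = np.sort(np.concatenate(edges, axis=0), axis=1) if edges else np.empty((0, 2), int)
    if D >= 2:
        simplices[2] = np.sort(np.concatenate(triangles, axis=0), axis=1)
    if D == 3:
        simplices[3] = np.sort(tets, axis=1)
    return SimplicialComplex(dim=D, n_vertices=nv, simplices=simplices,
                             coords=coords, lattice=info)


def mesh_complex(triangles: np.ndarray, n_vertices: int | None = None,
                 coords: np.ndarray | None = None) -> SimplicialComplex:
    """Build a 2D complex from a 0-based triangle index array (n, 3).

    Edges are derived as the unique sorted vertex pairs of the triangles.
    Suitable for closed or open surface meshes (e.g. cortical surfaces).
    """
    triangles = np.asarray(triangles, dtype=np.int64)
    if triangles.ndim != 2 or triangles.shape[1] != 3:
        raise ValueError("triangles must be an (n, 3) index array")
    if n_vertices is None:
        n_vertices = int(triangles.max()) + 1
    tri = np.sort(triangles, axis=1)
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [0, 2]], tri[:, [1, 2]]], axis=0)
    edges = np.unique(edges, axis=0)
    simplices = {
        0: np.arange(n_vertices, dtype=np.int64)[:, None],
        1: edges,
        2: tri,
    }
    return SimplicialComplex(dim=2, n_vertices=n_vertices, simplices=simplices,
                             coords=coords)


def euler_characteristic(complex: SimplicialComplex, values: np.ndarray | None = None,
                         u: float = -np.inf) -> int:
    """EC of the excursion set {value >= u} under the closed-simplex rule.

    With ``values=None`` (or ``u=-inf``) this is the EC of the full space:
    the alternating sum of simplex counts.
    """
    chi = 0
    for d in range(complex.dim + 1):
        n = complex.n_simplices(d)
        if n == 0:
            continue
        if values is None or u == -np.inf:
            count = n
        else:
            count = int((complex.min_values(np.asarray(values, float), d) >= u).sum())
        chi += (-1) ** d * count
    return int(chi)


def l0(complex: SimplicialComplex) -> int:
    """EC of the full search space (the zeroth Lipschitz-Killing curvature)."""
    return euler_characteristic(complex)


def ec_curve(values: np.ndarray, complex: SimplicialComplex,
             thresholds: np.ndarray) -> ECCurve | list[ECCurve]:
    """Euler characteristic over a strictly increasing threshold grid.

    ``values`` may be a single (n_vertices,) field or a stack
    (n_fields, n_vertices); a list of curves is returned for a stack.
    The count of simplices alive at each threshold is obtained by sorting
    per-simplex birth values once and binary-searching the grid.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if thresholds.size > 1 and not np.all(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be strictly increasing")
    values = np.asarray(values, dtype=float)
    single = values.ndim == 1
    vals = values[None, :] if single else values
    n_fields = vals.shape[0]

    ec = np.zeros((n_fields, thresholds.size), dtype=np.int64)
    for d in range(complex.dim + 1):
        n = complex.n_simplices(d)
        if n == 0:
            continue
        mins = np.sort(complex.min_values(vals, d), axis=-1)
        for i in range(n_fields):
            alive = n - np.searchsorted(mins[i], thresholds, side="left")
            ec[i] += (-1) ** d * alive
    curves = [ECCurve(thresholds.copy(), ec[i]) for i in range(n_fields)]
    return curves[0] if single else curves


def count_clusters(values: np.ndarray, complex: SimplicialComplex, u: float) -> int:
    """Number of connected components of {value >= u} under edge adjacency.

    Connectivity follows the complex's edges, which for lattice complexes
    include the triangulation diagonals — the same topology used for EC
    counting.
    """
    values = np.asarray(values, dtype=float)
    included = values >= u
    n_inc = int(included.sum())
    if n_inc == 0:
        return 0
    edges = complex.simplices.get(1)
    if edges is None or len(edges) == 0:
        return n_inc
    keep = included[edges[:, 0]] & included[edges[:, 1]]
    sub = edges[keep]
    new_idx = np.cumsum(included) - 1
    if len(sub) == 0:
        return n_inc
    i, j = new_idx[sub[:, 0]], new_idx[sub[:, 1]]
    adj = coo_matrix((np.ones(len(sub)), (i, j)), shape=(n_inc, n_inc))
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)
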