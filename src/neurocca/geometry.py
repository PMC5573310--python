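"""Feature geometries: cortical surface vertex sets and 2D skeleton grids.

A :class:`FeatureGeometry` tells the statistics modules how features are
arranged in space.  Only the adjacency structure matters downstream (TFCE
clusters over it); coordinates are never needed.

Two kinds are supported:

``surface``
    Two hemispheres of mesh vertices.  The default size is 40,962 vertices
    per hemisphere, the resolution of a 6-times-subdivided icosahedral
    sphere and the standard vertex count of CIVET/CLASP cortical models.
    Adjacency is the edge graph of the icosphere mesh, built lazily (the
    full-resolution graph is only constructed when actually requested).

``skeleton``
    A 2D grid standing in for a white-matter tract skeleton, with 4- or
    8-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError

#: vertex counts of icospheres by subdivision level: 10 * 4**k + 2
_ICOSPHERE_COUNTS = {10 * 4 ** k + 2: k for k in range(9)}

DEFAULT_VERTICES_PER_HEMISPHERE = 40962


@dataclass
class FeatureGeometry:
    """Spatial layout of the features of one modality.

    Parameters
    ----------
    kind
        ``"surface"`` or ``"skeleton"``.
    n_features
        Total number of features (both hemispheres for a surface).
    hemispheres
        For surfaces, an integer label (0 = left, 1 = right) per feature;
        ``None`` for skeletons.
    grid_shape
        For skeletons, the (rows, cols) of the grid.
    connectivity
        For skeletons, 4 or 8.
    """

    kind: str
    n_features: int
    hemispheres: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None
    connectivity: int = 4
    _adjacency: sp.csr_matrix | None = field(
        default=None, repr=False, compare=False)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix (no self edges), built lazily."""
        if self._adjacency is None:
            if self.kind == "surface":
                self._adjacency = _surface_adjacency(self.n_features)
            else:
                self._adjacency = _grid_adjacency(
                    self.grid_shape, self.connectivity)
        return self._adjacency

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the features adjacent to feature ``i``."""
        a = self.adjacency
        return a.indices[a.indptr[i]:a.indptr[i + 1]]

    def feature_ids(self) -> list[str]:
        if self.kind == "surface":
            half = self.n_features // 2
            return [f"{'lh' if i < half else 'rh'}_v{i % half:06d}"
                    for i in range(self.n_features)]
        return [f"s{i:06d}" for i in range(self.n_features)]


def make_geometry(kind: str, dims=None, connectivity: int = 4) -> FeatureGeometry:
    """Build a feature geometry.

    Parameters
    ----------
    kind
        ``"surface"``: ``dims`` is the vertex count per hemisphere (default
        40,962); must be an icosphere count ``10 * 4**k + 2`` so that a mesh
        adjacency exists.
        ``"skeleton"``: ``dims`` is a ``(rows, cols)`` grid shape.
    connectivity
        Grid connectivity for skeletons, 4 or 8.
    """
    if kind == "surface":
        per_hemi = DEFAULT_VERTICES_PER_HEMISPHERE if dims is None else int(dims)
        if per_hemi <= 0:
            raise ValidationError("surface vertex count must be positive")
        if per_hemi not in _ICOSPHERE_COUNTS:
            raise ValidationError(
                f"surface size {per_hemi} is not an icosphere vertex count "
                f"(10 * 4**k + 2); e.g. 12, 42, 162, ..., 40962")
        n = 2 * per_hemi
        hemis = np.repeat([0, 1], per_hemi)
        return FeatureGeometry(kind="surface", n_features=n, hemispheres=hemis)
    if kind == "skeleton":
        if dims is None:
            raise ValidationError("skeleton geometry needs (rows, cols) dims")
        rows, cols = int(dims[0]), int(dims[1])
        if rows <= 0 or cols <= 0:
            raise ValidationError("grid dims must be positive")
        if connectivity not in (4, 8):
            raise ValidationError("skeleton connectivity must be 4 or 8")
        return FeatureGeometry(
            kind="skeleton", n_features=rows * cols,
            grid_shape=(rows, cols), connectivity=connectivity)
    raise ValidationError(f"unknown geometry kind: {kind!r}")


def _surface_adjacency(n_features: int) -> sp.csr_matrix:
    # one icosphere mesh per hemisphere; hemispheres are disconnected
    import trimesh  # heavier import kept local

    per_hemi = n_features // 2
    level = _ICOSPHERE_COUNTS[per_hemi]
    mesh = trimesh.creation.icosphere(subdivisions=level)
    e = mesh.edges_unique
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    one = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)),
        shape=(per_hemi, per_hemi))
    return sp.block_diag([one, one], format="csr")


def _grid_adjacency(shape: tuple[int, int], connectivity: int) -> sp.csr_matrix:
    rows, cols = shape
    idx = np.arange(rows * cols).reshape(shape)
    pairs = []
    if cols > 1:
        pairs.append((idx[:, :-1].ravel(), idx[:, 1:].ravel()))
    if rows > 1:
        pairs.append((idx[:-1, :].ravel(), idx[1:, :].ravel()))
    if connectivity == 8 and rows > 1 and cols > 1:
        pairs.append((idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()))
        pairs.append((idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()))
    if not pairs:
        return sp.csr_matrix((rows * cols, rows * cols), dtype=np.int8)
    a = np.concatenate([p[0] for p in pairs])
    b = np.concatenate([p[1] for p in pairs])
    r = np.concatenate([a, b])
    c = np.concatenate([b, a])
    return sp.csr_matrix(
        (np.ones(r.size, dtype=np.int8), (r, c)),
        shape=(rows * cols, rows * cols))
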