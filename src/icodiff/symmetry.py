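"""Icosahedral rotation group, symmetry-axis direction sets, and map averaging.

The icosahedral rotation group *I* has 60 proper rotations.  Its axes come
in 6 five-fold pairs (the 12 vertex directions of an icosahedron), 10
three-fold pairs (20 face directions) and 15 two-fold pairs (30 edge
directions).  We fix the common "222" orientation convention: the three
mutually perpendicular two-fold axes lie along the coordinate axes, and the
five-fold axes lie in the coordinate planes at directions like
(0, 1, phi)/|.| with phi the golden ratio.  All downstream results are
covariant with this choice; it is fixed so axis positions are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

__all__ = [
    "RotationOperator",
    "AxisSet",
    "build_icosahedral_group",
    "axis_directions",
    "symmetrize",
]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

#: angular orders supported by the icosahedral group (beyond the identity)
AXIS_ORDERS = (2, 3, 5)

#: expected number of axis directions per order
AXIS_COUNTS = {5: 12, 3: 20, 2: 30}


@dataclass(frozen=True)
class RotationOperator:
    """A proper rotation, element of the icosahedral group.

    The matrix is orthonormal with determinant +1 (tolerance 1e-9 on both,
    checked at construction).
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if abs(np.linalg.det(m) - 1.0) > 1e-9:
            raise ValueError("rotation matrix must have determinant +1")
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix must be orthonormal")
        object.__setattr__(self, "matrix", m)

    def __matmul__(self, other: "RotationOperator") -> "RotationOperator":
        return RotationOperator(self.matrix @ other.matrix)

    @property
    def angle(self) -> float:
        """Rotation angle in radians, in [0, pi]."""
        c = (np.trace(self.matrix) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    @property
    def axis(self) -> np.ndarray | None:
        """Unit rotation axis (sign arbitrary); None for the identity."""
        if self.angle < 1e-9:
            return None
        rv = Rotation.from_matrix(self.matrix).as_rotvec()
        return rv / np.linalg.norm(rv)


@dataclass(frozen=True)
class AxisSet:
    """The direction set of all icosahedral axes of a given order.

    Directions are unit vectors and come in antipodal pairs; there are
    12 for order 5, 20 for order 3 and 30 for order 2.
    """

    order: int
    directions: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.order not in AXIS_ORDERS:
            raise ValueError(f"axis order must be one of {AXIS_ORDERS}, got {self.order}")
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit vectors")
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return len(self.directions)

    def to_table(self) -> str:
        """Plain-text table: one `order x y z` row per direction."""
        lines = [f"{self.order} {x:+.12f} {y:+.12f} {z:+.12f}"
                 for x, y, z in self.directions]
        return "\n".join(lines) + "\n"


def _nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project onto SO(3) (polar decomposition) to stop numerical drift."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _close_group(generators: list[np.ndarray]) -> list[np.ndarray]:
    """Close a set of rotation matrices under multiplication."""
    elements = [np.eye(3)]

    def find(m):
        return any(np.allclose(e, m, atol=1e-8) for e in elements)

    frontier = [_nearest_rotation(g) for g in generators]
    while frontier:
        g = frontier.pop()
        if find(g):
            continue
        elements.append(g)
        for e in list(elements):
            for prod in (g @ e, e @ g):
                prod = _nearest_rotation(prod)
                if not find(prod):
                    frontier.append(prod)
        if len(elements) > 60:
            raise RuntimeError("group closure exceeded order 60; bad generators")
    return elements


_GROUP_CACHE: list[RotationOperator] | None = None


def build_icosahedral_group() -> list[RotationOperator]:
    """Return the 60 rotations of the icosahedral group *I* (222 setting).

    Generated by the two-fold rotation about z and the five-fold rotation
    about the vertex direction (0, 1, phi)/|.|, then closed under
    composition.  The result contains the identity and is closed under
    inverses (every rotation group is).  The group is built once per
    process and cached (elements are immutable).
    """
    global _GROUP_CACHE
    if _GROUP_CACHE is not None:
        return list(_GROUP_CACHE)
    two_fold_z = Rotation.from_rotvec([0, 0, np.pi]).as_matrix()
    two_fold_x = Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    v5 = np.array([0.0, 1.0, _PHI])
    v5 = v5 / np.linalg.norm(v5)
    five_fold = Rotation.from_rotvec(v5 * (2 * np.pi / 5)).as_matrix()
    mats = _close_group([two_fold_z, two_fold_x, five_fold])
    if len(mats) != 60:
        raise RuntimeError(f"icosahedral group closure produced {len(mats)} elements")
    _GROUP_CACHE = [RotationOperator(m) for m in mats]
    return list(_GROUP_CACHE)


def axis_directions(order: int, group: list[RotationOperator] | None = None) -> AxisSet:
    """Direction set of all icosahedral axes of the given order (2, 3 or 5).

    Each direction is the rotation axis of some group element whose angle
    is 2*pi/order; both antipodal directions are included.
    """
    if order not in AXIS_ORDERS:
        raise ValueError(f"axis order must be one of {AXIS_ORDERS}, got {order}")
    if group is None:
        group = build_icosahedral_group()
    target = 2 * np.pi / order
    dirs: list[np.ndarray] = []
    for op in group:
        ax = op.axis
        if ax is None:
            continue
        # an order-k axis carries rotations by 2*pi*j/k; match the primitive
        # one (tolerance 1e-6 rad: arccos is ill-conditioned near pi)
        if abs(op.angle - target) > 1e-6:
            continue
        for cand in (ax, -ax):
            if not any(np.allclose(cand, d, atol=1e-8) for d in dirs):
                dirs.append(cand)
    arr = np.array(dirs)
    if len(arr) != AXIS_COUNTS[order]:
        raise RuntimeError(
            f"expected {AXIS_COUNTS[order]} directions of order {order}, got {len(arr)}")
    return AxisSet(order=order, directions=arr)


def symmetrize(map3d, group: list[RotationOperator] | None = None):
    """Average a map over the 60 icosahedral rotations.

    Rotation center is the grid-center voxel (N//2 on each axis); resampling
    is trilinear with zero padding outside the grid, so density should stay
    away from the box edges.  The output is invariant under further group
    rotations up to interpolation error, and symmetrize is idempotent at
    that tolerance.
    """
    from .density_map import Map3D  # local import to avoid cycle

    if not isinstance(map3d, Map3D):
        raise TypeError("symmetrize expects a Map3D")
    data = map3d.data
    n = data.shape[0]
    if group is None:
        group = build_icosahedral_group()
    center = np.array([n // 2, n // 2, n // 2], dtype=float)
    acc = np.zeros_like(data, dtype=float)
    for op in group:
        # affine_transform maps output coords through the matrix, i.e. it
        # pulls back: out[x] = in[R x + offset]; using R^T rotates the map by R.
        rot = op.matrix.T
        offset = center - rot @ center
        acc += affine_transform(data, rot, offset=offset, order=1,
                                mode="constant", cval=0.0)
    acc /= len(group)
    return Map3D(acc, voxel_size=map3d.voxel_size)
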