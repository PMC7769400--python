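"""Closed-form least-squares rigid registration of corresponding fiducials.

The point-match (PM) problem: given corresponding marker positions
``a_i`` (planning frame) and ``b_i`` (setup frame), find the proper
rotation ``R`` and translation ``T`` minimizing

    sum_i || R a_i + T - b_i ||^2        over det(R) = +1.

This is the orthogonal Procrustes problem; :func:`solve_point_match`
implements the singular-value-decomposition closed form (center both
clouds, SVD of the cross-covariance, ``R = V U^T`` with a determinant
correction, ``T`` from the centroids).  Because the solution is analytic
it has no convergence failures, which is why PM on extrinsic fiducials
serves as the gold standard against which intensity- and surface-based
registration platforms are judged.

Two independent solvers are provided for verification: a quaternion
eigen-decomposition closed form (:func:`solve_quaternion_oracle`) and an
exhaustive small-angle grid search (:func:`brute_force_oracle`).

Marker correspondence is always by marker *id*, never by list order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateConfigurationError,
    InvalidArgumentError,
    InvalidCorrespondenceError,
)
from .transforms import RigidTransform

__all__ = [
    "MarkerCloud",
    "CenteredPair",
    "PointMatchSolution",
    "center_clouds",
    "solve_point_match",
    "solve_quaternion_oracle",
    "brute_force_oracle",
    "registration_cost",
    "read_marker_cloud",
    "write_marker_cloud",
]

#: Ratio of 2nd to 1st singular value of the centered compute-group
#: coordinates below which the configuration is treated as collinear.
COLLINEARITY_TOL = 1e-6

_FILE_COLUMNS = ["id", "group", "frame", "x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class MarkerCloud:
    """Named fiducial positions in one imaging frame.

    Markers carry a group label: ``"C"`` (compute — used to fit the
    transform) or ``"V"`` (validate — held out to measure TRE).

    Parameters
    ----------
    ids : tuple of str
        Unique marker identifiers.
    groups : tuple of str
        ``"C"`` or ``"V"`` per marker.
    positions : (n, 3) ndarray
        Coordinates in mm.
    frame : str
        Label of the imaging frame, e.g. ``"planning-CT"`` or ``"CBCT"``.
    """

    ids: tuple
    groups: tuple
    positions: np.ndarray
    frame: str = "unknown"

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        groups = tuple(str(g) for g in self.groups)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidArgumentError(f"positions must be (n, 3), got {pos.shape}")
        if not (len(ids) == len(groups) == pos.shape[0]):
            raise InvalidArgumentError("ids, groups and positions lengths differ")
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("marker ids must be unique")
        if not set(groups) <= {"C", "V"}:
            raise InvalidArgumentError(f"groups must be 'C' or 'V', got {sorted(set(groups))}")
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("marker positions must be finite")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, group: str) -> "MarkerCloud":
        """The sub-cloud with the given group label ('C' or 'V')."""
        keep = [i for i, g in enumerate(self.groups) if g == group]
        return MarkerCloud(
            tuple(self.ids[i] for i in keep),
            tuple(self.groups[i] for i in keep),
            self.positions[keep],
            self.frame,
        )

    def positions_by_id(self, ids) -> np.ndarray:
        index = {m: i for i, m in enumerate(self.ids)}
        missing = [m for m in ids if m not in index]
        if missing:
            raise InvalidCorrespondenceError(f"markers not in cloud: {missing}")
        return self.positions[[index[m] for m in ids]]

    def with_positions(self, positions, frame: str | None = None) -> "MarkerCloud":
        """Copy of the cloud with replaced coordinates (same ids/groups)."""
        return MarkerCloud(self.ids, self.groups, positions, frame or self.frame)

    def validate(self) -> None:
        """Check the compute-group geometry is usable for registration.

        Requires at least 3 'C' markers whose centered coordinates are
        well conditioned: both trailing singular values above
        ``COLLINEARITY_TOL`` times the leading one (non-collinear and
        non-coplanar).
        """
        c = self.subset("C")
        if len(c) < 3:
            raise InvalidCorrespondenceError(
                f"need >= 3 compute-group markers, have {len(c)}"
            )
        s = np.linalg.svd(c.positions - c.positions.mean(axis=0), compute_uv=False)
        if s[1] <= COLLINEARITY_TOL * s[0] or s[2] <= COLLINEARITY_TOL * s[0]:
            raise DegenerateConfigurationError(
                "compute-group markers are (nearly) collinear or coplanar: "
                f"singular values {s}"
            )


@dataclass(frozen=True)
class CenteredPair:
    """Two corresponding point sets re-centered on their centroids."""

    centroid_a: np.ndarray
    centroid_b: np.ndarray
    a_centered: np.ndarray
    b_centered: np.ndarray


@dataclass(frozen=True)
class PointMatchSolution:
    """A fitted rigid registration with its fiducial residuals.

    Attributes
    ----------
    transform : RigidTransform
        The fitted mapping planning -> setup, referenced to the origin.
    per_marker_residual : tuple of (id, mm)
        Post-registration distance at each fitted marker (FRE per marker).
    fre_rms : float
        Root-mean-square of the per-marker residuals, mm.
    n_used : int
        Number of markers used in the fit.
    used_ids : tuple of str
        Ids of the fitted markers, recorded so that target-error
        computations can enforce a held-out validation set.
    """

    transform: RigidTransform
    per_marker_residual: tuple
    fre_rms: float
    n_used: int
    used_ids: tuple = field(default=())


# ---------------------------------------------------------------------------
# core algebra


def center_clouds(a, b) -> CenteredPair:
    """Re-center two corresponding point lists on their centroids.

    Raises :class:`InvalidCorrespondenceError` if the lists differ in
    length or have fewer than 3 points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InvalidCorrespondenceError(
            f"point lists must both be (n, 3); got {a.shape} and {b.shape}"
        )
    if a.shape[0] < 3:
        raise InvalidCorrespondenceError(f"need >= 3 corresponding points, got {a.shape[0]}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    return CenteredPair(ca, cb, a - ca, b - cb)


def _check_not_collinear(a_centered: np.ndarray) -> None:
    s = np.linalg.svd(a_centered, compute_uv=False)
    if s[1] <= COLLINEARITY_TOL * s[0]:
        raise DegenerateConfigurationError(
            f"marker configuration is (nearly) collinear: singular values {s}"
        )


def fit_rigid(a, b) -> RigidTransform:
    """SVD closed form for the least-squares rigid motion taking ``a`` to ``b``.

    Steps: center both sets; SVD of the cross-covariance
    ``H = A'^T B' = U S V^T``; ``R = V diag(1, 1, det(V U^T)) U^T``;
    ``T = b_centroid - R a_centroid``.  The diagonal correction forces
    ``det(R) = +1`` when the unconstrained optimum is a reflection, which
    can happen for noisy near-coplanar clouds.
    """
    pair = center_clouds(a, b)
    _check_not_collinear(pair.a_centered)
    h = pair.a_centered.T @ pair.b_centered
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = pair.centroid_b - r @ pair.centroid_a
    return RigidTransform(r, t)


def _solution_from_transform(t: RigidTransform, a, b, ids) -> PointMatchSolution:
    resid = np.linalg.norm(t.apply(a) - b, axis=1)
    return PointMatchSolution(
        transform=t,
        per_marker_residual=tuple(zip(ids, resid.tolist())),
        fre_rms=float(np.sqrt(np.mean(resid**2))),
        n_used=len(ids),
        used_ids=tuple(ids),
    )


def _paired_positions(a: MarkerCloud, b: MarkerCloud, group: str | None, min_markers: int = 3):
    """Positions of matching markers, paired by id (order taken from ``a``).

    ``min_markers`` is 3 for fitting (fewer cannot pin a rigid motion) but
    1 for pure evaluation, where any number of probes is meaningful.
    """
    ac = a if group is None else a.subset(group)
    bc = b if group is None else b.subset(group)
    if set(ac.ids) != set(bc.ids):
        raise InvalidCorrespondenceError(
            f"marker ids differ between clouds: {sorted(set(ac.ids) ^ set(bc.ids))}"
        )
    if len(ac) < min_markers:
        raise InvalidCorrespondenceError(
            f"need >= {min_markers} matched markers, got {len(ac)}"
        )
    return ac.ids, ac.positions, bc.positions_by_id(ac.ids)


def solve_point_match(a: MarkerCloud, b: MarkerCloud, group: str | None = "C") -> PointMatchSolution:
    """Fit the gold-standard rigid registration on the compute group.

    Markers are paired by id; by default only the ``"C"`` group enters the
    fit, leaving the ``"V"`` group untouched for target-error validation.
    Pass ``group=None`` to use every marker.
    """
    ids, pa, pb = _paired_positions(a, b, group)
    t = fit_rigid(pa, pb)
    return _solution_from_transform(t, pa, pb, ids)


def registration_cost(transform: RigidTransform, a, b) -> float:
    """The least-squares objective sum_i ||R a_i + T - b_i||^2 in mm^2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sum((transform.apply(a) - b) ** 2))


# ---------------------------------------------------------------------------
# independent oracles


def solve_quaternion_oracle(a: MarkerCloud, b: MarkerCloud, group: str | None = "C") -> PointMatchSolution:
    """Independent closed form via the 4x4 quaternion profile matrix.

    Builds the symmetric matrix whose largest-eigenvalue eigenvector is
    the unit quaternion of the optimal rotation (Horn's absolute
    orientation method).  Exists purely to cross-check the SVD route; the
    two must agree to machine precision on non-degenerate input.
    """
    ids, pa, pb = _paired_positions(a, b, group)
    pair = center_clouds(pa, pb)
    _check_not_collinear(pair.a_centered)
    m = pair.a_centered.T @ pair.b_centered
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(n)
    q = v[:, -1]  # (w, x, y, z), unit norm
    qw, qx, qy, qz = q
    r = np.array(
        [
            [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
            [2 * (qx * qy + qz * qw), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - qx * qw)],
            [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx**2 + qy**2)],
        ]
    )
    t = RigidTransform(r, pair.centroid_b - r @ pair.centroid_a)
    return _solution_from_transform(t, pa, pb, ids)


def _euler_grid_matrices(angles_deg: np.ndarray) -> np.ndarray:
    """Stack of rotation matrices Rz@Ry@Rx for an (n, 3) array of degrees."""
    rad = np.deg2rad(angles_deg)
    cx, cy, cz = np.cos(rad).T
    sx, sy, sz = np.sin(rad).T
    r = np.empty((angles_deg.shape[0], 3, 3))
    r[:, 0, 0] = cz * cy
    r[:, 0, 1] = cz * sy * sx - sz * cx
    r[:, 0, 2] = cz * sy * cx + sz * sx
    r[:, 1, 0] = sz * cy
    r[:, 1, 1] = sz * sy * sx + cz * cx
    r[:, 1, 2] = sz * sy * cx - cz * sx
    r[:, 2, 0] = -sy
    r[:, 2, 1] = cy * sx
    r[:, 2, 2] = cy * cx
    return r


def brute_force_oracle(
    a: MarkerCloud,
    b: MarkerCloud,
    angle_window: float = 3.0,
    grid_step: float = 0.1,
    group: str | None = "C",
) -> PointMatchSolution:
    """Exhaustive small-angle grid search over (rx, ry, rz).

    Scans a cubic grid of Euler triples within ``+/-angle_window`` degrees
    (step ``grid_step``); for each candidate rotation the translation is
    centroid-matched, which is optimal for fixed ``R``, so the grid
    minimum brackets the true optimum up to the grid resolution.  For
    test-time verification only — the closed forms are exact and fast.
    """
    if not (0 < grid_step <= angle_window):
        raise InvalidArgumentError(
            f"need 0 < grid_step <= angle_window, got {grid_step}, {angle_window}"
        )
    ids, pa, pb = _paired_positions(a, b, group)
    pair = center_clouds(pa, pb)
    axis = np.arange(-angle_window, angle_window + grid_step / 2, grid_step)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rots = _euler_grid_matrices(grid)
    # ||R a' - b'||^2 summed over markers = const - 2 tr(R H), H = A'^T B'
    h = pair.a_centered.T @ pair.b_centered
    const = np.sum(pair.a_centered**2) + np.sum(pair.b_centered**2)
    costs = const - 2.0 * np.einsum("nij,ij->n", rots, h.T)
    best = int(np.argmin(costs))
    r = rots[best]
    t = RigidTransform(r, pair.centroid_b - r @ pair.centroid_a)
    return _solution_from_transform(t, pa, pb, ids)


# ---------------------------------------------------------------------------
# file interchange


def write_marker_cloud(cloud: MarkerCloud, path) -> None:
    """Write a marker cloud to delimited text (columns id,group,frame,x_mm,y_mm,z_mm)."""
    df = pd.DataFrame(
        {
            "id": cloud.ids,
            "group": cloud.groups,
            "frame": cloud.frame,
            "x_mm": cloud.positions[:, 0],
            "y_mm": cloud.positions[:, 1],
            "z_mm": cloud.positions[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_marker_cloud(path_or_buffer) -> MarkerCloud:
    """Read a marker cloud from delimited text.

    Header row required; lines starting with ``#`` are comments.  All
    rows must share one frame label.
    """
    if isinstance(path_or_buffer, (str, Path)):
        df = pd.read_csv(path_or_buffer, comment="#", skip_blank_lines=True)
    else:
        df = pd.read_csv(path_or_buffer, comment="#", skip_blank_lines=True)
    missing = [c for c in _FILE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"marker-cloud file missing columns: {missing}")
    frames = df["frame"].unique()
    if len(frames) != 1:
        raise InvalidArgumentError(f"marker-cloud file mixes frames: {list(frames)}")
    return MarkerCloud(
        tuple(df["id"].astype(str)),
        tuple(df["group"].astype(str)),
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        str(frames[0]),
    )


def cloud_from_points(points, frame: str = "frame", group: str = "C", prefix: str = "M") -> MarkerCloud:
    """Convenience constructor: wrap bare coordinates as a one-group cloud."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ids = tuple(f"{prefix}{i + 1:02d}" for i in range(points.shape[0]))
    return MarkerCloud(ids, (group,) * points.shape[0], points, frame)
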