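"""Registration accuracy metrics: FRE, FLE, TRE, rmsTRE and IRE.

Four complementary views of rigid-registration accuracy, all in mm (or
degrees for rotational residuals):

FRE (fiducial registration error)
    ``||R a_i + T - b_i||`` at each marker *used to fit* the transform.
    Measures goodness of fit, not accuracy at a target.

FLE (fiducial localization error)
    The uncertainty in locating one fiducial.  Not directly observable;
    estimated from the expected FRE via Sibson's relation
    ``<FLE^2> = n / (n - 2) * <FRE^2>`` for n non-collinear markers.

TRE / rmsTRE (target registration error)
    ``||R a_j + T - b_j||`` at *held-out* validation markers, and its
    root mean square over the validation set for one setup.  This is the
    honest accuracy measure: the markers entering it never influenced the
    fit, and any overlap raises :class:`~fidreg.exceptions.LeakageError`.

IRE (isocenter registration error)
    The 6D residual between a registration method's correction and the
    gold-standard point-match correction, both referenced to the machine
    isocenter: the residual transform ``delta = method o pm^-1`` is
    decomposed into a signed translation at ISO and residual rotation
    angles.  Because clinical targets sit near ISO while surface fiducials
    sit far from it, IRE and rmsTRE weight rotational error differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InvalidArgumentError, InvalidCorrespondenceError, LeakageError
from .point_match import MarkerCloud, PointMatchSolution, _paired_positions
from .transforms import EulerAngles6D, RigidTransform, compose, rereference, transform_to_euler

__all__ = [
    "FiducialErrorSummary",
    "TargetErrorSummary",
    "IreResult",
    "compute_fre",
    "estimate_fle",
    "compute_tre",
    "target_registration_error",
    "compute_ire",
]


@dataclass(frozen=True)
class FiducialErrorSummary:
    """Fit residuals over the compute group plus the implied FLE."""

    fre_per_marker: tuple  # (id, mm) pairs
    fre_rms: float
    fle_estimate: float
    n: int


@dataclass(frozen=True)
class TargetErrorSummary:
    """Held-out validation residuals for one registration."""

    tre_per_marker: tuple  # (id, mm) pairs
    rms_tre: float


@dataclass(frozen=True)
class IreResult:
    """6D isocenter residual of a method relative to the gold standard.

    ``dt`` is the signed per-axis translation residual at ISO (mm); ``dr``
    holds the per-axis rotation residuals (degrees, pitch/yaw/roll).
    ``dr_magnitude`` is the single rotation angle of the residual rotation
    (axis-angle), which upper-bounds any per-axis component.
    """

    dt: np.ndarray
    dr: EulerAngles6D
    dt_magnitude: float
    dr_magnitude: float


def compute_fre(solution: PointMatchSolution, a_c: MarkerCloud, b_c: MarkerCloud) -> FiducialErrorSummary:
    """Per-marker and rms fiducial registration error of a fitted solution.

    The clouds must contain exactly the markers the solution was fitted
    on (compute group); residuals are recomputed from the stored
    transform so the summary stays valid if clouds are re-read from file.
    """
    ids, pa, pb = _paired_positions(a_c, b_c, None)
    if set(ids) != set(solution.used_ids):
        raise InvalidCorrespondenceError(
            "clouds do not match the markers used to fit the solution: "
            f"{sorted(set(ids) ^ set(solution.used_ids))}"
        )
    resid = np.linalg.norm(solution.transform.apply(pa) - pb, axis=1)
    fre_rms = float(np.sqrt(np.mean(resid**2)))
    return FiducialErrorSummary(
        fre_per_marker=tuple(zip(ids, resid.tolist())),
        fre_rms=fre_rms,
        fle_estimate=estimate_fle(fre_rms, len(ids)),
        n=len(ids),
    )


def estimate_fle(fre_rms: float, n: int) -> float:
    """Estimate the fiducial localization error from the rms FRE.

    Sibson's approximation: ``<FLE^2> = n / (n - 2) * <FRE^2>``.  The
    sample rms FRE stands in for the expectation, so the estimate is as
    good as the number of registrations it is averaged over.
    """
    if n < 3:
        raise InvalidArgumentError(f"FLE estimate needs n >= 3 markers, got {n}")
    if not (math.isfinite(fre_rms) and fre_rms >= 0):
        raise InvalidArgumentError(f"fre_rms must be finite and >= 0, got {fre_rms}")
    return math.sqrt(n / (n - 2.0)) * fre_rms


def target_registration_error(transform: RigidTransform, a_v: MarkerCloud, b_v: MarkerCloud) -> TargetErrorSummary:
    """TRE of an arbitrary transform at matched validation markers.

    Lower-level form of :func:`compute_tre` for transforms that did not
    come from a marker fit (e.g. a platform's reported 6D correction,
    which never saw the markers at all).
    """
    ids, pa, pb = _paired_positions(a_v, b_v, None, min_markers=1)
    resid = np.linalg.norm(transform.apply(pa) - pb, axis=1)
    return TargetErrorSummary(
        tre_per_marker=tuple(zip(ids, resid.tolist())),
        rms_tre=float(np.sqrt(np.mean(resid**2))),
    )


def compute_tre(solution: PointMatchSolution, a_v: MarkerCloud, b_v: MarkerCloud) -> TargetErrorSummary:
    """TRE of a fitted solution at held-out validation markers.

    Enforces the central methodological safeguard: every validation
    marker id must be disjoint from the ids used to fit the solution.
    """
    overlap = set(a_v.ids) & set(solution.used_ids)
    if overlap:
        raise LeakageError(
            f"validation markers {sorted(overlap)} were used to fit the transform; "
            "TRE requires a held-out set"
        )
    return target_registration_error(solution.transform, a_v, b_v)


def compute_ire(method_transform: RigidTransform, pm_transform: RigidTransform, iso) -> IreResult:
    """6D isocenter residual of a method versus the point-match standard.

    Both transforms (planning -> setup) are re-referenced to ``iso``; the
    residual ``delta = method o pm^-1`` is then a rotation about ISO plus
    a translation.  ``dt`` is exactly the displacement ``delta`` induces
    at ISO, so a method that merely mis-rotates about ISO has ``dt = 0``
    while a probe point at distance d is displaced ~ ``2 sin(dr/2) d``.
    """
    iso = np.asarray(iso, dtype=float).reshape(-1)
    if iso.shape != (3,) or not np.all(np.isfinite(iso)):
        raise InvalidArgumentError(f"iso must be a finite 3-vector, got {iso}")
    m = rereference(method_transform, iso)
    p = rereference(pm_transform, iso)
    delta = compose(m, p.inverse())
    dr = transform_to_euler(delta)
    # axis-angle magnitude of the residual rotation (quaternion route:
    # well conditioned near identity, unlike acos of the trace)
    theta = math.degrees(float(Rotation.from_matrix(delta.rotation).magnitude()))
    return IreResult(
        dt=delta.translation.copy(),
        dr=dr,
        dt_magnitude=float(np.linalg.norm(delta.translation)),
        dr_magnitude=theta,
    )
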