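"""Synthetic phantom experiments: marker layouts, setups, noise, platforms.

A desk-scale emulation of the physical study design that makes the whole
pipeline testable without any measured data:

* **Marker layouts.**  External fiducials placed asymmetrically on an
  idealized head (ellipsoid shell, 13 markers: 8 compute + 5 validate)
  or body (cylinder shell, 8 markers: 5 compute + 3 validate).  Real
  layouts are not published, so positions are generated procedurally;
  asymmetry is enforced by rejecting layouts whose second-moment tensor
  has near-degenerate eigenvalues.

* **Setups.**  Each setup is a random 6D ground-truth motion of the
  phantom: per-axis rotations uniform within +/-3 degrees (the study's
  couch limit) and translations uniform within +/-10 mm, about the
  isocenter.

* **Localization noise.**  Marker positions in each imaging frame are
  perturbed with zero-mean Gaussian noise whose total 3D standard
  deviation defaults to one third of the largest voxel dimension of that
  frame — the empirical size of fiducial localization error on CT-like
  images.  Isotropic by default; per-axis (voxel-proportional) available.

* **Virtual platforms.**  The commercial registration systems are black
  boxes; their output is emulated as the ground-truth transform composed
  with a seeded random 6D error (per-axis Gaussian sigma + bias, about
  ISO).  The shipped demo models are calibrated to the accuracy
  *magnitudes reported for* such systems and exist for demonstration —
  using them as inputs can illustrate, but never validate, a platform.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .error_metrics import compute_fre, compute_ire, compute_tre, target_registration_error
from .exceptions import InvalidArgumentError
from .point_match import MarkerCloud, solve_point_match
from .transforms import EulerAngles6D, RigidTransform, compose, euler_to_transform, rereference

__all__ = [
    "PhantomConfig",
    "PlatformErrorModel",
    "SetupScenario",
    "build_phantom",
    "sample_setup",
    "add_localization_noise",
    "simulate_platform_registration",
    "run_experiment",
    "run_experiment_from_config",
    "demo_platform_models",
    "SITE_DEFAULTS",
]

#: Default FLE as a fraction of the largest voxel dimension.
DEFAULT_FLE_FRACTION = 1.0 / 3.0

#: Per-site defaults: marker counts, voxel dimensions (mm) per imaging
#: frame, isocenter position (mm), and surface-shell geometry.
SITE_DEFAULTS = {
    "cranial": {
        "n_markers": 13,
        "c_count": 8,
        "v_count": 5,
        "voxel_dims": {"planning": (0.6, 0.6, 1.25), "setup": (0.7, 0.7, 1.0)},
        "iso": (8.0, -25.0, -12.0),
        "min_spacing_mm": 25.0,
    },
    "body": {
        "n_markers": 8,
        "c_count": 5,
        "v_count": 3,
        "voxel_dims": {"planning": (0.8, 0.8, 2.0), "setup": (0.9, 0.9, 1.0)},
        "iso": (0.0, -30.0, 45.0),
        "min_spacing_mm": 40.0,
    },
}


@dataclass(frozen=True)
class PhantomConfig:
    """A synthetic phantom: marker layout, isocenter and voxel geometry."""

    site: str
    layout: MarkerCloud  # planning frame, groups assigned
    c_count: int
    v_count: int
    iso: np.ndarray
    voxel_dims: dict  # frame label -> (dx, dy, dz) mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "iso", np.asarray(self.iso, dtype=float))
        if self.c_count + self.v_count != len(self.layout):
            raise InvalidArgumentError(
                f"c_count + v_count = {self.c_count + self.v_count} "
                f"!= {len(self.layout)} markers"
            )


@dataclass(frozen=True)
class PlatformErrorModel:
    """Stochastic 6D error model for an emulated registration platform.

    The platform's reported transform is the ground truth composed with a
    random error about ISO: per-axis translations ~ N(bias_t, sigma_t^2)
    in mm, per-axis rotations ~ N(bias_r, sigma_r^2) in degrees.
    """

    name: str
    sigma_t: tuple = (0.0, 0.0, 0.0)
    sigma_r: tuple = (0.0, 0.0, 0.0)
    bias_t: tuple = (0.0, 0.0, 0.0)
    bias_r: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("sigma_t", "sigma_r", "bias_t", "bias_r"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3 or not all(np.isfinite(v)):
                raise InvalidArgumentError(f"{name} must be 3 finite numbers, got {v}")
            if name.startswith("sigma") and any(x < 0 for x in v):
                raise InvalidArgumentError(f"{name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass
class SetupScenario:
    """One realized setup: ground truth, noisy clouds, platform outputs."""

    true_transform: RigidTransform
    seed: int
    noisy_planning_cloud: MarkerCloud
    noisy_setup_cloud: MarkerCloud
    platform_transforms: dict = field(default_factory=dict)


def demo_platform_models() -> tuple:
    """Three emulated platforms for demonstration runs.

    Error magnitudes are set to the order reported for volumetric (3D/3D),
    stereoscopic X-ray (2D/3D) and optical-surface (3DS) registration of
    rigid phantoms: sub-half-millimeter for 3D/3D, a few tenths more for
    2D/3D, and around a millimeter with a systematic offset for surface
    match.  These are *outputs* of such measurements recast as inputs for
    demonstration; they do not validate any platform.
    """
    return (
        PlatformErrorModel("emulated-3D3D", sigma_t=(0.2, 0.2, 0.2), sigma_r=(0.15, 0.15, 0.15)),
        PlatformErrorModel(
            "emulated-2D3D",
            sigma_t=(0.35, 0.35, 0.35),
            sigma_r=(0.25, 0.25, 0.25),
            bias_r=(0.0, 0.0, 0.3),
        ),
        PlatformErrorModel(
            "emulated-3DS",
            sigma_t=(0.5, 0.5, 0.5),
            sigma_r=(0.3, 0.3, 0.3),
            bias_t=(0.5, 0.6, 0.3),
        ),
    )


# ---------------------------------------------------------------------------
# layout generation


def _ellipsoid_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random points on a head-sized ellipsoid shell (semi-axes mm)."""
    semi = np.array([75.0, 95.0, 70.0])
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * semi


def _cylinder_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random points on the anterior/lateral shell of a torso cylinder."""
    radius, half_len = 140.0, 120.0
    phi = rng.uniform(-110.0, 110.0, size=n)  # degrees from anterior (+y)
    z = rng.uniform(-half_len, half_len, size=n)
    phir = np.deg2rad(phi)
    return np.column_stack([radius * np.sin(phir), radius * np.cos(phir), z])


def _is_asymmetric(points: np.ndarray, rel_gap: float = 0.03) -> bool:
    """Reject layouts whose inertia eigenvalues nearly coincide."""
    centered = points - points.mean(axis=0)
    w = np.sort(np.linalg.eigvalsh(centered.T @ centered))
    return bool(np.all(np.diff(w) > rel_gap * w[-1]))


def _well_spread(points: np.ndarray, min_spacing: float) -> bool:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return bool(d.min() >= min_spacing)


def build_phantom(site: str, seed: int = 0, c_count: int | None = None, v_count: int | None = None) -> PhantomConfig:
    """Generate a deterministic asymmetric marker layout for one site.

    ``site`` is ``"cranial"`` (13 markers on an ellipsoid shell, 8 C + 5 V)
    or ``"body"`` (8 markers on a cylinder shell, 5 C + 3 V).  Marker
    counts can be overridden; the compute group must keep >= 3 markers.
    The same seed always yields identical coordinates and C/V assignment.
    """
    if site not in SITE_DEFAULTS:
        raise InvalidArgumentError(f"unknown site {site!r}; expected {sorted(SITE_DEFAULTS)}")
    spec = SITE_DEFAULTS[site]
    c_count = spec["c_count"] if c_count is None else int(c_count)
    v_count = spec["v_count"] if v_count is None else int(v_count)
    if c_count < 3:
        raise InvalidArgumentError(f"compute group needs >= 3 markers, got {c_count}")
    if v_count < 1:
        raise InvalidArgumentError(f"validation group needs >= 1 marker, got {v_count}")
    n = c_count + v_count
    rng = np.random.default_rng(seed)
    sampler = _ellipsoid_points if site == "cranial" else _cylinder_points
    for _ in range(1000):
        pts = sampler(rng, n)
        if not _well_spread(pts, spec["min_spacing_mm"]):
            continue
        if not _is_asymmetric(pts):
            continue
        order = rng.permutation(n)
        groups = np.array(["V"] * n)
        groups[order[:c_count]] = "C"
        cloud = MarkerCloud(
            tuple(f"{site[0].upper()}{i + 1:02d}" for i in range(n)),
            tuple(groups),
            pts,
            frame="planning-CT",
        )
        try:
            cloud.validate()
        except Exception:
            continue
        return PhantomConfig(site, cloud, c_count, v_count, np.asarray(spec["iso"]), dict(spec["voxel_dims"]))
    raise InvalidArgumentError(
        f"could not generate a well-spread asymmetric layout for {site} with n={n}"
    )


# ---------------------------------------------------------------------------
# noise and setups


def add_localization_noise(
    cloud: MarkerCloud,
    voxel_dims,
    fle_fraction: float = DEFAULT_FLE_FRACTION,
    seed: int = 0,
    anisotropic: bool = False,
    noise_free: bool = False,
) -> MarkerCloud:
    """Perturb marker positions with seeded fiducial localization noise.

    The total 3D standard deviation is ``fle_fraction * max(voxel_dims)``
    split evenly over the axes (per-axis sigma = total / sqrt(3)).  With
    ``anisotropic=True`` each axis instead gets
    ``sigma_axis = fle_fraction * voxel_axis``, reflecting that slice
    thickness usually exceeds in-plane pixel size.  ``noise_free=True``
    returns the cloud unchanged (explicit flag rather than fraction 0,
    so a vanishing fraction is always a configuration error).
    """
    voxel = np.asarray(voxel_dims, dtype=float).reshape(-1)
    if voxel.shape != (3,) or np.any(voxel <= 0) or not np.all(np.isfinite(voxel)):
        raise InvalidArgumentError(f"voxel_dims must be 3 positive numbers, got {voxel}")
    if noise_free:
        return cloud.with_positions(cloud.positions.copy())
    if not (np.isfinite(fle_fraction) and fle_fraction > 0):
        raise InvalidArgumentError(f"fle_fraction must be > 0, got {fle_fraction}")
    if anisotropic:
        sigma = fle_fraction * voxel
    else:
        sigma = np.full(3, fle_fraction * voxel.max() / np.sqrt(3.0))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=cloud.positions.shape) * sigma
    return cloud.with_positions(cloud.positions + noise)


def sample_setup(
    phantom: PhantomConfig,
    rotation_limit: float = 3.0,
    translation_limit: float = 10.0,
    fle_fraction: float = DEFAULT_FLE_FRACTION,
    seed: int = 0,
    anisotropic: bool = False,
    noise_free: bool = False,
) -> SetupScenario:
    """Draw one random phantom setup and its noisy marker observations.

    The ground-truth motion has per-axis rotations uniform on
    ``[-rotation_limit, +rotation_limit]`` degrees and translations
    uniform on ``[-translation_limit, +translation_limit]`` mm, expressed
    about the isocenter.  Planning-frame and setup-frame clouds get
    independent localization noise scaled to their own voxel dimensions.
    """
    if not (rotation_limit >= 0 and np.isfinite(rotation_limit)):
        raise InvalidArgumentError(f"rotation_limit must be >= 0, got {rotation_limit}")
    if not (translation_limit >= 0 and np.isfinite(translation_limit)):
        raise InvalidArgumentError(f"translation_limit must be >= 0, got {translation_limit}")
    rng = np.random.default_rng(seed)
    t = rng.uniform(-translation_limit, translation_limit, size=3)
    r = rng.uniform(-rotation_limit, rotation_limit, size=3)
    true = euler_to_transform(EulerAngles6D(*t, *r), phantom.iso)
    seed_plan = int(rng.integers(2**31))
    seed_setup = int(rng.integers(2**31))
    noisy_plan = add_localization_noise(
        phantom.layout, phantom.voxel_dims["planning"], fle_fraction, seed_plan,
        anisotropic=anisotropic, noise_free=noise_free,
    )
    exact_setup = phantom.layout.with_positions(true.apply(phantom.layout.positions), frame="CBCT")
    noisy_setup = add_localization_noise(
        exact_setup, phantom.voxel_dims["setup"], fle_fraction, seed_setup,
        anisotropic=anisotropic, noise_free=noise_free,
    )
    return SetupScenario(true, int(seed), noisy_plan, noisy_setup)


def simulate_platform_registration(
    scenario: SetupScenario,
    model: PlatformErrorModel,
    seed: int = 0,
    iso=(0.0, 0.0, 0.0),
) -> RigidTransform:
    """Emulate one platform's reported 6D transform for a setup.

    The ground truth is composed (about ``iso``) with a random error
    transform drawn from the model; with all sigmas and biases zero the
    ground truth is returned exactly.
    """
    rng = np.random.default_rng(seed)
    et = rng.normal(model.bias_t, model.sigma_t)
    er = rng.normal(model.bias_r, model.sigma_r)
    err = euler_to_transform(EulerAngles6D(*et, *er), iso)
    return compose(err, rereference(scenario.true_transform, iso))


# ---------------------------------------------------------------------------
# the full experiment


def run_experiment(
    phantom: PhantomConfig,
    n_setups: int,
    platform_models=(),
    seed: int = 0,
    rotation_limit: float = 3.0,
    translation_limit: float = 10.0,
    fle_fraction: float = DEFAULT_FLE_FRACTION,
    anisotropic: bool = False,
    noise_free: bool = False,
) -> pd.DataFrame:
    """Run the full simulated accuracy study for one phantom.

    For each setup: fit the gold-standard point-match transform on the
    noisy compute-group clouds, score it with FRE/FLE and held-out
    rmsTRE, then score each emulated platform with rmsTRE and its 6D IRE
    against the point-match transform.

    Returns a tidy table with one row per (setup, method, metric, axis):
    metrics ``fre_rms``/``fle_est``/``rms_tre`` (mm, axis empty),
    ``ire_dt`` (mm, axes x/y/z and ``mag``) and ``ire_dr`` (degrees,
    axes rx/ry/rz and ``mag``).  Bit-identical for identical arguments.
    """
    if n_setups < 1:
        raise InvalidArgumentError(f"n_setups must be >= 1, got {n_setups}")
    rng = np.random.default_rng(seed)
    iso = phantom.iso
    rows: list[dict] = []

    def add(setup, method, metric, axis, value):
        rows.append(
            {"site": phantom.site, "setup": setup, "method": method,
             "metric": metric, "axis": axis, "value": float(value)}
        )

    for k in range(n_setups):
        setup_seed = int(rng.integers(2**31))
        scenario = sample_setup(
            phantom, rotation_limit, translation_limit, fle_fraction,
            seed=setup_seed, anisotropic=anisotropic, noise_free=noise_free,
        )
        a, b = scenario.noisy_planning_cloud, scenario.noisy_setup_cloud
        pm = solve_point_match(a, b, group="C")
        fre = compute_fre(pm, a.subset("C"), b.subset("C"))
        tre = compute_tre(pm, a.subset("V"), b.subset("V"))
        add(k, "PM", "fre_rms", "", fre.fre_rms)
        add(k, "PM", "fle_est", "", fre.fle_estimate)
        add(k, "PM", "rms_tre", "", tre.rms_tre)
        pm_iso = rereference(pm.transform, iso)
        for model in platform_models:
            pseed = int(rng.integers(2**31))
            reported = simulate_platform_registration(scenario, model, seed=pseed, iso=iso)
            scenario.platform_transforms[model.name] = reported
            ptre = target_registration_error(reported, a.subset("V"), b.subset("V"))
            ire = compute_ire(reported, pm_iso, iso)
            add(k, model.name, "rms_tre", "", ptre.rms_tre)
            for axis, v in zip(("x", "y", "z"), ire.dt):
                add(k, model.name, "ire_dt", axis, v)
            add(k, model.name, "ire_dt", "mag", ire.dt_magnitude)
            for axis, v in zip(("rx", "ry", "rz"), ire.dr.rotation_degrees):
                add(k, model.name, "ire_dr", axis, v)
            add(k, model.name, "ire_dr", "mag", ire.dr_magnitude)
    return pd.DataFrame(rows, columns=["site", "setup", "method", "metric", "axis", "value"])


def _models_from_config(entries) -> tuple:
    models = []
    for e in entries or ():
        models.append(
            PlatformErrorModel(
                name=e["name"],
                sigma_t=tuple(e.get("sigma_t", (0, 0, 0))),
                sigma_r=tuple(e.get("sigma_r", (0, 0, 0))),
                bias_t=tuple(e.get("bias_t", (0, 0, 0))),
                bias_r=tuple(e.get("bias_r", (0, 0, 0))),
            )
        )
    return tuple(models)


def run_experiment_from_config(config, seed: int | None = None) -> pd.DataFrame:
    """Run an experiment described by a JSON/YAML file or a dict.

    Recognized keys: ``site``, ``n_setups``, ``seed``, ``rotation_limit_deg``,
    ``translation_limit_mm``, ``fle_fraction``, ``anisotropic``,
    ``layout_seed``, ``platforms`` (list of error-model dicts) or
    ``demo_platforms: true``.  An explicit ``seed`` argument overrides the
    file's.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text) if str(config).endswith((".yml", ".yaml")) else json.loads(text)
    else:
        cfg = dict(config)
    phantom = build_phantom(cfg.get("site", "cranial"), seed=int(cfg.get("layout_seed", 0)))
    if cfg.get("demo_platforms"):
        models = demo_platform_models()
    else:
        models = _models_from_config(cfg.get("platforms"))
    return run_experiment(
        phantom,
        n_setups=int(cfg.get("n_setups", 20)),
        platform_models=models,
        seed=int(cfg.get("seed", 0) if seed is None else seed),
        rotation_limit=float(cfg.get("rotation_limit_deg", 3.0)),
        translation_limit=float(cfg.get("translation_limit_mm", 10.0)),
        fle_fraction=float(cfg.get("fle_fraction", DEFAULT_FLE_FRACTION)),
        anisotropic=bool(cfg.get("anisotropic", False)),
        noise_free=bool(cfg.get("noise_free", False)),
    )
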