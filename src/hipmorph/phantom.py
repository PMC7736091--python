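"""Synthetic data: geometric hip phantoms and paired measurement cohorts.

Two generators stand in for patient radiographs:

* :func:`build_hip_phantom` inverts the angle definitions analytically and
  emits a contour annotation whose ground-truth Tönnis/Sharp/CE angles are
  prescribed. The system under test consumes traced contours, so synthetic
  contours (not rasterized images) are the right fidelity level. Noise-free
  phantoms are the round-trip oracle for the whole measurement chain;
  Gaussian contour jitter emulates tracing imprecision.
* :func:`simulate_cohort` draws latent per-hip angle triples from a
  correlated trivariate normal calibrated to the reference study's
  descriptive statistics, and derives paired physician/CAD observations
  with independent measurement noise sized so the physician-CAD
  correlation sits near 0.9. Threshold labels computed from both sources
  feed the evaluation and SVM pipelines end to end.

What these phantoms do **not** emulate: osteophytes, contour occlusion,
reader bias that depends on severity, and pixel-level appearance. Passing
round-trip tests therefore validates the geometry and statistics code,
not segmentation robustness on real films.

Phantom construction (per hip, in teardrop-anchored lateral/superior
coordinates): the rim point P sits on the ray from the teardrop at the
Sharp angle above line *a*, at a fixed teardrop-rim distance; the head
center C is then placed so that P is exactly on the ray from C at the CE
angle off the pelvic vertical; the sourcil medial point M is set medially
of P so the sourcil chord makes the Tönnis angle with line *a*. The
femoral arc samples the head circle; the acetabular arc is a quadratic
Bezier from P through M to the fossa floor. When Sharp + CE = 90° the two
defining rays are parallel (C would be collinear with teardrop and rim)
and construction is refused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import (
    ContourTrace,
    HipAnnotation,
    PelvisAnnotation,
    Point2D,
)
from .classification import classify_ce, classify_sharp, classify_tonnis, dichotomize_ce
from .errors import ParameterError, PhantomConstructionError
from .geometry import PelvisFrame, build_frame

#: Angular sweep (degrees) of the sampled femoral arc, measured from the
#: superior pole toward lateral then medial-inferior; wide enough that the
#: teardrop chord always re-crosses the sampled arc for study-range angles.
FEMORAL_ARC_SWEEP_DEG = (-30.0, 270.0)
#: How close (degrees) Sharp + CE may come to 90 before the defining rays
#: are treated as parallel.
PARALLEL_RAY_EPS_DEG = 1e-6

_TABLE_ANGLES = ("tonnis", "sharp", "ce")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth targets and construction constants for one hip phantom.

    ``rim_distance`` (teardrop to lateral acetabular margin) and
    ``center_distance`` (head center to margin) are construction scales in
    pixels; the defaults reproduce the package's canonical worked geometry
    (head center (100, 100), teardrop (80, 120), rim (110, 80) for
    Tönnis 10°, Sharp 53.130°, CE 26.565°). Angles are scale-invariant, so
    these scales do not affect the measured values.
    """

    tonnis_deg: float
    sharp_deg: float
    ce_deg: float
    head_radius: float = 25.0
    teardrop_separation: float = 140.0
    arc_sampling: int = 100
    jitter_sd: float = 0.0
    seed: int = 0
    rim_distance: float = 50.0
    center_distance: float = math.sqrt(500.0)
    sourcil_length: float = 20.0

    def __post_init__(self) -> None:
        if not 5.0 < self.sharp_deg < 85.0:
            raise ParameterError(f"sharp_deg must lie in (5, 85), got {self.sharp_deg}")
        for name in ("head_radius", "teardrop_separation", "rim_distance",
                     "center_distance", "sourcil_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.arc_sampling < 3:
            raise ParameterError("arc_sampling must be at least 3")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")
        for name in ("tonnis_deg", "ce_deg"):
            v = getattr(self, name)
            if not -90.0 < v < 90.0:
                raise ParameterError(f"{name} must lie in (-90, 90), got {v}")


def _hip_geometry(spec: PhantomSpec) -> dict:
    """Solve the phantom geometry in (lateral, superior) coordinates
    anchored at the teardrop inferior point."""
    s = math.radians(spec.sharp_deg)
    c = math.radians(spec.ce_deg)
    t = math.radians(spec.tonnis_deg)
    if abs(spec.sharp_deg + spec.ce_deg - 90.0) < PARALLEL_RAY_EPS_DEG:
        raise PhantomConstructionError(
            "sharp_deg + ce_deg = 90: the teardrop-rim ray and the CE ray are "
            "parallel, so the rim point is not a unique ray intersection"
        )
    # rim point on the Sharp ray
    p = spec.rim_distance * np.array([math.cos(s), math.sin(s)])
    if p[1] <= 0:
        raise PhantomConstructionError("rim point is not superior to the teardrop line")
    # head center: P lies on the ray from C at the CE angle off the vertical
    ce_dir = np.array([math.sin(c), math.cos(c)])
    center = p - spec.center_distance * ce_dir
    # sourcil medial point: the sourcil chord M->P makes the Tönnis angle
    m = p - spec.sourcil_length * np.array([math.cos(t), math.sin(t)])
    return {"rim": p, "center": center, "sourcil_medial": m}


def _femoral_arc_local(spec: PhantomSpec, center: np.ndarray) -> np.ndarray:
    lo, hi = FEMORAL_ARC_SWEEP_DEG
    phi = np.radians(np.linspace(lo, hi, spec.arc_sampling))
    # phi = 0 at the superior pole, 90 deg at the lateral pole
    return center + spec.head_radius * np.column_stack([np.sin(phi), np.cos(phi)])


def _acetabular_arc_local(
    spec: PhantomSpec, rim: np.ndarray, sourcil_medial: np.ndarray
) -> np.ndarray:
    fossa = np.array([3.0, 8.0])  # fossa floor, just superolateral to the teardrop
    # quadratic Bezier through the sourcil medial point at its midpoint
    control = 2.0 * sourcil_medial - 0.5 * (rim + fossa)
    u = np.linspace(0.0, 1.0, spec.arc_sampling)[:, None]
    return (1 - u) ** 2 * rim + 2 * u * (1 - u) * control + u**2 * fossa


def build_hip_phantom(
    spec: PhantomSpec, side: str, frame: PelvisFrame
) -> HipAnnotation:
    """Construct one annotated hip with prescribed ground-truth angles.

    The hip is anchored at the frame's teardrop for ``side`` and oriented
    by the frame's lateral/superior directions, so the same spec yields
    mirror-identical left and right hips. With ``jitter_sd > 0``, seeded
    Gaussian noise is added to every contour vertex (not to the manually
    marked points). Identical specs give byte-identical annotations.
    """
    geo = _hip_geometry(spec)
    femoral = _femoral_arc_local(spec, geo["center"])
    acetabular = _acetabular_arc_local(spec, geo["rim"], geo["sourcil_medial"])
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        femoral = femoral + rng.normal(0.0, spec.jitter_sd, femoral.shape)
        acetabular = acetabular + rng.normal(0.0, spec.jitter_sd, acetabular.shape)

    teardrop = frame.teardrop(side).as_array()
    lat = frame.lateral_unit(side)
    sup = frame.superior_unit

    def to_image(local: np.ndarray) -> np.ndarray:
        local = np.atleast_2d(local)
        return teardrop + np.outer(local[:, 0], lat) + np.outer(local[:, 1], sup)

    return HipAnnotation(
        side=side,
        acetabular_arc=ContourTrace(to_image(acetabular), "acetabular_arc", side),
        femoral_arc=ContourTrace(to_image(femoral), "femoral_arc", side),
        sourcil_medial=Point2D.of(to_image(geo["sourcil_medial"])[0]),
        teardrop_inferior=frame.teardrop(side),
    )


def build_pelvis_phantom(
    spec_left: PhantomSpec,
    spec_right: PhantomSpec | None = None,
    *,
    image_id: str = "phantom",
    origin: tuple[float, float] = (80.0, 120.0),
) -> PelvisAnnotation:
    """A full two-hip phantom radiograph annotation.

    Teardrops sit on a horizontal line *a* starting at ``origin`` (the
    anatomical-right teardrop, image left), separated by the left spec's
    ``teardrop_separation``. With ``spec_right=None`` the left spec is
    mirrored.
    """
    spec_right = spec_right or spec_left
    x0, y0 = origin
    frame = build_frame(
        teardrop_left=Point2D(x0 + spec_left.teardrop_separation, y0),
        teardrop_right=Point2D(x0, y0),
    )
    return PelvisAnnotation(
        image_id=image_id,
        left=build_hip_phantom(spec_left, "left", frame),
        right=build_hip_phantom(spec_right, "right", frame),
    )


# ---------------------------------------------------------------------------
# Paired physician/CAD measurement cohorts
# ---------------------------------------------------------------------------

#: Reference-study descriptive statistics (reader measurements): per-angle
#: mean and SD for (Tönnis, Sharp, CE) in degrees.
READER_MEAN = (8.490, 39.897, 28.129)
READER_SD = (6.510, 4.178, 8.090)
#: Mean CAD-minus-reader offsets from the same study.
CAD_BIAS = (-0.523, 0.988, -1.292)
#: Target correlation between paired physician and CAD measurements.
TARGET_PAIR_CORRELATION = 0.9

# Split each observed variance into latent truth plus measurement noise so
# that two independent observations of the same hip correlate at the target:
# sd_latent = sd_obs * sqrt(rho), sd_noise = sd_obs * sqrt(1 - rho).
_LATENT_SD = tuple(s * math.sqrt(TARGET_PAIR_CORRELATION) for s in READER_SD)
_NOISE_SD = tuple(s * math.sqrt(1.0 - TARGET_PAIR_CORRELATION) for s in READER_SD)

#: Plausible clinical inter-angle correlations (steeper sourcil and flatter
#: socket both accompany reduced lateral coverage); configurable, not a
#: study-reported quantity.
DEFAULT_ANGLE_CORRELATION = (
    (1.0, 0.4, -0.6),
    (0.4, 1.0, -0.5),
    (-0.6, -0.5, 1.0),
)


@dataclass(frozen=True)
class CohortParams:
    """Distributional parameters of a simulated paired-measurement cohort."""

    n_hips: int = 248
    latent_mean: tuple = READER_MEAN
    latent_sd: tuple = _LATENT_SD
    physician_noise_sd: tuple = _NOISE_SD
    cad_noise_sd: tuple = _NOISE_SD
    cad_bias: tuple = CAD_BIAS
    correlation: tuple = DEFAULT_ANGLE_CORRELATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hips < 10:
            raise ParameterError("a cohort needs at least 10 hips")
        for name in ("latent_mean", "latent_sd", "physician_noise_sd",
                     "cad_noise_sd", "cad_bias"):
            if len(getattr(self, name)) != 3:
                raise ParameterError(f"{name} needs one entry per angle (3)")
        if any(s <= 0 for s in self.latent_sd):
            raise ParameterError("latent_sd entries must be positive")
        if any(s < 0 for s in self.physician_noise_sd + self.cad_noise_sd):
            raise ParameterError("noise SDs must be non-negative")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ParameterError("correlation must be a symmetric 3x3 matrix")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ParameterError("correlation matrix is not positive semi-definite")

    def covariance(self) -> np.ndarray:
        d = np.diag(self.latent_sd)
        return d @ np.asarray(self.correlation, dtype=float) @ d


def simulate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a paired physician/CAD measurement table with threshold labels.

    Returns a DataFrame with one row per hip: latent truth, physician and
    CAD observations per angle, and the threshold labels each source
    implies (the physician columns are the reference standard downstream).
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    latent = rng.multivariate_normal(
        params.latent_mean, params.covariance(), size=params.n_hips,
        method="cholesky",
    )
    phys = latent + rng.normal(0.0, params.physician_noise_sd, latent.shape)
    cad = (
        latent
        + np.asarray(params.cad_bias)
        + rng.normal(0.0, params.cad_noise_sd, latent.shape)
    )
    df = pd.DataFrame({"hip_id": [f"hip-{i:04d}" for i in range(params.n_hips)]})
    for j, angle in enumerate(_TABLE_ANGLES):
        df[f"{angle}_true"] = latent[:, j]
        df[f"{angle}_physician"] = phys[:, j]
        df[f"{angle}_cad"] = cad[:, j]
    rules = {"tonnis": classify_tonnis, "sharp": classify_sharp, "ce": classify_ce}
    for source in ("physician", "cad"):
        for rule, fn in rules.items():
            df[f"label_{rule}_{source}"] = df[f"{rule}_{source}"].map(fn)
        df[f"label_ce2_{source}"] = df[f"label_ce_{source}"].map(dichotomize_ce)
    return df


def cohort_annotations(
    df: pd.DataFrame,
    *,
    jitter_sd: float = 0.0,
    seed: int = 0,
    image_prefix: str = "sim",
) -> list[PelvisAnnotation]:
    """Render a simulated cohort as contour annotations, two hips per image.

    Consecutive rows are paired into (right, left) hips of one pelvis; the
    cohort size must therefore be even. Hip truth angles become the
    phantom targets; the returned annotations can be fed through the full
    measure -> classify -> evaluate chain.
    """
    if len(df) % 2:
        raise ParameterError("cohort_annotations needs an even number of hips")
    out: list[PelvisAnnotation] = []
    for img_idx in range(len(df) // 2):
        rows = df.iloc[2 * img_idx: 2 * img_idx + 2]
        specs = [
            PhantomSpec(
                tonnis_deg=row["tonnis_true"],
                sharp_deg=row["sharp_true"],
                ce_deg=row["ce_true"],
                jitter_sd=jitter_sd,
                seed=seed + 2 * img_idx + k,
            )
            for k, (_, row) in enumerate(rows.iterrows())
        ]
        out.append(
            build_pelvis_phantom(
                specs[1], specs[0], image_id=f"{image_prefix}-{img_idx:04d}"
            )
        )
    return out
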