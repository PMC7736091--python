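"""Shared fixtures: the published validation tables and the canonical
worked phantom geometry used as hand-checked oracles throughout."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from hipmorph.annotation_io import (
    ContourTrace,
    HipAnnotation,
    PelvisAnnotation,
    Point2D,
)
from hipmorph.evaluation import ConfusionTable
from hipmorph.geometry import PelvisFrame, build_frame
from hipmorph.phantom import PhantomSpec, build_pelvis_phantom

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

# Canonical worked geometry: teardrop (80, 120), rim (110, 80), head center
# (100, 100) r=25, sourcil medial (90.30, 83.47); hand trigonometry gives
TONNIS_CANON = 10.0
SHARP_CANON = math.degrees(math.atan2(40.0, 30.0))     # 53.13010...
CE_CANON = math.degrees(math.atan2(10.0, 20.0))        # 26.56505...

# Published reference-reader vs CAD confusion tables from the clinical
# validation study of this measurement approach (n = 248 hips).
TONNIS_TABLE = (("normal", "dysplasia"), [[155, 8], [19, 66]])
SHARP_TABLE = (("normal", "dysplasia"), [[204, 9], [8, 27]])
CE3_TABLE = (("normal", "dysplasia", "borderline"),
             [[154, 2, 18], [0, 23, 4], [6, 14, 27]])
CE2_TABLE = (("normal", "abnormal"), [[154, 20], [6, 68]])


@pytest.fixture(scope="session")
def tonnis_table() -> ConfusionTable:
    return ConfusionTable(*TONNIS_TABLE)


@pytest.fixture(scope="session")
def sharp_table() -> ConfusionTable:
    return ConfusionTable(*SHARP_TABLE)


@pytest.fixture(scope="session")
def ce3_table() -> ConfusionTable:
    return ConfusionTable(*CE3_TABLE)


@pytest.fixture(scope="session")
def ce2_table() -> ConfusionTable:
    return ConfusionTable(*CE2_TABLE)


@pytest.fixture()
def worked_frame() -> PelvisFrame:
    """Horizontal frame in which the hip anchored at teardrop (80, 120) has
    lateral = +x (its mirror teardrop sits at x = -60)."""
    return build_frame(Point2D(80.0, 120.0), Point2D(-60.0, 120.0),
                       infer_sides=False)


@pytest.fixture()
def canonical_spec() -> PhantomSpec:
    return PhantomSpec(TONNIS_CANON, SHARP_CANON, CE_CANON)


@pytest.fixture()
def canonical_pelvis(canonical_spec) -> PelvisAnnotation:
    return build_pelvis_phantom(canonical_spec, image_id="canonical")


def transform_annotation(
    ann: PelvisAnnotation,
    angle_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
) -> PelvisAnnotation:
    """Apply a similarity transform (rotation + translation + uniform scale)
    to every coordinate of an annotation."""
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    t = np.asarray(translation, dtype=float)

    def tp(points: np.ndarray) -> np.ndarray:
        return scale * (np.atleast_2d(points) @ rot.T) + t

    def hip(h: HipAnnotation) -> HipAnnotation:
        return HipAnnotation(
            side=h.side,
            acetabular_arc=ContourTrace(tp(h.acetabular_arc.points), "acetabular_arc", h.side),
            femoral_arc=ContourTrace(tp(h.femoral_arc.points), "femoral_arc", h.side),
            sourcil_medial=Point2D.of(tp(h.sourcil_medial.as_array())[0]),
            teardrop_inferior=Point2D.of(tp(h.teardrop_inferior.as_array())[0]),
        )

    return PelvisAnnotation(
        image_id=ann.image_id,
        left=hip(ann.left),
        right=hip(ann.right),
        pixel_spacing=ann.pixel_spacing,
    )
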