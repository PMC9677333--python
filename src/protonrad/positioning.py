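"""Beam/target registration: isocenter detection, landmark similarity
transform, stage coordinates, spread statistics, and the ball-shadow QA
check.

The beam isocenter is the centroid of the collimator aperture seen in a
proton radiograph of the irradiation collimator (close-coupled geometry,
magnification assumed 1).  The treatment plan is aligned to the mouse
radiograph by a least-squares similarity transform (uniform scale,
rotation, translation; reflections disallowed) fitted to manually placed
landmark pairs; the target is then mapped into radiograph pixels, and the
lateral motor-stage shift follows from its offset to the isocenter and
the detector pitch, with the image-axis-to-stage-axis mapping taken from
a named convention entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .radiography import Radiograph

__all__ = [
    "LandmarkPairs",
    "SimilarityTransform2D",
    "Isocenter",
    "StageTarget",
    "QAResult",
    "AXIS_CONVENTIONS",
    "detect_isocenter",
    "fit_similarity",
    "map_target",
    "stage_shift",
    "target_spread",
    "qa_ball_shadow",
]


@dataclass
class LandmarkPairs:
    """n >= 2 paired (plan, radiograph) pixel coordinates, (row, col)."""

    plan: np.ndarray
    radio: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.plan = np.atleast_2d(np.asarray(self.plan, dtype=float))
        self.radio = np.atleast_2d(np.asarray(self.radio, dtype=float))
        if self.plan.shape != self.radio.shape or self.plan.shape[1] != 2:
            raise ValueError("plan and radio must be matching (n, 2) arrays")
        if len(self.plan) < 2:
            raise ValueError("need at least 2 landmark pairs")
        if len(np.unique(self.plan, axis=0)) != len(self.plan):
            raise ValueError("duplicated plan landmarks")


@dataclass
class SimilarityTransform2D:
    """x' = s R(theta) x + t on (row, col) pixel coordinates."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]
    rms_residual_px: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return self.scale * np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform2D":
        minv = np.linalg.inv(self.matrix)
        t = -minv @ np.asarray(self.translation)
        return SimilarityTransform2D(
            scale=1.0 / self.scale,
            rotation_deg=-self.rotation_deg,
            translation=(float(t[0]), float(t[1])),
        )

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_deg": self.rotation_deg,
            "translation_px": list(self.translation),
            "rms_residual_px": self.rms_residual_px,
        }


@dataclass
class Isocenter:
    """Subpixel aperture center in the collimator radiograph."""

    center: tuple[float, float]
    radius_px: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")


@dataclass
class StageTarget:
    """Lateral stage shifts (mm) relative to the current position."""

    x_mm: float
    y_mm: float
    convention: str = "detector-default"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_mm) and np.isfinite(self.y_mm)):
            raise ValueError("stage shifts must be finite")

    def to_dict(self) -> dict:
        return {"x_mm": self.x_mm, "y_mm": self.y_mm, "convention": self.convention}


@dataclass
class QAResult:
    """Daily-QA outcome from the ball-shadow film check."""

    spot_offset_mm: float | None
    shadow_offset_mm: float | None
    passed: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "spot_offset_mm": self.spot_offset_mm,
            "shadow_offset_mm": self.shadow_offset_mm,
            "passed": self.passed,
            "reason": self.reason,
        }


def detect_isocenter(collimator_radiograph: Radiograph) -> Isocenter:
    """Locate the beam isocenter as the collimator aperture centroid.

    Otsu threshold, largest bright connected component, intensity-weighted
    subpixel centroid (weights above threshold), equivalent-disk radius.
    Quality flags are raised when the component touches the image border
    or its circularity 4*pi*A/P^2 falls below 0.8.
    """
    img = collimator_radiograph.image
    thresh = threshold_otsu(img)
    mask = img > thresh
    if not mask.any():
        raise ValueError("no component above threshold")
    labels = sk_label(mask, connectivity=2)
    props = regionprops(labels, intensity_image=img)
    biggest = max(props, key=lambda p: p.area)
    comp = labels == biggest.label
    weights = np.clip(img - thresh, 0, None) * comp
    total = weights.sum()
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    center = (float((rr * weights).sum() / total), float((cc * weights).sum() / total))
    radius = math.sqrt(biggest.area / math.pi)

    flags: dict = {}
    r0, c0, r1, c1 = biggest.bbox
    if r0 == 0 or c0 == 0 or r1 == img.shape[0] or c1 == img.shape[1]:
        flags["touches_border"] = True
    perimeter = biggest.perimeter
    if perimeter > 0:
        circularity = 4.0 * math.pi * biggest.area / perimeter**2
        if circularity < 0.8:
            flags["low_circularity"] = round(float(circularity), 4)
    return Isocenter(center=center, radius_px=radius, flags=flags)


def fit_similarity(pairs: LandmarkPairs) -> SimilarityTransform2D:
    """Closed-form least-squares similarity transform from landmark pairs.

    Centroid-centred complex formulation: with z = row + i col, the
    optimal s e^{i theta} is sum(conj(p) q) / sum(|p|^2) over centred
    coordinates; reflections are excluded by construction.  Exact on
    consistent pairs for any n >= 2.
    """
    p = pairs.plan[:, 0] + 1j * pairs.plan[:, 1]
    q = pairs.radio[:, 0] + 1j * pairs.radio[:, 1]
    pc, qc = p - p.mean(), q - q.mean()
    denom = np.vdot(pc, pc).real
    if denom < 1e-12:
        raise np.linalg.LinAlgError("degenerate landmark configuration: plan points coincide")
    a = np.vdot(pc, qc) / denom  # vdot conjugates the first argument
    scale = abs(a)
    if scale <= 0:
        raise np.linalg.LinAlgError("degenerate landmark configuration")
    theta = math.degrees(np.angle(a))
    t = q.mean() - a * p.mean()
    residuals = np.abs(a * pc - qc)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return SimilarityTransform2D(
        scale=float(scale),
        rotation_deg=float(theta),
        translation=(float(t.real), float(t.imag)),
        rms_residual_px=rms,
    )


def map_target(transform: SimilarityTransform2D, target_plan_px) -> np.ndarray:
    """Forward-map a plan-pixel target into radiograph pixels."""
    return transform.apply(target_plan_px)[0]


# stage-axis conventions: how image (row, col) offsets map onto the motor
# stage's (x, y) axes.  Hardware-specific; registered by name.
AXIS_CONVENTIONS: dict[str, dict[str, tuple[str, float]]] = {
    # beam's-eye detector view: +col -> +x, +row (downwards) -> -y
    "detector-default": {"x": ("col", 1.0), "y": ("row", -1.0)},
    # same handedness, but stage x opposes the image columns
    "detector-flipped-x": {"x": ("col", -1.0), "y": ("row", -1.0)},
}


def stage_shift(
    target_radio_px,
    isocenter: Isocenter,
    pitch_mm: float,
    axis_convention: str = "detector-default",
) -> StageTarget:
    """Lateral stage shift that brings the target onto the isocenter."""
    if axis_convention not in AXIS_CONVENTIONS:
        raise KeyError(
            f"unknown axis convention {axis_convention!r}; "
            f"registered: {sorted(AXIS_CONVENTIONS)}"
        )
    conv = AXIS_CONVENTIONS[axis_convention]
    target = np.asarray(target_radio_px, dtype=float)
    d = {"row": target[0] - isocenter.center[0], "col": target[1] - isocenter.center[1]}
    shifts = {ax: sign * d[comp] * pitch_mm for ax, (comp, sign) in conv.items()}
    return StageTarget(x_mm=shifts["x"], y_mm=shifts["y"], convention=axis_convention)


def target_spread(targets: Sequence[StageTarget]) -> tuple[float, float]:
    """Mean (and sd of) Euclidean distance of targets to their centroid, mm."""
    if len(targets) < 2:
        raise ValueError("spread needs at least 2 targets")
    xy = np.array([[t.x_mm, t.y_mm] for t in targets])
    dists = np.linalg.norm(xy - xy.mean(axis=0), axis=1)
    return float(dists.mean()), float(dists.std())


def qa_ball_shadow(
    film_image: np.ndarray,
    expected_center_px: tuple[float, float],
    pixel_size_mm: float,
    tolerance_mm: float = 0.5,
) -> QAResult:
    """Verify the daily-QA film: dark collimator spot with the steel-ball
    shadow as an unirradiated bright area at its center.

    Segments the dark (irradiated) spot, then the bright shadow inside
    it; passes when both centers lie within ``tolerance_mm`` of the
    expected beam position and the shadow is contained in the spot.
    """
    from scipy import ndimage

    img = np.asarray(film_image, dtype=float)
    thresh = threshold_otsu(img)
    dark = img < thresh
    if not dark.any():
        return QAResult(None, None, False, "no spot: film appears blank")
    # a real irradiated spot is far darker than the unexposed film; on a
    # blank film Otsu merely splits the noise around its mean
    contrast = img[~dark].mean() - img[dark].mean()
    if contrast < 0.25 * img[~dark].mean():
        return QAResult(None, None, False, "no spot: film appears blank")
    labels = sk_label(dark, connectivity=2)
    props = regionprops(labels)
    spot_prop = max(props, key=lambda p: p.area)
    if spot_prop.area < 25:
        return QAResult(None, None, False, "no spot: largest dark region too small")
    spot = labels == spot_prop.label
    filled = ndimage.binary_fill_holes(spot)
    shadow = filled & ~spot
    if not shadow.any():
        return QAResult(None, None, False, "no shadow inside the irradiated spot")
    sh_labels = sk_label(shadow, connectivity=2)
    sh_prop = max(regionprops(sh_labels), key=lambda p: p.area)

    exp = np.asarray(expected_center_px, dtype=float)
    spot_center = np.array(ndimage.center_of_mass(filled))
    shadow_center = np.array(sh_prop.centroid)
    spot_off = float(np.linalg.norm(spot_center - exp) * pixel_size_mm)
    shadow_off = float(np.linalg.norm(shadow_center - exp) * pixel_size_mm)
    passed = spot_off <= tolerance_mm and shadow_off <= tolerance_mm
    reason = "" if passed else "center offset exceeds tolerance"
    return QAResult(spot_off, shadow_off, passed, reason)
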