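"""Proton radiograph formation and image-quality metrics.

Raw flat-panel frames carry two additive backgrounds: a detector dark
signal and a beam-fluence profile.  Both are estimated from dedicated
calibration stacks and subtracted frame-by-frame; the corrected frames are
then combined by a per-pixel median, which is robust against the
salt-and-pepper noise typical of direct proton hits on the panel.

Quality metrics follow the usual definitions: SNR = S/sigma and
CNR = (S_a - S_b)/sigma, with S the ROI mean and sigma a population
(divide-by-N) standard deviation; for CNR, sigma is taken from the
low-contrast (background) ROI.  Edge response is characterised by the FWHM
of the scattering-induced fluence-enhancement peak next to a material
edge, and spatial resolution by Michelson contrast of line-pair groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "Radiograph",
    "RoiSpec",
    "QualityReport",
    "correct_frames",
    "stack_median",
    "compute_snr",
    "compute_cnr",
    "edge_fwhm",
    "line_pair_resolution",
    "acquisition_time",
    "imaging_dose",
    "detectability_vs_frames",
]

DEFAULT_PIXEL_PITCH_MM = 0.05
DEFAULT_FRAME_RATE_HZ = 8.4


@dataclass
class FrameStack:
    """Ordered stack of 2D detector frames plus acquisition metadata.

    ``role`` distinguishes object frames ("raw") from the dark-signal and
    beam-background calibration stacks ("dark", "beam").
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    beam: tuple[float, float] = (200.0, 0.1)  # (energy_MeV, current_nA)
    role: str = "raw"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, rows, cols) stack")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.role not in ("raw", "dark", "beam"):
            raise ValueError("role must be one of raw/dark/beam")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Radiograph:
    """A corrected, stacked 2D image with physical pitch and provenance."""

    image: np.ndarray
    pixel_pitch_mm: float
    n_frames: int = 1
    acquisition_time_s: float | None = None
    estimated_dose_mGy: float | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("radiograph image must be 2D")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("radiograph must contain finite values")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")


@dataclass(frozen=True)
class RoiSpec:
    """Half-open pixel ranges [row0, row1) x [col0, col1), 0-based."""

    row0: int
    row1: int
    col0: int
    col1: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI must be non-empty")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        if self.row0 < 0 or self.col0 < 0 or self.row1 > shape[0] or self.col1 > shape[1]:
            raise ValueError(f"ROI {self} outside image bounds {shape}")

    def extract(self, image: np.ndarray) -> np.ndarray:
        self.check_bounds(image.shape)
        return image[self.row0 : self.row1, self.col0 : self.col1]

    def overlaps(self, other: "RoiSpec") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )


@dataclass
class QualityReport:
    """Container for image-quality metrics of one radiograph."""

    snr: float | None = None
    cnr: float | None = None
    edge_fwhm_mm: float | None = None
    resolved_lp_per_mm: float | None = None
    detectability: "pd.DataFrame | None" = None  # noqa: F821 - filled lazily

    def to_dict(self) -> dict:
        out = {
            "snr": self.snr,
            "cnr": self.cnr,
            "edge_fwhm_mm": self.edge_fwhm_mm,
            "resolved_lp_per_mm": self.resolved_lp_per_mm,
        }
        if self.detectability is not None:
            out["detectability"] = self.detectability.to_dict(orient="records")
        return out


def correct_frames(raw: FrameStack, dark: FrameStack, beam: FrameStack) -> FrameStack:
    """Subtract dark and beam backgrounds from every raw frame.

    ``I_dark`` is the pixelwise mean of the dark stack; ``I_beam`` the
    pixelwise mean of the beam stack after removing ``I_dark`` from it (the
    beam stack was itself recorded with the detector dark signal present).
    Each output frame is ``raw - I_dark - I_beam``.
    """
    for stack in (dark, beam):
        if stack.shape != raw.shape:
            raise ValueError(
                f"frame shape mismatch: raw {raw.shape} vs {stack.role} {stack.shape}"
            )
    i_dark = dark.frames.mean(axis=0)
    i_beam = beam.frames.mean(axis=0) - i_dark
    return FrameStack(
        frames=raw.frames - i_dark - i_beam,
        pixel_pitch_mm=raw.pixel_pitch_mm,
        frame_rate_hz=raw.frame_rate_hz,
        beam=raw.beam,
        role="raw",
    )


def stack_median(frames: FrameStack) -> Radiograph:
    """Combine a stack by the per-pixel median.

    An even frame count uses the mean of the two central order statistics.
    The median tolerates up to floor((n-1)/2) impulse-corrupted values per
    pixel without any change in output.
    """
    image = np.median(frames.frames, axis=0)
    return Radiograph(
        image=image,
        pixel_pitch_mm=frames.pixel_pitch_mm,
        n_frames=frames.n_frames,
        acquisition_time_s=acquisition_time(frames.n_frames, frames.frame_rate_hz),
    )


def compute_snr(radiograph: Radiograph, roi: RoiSpec) -> float:
    """SNR = mean/std of the ROI pixels (population std). Inf when std = 0."""
    values = roi.extract(radiograph.image)
    if values.size < 2:
        raise ValueError("SNR requires at least 2 pixels")
    sigma = values.std()  # population convention (ddof=0)
    if sigma == 0:
        return math.inf
    return float(values.mean() / sigma)


def compute_cnr(radiograph: Radiograph, roi_a: RoiSpec, roi_b: RoiSpec) -> float:
    """CNR = (mean_a - mean_b)/sigma_b, signed; sigma from the background ROI."""
    if roi_a.overlaps(roi_b):
        raise ValueError("CNR ROIs must be disjoint")
    a = roi_a.extract(radiograph.image)
    b = roi_b.extract(radiograph.image)
    diff = a.mean() - b.mean()
    sigma = b.std()
    if sigma == 0:
        return math.copysign(math.inf, diff) if diff != 0 else 0.0
    return float(diff / sigma)


class NoEdgeEnhancementError(RuntimeError):
    """Raised when no fluence-enhancement peak rises above the plateau."""


def edge_fwhm(radiograph: Radiograph, roi: RoiSpec, edge_axis: int = 0) -> float:
    """FWHM (mm) of the scatter-induced fluence peak next to a material edge.

    ``edge_axis`` is the axis along which the edge runs (0: edge is
    vertical, profiles run along rows/columns accordingly).  Profile lines
    perpendicular to the edge are averaged; the far-field plateau is
    estimated from the outer 20% of samples on each side, and the peak's
    full width at half its excess over the plateau is found by linear
    interpolation between samples.

    Raises :class:`NoEdgeEnhancementError` when the peak excess does not
    exceed the plateau by more than 3x the far-field noise.
    """
    patch = roi.extract(radiograph.image)
    # average lines parallel to the edge -> 1D profile across the edge
    profile = patch.mean(axis=edge_axis)
    if min(patch.shape) < 2 or profile.size < 8:
        raise ValueError("ROI too small to extract an edge profile")

    k = max(2, profile.size // 5)
    left, right = profile[:k], profile[-k:]
    plateau = max(np.median(left), np.median(right))
    noise = max(float(np.std(left)), float(np.std(right)))

    ipk = int(np.argmax(profile))
    excess = profile[ipk] - plateau
    if excess <= 3.0 * noise or excess <= 0:
        raise NoEdgeEnhancementError(
            "no fluence enhancement peak above plateau + 3*noise"
        )
    half = plateau + excess / 2.0

    def _cross(start: int, step: int) -> float:
        i = start
        while 0 <= i + step < profile.size and profile[i + step] > half:
            i += step
        j = i + step
        if j < 0 or j >= profile.size:
            return float(i)  # peak truncated by ROI edge; use boundary
        # linear interpolation between samples i (above) and j (below)
        frac = (profile[i] - half) / (profile[i] - profile[j])
        return i + step * frac

    width_px = abs(_cross(ipk, +1) - _cross(ipk, -1))
    return float(width_px * radiograph.pixel_pitch_mm)


def _michelson(profile: np.ndarray) -> float:
    hi, lo = float(profile.max()), float(profile.min())
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def line_pair_resolution(
    radiograph: Radiograph,
    grid_spec: Sequence[tuple[float, RoiSpec]],
    background: RoiSpec | None = None,
    bar_axis: int = 0,
    min_contrast: float = 0.1,
) -> tuple[float, bool]:
    """Highest resolved line-pair frequency (lp/mm) of a bar-grid image.

    ``grid_spec`` lists (frequency_lp_per_mm, roi) pairs.  For each group
    the image is averaged along the bars (``bar_axis``) and the Michelson
    contrast (max-min)/(max+min) of the resulting profile is computed.  A
    group is resolved when its contrast exceeds ``min_contrast`` and 3x the
    contrast measured the same way in the flat ``background`` region.
    Returns ``(frequency, warning)`` with frequency 0 and a warning flag
    when nothing is resolved.
    """
    noise_contrast = 0.0
    if background is not None:
        noise_contrast = _michelson(background.extract(radiograph.image).mean(axis=bar_axis))
    resolved = 0.0
    for freq, roi in sorted(grid_spec, key=lambda fr: fr[0]):
        profile = roi.extract(radiograph.image).mean(axis=bar_axis)
        contrast = _michelson(profile)
        if contrast > min_contrast and contrast > 3.0 * noise_contrast:
            resolved = freq
    return resolved, resolved == 0.0


def acquisition_time(n_frames: int, frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> float:
    """Acquisition time in seconds: n_frames / frame_rate."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    return n_frames / frame_rate_hz


def imaging_dose(
    n_frames: int,
    dose_rate_mGy_per_s: float,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
) -> float:
    """Imaging dose in mGy: acquisition time x geometry-calibrated dose rate.

    The dose rate is a per-setup calibration constant (it depends on beam
    energy, current and the object position in the field), supplied via
    configuration rather than hard-coded.
    """
    if dose_rate_mGy_per_s < 0:
        raise ValueError("dose rate must be non-negative")
    return acquisition_time(n_frames, frame_rate_hz) * dose_rate_mGy_per_s


def detectability_vs_frames(
    frames: FrameStack,
    feature_rois: Sequence[tuple[float, RoiSpec, RoiSpec]],
    dose_rate_mGy_per_s: float,
    cnr_threshold: float = 4.0,
    n_values: Iterable[int] | None = None,
) -> "pd.DataFrame":  # noqa: F821
    """Detectability of small features versus number of stacked frames.

    ``feature_rois`` lists (feature_size_mm, roi_feature, roi_background)
    triples.  For each n (default 1..N), the first n frames are
    median-stacked and each feature's CNR computed; a feature is detectable
    when |CNR| exceeds ``cnr_threshold`` (Rose criterion).  Returns a table
    with one row per n: time, dose, CNR of the smallest feature, and the
    smallest detectable feature size (NaN if none).
    """
    import pandas as pd

    if frames.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if n_values is None:
        n_values = range(1, frames.n_frames + 1)
    rows = []
    for n in n_values:
        sub = FrameStack(
            frames.frames[:n],
            pixel_pitch_mm=frames.pixel_pitch_mm,
            frame_rate_hz=frames.frame_rate_hz,
            beam=frames.beam,
        )
        radio = stack_median(sub)
        cnrs = {
            size: compute_cnr(radio, roi_f, roi_b)
            for size, roi_f, roi_b in feature_rois
        }
        detectable = [s for s, c in cnrs.items() if abs(c) > cnr_threshold]
        smallest = min(detectable) if detectable else math.nan
        rows.append(
            {
                "n_frames": n,
                "time_s": acquisition_time(n, frames.frame_rate_hz),
                "dose_mGy": imaging_dose(n, dose_rate_mGy_per_s, frames.frame_rate_hz),
                "cnr": cnrs[min(cnrs)],
                "smallest_resolved_feature_mm": smallest,
            }
        )
    return pd.DataFrame(rows)
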