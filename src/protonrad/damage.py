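"""Tile-wise relative DNA-damage maps and dose-damage correlation.

Nuclei (DAPI) and damage foci clusters (gamma-H2AX) are counted as
prominence-thresholded local maxima (see :mod:`protonrad.maxima`); counts
are aggregated on a square tile grid (256 px by default, matching the
slide-scanner tiling) and the relative damage of a tile is the fraction
of its nuclei that are gamma-H2AX positive.  Tiles with too few nuclei
are flagged invalid rather than reporting unstable ratios.  An aligned
damage/dose pair can then be reduced to profiles along the beam axis and
summarised by a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .beam import DoseMap2D
from .maxima import find_maxima
from .radiography import RoiSpec

__all__ = [
    "FluorescenceImage",
    "DamageTileMap",
    "AlignedDamage",
    "ProfileReport",
    "DEFAULT_PROMINENCES",
    "damage_map",
    "align_to_dose",
    "profile_correlation",
]

DEFAULT_PROMINENCES = (600.0, 1400.0)  # (DAPI, gamma-H2AX)
DEFAULT_TILE_PX = 256
DEFAULT_MIN_CELLS = 5


@dataclass
class FluorescenceImage:
    """Single-channel 16-bit fluorescence image with physical pixel size."""

    image: np.ndarray
    pixel_size_mm: float = 0.000325
    channel: str = "DAPI"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("fluorescence image must be 2D")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")
        if self.channel not in ("DAPI", "gH2AX"):
            raise ValueError("channel must be DAPI or gH2AX")


@dataclass
class DamageTileMap:
    """Per-tile nucleus counts, damage counts and relative-damage ratios."""

    n_dapi: np.ndarray
    n_damage: np.ndarray
    ratio: np.ndarray  # NaN where invalid
    valid: np.ndarray
    partial: np.ndarray  # edge tiles smaller than the nominal tile
    tile_px: int
    pixel_size_mm: float
    image_shape: tuple[int, int]

    @property
    def tile_size_mm(self) -> float:
        return self.tile_px * self.pixel_size_mm

    def to_frame(self):
        import pandas as pd

        nr, nc = self.n_dapi.shape
        rows = []
        for i in range(nr):
            for j in range(nc):
                rows.append(
                    {
                        "tile_row": i,
                        "tile_col": j,
                        "n_dapi": int(self.n_dapi[i, j]),
                        "n_damage": int(self.n_damage[i, j]),
                        "ratio": self.ratio[i, j],
                        "valid": bool(self.valid[i, j]),
                        "partial": bool(self.partial[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _detect(image: np.ndarray, prominence: float) -> np.ndarray:
    """Maxima filtered for cell counting.

    The maxima finder always reports the global maximum; for counting,
    a summit only qualifies as a cell when its prominence clears the
    channel threshold, so the noise ceiling of a featureless image is
    not counted.
    """
    m = find_maxima(np.asarray(image, dtype=float), prominence)
    return m[m["prominence"] >= prominence]


def _count_per_tile(maxima: np.ndarray, shape, tile_px: int) -> np.ndarray:
    nt_r = (shape[0] + tile_px - 1) // tile_px
    nt_c = (shape[1] + tile_px - 1) // tile_px
    counts = np.zeros((nt_r, nt_c), dtype=int)
    if len(maxima):
        np.add.at(counts, (maxima["row"] // tile_px, maxima["col"] // tile_px), 1)
    return counts


def damage_map(
    dapi: FluorescenceImage,
    gh2ax: FluorescenceImage,
    tile_px: int = DEFAULT_TILE_PX,
    prominences: tuple[float, float] = DEFAULT_PROMINENCES,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> DamageTileMap:
    """Tile-wise relative DNA damage from a (DAPI, gamma-H2AX) pair.

    Maxima are detected once per whole channel and binned into tiles, so
    tile counts sum to the whole-image counts.  Per tile the damage count
    is clipped to the nucleus count (the ratio is a fraction of cells);
    tiles with fewer than ``min_cells`` nuclei are invalid.  Edge tiles
    smaller than ``tile_px`` are processed but flagged partial.
    """
    if dapi.image.shape != gh2ax.image.shape:
        raise ValueError("channel images must be congruent")
    shape = dapi.image.shape
    n_dapi = _count_per_tile(_detect(dapi.image, prominences[0]), shape, tile_px)
    n_gh2ax = _count_per_tile(_detect(gh2ax.image, prominences[1]), shape, tile_px)
    n_damage = np.minimum(n_gh2ax, n_dapi)
    valid = n_dapi >= min_cells
    ratio = np.full(n_dapi.shape, np.nan)
    ratio[valid] = n_damage[valid] / n_dapi[valid]
    partial = np.zeros(n_dapi.shape, dtype=bool)
    if shape[0] % tile_px:
        partial[-1, :] = True
    if shape[1] % tile_px:
        partial[:, -1] = True
    return DamageTileMap(
        n_dapi=n_dapi,
        n_damage=n_damage,
        ratio=ratio,
        valid=valid,
        partial=partial,
        tile_px=tile_px,
        pixel_size_mm=dapi.pixel_size_mm,
        image_shape=shape,
    )


@dataclass
class AlignedDamage:
    """Relative-damage field resampled onto a dose grid."""

    dose: DoseMap2D
    damage: np.ndarray  # same shape as dose.dose, NaN where invalid
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.damage.shape != self.dose.dose.shape:
            raise ValueError("damage field must match the dose grid")


def align_to_dose(
    tile_map: DamageTileMap, dose: DoseMap2D, affine_2d: np.ndarray | None = None
) -> AlignedDamage:
    """Resample the tile-map ratio field into dose-grid coordinates.

    ``affine_2d`` is a 3x3 homogeneous matrix mapping damage-image
    physical coordinates (mm, (row, col) order) into dose physical
    coordinates; identity when omitted (grids share an origin).  Each
    dose pixel takes the value of the nearest tile; validity flags are
    carried along, and dose pixels falling outside the tile grid are
    invalid.
    """
    if affine_2d is None:
        affine_2d = np.eye(3)
    affine_2d = np.asarray(affine_2d, dtype=float)
    if affine_2d.shape != (3, 3):
        raise ValueError("affine_2d must be a 3x3 homogeneous matrix")
    if abs(np.linalg.det(affine_2d)) < 1e-12:
        raise np.linalg.LinAlgError("singular alignment transform")
    inv = np.linalg.inv(affine_2d)

    h, w = dose.dose.shape
    rr, cc = np.mgrid[0:h, 0:w]
    dose_mm = np.stack(
        [
            (rr.ravel() + 0.5) * dose.pixel_size_mm,  # pixel centres
            (cc.ravel() + 0.5) * dose.pixel_size_mm,
            np.ones(h * w),
        ]
    )
    img_mm = inv @ dose_mm
    tile_mm = tile_map.tile_size_mm
    ti = np.floor(img_mm[0] / tile_mm).astype(int)
    tj = np.floor(img_mm[1] / tile_mm).astype(int)
    nt_r, nt_c = tile_map.ratio.shape
    inside = (ti >= 0) & (ti < nt_r) & (tj >= 0) & (tj < nt_c)
    damage = np.full(h * w, np.nan)
    valid = np.zeros(h * w, dtype=bool)
    damage[inside] = tile_map.ratio[ti[inside], tj[inside]]
    valid[inside] = tile_map.valid[ti[inside], tj[inside]]
    damage[~valid] = np.nan
    return AlignedDamage(dose=dose, damage=damage.reshape(h, w), valid=valid.reshape(h, w))


@dataclass
class ProfileReport:
    """Binned dose and damage profiles along the beam axis."""

    coord_mm: np.ndarray
    dose_profile: np.ndarray
    damage_profile: np.ndarray
    pearson_r: float
    n_bins: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "n_bins": self.n_bins,
            "coord_mm": self.coord_mm.tolist(),
            "dose_profile": self.dose_profile.tolist(),
            "damage_profile": self.damage_profile.tolist(),
        }


def profile_correlation(
    aligned: AlignedDamage,
    box: RoiSpec,
    beam_axis: int | None = None,
    n_bins: int | None = None,
) -> ProfileReport:
    """Average dose and relative damage along the beam axis, plus Pearson r.

    The box (in dose-grid pixels) is split into ``n_bins`` equal bins
    along the beam axis; each bin averages dose over all its pixels and
    damage over its valid pixels.  Bins without any valid damage pixel
    are dropped from the correlation; at least 5 valid bins are required.
    """
    if beam_axis is None:
        beam_axis = aligned.dose.beam_axis
    dose = box.extract(aligned.dose.dose)
    damage = box.extract(aligned.damage)
    if beam_axis == 0:
        dose, damage = dose.T, damage.T
    n_along = dose.shape[1]
    if n_bins is None:
        n_bins = n_along
    edges = np.linspace(0, n_along, n_bins + 1).astype(int)

    coords, dose_prof, dmg_prof = [], [], []
    px = aligned.dose.pixel_size_mm
    offset = box.col0 if beam_axis == 1 else box.row0
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if hi <= lo:
            continue
        dose_bin = dose[:, lo:hi]
        dmg_bin = damage[:, lo:hi]
        coords.append((offset + 0.5 * (lo + hi)) * px)
        dose_prof.append(float(dose_bin.mean()))
        dmg_prof.append(
            float(np.nanmean(dmg_bin)) if np.isfinite(dmg_bin).any() else np.nan
        )
    coords = np.array(coords)
    dose_prof = np.array(dose_prof)
    dmg_prof = np.array(dmg_prof)
    ok = np.isfinite(dmg_prof)
    if ok.sum() < 5:
        raise ValueError(f"only {int(ok.sum())} valid bins; need at least 5")
    if np.ptp(dose_prof[ok]) == 0 or np.ptp(dmg_prof[ok]) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(dose_prof[ok], dmg_prof[ok]).statistic)
    return ProfileReport(
        coord_mm=coords,
        dose_profile=dose_prof,
        damage_profile=dmg_prof,
        pearson_r=r,
        n_bins=int(len(coords)),
    )
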