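"""2D treatment-plan construction and observer-agreement statistics.

A plan image is a sagittal maximum-intensity projection of the planning
volume together with a projected label image (0 background, 1 brain,
2 hippocampal region).  Agreement between observers delineating the
target region is quantified with Jaccard coefficients against a
majority-voted reference mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LabelImage2D",
    "AgreementReport",
    "mip_sagittal",
    "project_labels",
    "jaccard",
    "majority_vote",
    "agreement_study",
]

VALID_LABELS = (0, 1, 2)


@dataclass
class LabelImage2D:
    """2D integer label grid: 0 background, 1 brain, 2 hippocampal region."""

    labels: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2D")
        if not np.isin(self.labels, VALID_LABELS).all():
            raise ValueError(f"labels must be within {VALID_LABELS}")

    def mask(self, label: int = 2) -> np.ndarray:
        return self.labels == label


def mip_sagittal(volume: np.ndarray, slice_range: tuple[int, int]) -> np.ndarray:
    """Maximum-intensity projection over sagittal planes [start, stop).

    Sagittal planes are indexed along axis 0.  The usual central-skull
    projection uses 15-25 slices; ranges outside that window are allowed
    but warned about.
    """
    volume = np.asarray(volume)
    start, stop = slice_range
    if stop <= start:
        raise ValueError("empty slice range")
    if start < 0 or stop > volume.shape[0]:
        raise ValueError("slice range outside volume")
    n = stop - start
    if not 15 <= n <= 25:
        warnings.warn(
            f"{n} sagittal slices selected; 15-25 is the recommended window",
            stacklevel=2,
        )
    return volume[start:stop].max(axis=0)


def project_labels(
    label_volume: np.ndarray, slice_range: tuple[int, int], pixel_size_mm: float = 1.0
) -> LabelImage2D:
    """Priority label projection: hippocampus (2) wins over brain (1).

    Since the label priority coincides with the numeric order, this is a
    per-pixel maximum over the selected sagittal planes.
    """
    label_volume = np.asarray(label_volume)
    if not np.isin(label_volume, VALID_LABELS).all():
        raise ValueError(f"labels must be within {VALID_LABELS}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        projected = mip_sagittal(label_volume, slice_range)
    return LabelImage2D(projected, pixel_size_mm)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard coefficient |A n B| / |A u B|; 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0  # two empty contours agree perfectly
    return float(np.logical_and(a, b).sum() / union)


def majority_vote(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise majority of an odd number (>= 3) of binary masks."""
    if len(masks) < 3:
        raise ValueError("majority vote needs at least 3 masks")
    if len(masks) % 2 == 0:
        raise ValueError("majority vote needs an odd number of masks (ties)")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    return stack.sum(axis=0) > len(masks) / 2


@dataclass
class AgreementReport:
    """Per-plan Jaccard coefficients against majority-voted references."""

    inter_observer: list = field(default_factory=list)  # (animal, observer, J)
    intra_observer: list = field(default_factory=list)  # (animal, repeat, J)

    @staticmethod
    def _summary(values: list[float]) -> tuple[float, float]:
        arr = np.array(values, dtype=float)
        # population sd, matching small-n mean +/- sd reporting
        return float(arr.mean()), float(arr.std())

    @property
    def inter_mean_sd(self) -> tuple[float, float]:
        return self._summary([j for _, _, j in self.inter_observer])

    @property
    def intra_mean_sd(self) -> tuple[float, float]:
        return self._summary([j for _, _, j in self.intra_observer])

    def to_frame(self):
        import pandas as pd

        rows = [
            {"kind": "inter", "animal": a, "replicate": o, "jaccard": j}
            for a, o, j in self.inter_observer
        ] + [
            {"kind": "intra", "animal": a, "replicate": r, "jaccard": j}
            for a, r, j in self.intra_observer
        ]
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        im, isd = self.inter_mean_sd if self.inter_observer else (float("nan"),) * 2
        jm, jsd = self.intra_mean_sd if self.intra_observer else (float("nan"),) * 2
        return {
            "inter_observer_jaccard_mean": im,
            "inter_observer_jaccard_sd": isd,
            "intra_observer_jaccard_mean": jm,
            "intra_observer_jaccard_sd": jsd,
            "n_inter": len(self.inter_observer),
            "n_intra": len(self.intra_observer),
        }


def agreement_study(
    inter_plans: Mapping[str, Sequence[LabelImage2D]] | None = None,
    intra_plans: Mapping[str, Sequence[LabelImage2D]] | None = None,
    target_label: int = 2,
) -> AgreementReport:
    """Inter/intra-observer agreement over the projected target region.

    For each animal the reference mask F is the pixelwise majority of the
    observers' target masks (inter) or of one observer's repeated plans
    (intra); every plan is scored as J_i = jaccard(A_i, F).
    """
    report = AgreementReport()
    for plans, out, kind in (
        (inter_plans, report.inter_observer, "inter"),
        (intra_plans, report.intra_observer, "intra"),
    ):
        if plans is None:
            continue
        for animal, plan_list in plans.items():
            if len(plan_list) < 3:
                raise ValueError(
                    f"{kind}-observer agreement for {animal!r} needs >= 3 plans"
                )
            masks = [p.mask(target_label) for p in plan_list]
            reference = majority_vote(masks)
            for i, m in enumerate(masks):
                out.append((animal, i, jaccard(m, reference)))
    return report
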