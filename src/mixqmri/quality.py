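"""ROI-based image-quality surrogates: Weber contrast, CNR, CV.

The comparison scheme pairs tissues by morphologic weighting: on
PD-weighted fat-saturated images, cartilage is contrasted against
synovial fluid (with CV measured in fluid); on T1-weighted images,
cartilage is contrasted against the infrapatellar fat pad (with CV
measured in fat).  Paired ROIs have a nominal area of 2.11 mm^2 and the
single CV ROI 3.76 mm^2; all ROIs are placed from the label map (never
from intensities), so metric rows are deterministic given the stacks.

    Weber contrast  C_w = (SI_target - SI_ref) / SI_ref
    CNR             (SI_a - SI_b) / sqrt(sd_a^2 + sd_b^2)   (signed)
    CV              sd / mean                               (noise surrogate)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .acquisition import ImageStack
from .phantom import TissuePhantom, RoiSpec, roi_from_label, TISSUE_IDS

__all__ = [
    "RoiStats",
    "MetricsRow",
    "roi_stats",
    "weber_contrast",
    "cnr",
    "cv",
    "compare_sequences",
    "metrics_table",
    "PAIR_ROI_AREA_MM2",
    "CV_ROI_AREA_MM2",
]

PAIR_ROI_AREA_MM2 = 2.11
CV_ROI_AREA_MM2 = 3.76

#: reference tissue per weighting: (Weber/CNR reference, CV tissue)
_WEIGHTING_SCHEME = {
    "PD-w FS": "synovial_fluid",
    "T1-w": "infrapatellar_fat",
}


@dataclass(frozen=True)
class RoiStats:
    mean_si: float
    sd_si: float
    n_voxels: int


@dataclass
class MetricsRow:
    sequence: str
    weighting: str
    weber: float
    cnr: float
    cv: float
    rois: dict = field(default_factory=dict)


def roi_stats(volume: np.ndarray, roi: RoiSpec) -> RoiStats:
    """Arithmetic mean and population SD of the volume over the ROI voxels."""
    idx = np.asarray(roi.voxel_indices)
    if idx.size == 0:
        raise ValueError("empty ROI")
    if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
        raise ValueError("ROI extends outside the volume")
    vals = volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    return RoiStats(mean_si=float(vals.mean()), sd_si=float(vals.std()), n_voxels=len(vals))


def weber_contrast(si_target: float, si_reference: float) -> float:
    """(SI_target - SI_reference) / SI_reference."""
    if si_reference <= 0:
        raise ValueError("reference signal must be positive")
    return (si_target - si_reference) / si_reference


def cnr(si_a: float, si_b: float, sd_a: float, sd_b: float) -> float:
    """Signed contrast-to-noise ratio (SI_a - SI_b)/sqrt(sd_a^2 + sd_b^2)."""
    denom = sd_a**2 + sd_b**2
    if denom <= 0:
        raise ValueError("at least one ROI SD must be nonzero")
    return (si_a - si_b) / float(np.sqrt(denom))


def cv(sd: float, si: float) -> float:
    """Coefficient of variation sd/mean; higher values indicate stronger noise."""
    if si <= 0:
        raise ValueError("mean signal must be positive")
    return sd / si


def _morphologic_block_index(stack: ImageStack) -> int:
    """The morphologic (unprepared) block: first block with prep time 0."""
    for i, b in enumerate(stack.sequence.blocks):
        if b.prep_time_ms == 0:
            return i
    raise ValueError(f"sequence {stack.sequence.name!r} has no unprepared block")


def compare_sequences(
    stacks: Iterable[ImageStack],
    phantom: TissuePhantom,
    weighting: str,
    slice_index: int | None = None,
) -> list[MetricsRow]:
    """Per-sequence Weber/CNR/CV rows on the designated morphologic blocks.

    Weber and CNR use 2.11 mm^2 ROIs in femoral cartilage and the
    weighting's reference tissue (synovial fluid for PD-w FS, fat pad for
    T1-w); CV uses a 3.76 mm^2 ROI in the reference tissue.  ROIs are
    identical across sequences (placed once from the label map on the
    central slice by default).
    """
    if weighting not in _WEIGHTING_SCHEME:
        raise ValueError(f"weighting must be one of {sorted(_WEIGHTING_SCHEME)}")
    ref_name = _WEIGHTING_SCHEME[weighting]
    if slice_index is None:
        slice_index = phantom.shape[2] // 2
    cart_id = TISSUE_IDS["femoral_cartilage"]
    ref_id = TISSUE_IDS[ref_name]
    roi_cart = roi_from_label(phantom, cart_id, PAIR_ROI_AREA_MM2, slice_index)
    roi_ref = roi_from_label(phantom, ref_id, PAIR_ROI_AREA_MM2, slice_index)
    roi_cv = roi_from_label(phantom, ref_id, CV_ROI_AREA_MM2, slice_index)

    rows = []
    for stack in stacks:
        if stack.volumes[0].shape != phantom.shape:
            raise ValueError("stack/phantom shape mismatch")
        vol = stack.volumes[_morphologic_block_index(stack)]
        st_cart = roi_stats(vol, roi_cart)
        st_ref = roi_stats(vol, roi_ref)
        st_cv = roi_stats(vol, roi_cv)
        if st_cart.sd_si == 0 and st_ref.sd_si == 0:
            # degenerate noiseless ROIs: CNR undefined, reported as NaN
            cnr_val = float("nan")
        else:
            cnr_val = cnr(st_cart.mean_si, st_ref.mean_si, st_cart.sd_si, st_ref.sd_si)
        rows.append(
            MetricsRow(
                sequence=stack.sequence.name,
                weighting=weighting,
                weber=weber_contrast(st_cart.mean_si, st_ref.mean_si),
                cnr=cnr_val,
                cv=cv(st_cv.sd_si, st_cv.mean_si),
                rois={
                    "cartilage": roi_cart.voxel_indices.tolist(),
                    ref_name: roi_ref.voxel_indices.tolist(),
                    f"{ref_name}_cv": roi_cv.voxel_indices.tolist(),
                },
            )
        )
    return rows


def metrics_table(rows: Iterable[MetricsRow], phantom_id: str = "phantom-0") -> pd.DataFrame:
    """Tidy long-format table: phantom_id, sequence, weighting, metric, value."""
    records = []
    for r in rows:
        for metric in ("weber", "cnr", "cv"):
            records.append(
                {
                    "phantom_id": phantom_id,
                    "sequence": r.sequence,
                    "weighting": r.weighting,
                    "metric": metric,
                    "value": getattr(r, metric),
                }
            )
    return pd.DataFrame.from_records(records)
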