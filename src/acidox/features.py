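"""Per-patient imaging features.

The diagnostic and prognostic analyses operate on a handful of scalars per
patient: medians of MTR_asym, R2', rCBV and the combined acidity–hypoxia
product MTR_asym × R2' over the tumor ROI excluding necrosis (CET ∪ NET),
tumor volume, and the acidic tumor volume — the volume of tumor voxels
whose MTR_asym exceeds a normative-atlas threshold mean + k·SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .segment import Tissue, TumorROI

__all__ = [
    "PatientFeatures",
    "median_feature",
    "combined_map",
    "acidic_volume",
    "extract_features",
]

log = logging.getLogger(__name__)


@dataclass
class PatientFeatures:
    """One row of the per-patient feature table.

    Missing modalities (e.g. no multi-echo scan, hence no R2') are NaN and
    propagate to the derived product feature; such patients drop out of the
    affected analyses only.
    """

    median_mtr_asym_pct: float = np.nan
    median_r2prime_s: float = np.nan
    median_rcbv_au: float = np.nan
    median_mtrxr2p: float = np.nan
    tumor_volume_cm3: float = np.nan  # CET + NET
    acidic_volume_cm3: float = np.nan
    acidic_fraction_pct: float = np.nan
    age_years: float = np.nan
    treatment_status: str = "naive"  # naive | on_treatment
    idh: str = "NA"  # mutant | wildtype | NA
    codel_1p19q: str = "NA"  # codeleted | intact | NA
    egfr: str = "NA"  # amplified | non_amplified | NA
    os_days: float = np.nan
    os_event: int = 0
    pfs_days: float = np.nan
    pfs_event: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def median_feature(map_values: np.ndarray, roi_mask: np.ndarray) -> float:
    """Median of a parametric map over an ROI, ignoring invalid voxels.

    NaN voxels (missing or masked-out) do not contribute. Returns NaN when
    the ROI is empty or contains no valid voxel (missing modality semantics:
    missing, never zero).
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        return float("nan")
    vals = np.asarray(map_values, float)[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    log.debug("median_feature: %d contributing voxels", vals.size)
    return float(np.median(vals))


def combined_map(mtr_map: np.ndarray, r2prime_map: np.ndarray) -> np.ndarray:
    """Voxelwise MTR_asym × R2' map (combined acidity–hypoxia contrast).

    The patient-level feature is the median of this product over CET ∪ NET —
    which on heterogeneous tissue differs from the product of the two
    medians (the latter is available via ``product_of_medians`` in
    :func:`extract_features`).
    """
    mtr_map = np.asarray(mtr_map, float)
    r2prime_map = np.asarray(r2prime_map, float)
    if mtr_map.shape != r2prime_map.shape:
        raise ValueError("maps must share a grid")
    return mtr_map * r2prime_map


def acidic_volume(
    mtr_map: np.ndarray,
    roi: TumorROI,
    atlas_mean: float,
    atlas_sd: float,
    k_sd: float = 2.0,
) -> tuple[float, float]:
    """Acidic tumor volume (cm³) and fraction (%) of the CET ∪ NET ROI.

    A tumor voxel is acidic when its MTR_asym exceeds the normative-atlas
    threshold ``atlas_mean + k_sd·atlas_sd``. Fraction is 100 × acidic /
    tumor volume, NaN when the tumor volume is zero.
    """
    if atlas_sd <= 0:
        raise ValueError("atlas_sd must be positive")
    tumor = roi.mask(Tissue.CET, Tissue.NET)
    threshold = atlas_mean + k_sd * atlas_sd
    vals = np.asarray(mtr_map, float)
    acidic = tumor & np.isfinite(vals) & (vals > threshold)
    vol = int(acidic.sum()) * roi.voxel_volume_cm3
    tumor_vol = roi.volume_cm3(Tissue.CET, Tissue.NET)
    if tumor_vol > 0:
        frac = 100.0 * vol / tumor_vol
    else:
        frac = float("nan")
    return vol, frac


def extract_features(
    roi: TumorROI,
    mtr_map: np.ndarray | None = None,
    r2prime_map: np.ndarray | None = None,
    rcbv_map: np.ndarray | None = None,
    atlas_mean: float | None = None,
    atlas_sd: float | None = None,
    k_sd: float = 2.0,
    product_of_medians: bool = False,
    clinical: dict | None = None,
) -> PatientFeatures:
    """Assemble the full per-patient feature row from maps and ROI.

    Any map passed as None is treated as a missing modality (NaN features).
    By default the combined feature is the median of the voxelwise product;
    set ``product_of_medians`` to use the product of the two medians
    instead.
    """
    feats = PatientFeatures()
    tumor = roi.mask(Tissue.CET, Tissue.NET)
    feats.tumor_volume_cm3 = roi.volume_cm3(Tissue.CET, Tissue.NET)

    if mtr_map is not None:
        feats.median_mtr_asym_pct = median_feature(mtr_map, tumor)
    if r2prime_map is not None:
        feats.median_r2prime_s = median_feature(r2prime_map, tumor)
    if rcbv_map is not None:
        feats.median_rcbv_au = median_feature(rcbv_map, tumor)

    if mtr_map is not None and r2prime_map is not None:
        if product_of_medians:
            feats.median_mtrxr2p = feats.median_mtr_asym_pct * feats.median_r2prime_s
        else:
            feats.median_mtrxr2p = median_feature(combined_map(mtr_map, r2prime_map), tumor)

    if mtr_map is not None and atlas_mean is not None and atlas_sd is not None:
        vol, frac = acidic_volume(mtr_map, roi, atlas_mean, atlas_sd, k_sd)
        feats.acidic_volume_cm3 = vol
        feats.acidic_fraction_pct = frac

    for key, val in (clinical or {}).items():
        if not hasattr(feats, key):
            raise KeyError(f"unknown clinical field {key!r}")
        setattr(feats, key, val)
    return feats
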