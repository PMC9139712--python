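"""Tumor ROI delineation from anatomical volumes.

Three mutually exclusive tumor compartments are segmented by thresholding:

* CET — contrast-enhancing tumor: positive voxels on the pre/post T1
  subtraction map (each volume normalized to its reference-tissue median).
* necrosis — hypointense voxels on the subtraction map inside the filled
  CET hull (central necrosis does not enhance).
* NET — non-enhancing tumor: FLAIR-hyperintense voxels excluding CET and
  necrosis.

Normal-appearing white matter (NAWM) is everything in the brain mask away
from the (dilated) tumor, excluding CSF-like intensities; it serves as the
reference tissue for normalization throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

__all__ = ["Tissue", "TumorROI", "t1_subtraction", "segment_rois", "nawm_mask"]


class Tissue(IntEnum):
    BACKGROUND = 0
    NAWM = 1
    CET = 2
    NECROSIS = 3
    NET = 4


@dataclass
class TumorROI:
    """Mutually exclusive label volume over {background, NAWM, CET, necrosis, NET}."""

    labels: np.ndarray
    voxel_size_mm: tuple

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, [t.value for t in Tissue]).all():
            raise ValueError("labels contain values outside the tissue classes")
        if len(self.voxel_size_mm) != self.labels.ndim:
            raise ValueError("voxel_size_mm length must match label dimensionality")

    def mask(self, *tissues: Tissue) -> np.ndarray:
        return np.isin(self.labels, [t.value for t in tissues])

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def volume_cm3(self, *tissues: Tissue) -> float:
        return int(self.mask(*tissues).sum()) * self.voxel_volume_cm3


def t1_subtraction(
    pre_t1: np.ndarray, post_t1: np.ndarray, reference_mask: np.ndarray
) -> np.ndarray:
    """Normalized post-contrast minus normalized pre-contrast T1.

    Each volume is divided by its median over ``reference_mask`` (normally
    NAWM, or a provisional brain mask before segmentation exists), so the
    subtraction is in reference-tissue units and enhancing voxels come out
    positive regardless of scanner scaling.
    """
    pre_t1 = np.asarray(pre_t1, float)
    post_t1 = np.asarray(post_t1, float)
    if pre_t1.shape != post_t1.shape:
        raise ValueError("pre and post T1 grids must match")
    if reference_mask.shape != pre_t1.shape:
        raise ValueError("reference mask grid must match the T1 grids")
    m_pre = np.median(pre_t1[reference_mask])
    m_post = np.median(post_t1[reference_mask])
    if m_pre <= 0 or m_post <= 0:
        raise ValueError("reference medians must be positive for normalization")
    return post_t1 / m_post - pre_t1 / m_pre


def _keep_components(mask, min_voxels, seed_mask=None):
    """26-connected components; keep those intersecting the seed (if given)
    and larger than the size cutoff; otherwise keep all above cutoff."""
    if not mask.any():
        return mask
    lab = cc_label(mask, connectivity=mask.ndim)
    keep = np.zeros_like(mask)
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    for cid, cnt in zip(ids, counts):
        if cnt < min_voxels:
            continue
        comp = lab == cid
        if seed_mask is not None and not (comp & seed_mask).any():
            continue
        keep |= comp
    return keep


def segment_rois(
    subtraction: np.ndarray,
    flair: np.ndarray,
    brain_mask: np.ndarray,
    voxel_size_mm: tuple,
    subtraction_hi: float | None = None,
    subtraction_lo: float | None = None,
    flair_hi: float | None = None,
    reference_mask: np.ndarray | None = None,
    seed_mask: np.ndarray | None = None,
    min_component_cm3: float = 0.1,
) -> TumorROI:
    """Threshold-based tumor segmentation into CET / necrosis / NET + NAWM.

    Thresholds default to reference-tissue statistics: subtraction_hi =
    mean + 2·SD of the subtraction map over ``reference_mask``,
    subtraction_lo = mean − 2·SD, flair_hi = mean + 2·SD of FLAIR. CET is
    restricted to connected components above ``min_component_cm3``
    (26-connectivity) that touch ``seed_mask`` when one is provided (the
    semi-automated interaction); necrosis is the hypointense region inside
    the filled CET hull; NET is FLAIR-hyperintense tissue minus CET and
    necrosis. Remaining brain voxels become NAWM. Mutual exclusivity is
    guaranteed by construction and asserted.
    """
    subtraction = np.asarray(subtraction, float)
    flair = np.asarray(flair, float)
    brain_mask = np.asarray(brain_mask, bool)
    if subtraction.shape != flair.shape or subtraction.shape != brain_mask.shape:
        raise ValueError("subtraction, flair and brain mask grids must match")

    if reference_mask is None:
        reference_mask = brain_mask
    ref_sub = subtraction[reference_mask]
    ref_flair = flair[reference_mask]
    if subtraction_hi is None:
        subtraction_hi = float(ref_sub.mean() + 2.0 * ref_sub.std())
    if subtraction_lo is None:
        subtraction_lo = float(ref_sub.mean() - 2.0 * ref_sub.std())
    if flair_hi is None:
        flair_hi = float(ref_flair.mean() + 2.0 * ref_flair.std())

    voxel_cm3 = float(np.prod(voxel_size_mm)) / 1000.0
    min_vox = max(int(np.ceil(min_component_cm3 / voxel_cm3)), 1)

    cet = (subtraction > subtraction_hi) & brain_mask
    cet = _keep_components(cet, min_vox, seed_mask)
    if seed_mask is not None and seed_mask.any() and not cet.any():
        import warnings

        warnings.warn("seed provided but no enhancing component found; CET empty")

    hull = ndimage.binary_fill_holes(cet)
    necrosis = (subtraction < subtraction_lo) & hull & brain_mask & ~cet

    net = (flair > flair_hi) & brain_mask & ~cet & ~necrosis
    net = _keep_components(net, min_vox)

    labels = np.zeros(subtraction.shape, dtype=np.int16)
    labels[brain_mask] = Tissue.NAWM
    labels[net] = Tissue.NET
    labels[cet] = Tissue.CET
    labels[necrosis] = Tissue.NECROSIS

    assert not (cet & necrosis).any() and not (cet & net).any() and not (necrosis & net).any()
    return TumorROI(labels, tuple(voxel_size_mm))


def nawm_mask(
    roi: TumorROI,
    flair: np.ndarray | None = None,
    dilation_vox: int = 2,
    csf_flair_quantiles: tuple = (0.02, 0.98),
) -> np.ndarray:
    """Reference-tissue mask: brain minus dilated tumor minus CSF-like voxels.

    The tumor (CET ∪ necrosis ∪ NET) is dilated by ``dilation_vox`` voxels
    to exclude infiltrative margins. When a FLAIR volume is given, voxels in
    the extreme intensity tails (CSF-dark / lesion-bright) are also removed.
    Raises if the result is empty — a reference tissue is required.
    """
    brain = roi.labels > Tissue.BACKGROUND
    tumor = roi.mask(Tissue.CET, Tissue.NECROSIS, Tissue.NET)
    if dilation_vox > 0 and tumor.any():
        tumor = ndimage.binary_dilation(tumor, iterations=dilation_vox)
    out = brain & ~tumor
    if flair is not None and out.any():
        lo, hi = np.quantile(flair[out], csf_flair_quantiles)
        out &= (flair >= lo) & (flair <= hi)
    if not out.any():
        raise ValueError("NAWM mask is empty; reference tissue required")
    return out
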