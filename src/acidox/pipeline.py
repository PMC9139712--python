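"""End-to-end single-patient analysis on phantom or loaded data.

Chains the full voxelwise workflow: z-spectrum → B0 correction → MTR_asym;
SAGE echoes → R2/R2*/R2'; DSC → rCBV; anatomy → ROI segmentation → per-
patient features. Structural invariants (ROI exclusivity, NAWM rCBV
normalization, acidic ≤ tumor volume) are asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cest, dsc, features, phantom, sage, segment

__all__ = ["PatientAnalysis", "analyze_phantom_patient"]


@dataclass
class PatientAnalysis:
    roi: segment.TumorROI
    roi_true: segment.TumorROI
    nawm: np.ndarray
    mtr_map: np.ndarray
    b0: cest.B0Map
    relax: sage.RelaxMaps
    rcbv: np.ndarray
    feats: features.PatientFeatures
    atlas_mean: float
    atlas_sd: float


def analyze_phantom_patient(
    spec: phantom.PhantomSpec,
    noise_sigma: float | None = None,
    k_sd: float = 2.0,
    pin_delta: bool = True,
    clinical: dict | None = None,
) -> PatientAnalysis:
    """Simulate one phantom patient and run the full estimation pipeline.

    ``noise_sigma`` overrides the spec's noise for the raw image stacks.
    The SAGE fit pins δ = 1 by default (the simulator's truth) for speed;
    the acidity atlas statistics are taken from the phantom's NAWM voxels.
    """
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    roi_true, pmaps, anat = phantom.make_phantom(spec)
    brain = roi_true.labels > segment.Tissue.BACKGROUND
    b0_true = phantom.b0_field(spec)

    # acidity: simulate, correct B0, quantify
    zs = phantom.simulate_zspectrum(
        pmaps["mtr_asym"], b0_true, noise_sigma=sigma, seed=spec.seed + 10, mask=brain
    )
    b0 = cest.estimate_b0(zs)
    zc = cest.correct_b0(zs, b0)
    mtr_map = cest.mtr_asym(zc)

    # hypoxia
    series = phantom.simulate_sage(
        pmaps["r2"], pmaps["r2star"], noise_sigma=sigma, seed=spec.seed + 20, mask=brain
    )
    relax = sage.fit_sage(series, pin_delta=pin_delta)

    # perfusion
    ts = phantom.simulate_dsc(
        pmaps["cbv"], noise_sigma=sigma, seed=spec.seed + 30, mask=brain
    )
    dr2 = dsc.signal_to_dr2star(ts.signals, ts.baseline, ts.te_s, mask=brain)

    # segmentation from anatomy (provisional reference: whole brain)
    sub = segment.t1_subtraction(anat["t1pre"], anat["t1post"], brain)
    roi = segment.segment_rois(sub, anat["flair"], brain, spec.voxel_size_mm)
    nawm = segment.nawm_mask(roi, anat["flair"])

    rcbv = dsc.compute_rcbv(dr2, ts.time_s, nawm, mask=brain)

    atlas_vals = mtr_map[nawm]
    atlas_vals = atlas_vals[np.isfinite(atlas_vals)]
    atlas_mean, atlas_sd = float(atlas_vals.mean()), float(atlas_vals.std())

    r2p = np.where(relax.mask, relax.r2prime, np.nan)
    feats = features.extract_features(
        roi,
        mtr_map=mtr_map,
        r2prime_map=r2p,
        rcbv_map=rcbv,
        atlas_mean=atlas_mean,
        atlas_sd=atlas_sd,
        k_sd=k_sd,
        clinical=clinical,
    )

    _assert_invariants(roi, nawm, rcbv, feats)
    return PatientAnalysis(
        roi, roi_true, nawm, mtr_map, b0, relax, rcbv, feats, atlas_mean, atlas_sd
    )


def _assert_invariants(roi, nawm, rcbv, feats) -> None:
    t = segment.Tissue
    masks = [roi.mask(t.CET), roi.mask(t.NECROSIS), roi.mask(t.NET), nawm]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise AssertionError("ROI classes are not mutually exclusive")
    med = np.median(rcbv[nawm][np.isfinite(rcbv[nawm])])
    if not np.isclose(med, 1.0):
        raise AssertionError("NAWM median rCBV must equal 1 after normalization")
    if np.isfinite(feats.acidic_volume_cm3) and feats.acidic_volume_cm3 > feats.tumor_volume_cm3 + 1e-12:
        raise AssertionError("acidic volume exceeds tumor volume")
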