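"""Relative cerebral blood volume from dynamic susceptibility contrast MRI.

During a gadolinium bolus the susceptibility effect transiently raises the
effective transverse relaxation rate. The signal drop is converted to a
concentration-proportional curve ΔR2*(t) = −ln(S(t)/S̄_baseline)/TE, and the
blood-volume surrogate is the time integral of ΔR2* over the bolus,
optionally corrected for contrast-agent leakage (Boxerman–Weisskoff linear
fitting) and normalized so that the normal-appearing-white-matter (NAWM)
median equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DscTimeSeries", "signal_to_dr2star", "compute_rcbv"]


@dataclass
class DscTimeSeries:
    """DSC signal time courses.

    ``baseline`` is the half-open index range [start, stop) of pre-bolus
    timepoints (at least 5).
    """

    time_s: np.ndarray
    te_s: float
    signals: np.ndarray  # (..., n_t)
    baseline: tuple
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.te_s <= 0:
            raise ValueError("te_s must be positive")
        b0, b1 = self.baseline
        if b1 - b0 < 5:
            raise ValueError("need at least 5 baseline timepoints")
        if self.signals.shape[-1] != self.time_s.size:
            raise ValueError("signals last axis must match time_s")
        if self.mask.shape != self.signals.shape[:-1]:
            raise ValueError("mask shape must match signals spatial shape")


def signal_to_dr2star(
    signals: np.ndarray, baseline: tuple, te_s: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """ΔR2*(t) = −ln(S(t)/S̄_baseline)/TE per voxel.

    Timepoints with S ≤ 0 are returned as NaN for that voxel. Raises if any
    in-mask voxel has a non-positive baseline mean; out-of-mask voxels are
    returned as zero curves.
    """
    signals = np.asarray(signals, float)
    if mask is None:
        mask = np.ones(signals.shape[:-1], dtype=bool)
    b0, b1 = baseline
    sbar = signals[..., b0:b1].mean(axis=-1, keepdims=True)
    if np.any(sbar[mask] <= 0):
        raise ValueError("baseline mean must be positive for every in-mask voxel")
    out = np.zeros_like(signals)
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2 = -np.log(signals / sbar) / te_s
    dr2 = np.where(signals > 0, dr2, np.nan)
    out[mask] = dr2[mask]
    return out


def compute_rcbv(
    dr2star: np.ndarray,
    time_s: np.ndarray,
    nawm_mask: np.ndarray,
    integration_window: tuple | None = None,
    leakage_correction: bool = True,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """rCBV: bolus-integrated ΔR2*, NAWM-normalized.

    The trapezoidal integral of ΔR2* over ``integration_window`` (index
    range; default the full time axis) is divided by the NAWM median so
    that median rCBV over NAWM equals 1 exactly.

    With ``leakage_correction`` the Boxerman–Weisskoff two-regressor model
    is applied first: each voxel curve is regressed on the NAWM-mean curve
    and on minus its running integral,

        ΔR2*_vox(t) ≈ K1·ΔR2*_ref(t) − K2·∫0^t ΔR2*_ref dτ,

    and K2 times the running integral is added back before integration,
    removing the T1-leakage dip that otherwise biases rCBV downward.

    NaN samples (masked timepoints) are linearly interpolated across before
    integration.
    """
    dr2star = np.asarray(dr2star, float)
    time_s = np.asarray(time_s, float)
    nawm_mask = np.asarray(nawm_mask, bool)
    if not nawm_mask.any():
        raise ValueError("nawm_roi must be nonempty")
    if mask is None:
        mask = np.ones(dr2star.shape[:-1], dtype=bool)

    if integration_window is None:
        integration_window = (0, time_s.size)
    w0, w1 = integration_window
    if w0 < 0 or w1 > time_s.size or w1 - w0 < 2:
        raise ValueError("integration window must lie inside the acquisition")

    curves = dr2star.copy()
    bad = ~np.isfinite(curves)
    if bad.any():
        flat = curves.reshape(-1, time_s.size)
        for i in np.flatnonzero(bad.reshape(-1, time_s.size).any(axis=1)):
            row = flat[i]
            good = np.isfinite(row)
            if good.sum() >= 2:
                flat[i] = np.interp(time_s, time_s[good], row[good])
            else:
                flat[i] = 0.0

    if leakage_correction:
        ref = np.median(curves[nawm_mask], axis=0)
        cumint = np.concatenate(
            [[0.0], np.cumsum(0.5 * (ref[1:] + ref[:-1]) * np.diff(time_s))]
        )
        X = np.vstack([ref, -cumint]).T  # (n_t, 2)
        flat = curves.reshape(-1, time_s.size)
        coef, *_ = np.linalg.lstsq(X, flat.T, rcond=None)  # (2, n_vox)
        k2 = coef[1]
        flat = flat + k2[:, None] * cumint[None, :]
        curves = flat.reshape(curves.shape)

    integral = np.trapezoid(curves[..., w0:w1], time_s[w0:w1], axis=-1)
    nawm_med = np.median(integral[nawm_mask])
    if nawm_med <= 0:
        raise ValueError("NAWM median integral is non-positive; cannot normalize")
    rcbv = integral / nawm_med
    rcbv = np.where(mask, rcbv, np.nan)
    return rcbv
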