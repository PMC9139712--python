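"""Oxygen-sensitive relaxometry from spin-and-gradient-echo (SAGE) EPI.

A SAGE acquisition collects gradient echoes before the spin-echo refocusing
pulse and asymmetric spin echoes after it. Signal decay before te_se/2 is
governed by R2* alone; between te_se/2 and the spin echo the effective decay
mixes R2 and R2*:

    TE <  te_se/2 :  S(TE) = S0 · exp(−TE · R2*)
    TE >= te_se/2 :  S(TE) = S0 · δ · exp(−te_se · (R2* − R2)) · exp(−TE · (2·R2 − R2*))

δ absorbs slice-profile amplitude mismatch between the two regimes. Fitting
both regimes jointly yields R2 and R2* simultaneously, and the reversible
rate R2' = R2* − R2, which scales with paramagnetic deoxyhemoglobin content
and is used here as a hypoxia surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["SageEchoSeries", "RelaxMaps", "fit_sage", "r2prime", "sage_signal"]


@dataclass
class SageEchoSeries:
    """Multi-echo SAGE signals with timing.

    echo_times_s must be strictly increasing with at least two echoes before
    te_se/2 and at least two at/after; signals are (..., n_echo).
    """

    echo_times_s: np.ndarray
    te_se_s: float
    signals: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.echo_times_s = np.asarray(self.echo_times_s, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        te = self.echo_times_s
        if te.ndim != 1 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times_s must be 1-D strictly increasing")
        half = self.te_se_s / 2.0
        if np.sum(te < half) < 2 or np.sum(te >= half) < 2:
            raise ValueError("need >=2 echoes before te_se/2 and >=2 at/after")
        if self.signals.shape[-1] != te.size:
            raise ValueError("signals last axis must match echo_times_s")
        if self.mask.shape != self.signals.shape[:-1]:
            raise ValueError("mask shape must match signals spatial shape")
        if np.any(self.signals[self.mask] < 0):
            raise ValueError("signals must be non-negative inside mask")

    @property
    def spatial_shape(self) -> tuple:
        return self.mask.shape


@dataclass
class RelaxMaps:
    """Fitted relaxation-rate maps; r2prime = r2star − r2 identically."""

    r2: np.ndarray
    r2star: np.ndarray
    r2prime: np.ndarray
    s0: np.ndarray
    delta: np.ndarray
    fit_rss: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray  # voxels where nonlinear refinement failed; log-linear kept


def sage_signal(
    te: np.ndarray, te_se: float, s0: float, r2: float, r2star: float, delta: float = 1.0
) -> np.ndarray:
    """Forward SAGE model evaluated at echo times ``te``."""
    te = np.asarray(te, float)
    pre = te < te_se / 2.0
    out = np.empty_like(te)
    out[pre] = s0 * np.exp(-te[pre] * r2star)
    out[~pre] = (
        s0 * delta * np.exp(-te_se * (r2star - r2)) * np.exp(-te[~pre] * (2.0 * r2 - r2star))
    )
    return out


def _loglinear_init(te, te_se, sig):
    """Closed-form log-linear estimates (exact on noiseless model data)."""
    half = te_se / 2.0
    pre = te < half
    post = ~pre
    logs = np.log(sig)
    # gradient-echo regime: log S = log S0 − TE·R2*
    A = np.vstack([np.ones(pre.sum()), -te[pre]]).T
    c_pre, *_ = np.linalg.lstsq(A, logs[pre], rcond=None)
    log_s0, r2star = c_pre
    # spin-echo regime: log S = [log(S0·δ) − te_se·(R2*−R2)] − TE·(2R2−R2*)
    B = np.vstack([np.ones(post.sum()), -te[post]]).T
    c_post, *_ = np.linalg.lstsq(B, logs[post], rcond=None)
    icpt, slope = c_post  # slope = 2R2 − R2*
    r2 = (slope + r2star) / 2.0
    delta = np.exp(icpt + te_se * (r2star - r2) - log_s0)
    return np.exp(log_s0), r2, r2star, delta


def fit_sage(series: SageEchoSeries, pin_delta: bool = False) -> RelaxMaps:
    """Per-voxel nonlinear least-squares fit of the SAGE model.

    Initialization is log-linear (R2* from the pre-spin-echo slope, R2 from
    the spin-echo-regime slope), which is exact on noiseless model data; a
    Levenberg–Marquardt refinement of the untransformed residual follows.
    Voxels with any non-positive signal are masked out. If refinement fails
    the log-linear estimate is kept and the voxel flagged.

    Parameters
    ----------
    pin_delta : bool
        Fix the inter-regime amplitude factor δ to 1 instead of fitting it.
    """
    te = series.echo_times_s
    te_se = series.te_se_s
    shape = series.spatial_shape
    nan = np.full(shape, np.nan)
    maps = RelaxMaps(
        r2=nan.copy(), r2star=nan.copy(), r2prime=nan.copy(), s0=nan.copy(),
        delta=nan.copy(), fit_rss=nan.copy(), mask=series.mask.copy(),
        flagged=np.zeros(shape, dtype=bool),
    )
    vox_idx = np.flatnonzero(series.mask.reshape(-1))
    sig_flat = series.signals.reshape(-1, te.size)

    flat = {k: getattr(maps, k).reshape(-1) for k in
            ("r2", "r2star", "r2prime", "s0", "delta", "fit_rss")}
    mask_flat = maps.mask.reshape(-1)
    flag_flat = maps.flagged.reshape(-1)

    for i in vox_idx:
        sig = sig_flat[i]
        if np.any(sig <= 0):
            mask_flat[i] = False
            continue
        s0_0, r2_0, r2s_0, d_0 = _loglinear_init(te, te_se, sig)
        if pin_delta:
            d_0 = 1.0

        def resid(p):
            if pin_delta:
                s0, r2, r2star = p
                d = 1.0
            else:
                s0, r2, r2star, d = p
            return sage_signal(te, te_se, s0, r2, r2star, d) - sig

        x0 = [s0_0, r2_0, r2s_0] if pin_delta else [s0_0, r2_0, r2s_0, d_0]
        try:
            sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            ok = sol.success and np.all(np.isfinite(sol.x))
        except Exception:
            ok = False
        if ok:
            p = sol.x
            rss = float(np.sum(sol.fun**2))
        else:
            p = np.asarray(x0)
            rss = float(np.sum(resid(np.asarray(x0)) ** 2))
            flag_flat[i] = True
        if pin_delta:
            s0_f, r2_f, r2s_f, d_f = p[0], p[1], p[2], 1.0
        else:
            s0_f, r2_f, r2s_f, d_f = p
        flat["s0"][i] = s0_f
        flat["r2"][i] = r2_f
        flat["r2star"][i] = r2s_f
        flat["r2prime"][i] = r2s_f - r2_f
        flat["delta"][i] = d_f
        flat["fit_rss"][i] = rss
    return maps


def r2prime(r2star: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Reversible transverse relaxation rate R2' = R2* − R2 (elementwise).

    May be negative under noise; values are reported as-is, not clamped.
    """
    r2star = np.asarray(r2star, float)
    r2 = np.asarray(r2, float)
    return r2star - r2
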