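"""Digital glioma phantom and synthetic cohort generator.

Single-patient phantoms are concentric-ellipsoid tumors (non-enhancing rim
around an enhancing shell around a necrotic core) embedded in an ellipsoidal
brain of normal-appearing white matter, with class-constant parameter maps
(MTR_asym, R2, R2*, CBV, anatomical intensities), a smooth B0 offset field,
and Gaussian or Rician noise. Forward simulators produce the raw image
stacks the estimation modules consume:

* z-spectrum stacks from a 3-pool Lorentzian model (water, amine at
  +3.0 ppm, broad symmetric magnetization-transfer pool), with the amine
  amplitude calibrated so the noiseless band-averaged asymmetry equals the
  voxel's true MTR_asym;
* SAGE echo series from the two-regime R2/R2* decay model;
* DSC time series with a gamma-variate bolus whose amplitude scales with
  the voxel's true CBV.

Multi-patient cohorts draw per-patient median features from genotype-group
normal distributions and survival times from an exponential-baseline
proportional-hazards model with independent right censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cest import ZSpectrumStack, band_offsets
from .dsc import DscTimeSeries
from .sage import SageEchoSeries, sage_signal
from .segment import Tissue, TumorROI

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "GroupDef",
    "SurvivalModel",
    "CohortSpec",
    "make_phantom",
    "simulate_zspectrum",
    "simulate_sage",
    "simulate_dsc",
    "simulate_cohort",
    "default_offsets_ppm",
    "DEFAULT_TISSUE_PARAMS",
    "default_cohort_spec",
]


@dataclass
class TissueParams:
    """True per-class parameter values."""

    mtr_asym_pct: float
    r2_s: float
    r2star_s: float
    cbv_au: float
    t1post_intensity: float
    flair_intensity: float

    def __post_init__(self) -> None:
        if self.r2star_s < self.r2_s:
            raise ValueError("r2star must be >= r2 (R2' cannot be negative in truth)")
        if min(self.t1post_intensity, self.flair_intensity) < 0:
            raise ValueError("intensities must be non-negative")


# Class-constant defaults. NAWM anchors the normalization conventions
# (rCBV 1, anatomical intensity 1); tumor classes are separated enough for
# threshold segmentation to have a well-defined ground truth, with contrasts
# in the range reported for gliomas (tumor MTR_asym ~1–2.5%, R2' ~4–8 1/s,
# rCBV up to ~2 in enhancing tumor, low-perfusion necrotic core).
DEFAULT_TISSUE_PARAMS: dict[Tissue, TissueParams] = {
    Tissue.NAWM: TissueParams(1.0, 12.0, 16.0, 1.0, 1.0, 1.0),
    Tissue.CET: TissueParams(2.2, 15.0, 22.0, 2.0, 1.9, 1.35),
    Tissue.NET: TissueParams(1.8, 14.0, 19.5, 1.3, 1.0, 1.9),
    Tissue.NECROSIS: TissueParams(1.5, 9.0, 12.0, 0.25, 0.2, 1.2),
}


def default_offsets_ppm(step: float = 0.25, span: float = 4.0) -> np.ndarray:
    """Symmetric saturation-offset grid including 0 and the ±3 ppm band."""
    n = int(round(span / step))
    return np.arange(-n, n + 1) * step


@dataclass
class PhantomSpec:
    """Full generative description of a single-patient phantom."""

    grid_shape: tuple = (48, 48, 16)
    voxel_size_mm: tuple = (2.0, 2.0, 4.0)
    tissue_params: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_PARAMS))
    b0_field_ppm: float = 0.0  # peak amplitude of the smooth B0 offset field
    noise_sigma: float = 0.0  # additive noise scale relative to S0
    seed: int = 0
    # tumor geometry (semi-axes in voxels; class absent when None)
    net_radius_vox: float | None = 11.0
    cet_radius_vox: float | None = 7.0
    necrosis_radius_vox: float | None = 3.0
    boundary_jitter: float = 0.15  # relative radial jitter of class boundaries
    tumor_center_frac: tuple = (0.62, 0.40, 0.5)  # tumor center, fraction of grid

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        radii = [r for r in (self.net_radius_vox, self.cet_radius_vox,
                             self.necrosis_radius_vox) if r is not None]
        if radii != sorted(radii, reverse=True):
            raise ValueError("tumor radii must be nested: NET >= CET >= necrosis")


def _smooth_field(shape, rng, n_modes: int = 3) -> np.ndarray:
    """Smooth random field in [-1, 1] built from a few low-order cosines."""
    coords = [np.linspace(0, np.pi, s) for s in shape]
    grid = np.meshgrid(*coords, indexing="ij")
    out = np.zeros(shape)
    for _ in range(n_modes):
        ks = rng.integers(1, 4, size=len(shape))
        phases = rng.uniform(0, 2 * np.pi, size=len(shape))
        term = np.ones(shape)
        for g, k, p in zip(grid, ks, phases):
            term = term * np.cos(k * g + p)
        out += rng.uniform(0.3, 1.0) * term
    m = np.abs(out).max()
    return out / m if m > 0 else out


def make_phantom(spec: PhantomSpec):
    """Build label volume, true parameter maps and anatomical volumes.

    Returns ``(roi, parameter_maps, anatomical)`` where ``parameter_maps``
    holds per-voxel true ``mtr_asym`` (%), ``r2``, ``r2star``, ``cbv`` and
    ``anatomical`` holds ``t1pre``, ``t1post``, ``flair``. Background voxels
    are zero in every map. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    idx = np.indices(shape, dtype=float)

    # ellipsoidal brain filling ~90% of each axis
    center = np.array([(s - 1) / 2.0 for s in shape])
    semi = np.array([0.45 * s for s in shape])
    r2_brain = sum(((idx[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    brain = r2_brain <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = Tissue.NAWM

    radii = {
        Tissue.NET: spec.net_radius_vox,
        Tissue.CET: spec.cet_radius_vox,
        Tissue.NECROSIS: spec.necrosis_radius_vox,
    }
    any_tumor = any(r is not None for r in radii.values())
    if any_tumor:
        tc = np.array([f * (s - 1) for f, s in zip(spec.tumor_center_frac, shape)])
        # anisotropic voxels: radii are in-plane voxels, scaled by voxel size
        vs = np.asarray(spec.voxel_size_mm)
        scale = vs / vs[0]
        dist = np.sqrt(sum(((idx[d] - tc[d]) * scale[d]) ** 2 for d in range(3)))
        jitter = spec.boundary_jitter * _smooth_field(shape, rng)
        eff = dist * (1.0 + jitter)
        # nested assignment: outer first, inner classes overwrite
        for cls in (Tissue.NET, Tissue.CET, Tissue.NECROSIS):
            r = radii[cls]
            if r is None:
                continue
            ideal = eff <= r
            region = ideal & brain
            # the nested shapes must actually fit inside the brain
            if not region.any() or region.sum() < 0.8 * ideal.sum():
                raise ValueError(
                    f"grid too small to contain the {cls.name} shape (radius {r} vox)"
                )
            labels[region] = cls
        if not (labels == Tissue.NAWM).any():
            raise ValueError("grid too small: tumor leaves no normal-appearing tissue")

    roi = TumorROI(labels, tuple(spec.voxel_size_mm))

    pmaps = {k: np.zeros(shape) for k in ("mtr_asym", "r2", "r2star", "cbv")}
    anat = {k: np.zeros(shape) for k in ("t1pre", "t1post", "flair")}
    for cls, tp in spec.tissue_params.items():
        m = labels == cls
        pmaps["mtr_asym"][m] = tp.mtr_asym_pct
        pmaps["r2"][m] = tp.r2_s
        pmaps["r2star"][m] = tp.r2star_s
        pmaps["cbv"][m] = tp.cbv_au
        anat["t1post"][m] = tp.t1post_intensity
        anat["flair"][m] = tp.flair_intensity
    # pre-contrast T1: uniform brain intensity (enhancement only appears post)
    anat["t1pre"][brain] = 1.0
    # necrotic core is moderately dark pre-contrast and darker post-contrast,
    # so it reads as hypointense on the subtraction map
    anat["t1pre"][labels == Tissue.NECROSIS] = 0.7

    if spec.noise_sigma > 0:
        for vol in anat.values():
            vol += rng.normal(0.0, spec.noise_sigma, size=shape) * brain

    return roi, pmaps, anat


def b0_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth B0 offset field (ppm) with peak amplitude ``spec.b0_field_ppm``."""
    rng = np.random.default_rng(spec.seed + 1)
    return spec.b0_field_ppm * _smooth_field(spec.grid_shape, rng)


# 3-pool Lorentzian z-spectrum phenomenology. Amplitudes/widths chosen so the
# water dip dominates near 0 ppm (for B0 estimation), the broad MT pool is
# symmetric (contributing no asymmetry), and the spectrum stays in (0, 1).
_WATER_AMP, _WATER_FWHM = 0.82, 2.2
_MT_AMP, _MT_FWHM = 0.06, 40.0
_AMINE_FWHM = 1.6
_AMINE_PPM = 3.0


def _lorentz(x: np.ndarray, fwhm: float) -> np.ndarray:
    return 1.0 / (1.0 + (2.0 * x / fwhm) ** 2)


def amine_asym_per_unit_amplitude(
    offsets_ppm: np.ndarray, center_ppm: float = _AMINE_PPM, halfband_ppm: float = 0.5
) -> float:
    """Band-averaged asymmetry produced by a unit-amplitude amine pool.

    Used to calibrate the amine amplitude so the noiseless band-averaged
    MTR_asym equals the requested truth on the given acquisition grid.
    """
    offs = np.asarray(offsets_ppm, float)
    sel = band_offsets(offs, center_ppm, halfband_ppm)
    pos = offs[sel]
    return float(
        np.mean(_lorentz(pos - _AMINE_PPM, _AMINE_FWHM))
        - np.mean(_lorentz(-pos - _AMINE_PPM, _AMINE_FWHM))
    )


def zspectrum_model(
    offsets_ppm: np.ndarray, amine_amp: np.ndarray, b0_ppm: np.ndarray
) -> np.ndarray:
    """Noiseless z-spectra Z(Δω) for per-voxel amine amplitude and B0 shift.

    Z = 1 − L_water(Δω − b0) − amine_amp·L_amine(Δω − b0 − 3.0) − L_MT(Δω − b0),
    clipped below at 0 so signals stay physical.
    """
    offs = np.asarray(offsets_ppm, float)
    a = np.asarray(amine_amp, float)[..., None]
    b0 = np.asarray(b0_ppm, float)[..., None]
    x = offs - b0
    z = (
        1.0
        - _WATER_AMP * _lorentz(x, _WATER_FWHM)
        - a * _lorentz(x - _AMINE_PPM, _AMINE_FWHM)
        - _MT_AMP * _lorentz(x, _MT_FWHM)
    )
    return np.clip(z, 0.0, None)


def simulate_zspectrum(
    true_mtr_map: np.ndarray,
    b0_field_ppm: np.ndarray | float = 0.0,
    offsets_ppm: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    s0: float = 1000.0,
    rician: bool = False,
    halfband_ppm: float = 0.5,
) -> ZSpectrumStack:
    """Forward-simulate a z-spectrum stack from a true MTR_asym map (%).

    The amine amplitude of each voxel is set so that at zero B0 shift the
    band-averaged asymmetry on the acquisition grid equals the voxel's true
    MTR_asym. Offsets must be symmetric about 0 (asymmetry is otherwise
    undefined) and include the ±(2.5–3.5) ppm band. Noise is additive
    Gaussian with SD ``noise_sigma·s0`` (Rician optionally).
    """
    true_mtr_map = np.asarray(true_mtr_map, float)
    if offsets_ppm is None:
        offsets_ppm = default_offsets_ppm()
    offs = np.asarray(offsets_ppm, float)
    if not np.allclose(np.sort(-offs), offs, atol=1e-9):
        raise ValueError("offsets must be symmetric about 0")
    if band_offsets(offs, _AMINE_PPM, halfband_ppm).size == 0:
        raise ValueError("offsets must include the 2.5-3.5 ppm band")
    if mask is None:
        mask = np.ones(true_mtr_map.shape, dtype=bool)
    b0 = np.broadcast_to(np.asarray(b0_field_ppm, float), true_mtr_map.shape)

    cal = amine_asym_per_unit_amplitude(offs, halfband_ppm=halfband_ppm)
    amp = (true_mtr_map / 100.0) / cal
    z = zspectrum_model(offs, amp, b0)
    signals = s0 * z
    s0_map = np.full(true_mtr_map.shape, float(s0))

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma * s0, size=signals.shape)
        if rician:
            n2 = rng.normal(0.0, noise_sigma * s0, size=signals.shape)
            signals = np.sqrt((signals + n1) ** 2 + n2**2)
        else:
            signals = np.clip(signals + n1, 0.0, None)
    signals = signals * mask[..., None]
    return ZSpectrumStack(offs, signals, s0_map, mask)


DEFAULT_ECHO_TIMES_S = np.array([0.008, 0.028, 0.060, 0.080, 0.100])
DEFAULT_TE_SE_S = 0.100


def simulate_sage(
    true_r2_map: np.ndarray,
    true_r2star_map: np.ndarray,
    s0_map: np.ndarray | float = 1000.0,
    echo_times_s: np.ndarray | None = None,
    te_se_s: float = DEFAULT_TE_SE_S,
    noise_sigma: float = 0.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    delta: float = 1.0,
    rician: bool = False,
) -> SageEchoSeries:
    """Forward-simulate a SAGE echo series from true R2/R2* maps (1/s)."""
    true_r2_map = np.asarray(true_r2_map, float)
    true_r2star_map = np.asarray(true_r2star_map, float)
    if echo_times_s is None:
        echo_times_s = DEFAULT_ECHO_TIMES_S
    te = np.asarray(echo_times_s, float)
    if mask is None:
        mask = np.ones(true_r2_map.shape, dtype=bool)
    s0 = np.broadcast_to(np.asarray(s0_map, float), true_r2_map.shape)

    half = te_se_s / 2.0
    pre = te < half
    signals = np.empty(true_r2_map.shape + (te.size,))
    signals[..., pre] = s0[..., None] * np.exp(-te[pre] * true_r2star_map[..., None])
    r2p = true_r2star_map - true_r2_map
    signals[..., ~pre] = (
        s0[..., None]
        * delta
        * np.exp(-te_se_s * r2p[..., None])
        * np.exp(-te[~pre] * (2.0 * true_r2_map - true_r2star_map)[..., None])
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * float(np.mean(s0))
        n1 = rng.normal(0.0, scale, size=signals.shape)
        if rician:
            n2 = rng.normal(0.0, scale, size=signals.shape)
            signals = np.sqrt((signals + n1) ** 2 + n2**2)
        else:
            signals = np.clip(signals + n1, 1e-12, None)
    signals = signals * mask[..., None]
    return SageEchoSeries(te, te_se_s, signals, mask)


@dataclass
class AifParams:
    """Gamma-variate bolus shape: ΔR2*(t) = k·(t−t0)^α·exp(−(t−t0)/β) for t>t0."""

    t0_s: float = 30.0
    alpha: float = 3.0
    beta_s: float = 1.8
    peak_dr2star: float = 18.0  # peak ΔR2* (1/s) for a voxel with CBV = 1


def gamma_variate_dr2star(time_s: np.ndarray, aif: AifParams) -> np.ndarray:
    """Unit-CBV ΔR2*(t) bolus curve, scaled to ``aif.peak_dr2star`` at its peak."""
    t = np.asarray(time_s, float) - aif.t0_s
    curve = np.where(t > 0, np.power(np.clip(t, 0, None), aif.alpha) * np.exp(-t / aif.beta_s), 0.0)
    peak = curve.max()
    return aif.peak_dr2star * curve / peak if peak > 0 else curve


def simulate_dsc(
    true_cbv_map: np.ndarray,
    time_s: np.ndarray | None = None,
    aif: AifParams | None = None,
    te_s: float = 0.025,
    noise_sigma: float = 0.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    s0: float = 1000.0,
    leakage_rate: np.ndarray | float = 0.0,
) -> DscTimeSeries:
    """Forward-simulate DSC signal time series from a true CBV map (a.u.).

    Each voxel's ΔR2*(t) is the gamma-variate bolus scaled by its CBV;
    ``leakage_rate`` (1/s per unit of integrated bolus) optionally adds a
    T1-leakage term −L·∫ΔR2* dτ that depresses the post-bolus tail, the
    effect Boxerman-style correction removes. The baseline (t < t0) spans
    at least 5 timepoints.
    """
    true_cbv_map = np.asarray(true_cbv_map, float)
    if time_s is None:
        time_s = np.arange(90.0)  # 90 s at 1 s resolution
    time_s = np.asarray(time_s, float)
    if aif is None:
        aif = AifParams()
    n_base = int(np.sum(time_s < aif.t0_s))
    if n_base < 5:
        raise ValueError("need >= 5 pre-bolus baseline timepoints")
    if mask is None:
        mask = np.ones(true_cbv_map.shape, dtype=bool)

    unit = gamma_variate_dr2star(time_s, aif)
    dr2 = true_cbv_map[..., None] * unit
    L = np.broadcast_to(np.asarray(leakage_rate, float), true_cbv_map.shape)
    if np.any(L != 0):
        cumint = np.concatenate(
            [[0.0], np.cumsum(0.5 * (unit[1:] + unit[:-1]) * np.diff(time_s))]
        )
        dr2 = dr2 - L[..., None] * cumint
    signals = s0 * np.exp(-te_s * dr2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signals = np.clip(signals + rng.normal(0.0, noise_sigma * s0, size=signals.shape), 1e-9, None)
    signals = signals * mask[..., None]
    return DscTimeSeries(time_s, te_s, signals, (0, n_base), mask)


# ---------------------------------------------------------------------------
# Cohort generator


@dataclass
class GroupDef:
    """Genotype group: per-patient feature means/SDs and label assignment.

    Means/SDs are for the per-patient median features MTR_asym (%), R2'
    (1/s) and rCBV (a.u.); the combined feature is the product of the two
    per-patient draws, not separately parameterized.
    """

    idh: str
    mtr_mean: float
    mtr_sd: float
    r2p_mean: float
    r2p_sd: float
    rcbv_mean: float
    rcbv_sd: float
    codel_1p19q: str = "NA"
    egfr: str = "NA"

    def __post_init__(self) -> None:
        if min(self.mtr_sd, self.r2p_sd, self.rcbv_sd) < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class SurvivalModel:
    """Exponential-baseline proportional-hazards generator.

    hazard_i = baseline_hazard_per_day · exp(Σ log_hr[k]·x_ik). Censoring is
    independent exponential with per-patient rate λ_i·c/(1−c), which makes
    the per-patient censoring probability exactly ``censoring_rate``.
    ``log_hr`` keys name feature columns; 'age_years' enters centered at 52.
    """

    baseline_hazard_per_day: float = 7e-5
    log_hr: dict = field(default_factory=dict)
    censoring_rate: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must be in [0, 1)")
        if self.baseline_hazard_per_day <= 0:
            raise ValueError("baseline hazard must be positive")


_AGE_CENTER = 52.0


@dataclass
class CohortSpec:
    """Generative description of a synthetic patient cohort.

    Defaults reproduce the two-genotype structure of the study population:
    IDH-mutant vs wild-type feature distributions and an OS/PFS hazard that
    increases with age, active treatment and the combined acidity–hypoxia
    feature and decreases with IDH mutation.
    """

    n_per_group: dict = field(default_factory=lambda: {"idh_mutant": 70, "idh_wildtype": 89})
    group_defs: dict = field(default_factory=dict)
    survival_os: SurvivalModel = field(default_factory=lambda: SurvivalModel(
        baseline_hazard_per_day=7e-5,
        log_hr={
            "age_years": 0.034,
            "on_treatment": 1.32,
            "idh_mutant": -2.37,
            "median_mtrxr2p": 0.13,
        },
        censoring_rate=0.60,
    ))
    survival_pfs: SurvivalModel = field(default_factory=lambda: SurvivalModel(
        baseline_hazard_per_day=1.4e-4,
        log_hr={
            "age_years": 0.025,
            "on_treatment": 1.14,
            "idh_mutant": -1.98,
            "median_mtrxr2p": 0.16,
        },
        censoring_rate=0.50,
    ))
    frac_on_treatment: float = 63.0 / 159.0
    frac_single_echo: float = 0.0  # fraction lacking multi-echo data (missing R2')
    age_mean: float = 52.0
    age_sd: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_defs:
            self.group_defs = {
                "idh_mutant": GroupDef("mutant", 1.48, 0.45, 5.17, 1.74, 1.19, 0.44),
                "idh_wildtype": GroupDef("wildtype", 1.73, 0.50, 5.94, 1.54, 1.69, 0.85),
            }
        if set(self.n_per_group) != set(self.group_defs):
            raise ValueError("n_per_group and group_defs must share keys")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("need n >= 2 per group")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic per-patient feature table with survival fields.

    Per group, median features are normal draws at the group means/SDs; the
    combined feature is the product of the MTR_asym and R2' draws. Tumor
    volume is log-normal; the acidic fraction is a logistic function of the
    patient's acidity so that acidic volume never exceeds tumor volume.
    Survival times follow the proportional-hazards generators in the spec.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gname in sorted(spec.n_per_group):
        gd = spec.group_defs[gname]
        n = spec.n_per_group[gname]
        mtr = rng.normal(gd.mtr_mean, gd.mtr_sd, n)
        r2p = rng.normal(gd.r2p_mean, gd.r2p_sd, n)
        rcbv = rng.normal(gd.rcbv_mean, gd.rcbv_sd, n)
        age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 19, 90)
        on_trt = rng.random(n) < spec.frac_on_treatment
        tumor_vol = rng.lognormal(np.log(25.0), 0.6, n)
        frac = _expit((mtr - 1.6) / 0.4)
        acidic_vol = frac * tumor_vol
        single_echo = rng.random(n) < spec.frac_single_echo
        for i in range(n):
            rows.append(
                {
                    "group": gname,
                    "median_mtr_asym_pct": mtr[i],
                    "median_r2prime_s": np.nan if single_echo[i] else r2p[i],
                    "median_rcbv_au": rcbv[i],
                    "median_mtrxr2p": np.nan if single_echo[i] else mtr[i] * r2p[i],
                    "tumor_volume_cm3": tumor_vol[i],
                    "acidic_volume_cm3": acidic_vol[i],
                    "acidic_fraction_pct": 100.0 * frac[i],
                    "age_years": age[i],
                    "treatment_status": "on_treatment" if on_trt[i] else "naive",
                    "idh": gd.idh,
                    "codel_1p19q": gd.codel_1p19q,
                    "egfr": gd.egfr,
                }
            )
    df = pd.DataFrame(rows)
    df["on_treatment"] = (df["treatment_status"] == "on_treatment").astype(int)
    df["idh_mutant"] = (df["idh"] == "mutant").astype(int)

    for endpoint, model in (("os", spec.survival_os), ("pfs", spec.survival_pfs)):
        lp = np.zeros(len(df))
        for k, beta in model.log_hr.items():
            x = df[k].to_numpy(dtype=float)
            if k == "age_years":
                x = x - _AGE_CENTER
            x = np.nan_to_num(x, nan=float(np.nanmean(x)))
            lp += beta * x
        hazard = model.baseline_hazard_per_day * np.exp(lp)
        t_event = rng.exponential(1.0 / hazard)
        c = model.censoring_rate
        if c > 0:
            t_cens = rng.exponential((1.0 - c) / (c * hazard))
            observed = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        else:
            observed, event = t_event, np.ones(len(df), dtype=int)
        df[f"{endpoint}_days"] = observed
        df[f"{endpoint}_event"] = event
    return df


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Study-condition cohort spec (two IDH genotype groups, 70/89)."""
    return CohortSpec(seed=seed, **overrides)
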