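"""Headline diffusion workflows: calibration, spot-variation FCS,
chequerboard cross-correlation, pair-correlation FCS and calibration-free
iMSD.

The array detector is read out in three nested detection configurations —
the central pixel alone, the central 3x3 block, and all 25 pixels — whose
effective lateral waists grow with the number of summed pixels.  Spot-
variation FCS exploits this: for free diffusion the diffusion time is
directly proportional to omega0^2, so the intercept tau(0) of the
tau_D(omega0^2) line diagnoses the diffusion mode (zero: free; positive:
microdomain trapping; negative: meshwork hindrance).  Pair-correlation FCS
cross-correlates the centre pixel with each off-centre pixel, grouped by
interpixel distance rho, and fits all curves globally with the two-focus
model.  STICS/iMSD needs no volume calibration at all: the variance of the
2D Gaussian fitted to the spatial-shift correlation matrices grows as
sigma^2 = 2 D tau + omega0^2/2, so D is half the slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .correlate import (
    CorrelationCurve,
    chunked_correlate,
    cross_center_by_rho,
    stics_correlate,
    sum_pixels,
    DEFAULT_CHUNK,
    DEFAULT_M,
    DEFAULT_MAX_LAG,
)
from .errors import InvalidInputError, SpadFfsError
from .fitmodels import (
    AcfFit,
    DEFAULT_CROP_SINGLE,
    DEFAULT_CROP_SUMMED,
    ImsdFit,
    TwoFocusFit,
    fit_acf,
    fit_twofocus_global,
    gauss2d_fit,
    imsd_line_fit,
)
from .spadio import IntensityTrace, PixelGrid

CONFIGS = ("center", "sum3x3", "sum5x5")


@dataclass
class WaistCalibration:
    """Effective lateral waists of the three detection configurations,
    measured by FCS on a reference diffusant of known D via
    omega0 = sqrt(4 * D_reference * tau_D)."""

    omega0_by_config: dict[str, float]  # um
    tauD_by_config: dict[str, float]  # s
    D_reference: float  # um^2/s
    tauD_stderr_by_config: dict[str, float] = field(default_factory=dict)  # s
    source: str = ""
    S: float = 5.0

    def omega0_sq_stderr(self, config: str) -> float:
        """Error of omega0^2 = 4 D_ref tau_D propagated from the tau_D error."""
        se = self.tauD_stderr_by_config.get(config, np.nan)
        return 4.0 * self.D_reference * se

    def __post_init__(self):
        w = self.omega0_by_config
        if set(CONFIGS) <= set(w) and not (
            w["center"] < w["sum3x3"] < w["sum5x5"]
        ):
            warnings.warn(
                "calibrated waists are not ordered center < sum3x3 < sum5x5",
                stacklevel=2,
            )


@dataclass
class SpotVariationResult:
    """Diffusion-law analysis: tau_D versus omega0^2 across configurations."""

    omega0_sq: np.ndarray  # um^2, per configuration
    tau_D: np.ndarray  # s
    tau_D_stderr: np.ndarray  # s
    slope: float  # s / um^2
    intercept: float  # s, tau(0)
    intercept_stderr: float
    D_by_config: dict[str, float]  # um^2/s, pointwise omega0^2/(4 tau_D)
    D_slope: float  # um^2/s, 1/(4 slope)
    law: str  # free | microdomain | meshwork
    fits: dict[str, AcfFit] = field(default_factory=dict)
    curves: dict[str, CorrelationCurve] = field(default_factory=dict)


def _config_acf(
    trace: IntensityTrace,
    config: str,
    m=DEFAULT_M,
    chunk_length=DEFAULT_CHUNK,
    max_lag=DEFAULT_MAX_LAG,
    grid: PixelGrid | None = None,
) -> CorrelationCurve:
    s = sum_pixels(trace, config, grid=grid)
    return chunked_correlate(
        s, bin_width=trace.bin_width, chunk_length=chunk_length, m=m,
        max_lag=max_lag, label={"group_a": config, "group_b": config},
    )


def _acf_fit_with_chunk_error(
    trace: IntensityTrace,
    config: str,
    fit_mode: str,
    crop: float,
    S: float,
    m=DEFAULT_M,
    chunk_length=DEFAULT_CHUNK,
    grid: PixelGrid | None = None,
) -> tuple[AcfFit, float, CorrelationCurve]:
    """Fit a configuration ACF and estimate the tau_D standard error from
    independent per-chunk fits.

    The parametric covariance of a single-curve fit underestimates the real
    uncertainty because residuals are correlated across lags (few molecular
    transits dominate whole regions of the curve).  Fitting each chunk's
    curve separately and taking the spread of the diffusion times — the
    chunk-level analogue of error bars over repeated measurements — gives an
    honest error.  Falls back to the parametric error when fewer than 3
    chunks are available.
    """
    from .correlate import _chunk_G_matrix  # shared engine, internal on purpose

    s = sum_pixels(trace, config, grid=grid)
    lags, Gm = _chunk_G_matrix(s, None, m, trace.bin_width, chunk_length,
                               DEFAULT_MAX_LAG)
    n_chunks = Gm.shape[0]
    G = Gm.mean(axis=0)
    G_std = Gm.std(axis=0, ddof=1) if n_chunks > 1 else np.zeros_like(G)
    curve = CorrelationCurve(lags, G, G_std, n_chunks,
                             {"group_a": config, "group_b": config})
    fit = fit_acf(curve, mode=fit_mode, S_fixed=S, crop_min_lag=crop)
    se = fit.tau_D_stderr
    if n_chunks >= 3:
        taus = []
        for row in Gm:
            sub = CorrelationCurve(lags, row, np.zeros_like(row), 1, {})
            try:
                f = fit_acf(sub, mode=fit_mode, S_fixed=S, crop_min_lag=crop)
                if f.valid:
                    taus.append(f.tau_D)
            except SpadFfsError:
                continue
        if len(taus) >= 3:
            se = float(np.std(taus, ddof=1) / np.sqrt(len(taus)))
    return fit, se, curve


def _default_crop(config: str) -> float:
    return DEFAULT_CROP_SINGLE if config == "center" else DEFAULT_CROP_SUMMED


def waist_from_tau_d(D_reference: float, tau_D: float) -> float:
    """Beam waist from a reference diffusion time: omega0 = sqrt(4 D tau_D).

    With D in um^2/s and tau_D in s the result is in um (e.g. D = 90 um^2/s
    and tau_D = 94 us give 0.184 um).
    """
    if D_reference <= 0 or tau_D <= 0:
        raise InvalidInputError("D_reference and tau_D must be positive")
    return float(np.sqrt(4.0 * D_reference * tau_D))


def calibrate_waists(
    reference_trace: IntensityTrace,
    D_reference: float,
    S_fixed: float = 5.0,
    fit_mode: str = "crop",
    crop_min_lag: dict[str, float] | None = None,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    grid: PixelGrid | None = None,
    source: str = "reference",
) -> WaistCalibration:
    """Measure the effective waists of the three detection configurations.

    Fits the ACF of each configuration on a reference measurement whose
    diffusion coefficient is known and converts each diffusion time with
    omega0 = sqrt(4 * D_reference * tau_D).
    """
    if D_reference <= 0:
        raise InvalidInputError("D_reference must be positive")
    waists: dict[str, float] = {}
    taus: dict[str, float] = {}
    tau_ses: dict[str, float] = {}
    for config in CONFIGS:
        crop = (crop_min_lag or {}).get(config, _default_crop(config))
        try:
            f, se, _ = _acf_fit_with_chunk_error(
                reference_trace, config, fit_mode, crop, S_fixed,
                m=m, chunk_length=chunk_length, grid=grid,
            )
        except SpadFfsError as e:
            raise type(e)(f"calibration fit failed for {config}: {e}") from e
        if f.tau_D <= 0:
            raise InvalidInputError(f"non-positive tau_D for {config}")
        taus[config] = f.tau_D
        tau_ses[config] = se
        waists[config] = waist_from_tau_d(D_reference, f.tau_D)
    return WaistCalibration(
        omega0_by_config=waists, tauD_by_config=taus,
        D_reference=D_reference, tauD_stderr_by_config=tau_ses,
        source=source, S=S_fixed,
    )


def classify_diffusion_law(intercept: float, stderr: float, z: float = 2.0) -> str:
    """Diffusion-law verdict from the tau(0) intercept and its uncertainty.

    free if |tau(0)| < z*stderr, microdomain if significantly positive,
    meshwork if significantly negative.
    """
    if stderr <= 0:
        raise InvalidInputError("stderr must be positive")
    if intercept > z * stderr:
        return "microdomain"
    if intercept < -z * stderr:
        return "meshwork"
    return "free"


def spot_variation(
    trace: IntensityTrace,
    calibration: WaistCalibration,
    fit_mode: str = "crop",
    crop_min_lag: dict[str, float] | None = None,
    S_fixed: float | None = None,
    z_threshold: float = 2.0,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    grid: PixelGrid | None = None,
) -> SpotVariationResult:
    """Spot-variation FCS: tau_D versus omega0^2 across the three configurations.

    Fits the three configuration ACFs of ``trace``, pairs each diffusion
    time with the calibrated waist, fits a weighted line and classifies the
    diffusion law from the intercept.  Configurations whose fit fails are
    dropped; fewer than two surviving points is an error.
    """
    S = calibration.S if S_fixed is None else S_fixed
    fits: dict[str, AcfFit] = {}
    ses: dict[str, float] = {}
    curves: dict[str, CorrelationCurve] = {}
    for config in CONFIGS:
        crop = (crop_min_lag or {}).get(config, _default_crop(config))
        try:
            f, se_c, curve = _acf_fit_with_chunk_error(
                trace, config, fit_mode, crop, S,
                m=m, chunk_length=chunk_length, grid=grid,
            )
            if not f.valid:
                raise InvalidInputError(f.message)
        except SpadFfsError as e:
            warnings.warn(f"ACF fit failed for {config}: {e}", stacklevel=2)
            continue
        fits[config] = f
        ses[config] = se_c
        curves[config] = curve
    if len(fits) < 2:
        raise InvalidInputError("spot variation needs at least 2 fitted configurations")

    configs = [c for c in CONFIGS if c in fits]
    w2 = np.array([calibration.omega0_by_config[c] ** 2 for c in configs])
    sx = np.array([calibration.omega0_sq_stderr(c) for c in configs])
    tD = np.array([fits[c].tau_D for c in configs])
    se = np.array([ses[c] for c in configs])
    if not np.all(np.isfinite(se) & (se > 0)):
        se = np.maximum(np.where(np.isfinite(se), se, 0.0), 1e-3 * tD)
    if not np.all(np.isfinite(sx)):
        sx = np.zeros_like(w2)

    # effective-variance straight-line fit: the calibration errors on
    # omega0^2 act as x-errors and are folded in via the current slope
    slope = float(np.polyfit(w2, tD, 1)[0])
    for _ in range(3):
        var_eff = se**2 + (slope * sx) ** 2
        wts = 1.0 / np.maximum(var_eff, 1e-30)
        W = wts.sum()
        xb = (wts * w2).sum() / W
        yb = (wts * tD).sum() / W
        Sxx = (wts * (w2 - xb) ** 2).sum()
        slope = (wts * (w2 - xb) * (tD - yb)).sum() / Sxx
    inter = yb - slope * xb
    # error from the stated per-point uncertainties, inflated if the
    # residual chi^2 indicates they are still optimistic
    resid = tD - (inter + slope * w2)
    dof = max(len(tD) - 2, 1)
    chi2_red = float((wts * resid**2).sum() / dof)
    inter_se = float(np.sqrt((1.0 / W + xb**2 / Sxx) * max(chi2_red, 1.0)))

    D_by = {c: calibration.omega0_by_config[c] ** 2 / (4.0 * fits[c].tau_D) for c in configs}
    return SpotVariationResult(
        omega0_sq=w2,
        tau_D=tD,
        tau_D_stderr=se,
        slope=float(slope),
        intercept=float(inter),
        intercept_stderr=inter_se,
        D_by_config=D_by,
        D_slope=float(1.0 / (4.0 * slope)),
        law=classify_diffusion_law(float(inter), inter_se, z=z_threshold),
        fits=fits,
        curves=curves,
    )


def checkerboard_fcs(
    trace: IntensityTrace,
    calibration: WaistCalibration | None = None,
    omega0: float | None = None,
    S_fixed: float = 5.0,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    grid: PixelGrid | None = None,
) -> tuple[AcfFit, float, CorrelationCurve]:
    """Chequerboard cross-correlation: odd- versus even-numbered pixel sums.

    After-pulsing is uncorrelated between pixels, so the cross-correlation
    of the two parity streams is free of the short-lag artefact and is
    fitted without cropping.  D is converted with the full-array (sum5x5)
    waist, the closest calibrated volume to the two parity volumes.
    Returns (fit, D, curve).
    """
    even = sum_pixels(trace, "checker_even", grid=grid)
    odd = sum_pixels(trace, "checker_odd", grid=grid)
    curve = chunked_correlate(
        even, odd, bin_width=trace.bin_width, chunk_length=chunk_length, m=m,
        label={"group_a": "checker_even", "group_b": "checker_odd"},
    )
    S = calibration.S if calibration is not None else S_fixed
    fit = fit_acf(curve, mode="none", S_fixed=S)
    if omega0 is None:
        if calibration is None:
            raise InvalidInputError("need a calibration or an explicit omega0")
        omega0 = calibration.omega0_by_config["sum5x5"]
    return fit, fit.diffusion_coefficient(omega0), curve


def pair_correlation(
    trace: IntensityTrace,
    calibration: WaistCalibration | None = None,
    omega0: float | None = None,
    d_fixed: float = 0.075,
    S_fixed: float | None = None,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    grid: PixelGrid | None = None,
) -> TwoFocusFit:
    """Pair-correlation (two-focus) FCS with a global fit over rho classes.

    Cross-correlates the centre pixel with every usable pixel, averages
    within interpixel-distance classes and fits all curves simultaneously
    with the two-focus model; the single-pixel waist is fixed from the
    calibration and the focal-shift unit is d = 75 nm per pixel.
    """
    if omega0 is None:
        if calibration is None:
            raise InvalidInputError("need a calibration or an explicit omega0")
        omega0 = calibration.omega0_by_config["center"]
    S = (calibration.S if calibration is not None else 5.0) if S_fixed is None else S_fixed
    curves = cross_center_by_rho(trace, m=m, chunk_length=chunk_length, grid=grid)
    return fit_twofocus_global(curves, omega0_fixed=omega0, d_fixed=d_fixed, S_fixed=S)


def imsd(
    trace: IntensityTrace,
    pitch_sample: float = 0.075,
    max_lag: float = 800e-6,
    stics_max_lag: float | None = None,
    exclude_center_below: float = 2e-5,
    m: int = DEFAULT_M,
    chunk_length: float = DEFAULT_CHUNK,
    include_excluded: bool = False,
    grid: PixelGrid | None = None,
    min_amplitude_snr: float = 3.0,
):
    """Calibration-free iMSD: STICS -> per-lag 2D Gaussian -> line fit.

    The (0, 0) cell is excluded from the Gaussian fits at lags below
    ``exclude_center_below`` where after-pulsing inflates it; lags whose
    fitted amplitude is not significant (A < ``min_amplitude_snr`` standard
    errors) are dropped; the surviving variances below ``max_lag`` are fitted
    with sigma^2 = 2 D tau + const.  Returns (ImsdFit, ShiftCorrelationSeries,
    per-lag Gauss2DFit list).
    """
    grid = grid or PixelGrid(pitch_sample=pitch_sample)
    series = stics_correlate(
        trace, m=m, chunk_length=chunk_length,
        max_lag=stics_max_lag or max(2.0 * max_lag, 2e-3),
        include_excluded=include_excluded, grid=grid,
    )
    lags, s2, s2err, gfits = [], [], [], []
    for lag, mat in zip(series.lag_times, series.matrices):
        try:
            g = gauss2d_fit(mat, exclude_center=lag < exclude_center_below)
        except SpadFfsError:
            gfits.append(None)
            continue
        gfits.append(g)
        if not g.valid or g.amplitude < min_amplitude_snr * g.amplitude_stderr:
            continue
        lags.append(lag)
        s2.append(g.sigma2)
        s2err.append(g.sigma2_stderr)
    if len([l for l in lags if l <= max_lag]) < 3:
        raise InvalidInputError("too few significant STICS lags below max_lag")
    fit = imsd_line_fit(
        np.asarray(lags), np.asarray(s2), np.asarray(s2err),
        max_lag=max_lag, pitch_sample=pitch_sample,
    )
    return fit, series, gfits
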