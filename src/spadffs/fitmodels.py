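"""Analytic correlation models and least-squares fitting.

Models
------
Free 3D diffusion through a 3D Gaussian detection volume with lateral 1/e^2
waist ``omega0`` and structural parameter ``S = z0/omega0``:

    G(tau) = (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(S^2 tau_D))^-1/2 + offset

with mean occupancy ``N`` and diffusion time ``tau_D = omega0^2 / (4 D)``.

Detector after-pulsing adds a decaying power law ``A * tau^(-B)`` at short
lags (B = 1.103 for this detector); alternatively the short-lag region is
simply cropped before fitting (7.5 us for a single pixel, 15 us for summed
traces).

Two-focus (pair-correlation) FCS cross-correlates two identical Gaussian
volumes whose centres are separated by ``shift = d * rho`` in sample space:

    G_x(tau) = G(tau) * exp(-shift^2 / (omega0^2 (1 + tau/tau_D)))

STICS/iMSD fits each spatial-shift correlation matrix with a 2D Gaussian;
for free diffusion its variance grows as ``sigma^2 = 2 D tau + omega0^2/2``,
so D is half the slope — no volume calibration required.

Fitting uses least squares with positivity enforced by a log transform of N
and tau_D and a small multistart on non-convergence.  Plain (unweighted)
least squares is the default; inverse-variance weighting from the
smoothed chunk spread is available for long measurements with many chunks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .correlate import CorrelationCurve
from .errors import FitConvergenceError, InvalidInputError

DEFAULT_B_AP = 1.103
DEFAULT_CROP_SINGLE = 7.5e-6  # s, single-pixel ACF
DEFAULT_CROP_SUMMED = 15e-6  # s, summed-pixel ACF


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def acf_free3d(tau, N, tau_D, S=5.0, offset=0.0):
    """Free-3D-diffusion autocorrelation for a 3D Gaussian volume."""
    tau = np.asarray(tau, dtype=np.float64)
    return (1.0 / N) / (1.0 + tau / tau_D) / np.sqrt(1.0 + tau / (S * S * tau_D)) + offset


def afterpulse_term(tau, A, B=DEFAULT_B_AP):
    """Decaying power-law after-pulse component A * tau^(-B)."""
    if np.any(np.asarray(A) < 0) or B <= 0:
        raise InvalidInputError("after-pulse term requires A >= 0 and B > 0")
    tau = np.asarray(tau, dtype=np.float64)
    return A * tau ** (-B)


def twofocus_model(tau, N, tau_D, S, omega0, shift):
    """Cross-correlation of two equal Gaussian volumes separated by ``shift`` (um)."""
    tau = np.asarray(tau, dtype=np.float64)
    g = acf_free3d(tau, N, tau_D, S, 0.0)
    return g * np.exp(-(shift * shift) / (omega0 * omega0 * (1.0 + tau / tau_D)))


def gauss2d(coords, amplitude, mu_x, mu_y, sigma2, offset):
    """Isotropic 2D Gaussian A*exp(-((x-mux)^2+(y-muy)^2)/(2 sigma2)) + offset."""
    x, y = coords
    return amplitude * np.exp(
        -((x - mu_x) ** 2 + (y - mu_y) ** 2) / (2.0 * sigma2)
    ) + offset


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class AcfFit:
    N: float
    tau_D: float  # s
    S: float
    offset: float
    A_ap: float | None = None
    B_ap: float = DEFAULT_B_AP
    covariance: np.ndarray | None = None  # order: N, tau_D, offset[, A_ap]
    crop_min_lag: float = 0.0
    valid: bool = True
    message: str = ""

    @property
    def tau_D_stderr(self) -> float:
        if self.covariance is None:
            return np.nan
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def N_stderr(self) -> float:
        if self.covariance is None:
            return np.nan
        return float(np.sqrt(self.covariance[0, 0]))

    def diffusion_coefficient(self, omega0: float) -> float:
        """D = omega0^2 / (4 tau_D), with omega0 in um -> D in um^2/s."""
        return omega0 * omega0 / (4.0 * self.tau_D)


@dataclass
class TwoFocusFit:
    D: float  # um^2/s
    N: float
    tau_D: float  # s
    omega0: float  # um, fixed from calibration
    d: float = 0.075  # um per pixel unit
    S: float = 5.0
    D_stderr: float = np.nan
    per_rho_tauD: dict = field(default_factory=dict)
    per_rho_D: dict = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None


@dataclass
class Gauss2DFit:
    amplitude: float
    sigma2: float  # px^2
    center: tuple[float, float]
    offset: float
    amplitude_stderr: float = np.nan
    sigma2_stderr: float = np.nan
    valid: bool = True
    message: str = ""


@dataclass
class ImsdFit:
    sigma2: np.ndarray  # um^2, per used lag
    lags: np.ndarray  # s, used lags
    sigma2_err: np.ndarray | None = None  # um^2, parametric fit errors
    slope: float = np.nan  # um^2/s
    intercept: float = np.nan  # um^2
    slope_stderr: float = np.nan
    intercept_stderr: float = np.nan
    max_lag_used: float = np.nan

    @property
    def D(self) -> float:
        """Diffusion coefficient, half the slope of sigma^2(tau)."""
        return 0.5 * self.slope

    @property
    def D_stderr(self) -> float:
        return 0.5 * self.slope_stderr


# ---------------------------------------------------------------------------
# Weights and optimizer helpers
# ---------------------------------------------------------------------------

def _fit_weights(curve: CorrelationCurve) -> np.ndarray | None:
    """Inverse-std weights from chunk spread when >= 3 chunks, else None.

    The raw per-lag standard deviation over a handful of chunks is itself
    very noisy, and weighting by it directly over-weights lags whose spread
    happened to come out small (which correlates with their G fluctuation
    and biases the fit).  The spread is therefore smoothed with a running
    median across neighbouring lags before inversion: the genuine
    decade-scale variance structure survives, the per-lag sampling noise
    does not.
    """
    if curve.n_chunks >= 3 and np.all(np.isfinite(curve.G_std)):
        std = np.asarray(curve.G_std, dtype=float)
        pos = std[std > 0]
        if len(pos) == 0:
            return None
        n = len(std)
        half = 3
        smooth = np.empty(n)
        for i in range(n):
            window = std[max(0, i - half) : min(n, i + half + 1)]
            smooth[i] = np.median(window[window > 0]) if np.any(window > 0) else 0.0
        floor = max(pos.min(), 1e-3 * np.median(pos))
        return 1.0 / np.maximum(smooth, floor)
    return None


def _run_least_squares(resid, x0, tauD_factors=(1.0, 0.1, 10.0)):
    """Least squares on log-transformed parameters with a small multistart
    over the diffusion-time guess on non-convergence."""
    best = None
    for attempt, factor in enumerate(tauD_factors):
        x_try = np.array(x0, dtype=float)
        if len(x_try) > 1:
            x_try[1] += np.log(factor)
        try:
            sol = least_squares(resid, x_try, method="lm", xtol=1e-15, ftol=1e-15,
                                gtol=1e-15, max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and attempt == 0:
            break
    if best is None:
        raise FitConvergenceError("least-squares optimizer failed from all starts")
    if not best.success:
        raise FitConvergenceError(
            f"fit did not converge: {best.message}",
            residual_norm=float(np.linalg.norm(best.fun)),
        )
    return best


def _covariance(sol, n_params):
    J = sol.jac
    try:
        JTJ = J.T @ J
        cov = np.linalg.inv(JTJ)
        dof = max(len(sol.fun) - n_params, 1)
        cov *= 2.0 * sol.cost / dof  # cost = 0.5 * sum r^2
        return cov
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# ACF fitting
# ---------------------------------------------------------------------------

def fit_acf(
    curve: CorrelationCurve,
    mode: str = "crop",
    S_fixed: float = 5.0,
    crop_min_lag: float = DEFAULT_CROP_SINGLE,
    B_ap: float = DEFAULT_B_AP,
    weighted: bool = False,
) -> AcfFit:
    """Fit the free-3D-diffusion model to a correlation curve.

    ``mode``:
      * ``"crop"``  — drop lags below ``crop_min_lag`` (removes after-pulsing)
      * ``"afterpulse"`` — keep all lags and add ``A * tau^(-B_ap)`` with A free
      * ``"none"``  — keep all lags, no after-pulse term

    S is held fixed (it comes from an independent axial calibration).
    Fitting is plain least squares by default; inverse-variance weighting
    from the chunk spread is available but needs many chunks before the
    spread estimates are reliable enough not to bias the fit.
    """
    if mode not in ("crop", "afterpulse", "none"):
        raise InvalidInputError(f"unknown fit mode {mode!r}")
    c = curve.cropped(min_lag=crop_min_lag) if mode == "crop" else curve
    if len(c.lags) < 8:
        raise InvalidInputError(
            f"need at least 8 lag points after cropping, got {len(c.lags)}"
        )
    tau, G = c.lags, c.G
    w = _fit_weights(c) if weighted else None
    with_ap = mode == "afterpulse"

    amp0 = max(float(np.max(G)), 1e-6)
    # crude tau_D guess: lag where G first drops below half its initial value
    below = np.nonzero(G < 0.5 * amp0)[0]
    tauD0 = float(tau[below[0]]) if len(below) else float(tau[len(tau) // 2])
    x0 = [np.log(1.0 / amp0), np.log(tauD0), 0.0]
    if with_ap:
        x0.append(np.log(max(amp0 * tau[0] ** B_ap * 0.1, 1e-12)))

    def unpack(x):
        N = np.exp(x[0])
        tau_D = np.exp(x[1])
        offset = x[2]
        A = np.exp(x[3]) if with_ap else 0.0
        return N, tau_D, offset, A

    def resid(x):
        N, tau_D, offset, A = unpack(x)
        model = acf_free3d(tau, N, tau_D, S_fixed, offset)
        if with_ap:
            model = model + A * tau ** (-B_ap)
        r = model - G
        return r * w if w is not None else r

    sol = _run_least_squares(resid, x0)
    N, tau_D, offset, A = unpack(sol.x)
    cov_log = _covariance(sol, len(sol.x))
    cov = None
    if cov_log is not None:
        # delta method for the log-transformed parameters
        jac_diag = [N, tau_D, 1.0] + ([A] if with_ap else [])
        Jd = np.diag(jac_diag)
        cov = Jd @ cov_log @ Jd
    fit = AcfFit(
        N=N,
        tau_D=tau_D,
        S=S_fixed,
        offset=offset,
        A_ap=A if with_ap else None,
        B_ap=B_ap,
        covariance=cov,
        crop_min_lag=crop_min_lag if mode == "crop" else float(curve.lags[0]),
    )
    if N <= 0 or tau_D <= 0:
        fit.valid = False
        fit.message = "non-positive fitted N or tau_D"
    return fit


def fit_afterpulse(
    curve: CorrelationCurve,
    lag_window: tuple[float, float],
    weighted: bool = True,
) -> tuple[float, float, float]:
    """Fit A * tau^(-B) with both A and B free over ``lag_window``.

    After-pulsing is the only correlated component of a dark-trace ACF, so
    a pure power law is fitted, by weighted least squares in linear G space
    (fitting log G on the positive values only would censor the downward
    noise excursions of the tail and bias B low).  Weights come from the
    chunk spread when available.  Returns ``(A, B, B_stderr)``.
    """
    lo, hi = lag_window
    c = curve.cropped(min_lag=lo, max_lag=hi)
    if len(c.lags) < 4:
        raise InvalidInputError("need at least 4 lags in the window")
    if np.max(c.G) <= 0:
        raise InvalidInputError("no positive correlation in the window")
    tau, G = c.lags, c.G
    if weighted and curve.n_chunks >= 3 and np.any(c.G_std > 0):
        w = 1.0 / np.maximum(c.G_std, 1e-3 * float(np.median(c.G_std[c.G_std > 0])))
    else:
        w = np.ones_like(tau)
    # initial guess from the two window endpoints with positive G
    pos = np.nonzero(G > 0)[0]
    i0, i1 = pos[0], pos[-1]
    B0 = 1.0
    if i1 > i0 and G[i1] > 0:
        B0 = min(max(-np.log(G[i1] / G[i0]) / np.log(tau[i1] / tau[i0]), 0.1), 3.0)
    x0 = [np.log(G[i0] * tau[i0] ** B0), B0]

    def resid(x):
        return (np.exp(x[0]) * tau ** (-x[1]) - G) * w

    sol = _run_least_squares(resid, x0, tauD_factors=(1.0,))
    cov = _covariance(sol, 2)
    B_se = float(np.sqrt(cov[1, 1])) if cov is not None else np.nan
    return float(np.exp(sol.x[0])), float(sol.x[1]), B_se


# ---------------------------------------------------------------------------
# Two-focus global fit
# ---------------------------------------------------------------------------

def fit_twofocus_global(
    curves: dict[float, CorrelationCurve],
    omega0_fixed: float,
    d_fixed: float = 0.075,
    S_fixed: float = 5.0,
    weighted: bool = False,
    individual_fits: bool = True,
) -> TwoFocusFit:
    """Simultaneously fit rho-class cross-correlation curves with a single
    shared (N, tau_D); D = omega0^2 / (4 tau_D).

    ``curves`` maps the interpixel distance rho (pixel units) to its averaged
    cross-correlation curve.  Per-class individual fits (diffusion time and
    apparent D per rho) are reported alongside the global result.
    """
    if not curves:
        raise InvalidInputError("no curves to fit")
    items = sorted(curves.items())

    def global_resid_builder(use):
        def resid(x):
            N = np.exp(x[0])
            tau_D = np.exp(x[1])
            parts = []
            for rho, c in use:
                model = twofocus_model(c.lags, N, tau_D, S_fixed, omega0_fixed, d_fixed * rho)
                r = model - c.G
                w = _fit_weights(c) if weighted else None
                parts.append(r * w if w is not None else r)
            return np.concatenate(parts)

        return resid

    amp0 = max(float(np.max(items[0][1].G)), 1e-6)
    tauD0 = omega0_fixed**2 / (4.0 * 30.0)  # ~usual small-dye scale as a start
    x0 = [np.log(1.0 / amp0), np.log(tauD0)]
    sol = _run_least_squares(global_resid_builder(items), x0)
    N = float(np.exp(sol.x[0]))
    tau_D = float(np.exp(sol.x[1]))
    D = omega0_fixed**2 / (4.0 * tau_D)
    cov_log = _covariance(sol, 2)
    D_se = np.nan
    cov = None
    if cov_log is not None:
        Jd = np.diag([N, tau_D])
        cov = Jd @ cov_log @ Jd
        # D = w^2/(4 tauD) -> |dD/dtauD| = D / tauD
        D_se = float(D / tau_D * np.sqrt(cov[1, 1]))

    per_tau: dict[float, float] = {}
    per_D: dict[float, float] = {}
    residuals: dict[float, np.ndarray] = {}
    if individual_fits:
        for rho, c in items:
            try:
                s = _run_least_squares(global_resid_builder([(rho, c)]), list(sol.x))
                tD = float(np.exp(s.x[1]))
                per_tau[rho] = tD
                per_D[rho] = omega0_fixed**2 / (4.0 * tD)
            except FitConvergenceError:
                warnings.warn(f"individual fit failed for rho={rho:g}", stacklevel=2)
    for rho, c in items:
        model = twofocus_model(c.lags, N, tau_D, S_fixed, omega0_fixed, d_fixed * rho)
        residuals[rho] = c.G - model
    return TwoFocusFit(
        D=D,
        N=N,
        tau_D=tau_D,
        omega0=omega0_fixed,
        d=d_fixed,
        S=S_fixed,
        D_stderr=D_se,
        per_rho_tauD=per_tau,
        per_rho_D=per_D,
        residuals=residuals,
        covariance=cov,
    )


# ---------------------------------------------------------------------------
# STICS / iMSD fits
# ---------------------------------------------------------------------------

def gauss2d_fit(matrix: np.ndarray, exclude_center: bool = False) -> Gauss2DFit:
    """Fit a 9x9 shift-correlation matrix with an isotropic 2D Gaussian.

    Coordinates are integer pixel shifts (xi, psi) in [-4, 4]; with
    ``exclude_center`` the (0, 0) cell (inflated by after-pulsing at short
    lags) is omitted.  NaN cells (empty shift classes) are always omitted.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (9, 9):
        raise InvalidInputError("expected a 9x9 shift-correlation matrix")
    xi, psi = np.meshgrid(np.arange(-4, 5), np.arange(-4, 5))  # xi: columns
    mask = np.isfinite(matrix)
    if exclude_center:
        mask[4, 4] = False
    if mask.sum() < 6:
        raise InvalidInputError("need at least 6 valid matrix cells")
    x = xi[mask].astype(float)
    y = psi[mask].astype(float)
    z = matrix[mask]

    zmin, zmax = float(z.min()), float(z.max())
    p0 = [zmax - zmin, 0.0, 0.0, 2.0, zmin]
    try:
        popt, pcov = curve_fit(
            lambda c, A, mx, my, s2, off: gauss2d(c, A, mx, my, s2, off),
            (x, y),
            z,
            p0=p0,
            bounds=([-np.inf, -4, -4, 1e-6, -np.inf], [np.inf, 4, 4, 1e4, np.inf]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except RuntimeError as e:
        raise FitConvergenceError(f"2D Gaussian fit failed: {e}") from e
    A, mx, my, s2, off = popt
    se = np.sqrt(np.diag(pcov))
    fit = Gauss2DFit(
        amplitude=float(A),
        sigma2=float(s2),
        center=(float(mx), float(my)),
        offset=float(off),
        amplitude_stderr=float(se[0]),
        sigma2_stderr=float(se[3]),
    )
    if A <= 0 or not np.isfinite(se[0]) or A < 3.0 * se[0]:
        fit.valid = False
        fit.message = "amplitude not significant (A < 3 SE); sigma2 unreliable"
    if s2 <= 0:
        fit.valid = False
        fit.message = "non-positive variance"
    return fit


def imsd_line_fit(
    lags,
    sigma2_px,
    sigma2_err_px=None,
    max_lag: float = 800e-6,
    pitch_sample: float = 0.075,
) -> ImsdFit:
    """Weighted first-order fit of sigma^2(tau) = 2 D tau + omega0^2/2.

    ``sigma2_px`` are the fitted Gaussian variances in detector pixel units;
    they are converted to um^2 through the sample-space pixel pitch before
    fitting, so ``slope/2`` is D in um^2/s.
    """
    lags = np.asarray(lags, dtype=float)
    s2 = np.asarray(sigma2_px, dtype=float) * pitch_sample**2
    keep = (lags <= max_lag) & np.isfinite(s2)
    if sigma2_err_px is not None:
        err = np.asarray(sigma2_err_px, dtype=float) * pitch_sample**2
        keep &= np.isfinite(err) & (err >= 0)
    if keep.sum() < 3:
        raise InvalidInputError("need at least 3 usable lags below max_lag")
    x, y = lags[keep], s2[keep]
    if sigma2_err_px is not None:
        e = err[keep]
        w = 1.0 / np.maximum(e, max(e[e > 0].min() if np.any(e > 0) else 1.0, 1e-30)) ** 2
    else:
        w = np.ones_like(x)
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    Sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / Sxx
    inter = yb - slope * xb
    r = y - (inter + slope * x)
    dof = max(len(x) - 2, 1)
    s2res = np.sum(w * r**2) / dof
    slope_se = np.sqrt(s2res / Sxx)
    inter_se = np.sqrt(s2res * (1.0 / W + xb**2 / Sxx))
    return ImsdFit(
        sigma2=y,
        lags=x,
        sigma2_err=e if sigma2_err_px is not None else None,
        slope=float(slope),
        intercept=float(inter),
        slope_stderr=float(slope_se),
        intercept_stderr=float(inter_se),
        max_lag_used=float(x.max()),
    )
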