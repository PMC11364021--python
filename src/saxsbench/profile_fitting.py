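"""Fitting model profiles to experimental SAXS data, and Guinier analysis.

Model-to-data fits use a closed-form weighted least squares for the
multiplicative scale and additive constant; the excluded-volume and
hydration parameters (c1, c2) are optimized by exhaustive grid search with
the full Debye intensity assembled from precomputed partial sums at every
node.  The error weighting is either the experimental sigma alone or, for
model profiles that carry their own statistical errors sigma_w (frame
averaging), the combination [sigma_w^2 + sigma_expt^2]^(1/2).

Guinier analysis fits ln I(q) versus q^2 by linear regression with
Rg = sqrt(-3 * slope), restricted to q * Rg <= 1.3 (globular-particle
limit), either from a fixed starting point or with an automatic scan for
the best low-q window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_predictor import PartialIntensities, R_M_DEFAULT, RHO_BULK_DEFAULT
from .sas_io import AtomicModel, SASProfile

QRG_LIMIT = 1.3


@dataclass
class GuinierResult:
    rg: float                 # radius of gyration [A]
    rg_err: float
    i0: float                 # extrapolated forward scattering
    i0_err: float
    q_range: tuple            # (q_min, q_max) of the fitted window
    qrg_range: tuple          # (q_min * rg, q_max * rg)
    n_points: int


@dataclass
class HydrationFitResult:
    """Best (c1, c2) grid node with its scale/constant fit and residuals."""

    scale: float
    constant: float
    c1: float
    c2: float
    chi2: float               # reduced
    residuals: np.ndarray     # (data - fit)/sigma_eff on the data grid
    q: np.ndarray
    sigma_policy: str
    c1_values: np.ndarray | None = None
    c2_values: np.ndarray | None = None
    chi2_grid: np.ndarray | None = None   # (n_c2, n_c1)


def _effective_sigma(model: SASProfile, data: SASProfile, sigma_policy: str,
                     model_sigma_interp=None) -> np.ndarray:
    if sigma_policy == "expt_only":
        return data.sigma.copy()
    if sigma_policy == "combined":
        sw = model_sigma_interp
        if sw is None:
            sw = np.interp(data.q, model.q, model.sigma)
        return np.sqrt(data.sigma ** 2 + sw ** 2)
    raise ValueError(f"unknown sigma policy {sigma_policy!r}")


def _wls_scale_const(y_model, y_data, sigma):
    """Closed-form weighted LS for y_data ~ scale * y_model + C."""
    w = 1.0 / sigma ** 2
    sw, sx, sy = w.sum(), (w * y_model).sum(), (w * y_data).sum()
    sxx = (w * y_model * y_model).sum()
    sxy = (w * y_model * y_data).sum()
    det = sw * sxx - sx * sx
    if det <= 0 or not np.isfinite(det):
        raise ValueError("degenerate (constant) model profile")
    scale = (sw * sxy - sx * sy) / det
    const = (sxx * sy - sx * sxy) / det
    m = y_data.size
    chi2 = float((w * (y_data - scale * y_model - const) ** 2).sum()
                 / max(m - 2, 1))
    return float(scale), float(const), chi2


def scale_const_fit(model: SASProfile, data: SASProfile,
                    sigma_policy: str = "expt_only"):
    """Fit scale and constant of a model profile to data; reduced chi^2.

    The model is linearly interpolated onto the data grid; its q range must
    cover the data range (no extrapolation).
    """
    if model.q[0] > data.q[0] + 1e-12 or model.q[-1] < data.q[-1] - 1e-12:
        raise ValueError("model q range must cover the data range")
    y_model = np.interp(data.q, model.q, model.I)
    sigma = _effective_sigma(model, data, sigma_policy)
    return _wls_scale_const(y_model, data.I, sigma)


@dataclass
class ResidualReport:
    q: np.ndarray
    residuals: np.ndarray
    flagged: bool                 # any run of >= run_length points beyond 3
    run_length: int
    scale: float
    constant: float
    chi2: float


def residual_series(model: SASProfile, data: SASProfile,
                    sigma_policy: str = "expt_only",
                    run_length: int = 5) -> ResidualReport:
    """Error-weighted residuals after the scale/constant fit.

    A run of ``run_length`` or more consecutive points beyond +-3 sigma is
    flagged as a systematic deviation.
    """
    scale, const, chi2 = scale_const_fit(model, data, sigma_policy)
    y_model = np.interp(data.q, model.q, model.I)
    sigma = _effective_sigma(model, data, sigma_policy)
    resid = (data.I - scale * y_model - const) / sigma
    beyond = np.abs(resid) > 3.0
    flagged = False
    run = 0
    for flag in beyond:
        run = run + 1 if flag else 0
        if run >= run_length:
            flagged = True
            break
    return ResidualReport(q=data.q.copy(), residuals=resid, flagged=flagged,
                          run_length=run_length, scale=scale, constant=const,
                          chi2=chi2)


def fit_hydration(model, data: SASProfile,
                  c1_range: tuple = (0.95, 1.05), c1_step: float = 0.01,
                  c2_range: tuple = (-2.0, 4.0), c2_step: float = 0.1,
                  sigma_policy: str = "expt_only", mode: str = "binned",
                  rho_bulk: float = RHO_BULK_DEFAULT, r_m: float = R_M_DEFAULT,
                  allow_negative_c2: bool = True,
                  keep_grid: bool = True) -> HydrationFitResult:
    """Exhaustive (c1, c2) grid search for the best fit to ``data``.

    ``model`` is an :class:`AtomicModel` (with SASA fractions filled) or a
    precomputed :class:`PartialIntensities` on the data q grid.  At every
    grid node the Debye intensity is assembled and the scale/constant fit
    evaluated; the global minimum chi^2 wins, with ties broken in favour of
    the least-adjusted model (smallest |c2|, then smallest |c1 - 1|).
    Setting ``allow_negative_c2=False`` restricts the scan to c2 >= 0
    (no-negative-contrast policy).
    """
    if isinstance(model, AtomicModel):
        parts = PartialIntensities(model, data.q, mode=mode,
                                   rho_bulk=rho_bulk)
    elif isinstance(model, PartialIntensities):
        parts = model
        if parts.q.shape != data.q.shape or not np.allclose(parts.q, data.q):
            raise ValueError("partial intensities not on the data q grid")
    else:
        raise TypeError("model must be AtomicModel or PartialIntensities")
    n1 = int(round((c1_range[1] - c1_range[0]) / c1_step)) + 1
    c1s = np.round(c1_range[0] + c1_step * np.arange(n1), 10)
    lo2 = c2_range[0] if allow_negative_c2 else max(0.0, c2_range[0])
    n2 = int(round((c2_range[1] - lo2) / c2_step)) + 1
    c2s = np.round(lo2 + c2_step * np.arange(n2), 10)
    if sigma_policy not in ("expt_only", "combined"):
        raise ValueError(f"unknown sigma policy {sigma_policy!r}")
    sigma = data.sigma.copy()   # Debye predictions carry no statistical error
    chi2_grid = np.empty((n2, n1))
    fits = {}
    for j, c2 in enumerate(c2s):
        for i, c1 in enumerate(c1s):
            y = parts.intensity(c1=c1, c2=c2, r_m=r_m)
            scale, const, chi2 = _wls_scale_const(y, data.I, sigma)
            chi2_grid[j, i] = chi2
            fits[(j, i)] = (scale, const)
    best = np.min(chi2_grid)
    ties = np.argwhere(chi2_grid <= best * (1 + 1e-12) + 1e-300)
    j, i = min(ties, key=lambda ji: (abs(c2s[ji[0]]), abs(c1s[ji[1]] - 1.0)))
    scale, const = fits[(j, i)]
    y = parts.intensity(c1=c1s[i], c2=c2s[j], r_m=r_m)
    resid = (data.I - scale * y - const) / sigma
    return HydrationFitResult(
        scale=scale, constant=const, c1=float(c1s[i]), c2=float(c2s[j]),
        chi2=float(chi2_grid[j, i]), residuals=resid, q=data.q.copy(),
        sigma_policy=sigma_policy,
        c1_values=c1s if keep_grid else None,
        c2_values=c2s if keep_grid else None,
        chi2_grid=chi2_grid if keep_grid else None)


def _linfit(x, y):
    """Unweighted linear regression with standard errors on the slope."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    if n > 2:
        s2 = (resid ** 2).sum() / (n - 2)
    else:
        s2 = 0.0
    slope_err = np.sqrt(s2 / sxx)
    inter_err = np.sqrt(s2 * (1.0 / n + xm * xm / sxx))
    return slope, intercept, slope_err, inter_err


def _guinier_window(profile: SASProfile, i0: int, qrg_limit: float,
                    min_points: int = 5, max_rounds: int = 50):
    """Self-consistent fixed-limit fit starting at index ``i0``."""
    q, intensity = profile.q[i0:], profile.I[i0:]
    pos = intensity > 0
    if pos.sum() < min_points:
        return None
    q, intensity = q[pos], intensity[pos]
    x, y = q * q, np.log(intensity)
    i1 = q.size
    for _ in range(max_rounds):
        if i1 < min_points:
            return None
        slope, inter, slope_err, inter_err = _linfit(x[:i1], y[:i1])
        if slope >= 0:
            i1 -= 1
            continue
        rg = np.sqrt(-3.0 * slope)
        new_i1 = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        if new_i1 == i1:
            rg_err = 3.0 * slope_err / (2.0 * rg)
            return dict(rg=float(rg), rg_err=float(rg_err),
                        i0=float(np.exp(inter)),
                        i0_err=float(np.exp(inter) * inter_err),
                        q_lo=float(q[0]), q_hi=float(q[i1 - 1]), n=int(i1))
        i1 = new_i1
    return None


def _window_self_consistent(profile: SASProfile, i0: int, win: dict,
                            qrg_limit: float) -> bool:
    """Linearity screen for the automatic window scan.

    Refit the upper half of the candidate window; a low-q artifact
    (aggregation upturn, parasitic scattering) biases the full-window Rg
    but not the upper half, so the window is rejected when the two disagree
    beyond their combined regression errors (plus a 0.3% relative slack for
    the intrinsic Guinier curvature of globular particles).
    """
    half = _guinier_window(profile, i0 + win["n"] // 2, qrg_limit,
                           min_points=5)
    if half is None:
        return False
    tol = (3.0 * np.hypot(win["rg_err"], half["rg_err"])
           + 0.003 * win["rg"])
    return abs(win["rg"] - half["rg"]) < tol


def guinier_fit(profile: SASProfile, policy: str = "fixed_limit",
                q_min: float | None = None,
                qrg_limit: float = QRG_LIMIT) -> GuinierResult:
    """Guinier analysis: ln I vs q^2 regression with q * Rg <= ``qrg_limit``.

    ``fixed_limit`` iterates the upper limit to self-consistency from the
    first usable point (or ``q_min``).  ``auto`` additionally scans lower
    limits and keeps the longest window with at least 10 points and
    q_min * Rg < 1.0, screening out low-q upturns from aggregation or
    parasitic scattering.
    """
    start = 0
    if q_min is not None:
        start = int(np.searchsorted(profile.q, q_min))
    if policy == "fixed_limit":
        win = _guinier_window(profile, start, qrg_limit)
        if win is None:
            raise ValueError("no valid Guinier window (need >= 5 positive "
                             "points with negative slope)")
    elif policy == "auto":
        best = None
        n = profile.n_points
        for i0 in range(start, n - 10):
            win = _guinier_window(profile, i0, qrg_limit, min_points=10)
            if win is None:
                if profile.q[i0] ** 2 > 3.0:   # far beyond any Guinier region
                    break
                continue
            if win["q_lo"] * win["rg"] >= 1.0:
                break                          # windows only shrink further
            if not _window_self_consistent(profile, i0, win, qrg_limit):
                continue
            if best is None or win["n"] > best["n"]:
                best = win
        if best is None:
            raise ValueError("auto policy found no admissible Guinier window")
        win = best
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return GuinierResult(rg=win["rg"], rg_err=win["rg_err"], i0=win["i0"],
                         i0_err=win["i0_err"],
                         q_range=(win["q_lo"], win["q_hi"]),
                         qrg_range=(win["q_lo"] * win["rg"],
                                    win["q_hi"] * win["rg"]),
                         n_points=win["n"])
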