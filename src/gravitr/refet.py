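"""Penman-Monteith reference evapotranspiration at 15-min resolution.

Sub-daily reference ET (ET0) serves as the physical benchmark against which
observed sector evapotranspiration (ETr) is filtered: an ETr sample that
exceeds what a well-watered reference surface could plausibly lose is a
measurement artifact, not plant water use.  The standard hourly FAO-56
formulation is adapted to 15-min steps by replacing the aerodynamic constant
900 (per day) with 900/96, i.e. the number of observation intervals per day.

Functions here are vectorised over numpy arrays / pandas Series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: psychrometric constant, kPa per degC (sea-level standard)
GAMMA_DEFAULT = 0.0665

#: aerodynamic numerator constant for 15-min steps: 900 per day / 96 steps
WIND_CONSTANT_15MIN = 900.0 / 96.0


def svp(t_c):
    """Saturation vapour pressure es (kPa) at air temperature ``t_c`` (degC).

    es = 0.6108 * exp(17.27 T / (T + 237.3))  (Tetens form).
    """
    t = np.asarray(t_c, dtype=float)
    if np.any(t <= -237.3):
        raise ValueError("temperature at or below -237.3 degC is unphysical")
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def avp(t_c, rh_pct):
    """Actual vapour pressure ea (kPa): ea = es(T) * RH/100."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    return svp(t_c) * rh / 100.0


def vpd(t_c, rh_pct):
    """Vapour pressure deficit (kPa): es(T) * (1 - RH/100)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    return svp(t_c) * (1.0 - rh / 100.0)


def delta_svp(t_c):
    """Slope of the saturation vapour pressure curve, kPa per degC.

    Delta = 4098 * es(T) / (T + 237.3)^2.
    """
    t = np.asarray(t_c, dtype=float)
    return 4098.0 * svp(t) / (t + 237.3) ** 2


def net_radiation(rad):
    """Default net radiation Rn (MJ m-2 15min-1) from incoming solar RAD.

    Rn = (1 - albedo) * RAD with grass albedo 0.23; net longwave is
    neglected at the 15-min scale.  Overridden whenever an Rn column is
    supplied with the weather data.
    """
    return 0.77 * np.asarray(rad, dtype=float)


def soil_heat_flux(rn, daytime):
    """Default soil heat flux G: 0.1 Rn by day, 0.5 Rn by night."""
    rn = np.asarray(rn, dtype=float)
    day = np.asarray(daytime, dtype=bool)
    return np.where(day, 0.1 * rn, 0.5 * rn)


def penman_monteith_15min(t_c, rh_pct, ws, rn, g, gamma=GAMMA_DEFAULT,
                          floor=0.0):
    """Reference evapotranspiration ET0 per 15-min step (mm).

    ET0 = [0.408 Delta (Rn - G) + gamma (900/96)/(T+273) WS (es - ea)]
          / [Delta + gamma (1 + 0.34 WS)]

    Negative values (possible at night when Rn - G < 0) are clamped at
    ``floor`` (default 0), matching the convention that reference ET is
    non-negative.
    """
    t = np.asarray(t_c, dtype=float)
    ws = np.asarray(ws, dtype=float)
    rn = np.asarray(rn, dtype=float)
    g = np.asarray(g, dtype=float)
    d = delta_svp(t)
    es = svp(t)
    ea = avp(t, rh_pct)
    denom = d + gamma * (1.0 + 0.34 * ws)
    if np.any(denom <= 0):
        raise ValueError("Penman-Monteith denominator non-positive")
    num = 0.408 * d * (rn - g) + gamma * (WIND_CONSTANT_15MIN / (t + 273.0)) * ws * (es - ea)
    et0 = num / denom
    if floor is not None:
        et0 = np.maximum(et0, floor)
    return et0


def derive_weather(weather: pd.DataFrame, gamma=GAMMA_DEFAULT) -> pd.DataFrame:
    """Attach derived columns (es, ea, vpd, delta, Rn, G, et0) to a weather table.

    Expects columns T (degC), RH (%), WS (m s-1), RAD (MJ m-2 15min-1) and
    optionally Rn and G; when Rn/G are absent they are estimated with
    :func:`net_radiation` and :func:`soil_heat_flux`.
    """
    w = weather.copy()
    w["es"] = svp(w["T"])
    w["ea"] = avp(w["T"], w["RH"])
    w["vpd"] = w["es"] - w["ea"]
    w["delta"] = delta_svp(w["T"])
    day = w["RAD"].to_numpy() > 0
    if "Rn" not in w.columns:
        w["Rn"] = net_radiation(w["RAD"])
    if "G" not in w.columns:
        w["G"] = soil_heat_flux(w["Rn"], day)
    w["day_flag"] = day
    w["et0"] = penman_monteith_15min(w["T"], w["RH"], w["WS"], w["Rn"], w["G"],
                                     gamma=gamma)
    return w


# ---------------------------------------------------------------------------
# ET0-ratio filter
# ---------------------------------------------------------------------------

@dataclass
class RatioFilterResult:
    """Outcome of filtering an ETr series against reference ET0."""

    etr: np.ndarray                    # filtered + re-interpolated series
    removed_mask: np.ndarray           # original samples ever removed
    n_removed: int
    removal_fraction: float            # n_removed / len(series)
    passes: int = 1

    @property
    def removal_percent(self) -> float:
        return 100.0 * self.removal_fraction


def _interpolate_over(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    keep = ~bad
    if not keep.any():
        raise ValueError("every sample removed; nothing left to interpolate")
    idx = np.arange(x.size)
    out = x.astype(float).copy()
    out[bad] = np.interp(idx[bad], idx[keep], x[keep])
    return out


def ratio_filter(etr, et0, rad, day_threshold=1.0, night_threshold=1.5,
                 exempt=None) -> RatioFilterResult:
    """Remove ETr samples implausibly large relative to reference ET0.

    Day samples (RAD > 0) with ETr/ET0 strictly greater than
    ``day_threshold`` and night samples exceeding ``night_threshold`` are
    removed and linearly re-interpolated from the retained neighbours.
    Steps where ET0 = 0 are never removed (no defined ratio).

    Removal is monotone over *observed* samples: a pass flags violators
    among not-yet-removed samples, re-interpolates, and repeats until no
    observed sample violates.  Interpolated fills are bookkeeping, not
    observations; they are recorded in ``removed_mask`` and never re-tested,
    so re-applying the filter with ``exempt=result.removed_mask`` removes
    nothing (idempotence over the observed data).
    """
    etr = np.asarray(etr, dtype=float)
    et0 = np.asarray(et0, dtype=float)
    rad = np.asarray(rad, dtype=float)
    if not (etr.shape == et0.shape == rad.shape):
        raise ValueError("etr, et0 and rad must share one 15-min grid")
    thr = np.where(rad > 0, day_threshold, night_threshold)
    ever_removed = np.zeros(etr.size, dtype=bool)
    if exempt is not None:
        ever_removed |= np.asarray(exempt, dtype=bool)
    current = etr.copy()
    passes = 0
    while True:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(et0 > 0, current / et0, 0.0)
        bad = (et0 > 0) & (ratio > thr) & ~ever_removed
        passes += 1
        if not bad.any():
            break
        ever_removed |= bad
        current = _interpolate_over(current, ever_removed)
    if exempt is not None:
        ever_removed &= ~np.asarray(exempt, dtype=bool)
    n_removed = int(ever_removed.sum())
    return RatioFilterResult(
        etr=current,
        removed_mask=ever_removed,
        n_removed=n_removed,
        removal_fraction=n_removed / etr.size,
        passes=passes,
    )


# ---------------------------------------------------------------------------
# GCV cubic smoothing spline with a fixed interior-knot basis
# ---------------------------------------------------------------------------

@dataclass
class SplineFit:
    """A penalised cubic regression-spline fit."""

    x: np.ndarray
    fitted: np.ndarray
    lambda_: float
    gcv_path: pd.DataFrame = field(repr=False, default=None)
    coefficients: np.ndarray = field(repr=False, default=None)


def _bspline_design(x, knots_interior, degree=3):
    from scipy.interpolate import BSpline

    t = np.concatenate([
        np.repeat(x[0], degree + 1),
        knots_interior,
        np.repeat(x[-1], degree + 1),
    ])
    n_basis = len(t) - degree - 1
    B = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    return B, t, n_basis


def _second_derivative_penalty(t, n_basis, degree=3):
    """Gram matrix of second derivatives of the B-spline basis.

    Exact via 2-point Gauss-Legendre per knot span (integrand is quadratic
    for cubic splines).
    """
    from scipy.interpolate import BSpline

    spans = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    pts, wts = [], []
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts.extend(mid + half * gauss)
        wts.extend([half, half])
    pts = np.asarray(pts)
    wts = np.asarray(wts)
    # second-derivative design at quadrature points
    D2 = np.empty((pts.size, n_basis))
    eye = np.eye(n_basis)
    for j in range(n_basis):
        D2[:, j] = BSpline(t, eye[j], degree)(pts, nu=2)
    return (D2 * wts[:, None]).T @ D2


def smooth_spline(y, x=None, knots=20, lambda_grid=None,
                  floor=0.0) -> SplineFit:
    """Cubic smoothing spline with GCV-selected penalty.

    ``knots`` equally spaced interior knots span the x range; the roughness
    penalty is the integrated squared second derivative, and the smoothing
    parameter lambda minimises the generalised cross-validation score
    GCV(lambda) = n RSS / (n - tr H)^2 over a log-spaced grid
    (default 1e-6 ... 1e3, 60 points).  Negative fitted values are floored
    at ``floor`` (pass ``floor=None`` to disable).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if x is None:
        x = np.arange(n, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    if n < 2 * knots:
        raise ValueError(f"need at least {2 * knots} samples for {knots} knots")
    if np.ptp(y) == 0:  # degenerate constant input
        return SplineFit(x=x, fitted=y.copy(), lambda_=np.nan)
    if lambda_grid is None:
        lambda_grid = np.logspace(-6, 3, 60)

    # basis and penalty are built on x rescaled to [0, 1] so that lambda is
    # dimensionless and one grid serves any sampling interval
    xs = (x - x[0]) / (x[-1] - x[0])
    knots_interior = np.linspace(0.0, 1.0, knots + 2)[1:-1]
    B, t, n_basis = _bspline_design(xs, knots_interior)
    Omega = _second_derivative_penalty(t, n_basis)
    BtB = B.T @ B
    Bty = B.T @ y

    records = []
    best = None
    for lam in lambda_grid:
        A = BtB + lam * Omega
        try:
            coef = np.linalg.solve(A, Bty)
            # tr H = tr[(B'B + lam*Omega)^-1 B'B]
            tr_h = np.trace(np.linalg.solve(A, BtB))
        except np.linalg.LinAlgError:
            continue
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        gcv = n * rss / (n - tr_h) ** 2
        records.append((lam, gcv, tr_h))
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, fitted)
    if best is None:
        raise np.linalg.LinAlgError("spline system singular for all lambda")
    _, lam, coef, fitted = best
    if floor is not None:
        fitted = np.maximum(fitted, floor)
    path = pd.DataFrame(records, columns=["lambda", "gcv", "edf"])
    return SplineFit(x=x, fitted=fitted, lambda_=lam, gcv_path=path,
                     coefficients=coef)


def smooth_daily(etr, steps_per_day: int = 96, knots: int = 20,
                 floor=0.0) -> np.ndarray:
    """GCV cubic smoothing spline applied day by day.

    One spline with 20 interior knots cannot represent a multi-day series of
    diurnal cycles (fewer than two knots per cycle), so the smoother is
    fitted to each day's profile separately and the fits concatenated.  A
    trailing partial day (the first differenced day is one sample short) is
    smoothed as its own segment.
    """
    etr = np.asarray(etr, dtype=float)
    out = np.empty_like(etr)
    n = etr.size
    start = n % steps_per_day  # leading partial segment, if any
    if start:
        seg = etr[:start]
        out[:start] = (smooth_spline(seg, knots=knots, floor=floor).fitted
                       if seg.size >= 2 * knots else np.maximum(seg, 0.0))
    for d in range(start, n, steps_per_day):
        seg = etr[d:d + steps_per_day]
        out[d:d + steps_per_day] = smooth_spline(seg, knots=knots,
                                                 floor=floor).fitted
    return out
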