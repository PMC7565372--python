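"""Per-day transpiration-profile features and genotype aggregation.

Fifteen features summarise each sector-day: areas under the TR curve over
diurnal windows, window slopes, the magnitude and local geometry of the TR
peak, within-window variability, and the cosine similarity between the
day's observed ETr profile and the Penman-Monteith reference ET profile.
Clock windows follow the site's diurnal cycle: daylight 07:00-19:00, the
peak-demand window 10:00-15:00, evening decline 19:00-23:45.

Feature means per genotype (over replicates and days) are the clustering
inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical feature order and column headers
FEATURE_NAMES = [
    "total.auc", "auc.07.19", "auc.prop.07.19", "auc.prop.night",
    "slope.19.23.45", "maxTR", "slope.maxTR.6", "slope.00.07",
    "slope.07maxTR", "curvmaxTR", "auc.10.15", "auc.prop.10.15",
    "sd.10.15", "sd.07.19", "cos.sim.index",
]


def _window(hours, a, b):
    return (hours >= a) & (hours <= b)


def _auc(hours, y, mask):
    h, v = hours[mask], y[mask]
    if h.size < 2:
        return np.nan
    return float(np.trapezoid(v, h))


def _ols_slope(hours, y, mask):
    h, v = hours[mask], y[mask]
    if h.size < 2 or np.ptp(h) == 0:
        return np.nan
    return float(np.polyfit(h, v, 1)[0])


def _curvature_quadratic(hours, y, i):
    lo, hi = max(0, i - 3), min(y.size, i + 4)
    h, v = hours[lo:hi], y[lo:hi]
    if h.size < 3:
        return np.nan, True
    a = np.polyfit(h - hours[i], v, 2)[0]
    return float(2.0 * a), hi - lo < 7


def _curvature_angle(hours, y, i):
    """Angle (radians) between incoming and outgoing secants at the peak."""
    lo, hi = max(0, i - 3), min(y.size - 1, i + 3)
    if lo == i or hi == i:
        return np.nan, True
    v_in = np.array([hours[i] - hours[lo], y[i] - y[lo]])
    v_out = np.array([hours[hi] - hours[i], y[hi] - y[i]])
    na, nb = np.linalg.norm(v_in), np.linalg.norm(v_out)
    if na == 0 or nb == 0:
        return 0.0, False
    cosang = np.clip(v_in @ v_out / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang)), False


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def extract_features(tr_day, etr_day=None, et0_day=None, hours=None,
                     curvature_method: str = "quadratic") -> dict:
    """Fifteen features of one sector-day TR profile.

    Parameters
    ----------
    tr_day : 1-D array
        TR samples on the 15-min grid (normally 96 per day).
    etr_day, et0_day : 1-D arrays, optional
        The day's observed ETr and reference ET0 profiles for the cosine
        similarity feature (NaN when absent).
    hours : 1-D array, optional
        Sample clock times in hours (default 0.00, 0.25, ... for the grid).
    curvature_method : ``"quadratic"`` or ``"angle"``
        Curvature at the peak as the second derivative of a local quadratic
        (default) or as the angle between the incoming/outgoing secants.

    AUC features are trapezoidal in TR x hours; ``total.auc`` closes the day
    periodically (24:00 = 00:00) so a constant profile c integrates to 24c
    and day/night proportions sum to one.  Slopes are OLS fits of TR on
    clock time.  A ``boundary_flag`` key marks days whose peak sits too
    close to the day edge for the full peak-window fits.
    """
    tr = np.asarray(tr_day, dtype=float)
    n = tr.size
    if hours is None:
        hours = np.arange(n) * (24.0 / n)
    else:
        hours = np.asarray(hours, dtype=float)

    # periodic closure of the daily integral
    h_ext = np.append(hours, hours[0] + 24.0)
    tr_ext = np.append(tr, tr[0])
    total_auc = float(np.trapezoid(tr_ext, h_ext))

    w_day = _window(hours, 7.0, 19.0)
    w_1015 = _window(hours, 10.0, 15.0)
    auc_day = _auc(hours, tr, w_day)
    auc_1015 = _auc(hours, tr, w_1015)

    with np.errstate(divide="ignore", invalid="ignore"):
        prop_day = auc_day / total_auc if total_auc != 0 else np.nan
        prop_1015 = auc_1015 / total_auc if total_auc != 0 else np.nan

    i_max = int(np.nanargmax(tr))
    max_tr = float(tr[i_max])

    lo6 = i_max - 5
    boundary = lo6 < 0
    w6 = np.zeros(n, dtype=bool)
    w6[max(0, lo6):i_max + 1] = True
    if w6.sum() < 2:  # peak on the first sample: use the one-sided forward run
        w6[i_max:min(n, i_max + 6)] = True

    w_07max = _window(hours, 7.0, hours[i_max])
    if hours[i_max] <= 7.0:
        boundary = True

    if curvature_method == "quadratic":
        curv, curv_flag = _curvature_quadratic(hours, tr, i_max)
    elif curvature_method == "angle":
        curv, curv_flag = _curvature_angle(hours, tr, i_max)
    else:
        raise ValueError("curvature_method must be 'quadratic' or 'angle'")
    boundary = boundary or curv_flag

    sd = lambda m: float(np.std(tr[m], ddof=1)) if m.sum() >= 2 else np.nan

    if etr_day is not None and et0_day is not None:
        cos_sim = cosine_similarity(etr_day, et0_day)
    else:
        cos_sim = np.nan

    return {
        "total.auc": total_auc,
        "auc.07.19": auc_day,
        "auc.prop.07.19": prop_day,
        "auc.prop.night": 1.0 - prop_day if np.isfinite(prop_day) else np.nan,
        "slope.19.23.45": _ols_slope(hours, tr, _window(hours, 19.0, 23.75)),
        "maxTR": max_tr,
        "slope.maxTR.6": _ols_slope(hours, tr, w6),
        "slope.00.07": _ols_slope(hours, tr, _window(hours, 0.0, 7.0)),
        "slope.07maxTR": _ols_slope(hours, tr, w_07max),
        "curvmaxTR": curv,
        "auc.10.15": auc_1015,
        "auc.prop.10.15": prop_1015,
        "sd.10.15": sd(w_1015),
        "sd.07.19": sd(w_day),
        "cos.sim.index": cos_sim,
        "boundary_flag": bool(boundary),
    }


def extract_feature_table(tr: pd.DataFrame, etr: pd.DataFrame | None = None,
                          et0: pd.Series | None = None,
                          curvature_method: str = "quadratic") -> pd.DataFrame:
    """Features for every sector-day of a datetime-indexed TR table.

    ``tr`` (and optionally ``etr``) have one column per sector; ``et0`` is
    the shared reference-ET series.  Returns one row per sector-day.
    """
    rows = []
    dates = tr.index.normalize()
    for date in dates.unique():
        sel = dates == date
        idx = tr.index[sel]
        hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
        et0_day = et0.loc[idx].to_numpy() if et0 is not None else None
        for sector in tr.columns:
            tr_day = tr.loc[idx, sector].to_numpy()
            if np.isnan(tr_day).all():
                continue
            etr_day = (etr.loc[idx, sector].to_numpy()
                       if etr is not None else None)
            feats = extract_features(tr_day, etr_day, et0_day, hours=hours,
                                     curvature_method=curvature_method)
            feats["sector_id"] = sector
            feats["date"] = date
            rows.append(feats)
    cols = ["sector_id", "date"] + FEATURE_NAMES + ["boundary_flag"]
    return pd.DataFrame(rows)[cols]


def aggregate_features(feature_table: pd.DataFrame,
                       design: pd.DataFrame) -> pd.DataFrame:
    """Genotype means over replicates and days (missing sector-days dropped).

    ``design`` maps ``sector_id`` to ``genotype_id``.  Genotypes with no
    data are absent from the output.
    """
    missing = set(feature_table["sector_id"]) - set(design["sector_id"])
    if missing:
        raise ValueError(f"sectors missing from design table: {sorted(missing)}")
    merged = feature_table.merge(design[["sector_id", "genotype_id"]],
                                 on="sector_id", how="left")
    means = (merged.groupby("genotype_id")[FEATURE_NAMES]
             .mean())  # pandas mean skips NaN per feature
    return means
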