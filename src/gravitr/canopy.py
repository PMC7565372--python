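"""From evapotranspiration to transpiration rate per unit leaf area.

Sector evapotranspiration mixes soil evaporation and plant transpiration.
A Beer-Lambert light-interception term splits the two: the canopy
intercepts a fraction 1 - exp(-beta * LAI) of incoming radiation, and the
same fraction of ETr is attributed to transpiration (Tr).  Dividing Tr by
the observed leaf area of the day yields the transpiration rate TR, the
per-leaf-area flux on which genotypes are compared.

Leaf area comes from 3-D laser scans; the platform regression gives
observed LA = 2.5 x 3DLA.  LAI is observed LA over the tray footprint
(default 0.24 m2, a 40 x 60 cm tray).  Scans within a day are reduced by a
per-day maximum, treating within-day canopy growth as negligible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BETA_DEFAULT = 0.463          # canopy light-extinction coefficient
LA_SCANNER_FACTOR = 2.5       # observed LA = 2.5 * 3-D scanner LA
TRAY_AREA_M2 = 0.24           # 40 cm x 60 cm tray footprint


def observed_la_from_3d(la3d):
    """Observed leaf area (m2) from scanner leaf area: 2.5 x 3DLA."""
    la3d = np.asarray(la3d, dtype=float)
    if np.any(la3d < 0):
        raise ValueError("scanner leaf area must be non-negative")
    return LA_SCANNER_FACTOR * la3d


def lai_from_observed_la(observed_la, ground_area_m2: float = TRAY_AREA_M2):
    """Leaf area index = observed LA / ground area (default tray footprint)."""
    if ground_area_m2 <= 0:
        raise ValueError("ground area must be positive")
    return np.asarray(observed_la, dtype=float) / ground_area_m2


def beer_interception(etr, lai, beta: float = BETA_DEFAULT):
    """Transpiration from ETr via Beer's law: Tr = (1 - exp(-beta*LAI)) * ETr."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    return (1.0 - np.exp(-beta * lai)) * np.asarray(etr, dtype=float)


def tr_per_leaf_area(tr, observed_la):
    """Transpiration rate TR = Tr / observed LA (per-day LA, broadcastable).

    Days with zero or missing leaf area yield missing TR (NaN), never zero.
    """
    la = np.asarray(observed_la, dtype=float)
    la = np.where(la > 0, la, np.nan)
    return np.asarray(tr, dtype=float) / la


def daily_max_leaf_area(scans: pd.DataFrame) -> pd.DataFrame:
    """Reduce repeated within-day scans to the daily maximum observed LA.

    ``scans`` needs columns ``sector_id``, ``timestamp``, ``la3d_m2``.
    Returns one row per sector-day with ``observed_la_m2`` and ``lai``.
    """
    s = scans.copy()
    s["timestamp"] = pd.to_datetime(s["timestamp"])
    s["date"] = s["timestamp"].dt.normalize()
    daily = (s.groupby(["sector_id", "date"], as_index=False)["la3d_m2"]
             .max())
    daily["observed_la_m2"] = observed_la_from_3d(daily["la3d_m2"])
    daily["lai"] = lai_from_observed_la(daily["observed_la_m2"])
    return daily


def etr_to_tr(etr: pd.Series, daily_la: pd.DataFrame, sector_id: str,
              beta: float = BETA_DEFAULT) -> pd.DataFrame:
    """Apply the Beer split and per-leaf-area division to one sector.

    ``etr`` is a datetime-indexed ETr series; ``daily_la`` comes from
    :func:`daily_max_leaf_area`.  Returns a frame with Tr and TR columns.
    """
    la = daily_la[daily_la["sector_id"] == sector_id].set_index("date")
    dates = etr.index.normalize()
    obs_la = la["observed_la_m2"].reindex(dates).to_numpy()
    lai = la["lai"].reindex(dates).to_numpy()
    lai_filled = np.where(np.isnan(lai), 0.0, lai)
    tr = beer_interception(etr.to_numpy(), lai_filled, beta=beta)
    tr = np.where(np.isnan(lai), np.nan, tr)
    tr_rate = tr_per_leaf_area(tr, np.where(np.isnan(obs_la), 0.0, obs_la))
    return pd.DataFrame({"Tr": tr, "TR": tr_rate,
                         "observed_la_m2": obs_la}, index=etr.index)
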