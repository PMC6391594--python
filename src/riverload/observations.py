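"""Observed loads from concentration and discharge records.

The observed load of a record is the product of measured concentration and
discharge (ug/L x m3/s x 1e6 = ng/s).  Records are never averaged per
station: every record contributes one load to a single statistical
population.  Records below the limit of quantification carry a flag plus
the LOQ value; the default policy excludes them, with LOQ/2 and zero
substitution available for sensitivity runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .network import NetworkError, StreamNetwork
from .units import UGL_TIMES_M3S_TO_NG_S

__all__ = [
    "LOQ_POLICIES",
    "compute_observed_loads",
    "snap_stations",
    "read_observations",
]

logger = logging.getLogger(__name__)

LOQ_POLICIES = ("exclude", "half", "zero")

_REQUIRED = ("station_id", "reach_id", "concentration_ug_L", "discharge_m3s")


def compute_observed_loads(records: pd.DataFrame, loq_policy: str = "exclude"
                           ) -> tuple[pd.DataFrame, dict]:
    """Turn observation records into observed loads (ng/s).

    Parameters
    ----------
    records : DataFrame
        Columns ``station_id, reach_id, concentration_ug_L, discharge_m3s``
        plus optional ``date, substance, below_loq``.
    loq_policy : str
        ``"exclude"`` drops below-LOQ records, ``"half"`` substitutes
        LOQ/2, ``"zero"`` substitutes zero.

    Returns
    -------
    (loads, summary)
        ``loads`` is the usable records with an added ``load_ng_s`` column;
        ``summary`` counts usable, skipped (nonpositive discharge) and
        censored-excluded records.  The three counts always sum to the
        input count.
    """
    missing = set(_REQUIRED) - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")
    if loq_policy not in LOQ_POLICIES:
        raise ValueError(f"loq_policy must be one of {LOQ_POLICIES}")
    df = records.copy()
    if (df["concentration_ug_L"] < 0).any():
        raise ValueError("negative concentration in records")
    n_input = len(df)

    bad_q = df["discharge_m3s"] <= 0
    if bad_q.any():
        logger.warning("skipping %d record(s) with nonpositive discharge",
                       int(bad_q.sum()))
    df = df[~bad_q]

    censored_excluded = 0
    if "below_loq" in df.columns:
        below = df["below_loq"].astype(bool)
        if loq_policy == "exclude":
            censored_excluded = int(below.sum())
            df = df[~below]
        elif loq_policy == "half":
            df.loc[below, "concentration_ug_L"] = (
                df.loc[below, "concentration_ug_L"] / 2.0)
        else:  # zero
            df.loc[below, "concentration_ug_L"] = 0.0

    df = df.copy()
    df["load_ng_s"] = (df["concentration_ug_L"] * df["discharge_m3s"]
                       * UGL_TIMES_M3S_TO_NG_S)
    summary = {
        "n_input": n_input,
        "usable": len(df),
        "skipped_nonpositive_discharge": int(bad_q.sum()),
        "censored_excluded": censored_excluded,
    }
    return df, summary


def snap_stations(stations: pd.DataFrame, network: StreamNetwork
                  ) -> pd.DataFrame:
    """Assign stations to the nearest reach node (planar Euclidean).

    ``stations`` needs columns ``station_id, x, y``.  Ties (within
    floating tolerance) are broken by larger drainage area, then by reach
    id for stability.  Returns a table of assignments with distances.
    """
    missing = {"station_id", "x", "y"} - set(stations.columns)
    if missing:
        raise ValueError(f"stations are missing columns: {sorted(missing)}")
    rids = network.reach_ids
    nx = np.array([network[r].x for r in rids], dtype=float)
    ny = np.array([network[r].y for r in rids], dtype=float)
    if np.isnan(nx).any() or np.isnan(ny).any():
        bad = rids[int(np.flatnonzero(np.isnan(nx) | np.isnan(ny))[0])]
        raise NetworkError(f"reach '{bad}' has no coordinates")
    areas = network.drainage_areas.loc[rids].to_numpy(dtype=float)
    rows = []
    for row in stations.itertuples(index=False):
        d = np.hypot(nx - float(row.x), ny - float(row.y))
        dmin = d.min()
        tied = np.flatnonzero(d <= dmin * (1.0 + 1e-12) + 1e-300)
        # larger drainage area first, reach id as final deterministic key
        best = min(tied, key=lambda i: (-areas[i], rids[i]))
        rows.append({"station_id": row.station_id,
                     "reach_id": rids[best],
                     "distance": float(d[best])})
        logger.debug("station %s -> reach %s (distance %.3f)",
                     row.station_id, rids[best], d[best])
    return pd.DataFrame(rows)


def read_observations(path) -> pd.DataFrame:
    """Read an observations CSV (station, reach, date, substance, C, Q)."""
    df = pd.read_csv(path, dtype={"station_id": str, "reach_id": str})
    if "below_loq" in df.columns:
        df["below_loq"] = df["below_loq"].astype(int)
    return df
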