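"""Point-source load propagation and point-vs-diffuse impact indicators.

Point emissions are accumulated downstream with the same decayed
accumulation used for diffuse loads.  The per-reach indicators are
``Z`` = maximum over substances of the point-to-diffuse load ratio, and
``W`` = number of substances whose ratio strictly exceeds the 25%
threshold.  Reaches with zero diffuse load but positive point load are
flagged with an infinite ratio rather than dropped.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .network import EmissionField, StreamNetwork, accumulate_decayed

__all__ = [
    "point_loads",
    "impact_indicators",
    "district_point_share",
    "read_point_sources",
    "emissions_by_reach",
]


def emissions_by_reach(point_emissions: pd.DataFrame | Mapping[str, float]
                       ) -> dict[str, float]:
    """Collapse a point-source table to total emission (ng/s) per reach."""
    if isinstance(point_emissions, pd.DataFrame):
        missing = {"reach_id", "emission_ng_s"} - set(point_emissions.columns)
        if missing:
            raise ValueError(
                f"point source table is missing columns: {sorted(missing)}")
        grouped = point_emissions.groupby(
            point_emissions["reach_id"].astype(str))["emission_ng_s"].sum()
        return {str(k): float(v) for k, v in grouped.items()}
    return {str(k): float(v) for k, v in dict(point_emissions).items()}


def point_loads(network: StreamNetwork, point_emissions, dt50: float
                ) -> pd.Series:
    """Per-reach load (ng/s) from point emissions, decayed downstream.

    Identical accumulation contract as diffuse loads; emissions on unknown
    reaches raise an error.
    """
    field = EmissionField.from_point_sources(
        network, emissions_by_reach(point_emissions))
    return accumulate_decayed(network, field, dt50)


def impact_indicators(diffuse_loads: Mapping[str, pd.Series],
                      point_loads_by_substance: Mapping[str, pd.Series],
                      threshold: float = 0.25) -> pd.DataFrame:
    """Per-reach Z and W impact indicators.

    Both mappings must cover the same substances and the same reaches.
    The ratio denominator is the diffuse load; zero diffuse with positive
    point load yields an infinite ratio (flagged hot spot).
    """
    d_subs = set(diffuse_loads)
    p_subs = set(point_loads_by_substance)
    if d_subs != p_subs:
        raise ValueError(
            "substance sets differ between diffuse and point loads: "
            f"{sorted(d_subs ^ p_subs)}"
        )
    if not d_subs:
        raise ValueError("no substances supplied")
    index = None
    ratios = []
    for sub in sorted(d_subs):
        d = pd.Series(diffuse_loads[sub], dtype=float)
        p = pd.Series(point_loads_by_substance[sub], dtype=float)
        if index is None:
            index = d.index
        if not d.index.equals(p.index) or not d.index.equals(index):
            raise ValueError(f"reach sets differ for substance '{sub}'")
        ratio = np.where(d > 0, p / d.where(d > 0, 1.0),
                         np.where(p > 0, np.inf, 0.0))
        ratios.append(pd.Series(ratio, index=index, name=sub))
    table = pd.concat(ratios, axis=1)
    return pd.DataFrame({
        "Z": table.max(axis=1),
        "W": (table > threshold).sum(axis=1).astype(int),
    })


def district_point_share(point_emissions: pd.DataFrame,
                         diffuse_emissions: Mapping[str, pd.Series],
                         districts: pd.Series,
                         percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)
                         ) -> pd.DataFrame:
    """District-level point:diffuse emission shares per substance.

    Emissions (not decayed loads) are summed within each district; the
    requested percentiles of the ratio are computed over districts with
    nonzero point emissions.  Returns one row per substance with share
    percentiles (fractions) and the count of districts with share > 0.
    """
    districts = pd.Series(districts).astype(str)
    if districts.empty or (districts == "").all():
        raise ValueError("no districts defined on the network")
    point_by_reach = point_emissions.copy()
    unknown = set(point_by_reach["substance"]) - set(diffuse_emissions)
    if unknown:
        raise ValueError(
            f"point sources for substances without diffuse emissions: "
            f"{sorted(unknown)}"
        )
    rows = []
    for sub in sorted(diffuse_emissions):
        diffuse = pd.Series(diffuse_emissions[sub], dtype=float)
        diffuse_by_d = diffuse.groupby(districts.reindex(diffuse.index)).sum()
        sub_points = point_by_reach[point_by_reach["substance"] == sub]
        point_by_d = pd.Series(0.0, index=diffuse_by_d.index)
        if len(sub_points):
            grouped = sub_points.groupby(
                sub_points["reach_id"].astype(str).map(districts)
            )["emission_ng_s"].sum()
            point_by_d = point_by_d.add(grouped, fill_value=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(diffuse_by_d > 0, point_by_d / diffuse_by_d,
                             np.where(point_by_d > 0, np.inf, 0.0))
        share = pd.Series(share, index=diffuse_by_d.index)
        positive = share[point_by_d > 0]
        row = {"substance": sub,
               "n_districts_positive": int((share > 0).sum())}
        if len(positive):
            values = np.percentile(positive.to_numpy(), percentiles)
        else:
            values = [np.nan] * len(percentiles)
        for p, v in zip(percentiles, values):
            row[f"share_p{p:g}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def read_point_sources(path) -> pd.DataFrame:
    """Read a point-source CSV (substance, reach_id, emission_ng_s)."""
    df = pd.read_csv(path, dtype={"substance": str, "reach_id": str})
    missing = {"substance", "reach_id", "emission_ng_s"} - set(df.columns)
    if missing:
        raise ValueError(
            f"point source file is missing columns: {sorted(missing)}")
    return df
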