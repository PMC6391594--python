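"""Emission inventories by reporting district and loads to sea.

Diffuse emissions are the district sum of the emission pattern times the
calibrated emission factor -- no in-stream decay is applied to emissions
(decay applies to loads).  Sea loads are the decayed loads arriving at
outlet reaches, grouped by receiving sea.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .calibration import UNIFORM_PATTERN
from .network import StreamNetwork
from .units import KG_Y_TO_T_Y, NG_S_TO_KG_Y

__all__ = ["build_inventory", "sea_loads", "diffuse_emission_field"]

logger = logging.getLogger(__name__)


def diffuse_emission_field(network: StreamNetwork, pattern: str,
                           emission_factor: float) -> pd.Series:
    """Per-reach diffuse emission (ng/s) = emission factor x pattern."""
    if pattern == UNIFORM_PATTERN:
        values = network.local_areas
    else:
        values = network.pattern(pattern)
    return values * emission_factor


def build_inventory(network: StreamNetwork,
                    factors: Mapping[str, tuple[str, float]],
                    point_emissions: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """District x substance emission inventory in kg/y.

    ``factors`` maps substance name to ``(pattern, emission_factor)``
    with the factor in ng per pattern unit per second.  Point emissions
    (ng/s per facility) are summed into the district of their reach.
    A point-source substance without an emission factor raises an error
    naming the substance.
    """
    if not factors:
        raise ValueError("no emission factors supplied")
    districts = network.districts
    district_ids = sorted(districts.unique())
    rows = []
    point_by = {}
    if point_emissions is not None and len(point_emissions):
        unknown = set(point_emissions["substance"]) - set(factors)
        if unknown:
            raise ValueError(
                "missing emission factor for substance "
                f"'{sorted(unknown)[0]}'"
            )
        grouped = point_emissions.groupby(
            ["substance",
             point_emissions["reach_id"].astype(str).map(districts)]
        )["emission_ng_s"].sum()
        point_by = grouped.to_dict()
    for substance in sorted(factors):
        pattern, ef = factors[substance]
        emissions = diffuse_emission_field(network, pattern, ef)
        diffuse_by_district = emissions.groupby(districts).sum() * NG_S_TO_KG_Y
        for district in district_ids:
            diffuse = float(diffuse_by_district.get(district, 0.0))
            point = float(point_by.get((substance, district), 0.0)) \
                * NG_S_TO_KG_Y
            rows.append({
                "district_id": district,
                "substance": substance,
                "diffuse_kg_y": diffuse,
                "point_kg_y": point,
                "total_kg_y": diffuse + point,
            })
    return pd.DataFrame(rows)


def sea_loads(network: StreamNetwork,
              loads_by_substance: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Loads (tonnes/y) delivered at outlet reaches, grouped by sea.

    Outlets without a sea label are grouped under ``"unassigned"`` with a
    warning rather than dropped.
    """
    if not loads_by_substance:
        raise ValueError("no loads supplied")
    outlet_sea = {}
    for rid in network.outlets:
        sea = network[rid].sea_id
        if not sea:
            logger.warning("outlet reach '%s' has no sea label; grouped "
                           "under 'unassigned'", rid)
            sea = "unassigned"
        outlet_sea[rid] = sea
    rows = []
    for substance in sorted(loads_by_substance):
        loads = pd.Series(loads_by_substance[substance], dtype=float)
        by_sea: dict[str, float] = {}
        for rid, sea in outlet_sea.items():
            by_sea[sea] = by_sea.get(sea, 0.0) + float(loads[rid])
        for sea in sorted(by_sea):
            rows.append({
                "sea_id": sea,
                "substance": substance,
                "load_t_y": by_sea[sea] * NG_S_TO_KG_Y * KG_Y_TO_T_Y,
            })
    return pd.DataFrame(rows)
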