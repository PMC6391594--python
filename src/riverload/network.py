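"""Stream-network data model and decayed catchment accumulation.

A :class:`StreamNetwork` is a forest of in-trees: every reach drains to at
most one downstream reach and the downstream graph is acyclic.  The core
computation, :func:`accumulate_decayed`, propagates a per-reach field down
the network while applying first-order exponential dissipation over water
travel time.  Loads and load proxies are evaluated at each reach's
downstream node; the path time from a source reach to the evaluation reach
includes the travel time of *both* endpoint reaches (emissions enter at the
upstream end of the reach they originate in).

:func:`brute_force_load` re-computes the same quantity by explicit path
enumeration and serves as an independent test oracle.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field as dataclass_field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NetworkError",
    "CycleError",
    "Reach",
    "StreamNetwork",
    "EmissionField",
    "topological_order",
    "accumulate_decayed",
    "brute_force_load",
]


class NetworkError(ValueError):
    """Raised when a network violates its structural invariants."""


class CycleError(NetworkError):
    """Raised when the downstream graph contains a cycle."""


#: Columns of the network CSV that are not emission patterns.
RESERVED_COLUMNS = (
    "reach_id",
    "downstream_id",
    "travel_time_days",
    "drainage_area_km2",
    "district_id",
    "sea_id",
    "local_runoff_m3s",
    "x",
    "y",
    "precip_mm",
    "pet_mm",
)


@dataclass
class Reach:
    """One river reach (stream segment plus its local sub-basin).

    ``travel_time`` is the water travel time through the reach in days and
    includes any lake or reservoir residence on it.  ``drainage_area`` is
    the total upstream-inclusive area in km2.  ``pattern_values`` holds the
    local (sub-basin) quantity of each emission pattern, e.g. persons or
    km2 of agricultural land.
    """

    reach_id: str
    downstream_id: str | None = None
    travel_time: float = 0.0
    drainage_area: float = 1.0
    pattern_values: dict[str, float] = dataclass_field(default_factory=dict)
    local_runoff: float = 0.0  # m3/s generated in the local sub-basin
    district_id: str = ""
    sea_id: str = ""
    x: float = math.nan
    y: float = math.nan
    precip_mm: float = math.nan
    pet_mm: float = math.nan

    def __post_init__(self) -> None:
        if self.travel_time < 0:
            raise ValueError(
                f"reach '{self.reach_id}': travel_time must be >= 0, "
                f"got {self.travel_time}"
            )
        if not self.drainage_area > 0:
            raise ValueError(
                f"reach '{self.reach_id}': drainage_area must be > 0, "
                f"got {self.drainage_area}"
            )
        if self.local_runoff < 0:
            raise ValueError(
                f"reach '{self.reach_id}': local_runoff must be >= 0"
            )
        for name, value in self.pattern_values.items():
            if value < 0:
                raise ValueError(
                    f"reach '{self.reach_id}': pattern '{name}' must be "
                    f">= 0, got {value}"
                )


class StreamNetwork:
    """Forest of reaches with derived upstream adjacency.

    Construction validates the invariants: unique reach ids, downstream
    references resolve, the downstream graph is acyclic, and (unless
    ``check_areas=False``) each reach's drainage area is at least the sum
    of its immediate upstream drainage areas.
    """

    def __init__(self, reaches: Iterable[Reach], check_areas: bool = True):
        self._reaches: dict[str, Reach] = {}
        for reach in reaches:
            if reach.reach_id in self._reaches:
                raise NetworkError(f"duplicate reach id '{reach.reach_id}'")
            self._reaches[reach.reach_id] = reach
        if not self._reaches:
            raise NetworkError("network has no reaches")
        for reach in self._reaches.values():
            ds = reach.downstream_id
            if ds is not None and ds not in self._reaches:
                raise NetworkError(
                    f"reach '{reach.reach_id}' drains to unknown reach '{ds}'"
                )
            if ds == reach.reach_id:
                raise CycleError(
                    f"cycle detected involving reach '{reach.reach_id}'"
                )
        self._upstream: dict[str, list[str]] = {rid: [] for rid in self._reaches}
        for reach in self._reaches.values():
            if reach.downstream_id is not None:
                self._upstream[reach.downstream_id].append(reach.reach_id)
        self._order = self._toposort()
        if check_areas:
            self._check_areas()

    # -- basic protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._reaches)

    def __contains__(self, reach_id: str) -> bool:
        return reach_id in self._reaches

    def __getitem__(self, reach_id: str) -> Reach:
        try:
            return self._reaches[reach_id]
        except KeyError:
            raise NetworkError(f"unknown reach '{reach_id}'") from None

    @property
    def reach_ids(self) -> list[str]:
        return list(self._reaches)

    @property
    def outlets(self) -> list[str]:
        return [r.reach_id for r in self._reaches.values()
                if r.downstream_id is None]

    def upstream(self, reach_id: str) -> tuple[str, ...]:
        """Immediate upstream neighbours of ``reach_id``."""
        if reach_id not in self._reaches:
            raise NetworkError(f"unknown reach '{reach_id}'")
        return tuple(self._upstream[reach_id])

    # -- invariants -------------------------------------------------------

    def _toposort(self) -> list[str]:
        pending = {rid: len(ups) for rid, ups in self._upstream.items()}
        queue = deque(rid for rid, n in pending.items() if n == 0)
        order: list[str] = []
        while queue:
            rid = queue.popleft()
            order.append(rid)
            ds = self._reaches[rid].downstream_id
            if ds is not None:
                pending[ds] -= 1
                if pending[ds] == 0:
                    queue.append(ds)
        if len(order) < len(self._reaches):
            placed = set(order)
            offender = next(r for r in self._reaches if r not in placed)
            raise CycleError(f"cycle detected involving reach '{offender}'")
        return order

    def _check_areas(self) -> None:
        for rid, ups in self._upstream.items():
            if not ups:
                continue
            up_sum = sum(self._reaches[u].drainage_area for u in ups)
            area = self._reaches[rid].drainage_area
            if up_sum > area * (1.0 + 1e-9):
                raise NetworkError(
                    f"reach '{rid}': drainage area {area} km2 is smaller "
                    f"than the sum of its upstream areas ({up_sum} km2)"
                )

    def topological_order(self) -> list[str]:
        """Reach ids ordered headwaters-first."""
        return list(self._order)

    # -- derived fields ---------------------------------------------------

    def local_area(self, reach_id: str) -> float:
        """Local (incremental) sub-basin area of a reach, km2."""
        reach = self[reach_id]
        up = sum(self._reaches[u].drainage_area
                 for u in self._upstream[reach_id])
        return max(reach.drainage_area - up, 0.0)

    @property
    def local_areas(self) -> pd.Series:
        return pd.Series({rid: self.local_area(rid) for rid in self._reaches},
                         name="local_area_km2")

    @property
    def travel_times(self) -> pd.Series:
        return pd.Series({rid: r.travel_time
                          for rid, r in self._reaches.items()},
                         name="travel_time_days")

    @property
    def drainage_areas(self) -> pd.Series:
        return pd.Series({rid: r.drainage_area
                          for rid, r in self._reaches.items()},
                         name="drainage_area_km2")

    @property
    def districts(self) -> pd.Series:
        return pd.Series({rid: r.district_id
                          for rid, r in self._reaches.items()},
                         name="district_id")

    @property
    def local_runoff(self) -> pd.Series:
        return pd.Series({rid: r.local_runoff
                          for rid, r in self._reaches.items()},
                         name="local_runoff_m3s")

    @property
    def pattern_names(self) -> list[str]:
        names: list[str] = []
        for reach in self._reaches.values():
            for name in reach.pattern_values:
                if name not in names:
                    names.append(name)
        return names

    def pattern(self, name: str) -> pd.Series:
        """Per-reach values of one emission pattern."""
        values = {}
        for rid, reach in self._reaches.items():
            if name not in reach.pattern_values:
                raise NetworkError(
                    f"unknown pattern '{name}' (missing on reach '{rid}')"
                )
            values[rid] = reach.pattern_values[name]
        return pd.Series(values, name=name)

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        patterns = self.pattern_names
        rows = []
        for rid, r in self._reaches.items():
            row = {
                "reach_id": rid,
                "downstream_id": "" if r.downstream_id is None else r.downstream_id,
                "travel_time_days": r.travel_time,
                "drainage_area_km2": r.drainage_area,
                "district_id": r.district_id,
                "sea_id": r.sea_id,
                "local_runoff_m3s": r.local_runoff,
                "x": r.x,
                "y": r.y,
                "precip_mm": r.precip_mm,
                "pet_mm": r.pet_mm,
            }
            for name in patterns:
                row[name] = r.pattern_values.get(name, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, check_areas: bool = True
                   ) -> "StreamNetwork":
        required = {"reach_id", "downstream_id", "travel_time_days",
                    "drainage_area_km2"}
        missing = required - set(df.columns)
        if missing:
            raise NetworkError(
                f"network table is missing columns: {sorted(missing)}"
            )
        pattern_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
        reaches = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            ds = d["downstream_id"]
            if ds is None or (isinstance(ds, float) and math.isnan(ds)) \
                    or str(ds) == "" or pd.isna(ds):
                ds = None
            else:
                ds = str(ds)
            reaches.append(Reach(
                reach_id=str(d["reach_id"]),
                downstream_id=ds,
                travel_time=float(d["travel_time_days"]),
                drainage_area=float(d["drainage_area_km2"]),
                pattern_values={c: float(d[c]) for c in pattern_cols},
                local_runoff=float(d.get("local_runoff_m3s", 0.0) or 0.0),
                district_id=str(d.get("district_id", "") or ""),
                sea_id=str(d.get("sea_id", "") or ""),
                x=float(d["x"]) if "x" in d and pd.notna(d["x"]) else math.nan,
                y=float(d["y"]) if "y" in d and pd.notna(d["y"]) else math.nan,
                precip_mm=(float(d["precip_mm"])
                           if "precip_mm" in d and pd.notna(d["precip_mm"])
                           else math.nan),
                pet_mm=(float(d["pet_mm"])
                        if "pet_mm" in d and pd.notna(d["pet_mm"])
                        else math.nan),
            ))
        return cls(reaches, check_areas=check_areas)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, check_areas: bool = True) -> "StreamNetwork":
        df = pd.read_csv(
            path,
            dtype={"reach_id": str, "downstream_id": str,
                   "district_id": str, "sea_id": str},
            keep_default_na=True,
        )
        return cls.from_frame(df, check_areas=check_areas)


@dataclass
class EmissionField:
    """Per-reach emission intensity.

    ``is_pattern`` distinguishes a unit-emission pattern field (pattern
    units) from an absolute point-source field (ng/s).
    """

    values: pd.Series
    is_pattern: bool = True
    units: str = ""

    @classmethod
    def from_pattern(cls, network: StreamNetwork, name: str) -> "EmissionField":
        return cls(values=network.pattern(name), is_pattern=True, units=name)

    @classmethod
    def from_point_sources(cls, network: StreamNetwork,
                           emissions: Mapping[str, float]) -> "EmissionField":
        """Dense ng/s field from sparse per-reach point emissions."""
        values = pd.Series(0.0, index=network.reach_ids)
        for rid, e in emissions.items():
            if rid not in network:
                raise NetworkError(
                    f"point emission on unknown reach '{rid}'"
                )
            if e < 0:
                raise ValueError(
                    f"point emission on reach '{rid}' must be >= 0"
                )
            values[rid] += float(e)
        return cls(values=values, is_pattern=False, units="ng/s")


def _field_values(network: StreamNetwork, field) -> pd.Series:
    if isinstance(field, EmissionField):
        series = field.values
    elif isinstance(field, pd.Series):
        series = field
    else:
        series = pd.Series(dict(field), dtype=float)
    series = series.reindex(network.reach_ids).astype(float)
    if series.isna().any():
        missing = series.index[series.isna()][0]
        raise NetworkError(
            f"field is not defined on every reach (missing '{missing}')"
        )
    if (series < 0).any():
        offender = series.index[series < 0][0]
        raise ValueError(f"field is negative on reach '{offender}'")
    return series


def _check_dt50(dt50: float) -> bool:
    """Validate dt50 and return whether it is finite."""
    if not dt50 > 0:
        raise ValueError(
            f"dt50 must be > 0 days (use math.inf for no decay), got {dt50}"
        )
    return math.isfinite(dt50)


def topological_order(network: StreamNetwork) -> list[str]:
    """Reach ids ordered so every reach follows all its upstream reaches."""
    return network.topological_order()


def accumulate_decayed(network: StreamNetwork, field, dt50: float) -> pd.Series:
    """Accumulate a per-reach field downstream with first-order decay.

    The value at reach ``x`` is ``sum_i field(i) * 0.5 ** (T(i->x)/dt50)``
    over all reaches ``i`` in the catchment of ``x``, where ``T(i->x)`` is
    the travel time along the path from ``i`` to ``x`` inclusive of both
    endpoint reaches (``T(x->x)`` equals the travel time of ``x`` itself).
    With ``dt50 = math.inf`` the decay factor is exactly 1.

    Parameters
    ----------
    field : EmissionField, pandas.Series or mapping
        Nonnegative value for every reach.
    dt50 : float
        Dissipation half-life in days, > 0 or ``math.inf``.

    Returns
    -------
    pandas.Series indexed by reach id, in network order.
    """
    finite = _check_dt50(dt50)
    values = _field_values(network, field)
    acc: dict[str, float] = {}
    for rid in network.topological_order():
        reach = network[rid]
        total = values[rid]
        for up in network.upstream(rid):
            total += acc[up]
        decay = 0.5 ** (reach.travel_time / dt50) if finite else 1.0
        acc[rid] = total * decay
    return pd.Series(acc, dtype=float).reindex(network.reach_ids)


def brute_force_load(network: StreamNetwork, field, dt50: float,
                     target_reach: str) -> float:
    """Oracle: decayed accumulation at one reach by explicit path walking.

    Same contract as :func:`accumulate_decayed` evaluated at
    ``target_reach``, but computed by enumerating every source reach in the
    catchment and summing travel times explicitly along its downstream
    path.  Intended for small networks only.
    """
    if target_reach not in network:
        raise NetworkError(f"unknown target reach '{target_reach}'")
    finite = _check_dt50(dt50)
    values = _field_values(network, field)
    # catchment of the target, via upstream traversal
    catchment = []
    stack = [target_reach]
    while stack:
        rid = stack.pop()
        catchment.append(rid)
        stack.extend(network.upstream(rid))
    total = 0.0
    for src in catchment:
        t = 0.0
        cur = src
        while True:
            t += network[cur].travel_time
            if cur == target_reach:
                break
            cur = network[cur].downstream_id
        decay = 0.5 ** (t / dt50) if finite else 1.0
        total += values[src] * decay
    return float(total)
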