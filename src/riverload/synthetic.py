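"""Seeded synthetic scenarios: networks, patterns, truth and observations.

These generators replace the pan-European input datasets with desk-scale
stand-ins that keep the statistical structure the analysis assumes:
tree-shaped networks, spatially heterogeneous lognormal population, patchy
agricultural area, multiplicative-lognormal noise on observed
concentrations, sparse stations and point sources, and exceedance flags
obtained by thresholding concentrations.  Everything is deterministic
given the scenario seed: each generation stage draws from its own
``numpy`` ``default_rng`` seeded with ``(seed, stage_index)``.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import UNIFORM_PATTERN
from .hydrology import accumulate_discharge, budyko_runoff, concentration
from .network import Reach, StreamNetwork, accumulate_decayed
from .point_sources import point_loads
from .units import MM_KM2_Y_TO_M3_S

__all__ = [
    "Substance",
    "SyntheticScenario",
    "TrueState",
    "Exceedances",
    "generate_network",
    "generate_patterns",
    "generate_true_state",
    "generate_observations",
    "generate_point_sources",
    "generate_exceedances",
]

# RNG stream indices, one per generation stage
_STREAM_NETWORK = 0
_STREAM_PATTERNS = 1
_STREAM_OBSERVATIONS = 3
_STREAM_POINTS = 4
_STREAM_EXCEEDANCES = 5

_BASE_DATE = _dt.date(2005, 1, 1)


@dataclass(frozen=True)
class Substance:
    """True emission model of one synthetic chemical."""

    name: str
    pattern: str
    emission_factor: float  # ng per pattern unit per second
    dt50: float  # days
    eqs_aa: float | None = None  # ug/L; None -> quantile-derived threshold
    eqs_mac: float | None = None

    def __post_init__(self) -> None:
        if self.emission_factor < 0:
            raise ValueError(f"substance '{self.name}': emission factor "
                             "must be >= 0")
        if not self.dt50 > 0:
            raise ValueError(f"substance '{self.name}': dt50 must be > 0")


DEFAULT_SUBSTANCES: tuple[Substance, ...] = (
    Substance("chem_pop", "pop", 20.0, 10.0),
    Substance("chem_agri", "agri_km2", 300.0, 20.0),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic data-generation scenario."""

    seed: int = 0
    # network
    n_reaches: int = 300
    travel_time_mean: float = 1.0  # days; lognormal with this mean
    travel_time_sigma: float = 0.7  # sd of the log
    local_area_mean: float = 7.0  # km2
    local_area_sigma: float = 0.5
    precip_mean: float = 900.0  # mm/y
    precip_sigma: float = 0.2
    pet_mean: float = 600.0  # mm/y
    pet_sigma: float = 0.15
    n_districts: int = 5
    n_seas: int = 1
    # emission patterns
    pop_median: float = 500.0  # persons per sub-basin
    pop_sigma: float = 1.2
    urban_fraction: float = 0.05
    clustering_factor: float = 10.0  # scale-up of the urban subset
    agri_fraction_range: tuple[float, float] = (0.05, 0.6)
    livestock_density: float = 30.0  # units per km2 of agriculture
    livestock_noise: float = 0.3
    connection_range: tuple[float, float] = (0.5, 0.95)
    # substances
    substances: tuple[Substance, ...] = DEFAULT_SUBSTANCES
    # observation design
    n_stations: int = 25
    samples_per_station: int = 4
    noise_sigma: float = 0.3  # sd of log multiplicative concentration error
    discharge_day_sigma: float = 0.0  # sd of log daily discharge factor
    loq_fraction: float = 0.0  # fraction of lowest concentrations censored
    # point sources
    n_facilities: int = 0
    point_share: float = 0.1  # target total point emission / diffuse
    facility_sigma: float = 1.0
    # exceedances
    peak_factor: float = 3.0  # peak-to-annual concentration factor for MAC
    label_noise: float = 0.0
    eqs_quantile_aa: float = 0.9  # used when a substance has no EQS value
    eqs_quantile_mac: float = 0.95

    def __post_init__(self) -> None:
        if self.n_reaches < 1:
            raise ValueError("n_reaches must be >= 1")
        for name in ("travel_time_mean", "local_area_mean", "precip_mean",
                     "pet_mean", "pop_median"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("travel_time_sigma", "local_area_sigma", "precip_sigma",
                     "pet_sigma", "pop_sigma", "noise_sigma",
                     "discharge_day_sigma", "facility_sigma",
                     "livestock_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.loq_fraction <= 1:
            raise ValueError("loq_fraction must be in [0, 1]")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")
        lo, hi = self.agri_fraction_range
        if lo < 0 or hi > 1 or lo > hi:
            raise ValueError("agri_fraction_range must be within [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, stream]))

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["substances"] = [asdict(s) for s in self.substances]
        d["agri_fraction_range"] = list(self.agri_fraction_range)
        d["connection_range"] = list(self.connection_range)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticScenario":
        d = dict(data)
        if "substances" in d:
            d["substances"] = tuple(
                s if isinstance(s, Substance) else Substance(**s)
                for s in d["substances"])
        for key in ("agri_fraction_range", "connection_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _lognormal_with_mean(rng: np.random.Generator, mean: float, sigma: float,
                         size: int) -> np.ndarray:
    """Lognormal draws whose distribution mean equals ``mean``."""
    if sigma == 0:
        return np.full(size, mean)
    mu = math.log(mean) - 0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size)


def generate_network(scenario: SyntheticScenario) -> StreamNetwork:
    """Random in-tree network with hydrology columns filled.

    Each non-root reach attaches downstream-ward to an existing reach with
    preference for reaches that have few upstream neighbours, which yields
    realistic dendritic branching.  Travel times and local areas are
    lognormal; local runoff follows the Budyko balance of lognormal
    precipitation and potential ET.  Deterministic given the seed.
    """
    rng = scenario.rng(_STREAM_NETWORK)
    n = scenario.n_reaches
    ids = [f"r{i:05d}" for i in range(n)]
    parent = np.full(n, -1, dtype=int)
    n_children = np.zeros(n, dtype=int)
    for i in range(1, n):
        weights = 1.0 / (1.0 + n_children[:i]) ** 2
        j = int(rng.choice(i, p=weights / weights.sum()))
        parent[i] = j
        n_children[j] += 1

    travel = _lognormal_with_mean(rng, scenario.travel_time_mean,
                                  scenario.travel_time_sigma, n)
    local_area = _lognormal_with_mean(rng, scenario.local_area_mean,
                                      scenario.local_area_sigma, n)
    precip = _lognormal_with_mean(rng, scenario.precip_mean,
                                  scenario.precip_sigma, n)
    pet = _lognormal_with_mean(rng, scenario.pet_mean,
                               scenario.pet_sigma, n)
    runoff = budyko_runoff(precip, pet)
    local_q = runoff * local_area * MM_KM2_Y_TO_M3_S

    # coordinates: children scatter around their parent
    coords = np.zeros((n, 2))
    coords[0] = (50.0, 50.0)
    offsets = rng.normal(0.0, 3.0, size=(n, 2))
    for i in range(1, n):
        coords[i] = coords[parent[i]] + offsets[i]

    district = rng.integers(0, scenario.n_districts, size=n)

    # upstream-inclusive drainage areas (node i always attaches to j < i)
    drainage = local_area.copy()
    for i in range(n - 1, 0, -1):
        drainage[parent[i]] += drainage[i]

    reaches = []
    for i in range(n):
        reaches.append(Reach(
            reach_id=ids[i],
            downstream_id=None if parent[i] < 0 else ids[parent[i]],
            travel_time=float(travel[i]),
            drainage_area=float(drainage[i]),
            local_runoff=float(local_q[i]),
            district_id=f"d{district[i]}",
            sea_id=f"sea{i % scenario.n_seas}" if parent[i] < 0 else "",
            x=float(coords[i, 0]),
            y=float(coords[i, 1]),
            precip_mm=float(precip[i]),
            pet_mm=float(pet[i]),
        ))
    return StreamNetwork(reaches)


def generate_patterns(network: StreamNetwork, scenario: SyntheticScenario
                      ) -> StreamNetwork:
    """Fill the four emission patterns on every reach (in place).

    Population is lognormal with an "urban" subset scaled up by the
    clustering factor; agricultural area is a uniform fraction of local
    area; livestock and connected population are noisy transforms of
    agriculture and population respectively.
    """
    rng = scenario.rng(_STREAM_PATTERNS)
    rids = network.reach_ids
    n = len(rids)
    local_areas = network.local_areas.loc[rids].to_numpy()

    pop = rng.lognormal(math.log(scenario.pop_median), scenario.pop_sigma, n)
    urban = rng.random(n) < scenario.urban_fraction
    pop = np.where(urban, pop * scenario.clustering_factor, pop)
    lo, hi = scenario.agri_fraction_range
    agri = rng.uniform(lo, hi, n) * local_areas
    livestock = (agri * scenario.livestock_density
                 * np.exp(rng.normal(0.0, scenario.livestock_noise, n)))
    connected = pop * rng.uniform(*scenario.connection_range, n)

    for i, rid in enumerate(rids):
        network[rid].pattern_values.update({
            "pop": float(pop[i]),
            "agri_km2": float(agri[i]),
            "livestock": float(livestock[i]),
            "pop_connected": float(connected[i]),
        })
    return network


@dataclass(frozen=True)
class TrueState:
    """Noise-free loads, discharge and concentrations per substance."""

    network: StreamNetwork
    substances: tuple[Substance, ...]
    discharge: pd.Series  # m3/s
    loads: dict[str, pd.Series]  # total (diffuse + point) ng/s
    diffuse_loads: dict[str, pd.Series]
    point_loads: dict[str, pd.Series]
    concentrations: dict[str, pd.Series]  # ug/L


def generate_true_state(network: StreamNetwork, scenario: SyntheticScenario,
                        point_sources: pd.DataFrame | None = None
                        ) -> TrueState:
    """True per-reach loads and concentrations for every substance."""
    q = accumulate_discharge(network)
    loads: dict[str, pd.Series] = {}
    diffuse: dict[str, pd.Series] = {}
    points: dict[str, pd.Series] = {}
    concs: dict[str, pd.Series] = {}
    patterns = set(network.pattern_names) | {UNIFORM_PATTERN}
    for sub in scenario.substances:
        if sub.pattern not in patterns:
            raise ValueError(
                f"substance '{sub.name}' references unknown pattern "
                f"'{sub.pattern}'"
            )
        if sub.pattern == UNIFORM_PATTERN:
            pattern_field = network.local_areas
        else:
            pattern_field = network.pattern(sub.pattern)
        d = sub.emission_factor * accumulate_decayed(network, pattern_field,
                                                     sub.dt50)
        if point_sources is not None and len(point_sources):
            sub_points = point_sources[point_sources["substance"] == sub.name]
            p = (point_loads(network, sub_points, sub.dt50)
                 if len(sub_points)
                 else pd.Series(0.0, index=network.reach_ids))
        else:
            p = pd.Series(0.0, index=network.reach_ids)
        total = d + p
        loads[sub.name] = total
        diffuse[sub.name] = d
        points[sub.name] = p
        concs[sub.name] = concentration(total, q)
    return TrueState(network=network, substances=tuple(scenario.substances),
                     discharge=q, loads=loads, diffuse_loads=diffuse,
                     point_loads=points, concentrations=concs)


def generate_point_sources(network: StreamNetwork,
                           scenario: SyntheticScenario) -> pd.DataFrame:
    """Sparse facility emissions (substance, reach_id, emission_ng_s).

    Facility magnitudes are lognormal around a base chosen so that total
    point emissions are roughly ``point_share`` of diffuse emissions.
    """
    rng = scenario.rng(_STREAM_POINTS)
    columns = ["substance", "reach_id", "emission_ng_s"]
    if scenario.n_facilities == 0:
        return pd.DataFrame(columns=columns)
    totals = {}
    for sub in scenario.substances:
        if sub.pattern == UNIFORM_PATTERN:
            total_pattern = float(network.local_areas.sum())
        else:
            total_pattern = float(network.pattern(sub.pattern).sum())
        totals[sub.name] = sub.emission_factor * total_pattern
    rids = network.reach_ids
    rows = []
    for k in range(scenario.n_facilities):
        sub = scenario.substances[int(rng.integers(len(scenario.substances)))]
        rid = rids[int(rng.integers(len(rids)))]
        base = scenario.point_share * totals[sub.name] / scenario.n_facilities
        magnitude = base * math.exp(float(rng.normal(0.0,
                                                     scenario.facility_sigma)))
        rows.append({"substance": sub.name, "reach_id": rid,
                     "emission_ng_s": magnitude})
    return pd.DataFrame(rows, columns=columns)


def generate_observations(true_state: TrueState,
                          scenario: SyntheticScenario) -> pd.DataFrame:
    """Noisy observation records at randomly placed stations.

    Stations sample ``n_stations`` distinct reaches without replacement,
    weighted toward larger drainage areas.  Observed concentration is the
    true concentration times a multiplicative lognormal error; per-sample
    discharge is the annual mean times a lognormal day factor.  The lowest
    ``loq_fraction`` of concentrations per substance are flagged below the
    limit of quantification and carry the LOQ value.
    """
    rng = scenario.rng(_STREAM_OBSERVATIONS)
    network = true_state.network
    if scenario.n_stations > len(network):
        raise ValueError(
            f"n_stations={scenario.n_stations} exceeds the number of "
            f"reaches ({len(network)})"
        )
    areas = network.drainage_areas
    p = (areas / areas.sum()).to_numpy()
    station_reaches = rng.choice(network.reach_ids, size=scenario.n_stations,
                                 replace=False, p=p)
    rows = []
    for si, rid in enumerate(station_reaches):
        q_annual = float(true_state.discharge[rid])
        for _ in range(scenario.samples_per_station):
            day = int(rng.integers(0, 365))
            date = _BASE_DATE + _dt.timedelta(days=day)
            day_factor = math.exp(float(rng.normal(
                0.0, scenario.discharge_day_sigma)))
            q = q_annual * day_factor
            for sub in true_state.substances:
                c_true = float(true_state.concentrations[sub.name][rid])
                noise = math.exp(float(rng.normal(0.0, scenario.noise_sigma)))
                rows.append({
                    "station_id": f"s{si:03d}",
                    "reach_id": rid,
                    "date": date.isoformat(),
                    "substance": sub.name,
                    "concentration_ug_L": c_true * noise,
                    "below_loq": 0,
                    "discharge_m3s": q,
                })
    df = pd.DataFrame(rows)
    if scenario.loq_fraction > 0 and len(df):
        for sub in true_state.substances:
            mask = df["substance"] == sub.name
            conc = df.loc[mask, "concentration_ug_L"]
            k = int(math.ceil(scenario.loq_fraction * len(conc)))
            if k == 0:
                continue
            order = conc.to_numpy().argsort(kind="stable")
            flagged = conc.index[order[:k]]
            loq = float(conc.iloc[order[k - 1]])
            df.loc[flagged, "below_loq"] = 1
            df.loc[flagged, "concentration_ug_L"] = loq
    return df


@dataclass(frozen=True)
class Exceedances:
    """Per-reach, per-substance quality-standard exceedance flags."""

    frame: pd.DataFrame  # reach_id, substance, exceed_aa, exceed_mac
    thresholds: dict[str, tuple[float, float]]  # substance -> (AA, MAC)

    def flags(self, substance: str, kind: str = "aa") -> pd.Series:
        sub = self.frame[self.frame["substance"] == substance]
        return pd.Series(sub[f"exceed_{kind}"].to_numpy(dtype=bool),
                         index=sub["reach_id"].to_numpy())


def generate_exceedances(true_state: TrueState, scenario: SyntheticScenario
                         ) -> Exceedances:
    """Exceedance flags by thresholding true concentrations.

    AA flags compare the annual-average concentration with the AA
    standard; MAC flags compare a peak concentration (annual average times
    ``peak_factor``) with the MAC standard.  Substances without a standard
    get a quantile-derived threshold so flags are always well defined.
    An optional label-noise rate flips flags to emulate reporting
    inconsistency.
    """
    rng = scenario.rng(_STREAM_EXCEEDANCES)
    frames = []
    thresholds = {}
    for sub in true_state.substances:
        conc = true_state.concentrations[sub.name]
        values = conc.to_numpy(dtype=float)
        aa_thr = (sub.eqs_aa if sub.eqs_aa is not None
                  else float(np.nanquantile(values, scenario.eqs_quantile_aa)))
        mac_thr = (sub.eqs_mac if sub.eqs_mac is not None
                   else float(np.nanquantile(values * scenario.peak_factor,
                                             scenario.eqs_quantile_mac)))
        thresholds[sub.name] = (aa_thr, mac_thr)
        aa = values > aa_thr
        mac = values * scenario.peak_factor > mac_thr
        flip_aa = rng.random(len(values)) < scenario.label_noise
        flip_mac = rng.random(len(values)) < scenario.label_noise
        frames.append(pd.DataFrame({
            "reach_id": conc.index,
            "substance": sub.name,
            "exceed_aa": (aa ^ flip_aa).astype(int),
            "exceed_mac": (mac ^ flip_mac).astype(int),
        }))
    return Exceedances(frame=pd.concat(frames, ignore_index=True),
                       thresholds=thresholds)
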