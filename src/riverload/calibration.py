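"""Emission-factor calibration by grid search over patterns and half-lives.

Observed loads are regressed against load proxies (decayed catchment
accumulations of an emission pattern) by weighted least squares with
``sqrt(load)`` weights, one proxy at a time over a grid of emission
patterns and dissipation half-lives.  The winning proxy minimises the
Euclidean distance to the ideal point (r2 = 1, intercept = 0) in the
normalised intercept / explained-variance plane; its slope is the
emission factor and its intercept is ignored.  Uncertainty comes from a
record-level bootstrap with percentile intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .network import EmissionField, StreamNetwork, accumulate_decayed

__all__ = [
    "DT50_GRID",
    "DEFAULT_PATTERNS",
    "UNIFORM_PATTERN",
    "CalibrationError",
    "DegenerateProxyError",
    "WLSFit",
    "ProxyFit",
    "GridCalibration",
    "BootstrapResult",
    "CalibrationResult",
    "wls_fit",
    "build_proxy_grid",
    "grid_calibrate",
    "select_best",
    "bootstrap_uncertainty",
    "calibrate_substance",
    "apply_dt50_override",
    "r2_class",
]

#: Half-life grid, days.
DT50_GRID: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 10.0, 20.0, 50.0, 100.0,
                                1000.0)

#: Default emission patterns: population, agricultural area, livestock and
#: population connected to wastewater treatment.
DEFAULT_PATTERNS: tuple[str, ...] = ("pop", "agri_km2", "livestock",
                                     "pop_connected")

#: Pseudo-pattern name for catchment area alone (uniform areal emission).
UNIFORM_PATTERN = "uniform"


class CalibrationError(ValueError):
    """Raised when a calibration cannot be carried out."""


class DegenerateProxyError(CalibrationError):
    """Raised when the explanatory variable has zero variance."""


@dataclass(frozen=True)
class WLSFit:
    slope: float
    intercept: float
    r_squared: float


def wls_fit(x, y, weights) -> WLSFit:
    """Weighted least-squares line minimising ``sum w (y - a - b x)^2``.

    ``r_squared`` is the weighted coefficient of determination about the
    weighted mean of ``y``, clipped to ``[0, 1]`` (0 when ``y`` is
    constant).  Raises :class:`DegenerateProxyError` when ``x`` has zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y and weights must have identical shape")
    if x.size < 3:
        raise CalibrationError("need at least 3 points for a WLS fit")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    if np.all(x == x[0]):
        raise DegenerateProxyError(
            "degenerate proxy: explanatory variable has zero variance"
        )
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    scale = np.linalg.norm(design, axis=0)
    coef, *_ = np.linalg.lstsq(design / scale, sw * y, rcond=None)
    intercept, slope = coef / scale
    fitted = intercept + slope * x
    rss = float(np.sum(w * (y - fitted) ** 2))
    y_wmean = float(np.sum(w * y) / np.sum(w))
    tss = float(np.sum(w * (y - y_wmean) ** 2))
    r2 = 0.0 if tss == 0.0 else float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    return WLSFit(slope=float(slope), intercept=float(intercept), r_squared=r2)


def build_proxy_grid(network: StreamNetwork,
                     patterns: Sequence[str] = DEFAULT_PATTERNS,
                     dt50_grid: Sequence[float] = DT50_GRID,
                     include_uniform: bool = False) -> pd.DataFrame:
    """Per-reach load proxies for every (pattern, dt50) combination.

    Returns a DataFrame indexed by reach id whose columns are a MultiIndex
    ``(pattern, dt50)``; proxies carry the units of their pattern.  The
    pseudo-pattern :data:`UNIFORM_PATTERN` uses local catchment area.
    """
    patterns = list(patterns)
    if include_uniform and UNIFORM_PATTERN not in patterns:
        patterns.append(UNIFORM_PATTERN)
    columns = {}
    for pattern in patterns:
        if pattern == UNIFORM_PATTERN:
            field = network.local_areas
        else:
            field = EmissionField.from_pattern(network, pattern)
        for dt50 in dt50_grid:
            columns[(pattern, float(dt50))] = accumulate_decayed(
                network, field, float(dt50))
    proxies = pd.DataFrame(columns)
    proxies.columns = pd.MultiIndex.from_tuples(proxies.columns,
                                                names=["pattern", "dt50"])
    return proxies


@dataclass(frozen=True)
class ProxyFit:
    """WLS fit of observed loads against one load proxy."""

    pattern: str
    dt50: float
    slope: float
    intercept: float
    r_squared: float
    distance_to_ideal: float
    n_points: int


def _selection_key(fit: ProxyFit):
    # minimal distance; ties: higher r2, then smaller DT50
    return (fit.distance_to_ideal, -fit.r_squared, fit.dt50)


def select_best(fits: Sequence[ProxyFit]) -> ProxyFit:
    if not fits:
        raise CalibrationError("no proxy fits to select from")
    return min(fits, key=_selection_key)


@dataclass(frozen=True)
class GridCalibration:
    """All proxy fits for one substance plus the ideal-point selection."""

    fits: tuple[ProxyFit, ...]
    selected: ProxyFit
    intercept_normalizer: float
    skipped: tuple[tuple[str, float], ...] = ()

    def fit_for(self, pattern: str, dt50: float) -> ProxyFit:
        for fit in self.fits:
            if fit.pattern == pattern and fit.dt50 == float(dt50):
                return fit
        raise CalibrationError(
            f"no fit for pattern '{pattern}' at DT50 {dt50} d"
        )

    def best_for_pattern(self, pattern: str) -> ProxyFit:
        fits = [f for f in self.fits if f.pattern == pattern]
        if not fits:
            raise CalibrationError(f"no fits for pattern '{pattern}'")
        return select_best(fits)

    @property
    def dt50_values(self) -> tuple[float, ...]:
        return tuple(sorted({f.dt50 for f in self.fits}))


def _usable_loads(observed_loads: pd.DataFrame) -> pd.DataFrame:
    required = {"reach_id", "load_ng_s"}
    missing = required - set(observed_loads.columns)
    if missing:
        raise CalibrationError(
            f"observed loads table is missing columns: {sorted(missing)}"
        )
    usable = observed_loads[observed_loads["load_ng_s"] > 0]
    if len(usable) < 3:
        raise CalibrationError(
            f"fewer than 3 usable (positive) observed loads: {len(usable)}"
        )
    return usable


def grid_calibrate(proxies: pd.DataFrame, observed_loads: pd.DataFrame,
                   intercept_normalizer: float | str = "mean_load"
                   ) -> GridCalibration:
    """Fit every proxy to the observed loads and pick the ideal-point best.

    ``observed_loads`` needs columns ``reach_id`` and ``load_ng_s``; one
    row per record (records are never averaged per station).  Records with
    nonpositive load are excluded (their sqrt-load weight is undefined).
    The ideal-point distance is ``sqrt((1 - r2)^2 + (intercept/ybar)^2)``
    where ``ybar`` is the mean observed load unless a numeric
    ``intercept_normalizer`` is supplied.
    """
    usable = _usable_loads(observed_loads)
    y = usable["load_ng_s"].to_numpy(dtype=float)
    reach_ids = usable["reach_id"].astype(str)
    unknown = [r for r in reach_ids.unique() if r not in proxies.index]
    if unknown:
        raise CalibrationError(
            f"observed loads on reaches without proxies: {unknown[:5]}"
        )
    weights = np.sqrt(y)
    ybar = (float(np.mean(y)) if intercept_normalizer == "mean_load"
            else float(intercept_normalizer))
    if not ybar > 0:
        raise CalibrationError("intercept normalizer must be > 0")
    fits: list[ProxyFit] = []
    skipped: list[tuple[str, float]] = []
    for pattern, dt50 in proxies.columns:
        x = proxies.loc[reach_ids, (pattern, dt50)].to_numpy(dtype=float)
        try:
            f = wls_fit(x, y, weights)
        except DegenerateProxyError:
            skipped.append((pattern, dt50))
            continue
        distance = math.hypot(1.0 - f.r_squared, f.intercept / ybar)
        fits.append(ProxyFit(pattern=pattern, dt50=float(dt50),
                             slope=f.slope, intercept=f.intercept,
                             r_squared=f.r_squared,
                             distance_to_ideal=distance,
                             n_points=len(y)))
    if not fits:
        raise CalibrationError("every proxy was degenerate")
    return GridCalibration(fits=tuple(fits), selected=select_best(fits),
                           intercept_normalizer=ybar,
                           skipped=tuple(skipped))


@dataclass(frozen=True)
class BootstrapResult:
    slope_interval: tuple[float, float]
    intercept_interval: tuple[float, float]
    n_boot: int
    n_redrawn: int

    def covers_slope(self, value: float) -> bool:
        lo, hi = self.slope_interval
        return lo <= value <= hi


def bootstrap_uncertainty(x, y, n_boot: int = 1000,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None
                          ) -> BootstrapResult:
    """Record-level bootstrap percentile intervals for slope and intercept.

    Records (x, y pairs) are resampled with replacement and the WLS fit
    (weights ``sqrt(y)``) repeated; 2.5/97.5 percentiles are returned.
    Degenerate resamples (zero x variance) are redrawn and counted.
    Deterministic for a fixed ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if (y <= 0).any():
        raise ValueError("bootstrap requires positive loads (sqrt weights)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = x.size
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            xb = x[idx]
            if np.all(xb == xb[0]):
                redrawn += 1
                if redrawn > 100 * n_boot:
                    raise CalibrationError(
                        "bootstrap cannot draw a non-degenerate resample"
                    )
                continue
            break
        yb = y[idx]
        fit = wls_fit(xb, yb, np.sqrt(yb))
        slopes[b] = fit.slope
        intercepts[b] = fit.intercept
    s_lo, s_hi = np.percentile(slopes, [2.5, 97.5])
    i_lo, i_hi = np.percentile(intercepts, [2.5, 97.5])
    return BootstrapResult(slope_interval=(float(s_lo), float(s_hi)),
                           intercept_interval=(float(i_lo), float(i_hi)),
                           n_boot=n_boot, n_redrawn=redrawn)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated emission model for one substance.

    ``modelled_dt50`` is the ideal-point optimum for the assumed pattern;
    ``selected_dt50`` may differ after an ad-hoc override, in which case
    ``r2_drop`` reports the loss of explained variance relative to the
    modelled optimum.  The emission factor is the slope of the
    assumed-pattern fit at the selected DT50 (the intercept is ignored).
    """

    substance: str
    assumed_pattern: str
    grid: GridCalibration
    best: ProxyFit
    modelled_dt50: float
    selected_dt50: float
    emission_factor: float
    r_squared: float
    r2_drop: float = 0.0
    reported_dt50_range: str = ""
    bootstrap: BootstrapResult | None = None

    @property
    def negative_emission_factor(self) -> bool:
        return self.emission_factor < 0

    @property
    def r2_class(self) -> str:
        return r2_class(self.r_squared)


def r2_class(r2: float) -> str:
    """Qualitative explained-variance class: high / medium / low."""
    if r2 >= 0.6:
        return "high"
    if r2 > 0.4:
        return "medium"
    return "low"


def apply_dt50_override(result: CalibrationResult, override_dt50: float,
                        reported_range: str = "") -> CalibrationResult:
    """Re-read the emission factor at an ad-hoc, more realistic DT50.

    The override must be on the calibration grid.  Both the modelled and
    the selected DT50 are retained and the r2 drop relative to the
    modelled optimum is reported.  Any previous bootstrap is invalidated.
    """
    override_dt50 = float(override_dt50)
    if override_dt50 not in result.grid.dt50_values:
        raise CalibrationError(
            f"override DT50 {override_dt50} d is not on the grid "
            f"{result.grid.dt50_values}"
        )
    fit = result.grid.fit_for(result.assumed_pattern, override_dt50)
    base = result.grid.fit_for(result.assumed_pattern, result.modelled_dt50)
    return replace(result,
                   selected_dt50=override_dt50,
                   emission_factor=fit.slope,
                   r_squared=fit.r_squared,
                   r2_drop=base.r_squared - fit.r_squared,
                   reported_dt50_range=reported_range or
                   result.reported_dt50_range,
                   bootstrap=None)


def calibrate_substance(proxies: pd.DataFrame, observed_loads: pd.DataFrame,
                        substance: str, assumed_pattern: str,
                        n_boot: int = 1000, seed: int | None = None,
                        override_dt50: float | None = None,
                        reported_range: str = "",
                        intercept_normalizer: float | str = "mean_load"
                        ) -> CalibrationResult:
    """Full calibration of one substance: grid fit, selection, bootstrap."""
    grid = grid_calibrate(proxies, observed_loads,
                          intercept_normalizer=intercept_normalizer)
    assumed_best = grid.best_for_pattern(assumed_pattern)
    result = CalibrationResult(
        substance=substance,
        assumed_pattern=assumed_pattern,
        grid=grid,
        best=grid.selected,
        modelled_dt50=assumed_best.dt50,
        selected_dt50=assumed_best.dt50,
        emission_factor=assumed_best.slope,
        r_squared=assumed_best.r_squared,
        reported_dt50_range=reported_range,
    )
    if override_dt50 is not None:
        result = apply_dt50_override(result, override_dt50, reported_range)
    if n_boot:
        usable = _usable_loads(observed_loads)
        y = usable["load_ng_s"].to_numpy(dtype=float)
        reach_ids = usable["reach_id"].astype(str)
        x = proxies.loc[reach_ids,
                        (assumed_pattern,
                         result.selected_dt50)].to_numpy(dtype=float)
        boot = bootstrap_uncertainty(x, y, n_boot=n_boot, seed=seed)
        result = replace(result, bootstrap=boot)
    return result
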