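"""Model verification: percentile comparison and prediction-rate curves.

The prediction-rate curve sorts sub-basins by decreasing concentration and
accumulates the fraction of reported quality-standard exceedances captured
along the sorted list.  A curve above the 1:1 diagonal indicates that
concentration predicts exceedances better than random.  Sub-basins with
identical concentration form a single tie block so the curve never depends
on an arbitrary within-tie ordering.  The curve keeps the
fraction-of-sub-basins x axis for plotting and rate read-off, while the
``auc`` field is the proper ROC area (true-positive vs false-positive
rate, equal to the rank statistic), so a perfect predictor scores exactly
1 and random flags score 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RATE_FRACTIONS",
    "PredictionRateCurve",
    "percentile_comparison",
    "prediction_rate_curve",
    "observed_concentration_roc",
]

#: Fractions of sub-basins at which prediction rates are reported.
RATE_FRACTIONS: tuple[float, ...] = (0.1, 0.2, 0.5)


@dataclass(frozen=True)
class PredictionRateCurve:
    """Cumulative-exceedance curve over sub-basins sorted by concentration.

    ``fractions``/``cumulative`` are the curve vertices from (0, 0) to
    (1, 1); ``rates`` maps each fraction in :data:`RATE_FRACTIONS` to the
    linearly interpolated prediction rate; ``auc`` is the rank-based ROC
    area (NaN when every sub-basin is flagged).
    """

    fractions: np.ndarray
    cumulative: np.ndarray
    rates: dict[float, float]
    auc: float
    n_exceedances: int
    n_subbasins: int

    def rate_at(self, fraction: float) -> float:
        return float(np.interp(fraction, self.fractions, self.cumulative))


def prediction_rate_curve(concentrations: pd.Series, flags: pd.Series,
                          rate_fractions: tuple[float, ...] = RATE_FRACTIONS
                          ) -> PredictionRateCurve | None:
    """Build the prediction-rate curve, or ``None`` with zero exceedances.

    ``concentrations`` and ``flags`` are aligned on their common index
    (sub-basin ids); sub-basins without a concentration value are dropped.
    """
    conc = pd.Series(concentrations, dtype=float)
    fl = pd.Series(flags).astype(bool)
    common = conc.index.intersection(fl.index)
    conc = conc.loc[common].dropna()
    fl = fl.loc[conc.index]
    n = len(conc)
    if n == 0:
        raise ValueError("no sub-basins with both concentration and flag")
    values = conc.to_numpy()
    positives = fl.to_numpy()
    n_pos = int(positives.sum())
    if n_pos == 0:
        return None  # explicit "no curve" result

    order = np.argsort(-values, kind="mergesort")
    sorted_values = values[order]
    sorted_flags = positives[order]
    # one curve vertex per tie block (exceedances accrue across the block)
    block_ends = np.append(np.flatnonzero(np.diff(sorted_values)), n - 1)
    fractions = np.concatenate([[0.0], (block_ends + 1) / n])
    cumulative = np.concatenate(
        [[0.0], np.cumsum(sorted_flags)[block_ends] / n_pos])

    n_neg = n - n_pos
    if n_neg > 0:
        ranks = rankdata(values)  # average ranks handle ties
        auc = float((ranks[positives].sum() - n_pos * (n_pos + 1) / 2)
                    / (n_pos * n_neg))
    else:
        auc = float("nan")
    rates = {f: float(np.interp(f, fractions, cumulative))
             for f in rate_fractions}
    return PredictionRateCurve(fractions=fractions, cumulative=cumulative,
                               rates=rates, auc=auc,
                               n_exceedances=n_pos, n_subbasins=n)


def observed_concentration_roc(observed: pd.DataFrame, flags: pd.Series,
                               rate_fractions: tuple[float, ...] =
                               RATE_FRACTIONS) -> PredictionRateCurve | None:
    """Prediction-rate curve for observed concentrations.

    Restricted to sub-basins that have at least one observation; a
    sub-basin's observed concentration is the mean of its records.
    Returns ``None`` when no flagged sub-basin has an observation.
    """
    if observed.empty:
        return None
    missing = {"reach_id", "concentration_ug_L"} - set(observed.columns)
    if missing:
        raise ValueError(f"observed table is missing columns: "
                         f"{sorted(missing)}")
    by_reach = observed.groupby(
        observed["reach_id"].astype(str))["concentration_ug_L"].mean()
    restricted = pd.Series(flags).astype(bool).reindex(by_reach.index,
                                                       fill_value=False)
    if not restricted.any():
        return None
    return prediction_rate_curve(by_reach, restricted,
                                 rate_fractions=rate_fractions)


def percentile_comparison(modelled_conc: pd.Series,
                          drainage_areas: pd.Series,
                          observed: pd.DataFrame,
                          percentiles: tuple[float, ...] = (10.0, 50.0, 90.0)
                          ) -> pd.DataFrame:
    """Modelled vs observed concentration percentiles with area filtering.

    Modelled percentiles are computed only over reaches whose drainage
    area lies within the [min, max] range of the observation sites'
    drainage areas, so the two populations are comparable.  Observed
    percentiles use every record.  Returns a table indexed by percentile
    with columns ``modelled, observed, ratio``.
    """
    if observed.empty:
        raise ValueError("no observed records")
    modelled = pd.Series(modelled_conc, dtype=float)
    areas = pd.Series(drainage_areas, dtype=float)
    obs_reaches = observed["reach_id"].astype(str).unique()
    obs_areas = areas.reindex(obs_reaches)
    if obs_areas.isna().any():
        bad = obs_areas.index[obs_areas.isna()][0]
        raise ValueError(f"observation on reach '{bad}' without a known "
                         "drainage area")
    lo, hi = float(obs_areas.min()), float(obs_areas.max())
    in_range = areas[(areas >= lo) & (areas <= hi)].index
    pool = modelled.reindex(in_range).dropna()
    if pool.empty:
        raise ValueError("no modelled reaches in the observed drainage-area "
                         f"range [{lo}, {hi}] km2")
    model_pct = np.percentile(pool.to_numpy(), percentiles)
    obs_pct = np.percentile(
        observed["concentration_ug_L"].to_numpy(dtype=float), percentiles)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = model_pct / obs_pct
    return pd.DataFrame({"modelled": model_pct, "observed": obs_pct,
                         "ratio": ratio},
                        index=pd.Index(percentiles, name="percentile"))
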