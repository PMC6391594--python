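"""Annual water balance and conversion of loads to concentrations.

Annual runoff follows the classic Budyko relation: with aridity index
``phi = PET / P`` the evaporative fraction is

    AET / P = sqrt( phi * tanh(1/phi) * (1 - exp(-phi)) )

and runoff is ``P - AET``.  The functional form sits behind this single
function boundary so alternative Budyko-family curves can be swapped in.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .network import StreamNetwork, accumulate_decayed
from .units import MM_KM2_Y_TO_M3_S, NG_S_PER_M3S_TO_UGL

__all__ = ["budyko_runoff", "accumulate_discharge", "concentration"]


def budyko_runoff(precip, pet):
    """Annual runoff (mm/y) from precipitation and potential ET (mm/y).

    Scalar or array-like inputs; negative inputs raise ``ValueError``.
    Runoff is bounded in ``[0, P]``; ``P = 0`` gives runoff 0, ``PET = 0``
    gives runoff ``P``.
    """
    scalar = np.isscalar(precip) and np.isscalar(pet)
    p = np.atleast_1d(np.asarray(precip, dtype=float))
    e = np.atleast_1d(np.asarray(pet, dtype=float))
    p, e = np.broadcast_arrays(p, e)
    if (p < 0).any() or (e < 0).any():
        raise ValueError("precipitation and PET must be >= 0")
    wet = p > 0
    phi = np.zeros_like(p)
    with np.errstate(over="ignore"):
        np.divide(e, p, out=phi, where=wet)
    inv_phi = np.full_like(phi, np.inf)
    with np.errstate(over="ignore"):
        np.divide(1.0, phi, out=inv_phi, where=phi > 0)
    with np.errstate(invalid="ignore"):
        aet_frac = np.sqrt(phi * np.tanh(inv_phi) * (-np.expm1(-phi)))
    # fully arid limit: AET consumes all precipitation
    aet_frac = np.where(np.isfinite(phi), aet_frac, 1.0)
    runoff = np.where(wet, p * (1.0 - aet_frac), 0.0)
    runoff = np.clip(runoff, 0.0, p)
    return float(runoff[0]) if scalar else runoff


def accumulate_discharge(network: StreamNetwork,
                         runoff_mm: pd.Series | None = None) -> pd.Series:
    """Annual-average discharge (m3/s) per reach.

    Local runoff volume is accumulated downstream without decay.  If
    ``runoff_mm`` (mm/y per reach) is given, the local volume is
    ``runoff x local area``; otherwise each reach's stored
    ``local_runoff`` (m3/s) is used.
    """
    if runoff_mm is None:
        local = network.local_runoff
    else:
        runoff = pd.Series(runoff_mm).reindex(network.reach_ids)
        if runoff.isna().any():
            raise ValueError("runoff_mm is not defined on every reach")
        local = runoff * network.local_areas * MM_KM2_Y_TO_M3_S
    return accumulate_decayed(network, local, math.inf).rename("q_m3s")


def concentration(load_ng_s: pd.Series, q_m3s: pd.Series) -> pd.Series:
    """Concentration (ug/L) = load / discharge.

    Reaches with zero discharge are flagged with NaN rather than given a
    value; negative discharge raises ``ValueError``.
    """
    load = pd.Series(load_ng_s, dtype=float)
    q = pd.Series(q_m3s, dtype=float).reindex(load.index)
    if (q < 0).any():
        offender = q.index[q < 0][0]
        raise ValueError(f"negative discharge on reach '{offender}'")
    out = pd.Series(np.nan, index=load.index, name="concentration_ug_L")
    positive = q > 0
    out[positive] = load[positive] / q[positive] * NG_S_PER_M3S_TO_UGL
    return out
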