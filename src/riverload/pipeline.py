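"""End-to-end pipeline: simulate, calibrate, predict, verify, report.

``run_pipeline`` executes every stage on a synthetic scenario and writes
all artifacts as CSV plus a JSON manifest (config echo, seed, package
version, output checksums).  Outputs are deterministic for a fixed seed:
rerunning with the same configuration reproduces byte-identical files.
Any stage failure aborts with a diagnostic naming the stage.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import (DEFAULT_PATTERNS, DT50_GRID, build_proxy_grid,
                          calibrate_substance)
from .inventory import build_inventory, diffuse_emission_field, sea_loads
from .network import StreamNetwork, accumulate_decayed
from .observations import compute_observed_loads
from .point_sources import district_point_share, impact_indicators, point_loads
from .synthetic import (SyntheticScenario, generate_exceedances,
                        generate_network, generate_observations,
                        generate_patterns, generate_point_sources,
                        generate_true_state)
from .verification import observed_concentration_roc, prediction_rate_curve

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG: dict = {
    "scenario": {},  # SyntheticScenario keyword overrides
    "calibration": {
        "n_boot": 1000,
        "loq_policy": "exclude",
        "include_uniform": True,
        "patterns": list(DEFAULT_PATTERNS),
        "dt50_grid": list(DT50_GRID),
        "overrides": {},  # substance -> ad-hoc DT50
    },
    "stages": {
        "indicators": True,
        "roc": True,
        "inventory": True,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@contextmanager
def _stage(name: str):
    logger.info("stage '%s' starting", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage '%s' done", name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, index=False, **kwargs)
    return path


def run_pipeline(config: dict | None, outdir, seed: int | None = None) -> dict:
    """Run every stage on a synthetic scenario; return the manifest."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    with _stage("simulate"):
        scenario = SyntheticScenario.from_dict(cfg["scenario"])
        if seed is not None:
            scenario = scenario.with_seed(seed)
        network = generate_patterns(generate_network(scenario), scenario)
        points = generate_point_sources(network, scenario)
        truth = generate_true_state(network, scenario, point_sources=points)
        observations = generate_observations(truth, scenario)
        exceedances = generate_exceedances(truth, scenario)
        network.to_csv(outdir / "network.csv")
        written.append(outdir / "network.csv")
        written.append(_write(observations, outdir / "observations.csv"))
        written.append(_write(points, outdir / "point_sources.csv"))
        truth_rows = []
        for sub in truth.substances:
            for rid in network.reach_ids:
                truth_rows.append({
                    "reach_id": rid,
                    "substance": sub.name,
                    "true_load_ng_s": float(truth.loads[sub.name][rid]),
                    "true_concentration_ug_L":
                        float(truth.concentrations[sub.name][rid]),
                    "q_m3s": float(truth.discharge[rid]),
                })
        written.append(_write(pd.DataFrame(truth_rows), outdir / "truth.csv"))
        written.append(_write(exceedances.frame, outdir / "exceedances.csv"))

    with _stage("proxy"):
        cal_cfg = cfg["calibration"]
        proxies = build_proxy_grid(network,
                                   patterns=cal_cfg["patterns"],
                                   dt50_grid=cal_cfg["dt50_grid"],
                                   include_uniform=cal_cfg["include_uniform"])
        flat = proxies.copy()
        flat.columns = [f"{p}__dt50_{g:g}" for p, g in proxies.columns]
        flat.insert(0, "reach_id", flat.index)
        written.append(_write(flat.reset_index(drop=True),
                              outdir / "proxies.csv"))

    with _stage("calibrate"):
        results = {}
        rows = []
        for sub in scenario.substances:
            records = observations[observations["substance"] == sub.name]
            loads, _summary = compute_observed_loads(
                records, loq_policy=cal_cfg["loq_policy"])
            override = cal_cfg["overrides"].get(sub.name)
            result = calibrate_substance(
                proxies, loads, substance=sub.name,
                assumed_pattern=sub.pattern,
                n_boot=cal_cfg["n_boot"], seed=scenario.seed,
                override_dt50=override)
            results[sub.name] = result
            boot = result.bootstrap
            rows.append({
                "substance": sub.name,
                "assumed_pattern": result.assumed_pattern,
                "best_pattern": result.best.pattern,
                "best_dt50": result.best.dt50,
                "modelled_dt50": result.modelled_dt50,
                "selected_dt50": result.selected_dt50,
                "emission_factor": result.emission_factor,
                "r_squared": result.r_squared,
                "r2_class": result.r2_class,
                "r2_drop": result.r2_drop,
                "intercept": result.grid.fit_for(
                    result.assumed_pattern, result.selected_dt50).intercept,
                "distance_to_ideal": result.grid.fit_for(
                    result.assumed_pattern,
                    result.selected_dt50).distance_to_ideal,
                "n_points": result.best.n_points,
                "slope_ci_low": boot.slope_interval[0] if boot else "",
                "slope_ci_high": boot.slope_interval[1] if boot else "",
                "intercept_ci_low": boot.intercept_interval[0] if boot else "",
                "intercept_ci_high": boot.intercept_interval[1] if boot else "",
            })
        written.append(_write(pd.DataFrame(rows), outdir / "calibration.csv"))

    with _stage("concentrations"):
        from .hydrology import accumulate_discharge, concentration
        q = accumulate_discharge(network)
        modelled_loads = {}
        modelled_diffuse = {}
        modelled_point = {}
        modelled_conc = {}
        conc_rows = []
        for sub in scenario.substances:
            result = results[sub.name]
            pattern_field = (network.local_areas
                             if result.assumed_pattern == "uniform"
                             else network.pattern(result.assumed_pattern))
            diffuse = result.emission_factor * accumulate_decayed(
                network, pattern_field, result.selected_dt50)
            sub_points = points[points["substance"] == sub.name]
            pl = (point_loads(network, sub_points, result.selected_dt50)
                  if len(sub_points)
                  else pd.Series(0.0, index=network.reach_ids))
            total = diffuse + pl
            modelled_loads[sub.name] = total
            modelled_diffuse[sub.name] = diffuse
            modelled_point[sub.name] = pl
            modelled_conc[sub.name] = concentration(total, q)
            for rid in network.reach_ids:
                conc_rows.append({
                    "reach_id": rid,
                    "substance": sub.name,
                    "load_ng_s": float(total[rid]),
                    "concentration_ug_L":
                        float(modelled_conc[sub.name][rid]),
                })
        written.append(_write(pd.DataFrame(conc_rows),
                              outdir / "concentrations.csv"))

    if cfg["stages"]["indicators"]:
        with _stage("indicators"):
            indicators = impact_indicators(modelled_diffuse, modelled_point)
            out = indicators.copy()
            out.insert(0, "reach_id", out.index)
            written.append(_write(out.reset_index(drop=True),
                                  outdir / "indicators.csv"))
            diffuse_emissions = {
                sub.name: diffuse_emission_field(
                    network, results[sub.name].assumed_pattern,
                    results[sub.name].emission_factor)
                for sub in scenario.substances}
            shares = district_point_share(points, diffuse_emissions,
                                          network.districts)
            written.append(_write(shares, outdir / "district_shares.csv"))

    if cfg["stages"]["roc"]:
        with _stage("roc"):
            curve_rows = []
            rate_rows = []
            for sub in scenario.substances:
                flags = exceedances.flags(sub.name, "aa")
                curve = prediction_rate_curve(modelled_conc[sub.name], flags)
                obs_sub = observations[observations["substance"] == sub.name]
                obs_curve = observed_concentration_roc(obs_sub, flags)
                row = {"substance": sub.name}
                for label, c in (("modelled", curve), ("observed", obs_curve)):
                    if c is None:
                        row[f"{label}_n_exceedances"] = 0
                        continue
                    row[f"{label}_rate_10"] = c.rates[0.1]
                    row[f"{label}_rate_20"] = c.rates[0.2]
                    row[f"{label}_rate_50"] = c.rates[0.5]
                    row[f"{label}_auc"] = c.auc
                    row[f"{label}_n_exceedances"] = c.n_exceedances
                rate_rows.append(row)
                if curve is not None:
                    for f, c in zip(curve.fractions, curve.cumulative):
                        curve_rows.append({"substance": sub.name,
                                           "fraction": f, "cumulative": c})
            written.append(_write(pd.DataFrame(curve_rows),
                                  outdir / "roc_curves.csv"))
            written.append(_write(pd.DataFrame(rate_rows),
                                  outdir / "roc_rates.csv"))

    if cfg["stages"]["inventory"]:
        with _stage("inventory"):
            factors = {sub.name: (results[sub.name].assumed_pattern,
                                  results[sub.name].emission_factor)
                       for sub in scenario.substances}
            inv = build_inventory(network, factors, point_emissions=points)
            written.append(_write(inv, outdir / "inventory.csv"))
            seas = sea_loads(network, modelled_loads)
            written.append(_write(seas, outdir / "sea_loads.csv"))

    with _stage("manifest"):
        manifest = {
            "package": "riverload",
            "version": __version__,
            "seed": scenario.seed,
            "config": _merge(cfg, {"scenario": scenario.to_dict()}),
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
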