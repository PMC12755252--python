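"""Config-driven experiment drivers with reproducible outputs.

An experiment is described by a plain dictionary (usually loaded from a
YAML file) and produces tidy CSV/JSON artifacts in an output directory,
together with a metadata file recording every resolved parameter —
including the toggle parameter-parsing decision — the seeds, and the
package version, so any cell can be reproduced exactly.

Config schema (keys with defaults may be omitted)::

    experiment: cv_sweep | hybrid_heatmap | attempt_analysis | simulate
                | steady_states | rm_report
    model:      {name: toggle|pfl|phage, <parameter overrides>}
    kernel:     {family: gamma|bernoulli|fixed, mean: float, cv: float}
    regions:    {radius_frac: 0.85, iband_frac: 0.5}
    sweep:      {cv_grid: [...], r_grid: [...]}           # sweeps only
    stop:       {min_residences: 100, max_events: 4e9}
    seeds:      [0, 1]
    t_max:      float                                      # simulate only
    out:        output directory
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kernels import make_kernel
from .models import (
    PFLParams,
    PhageParams,
    ToggleParams,
    find_steady_states,
    make_pfl,
    make_phage,
    make_toggle,
)
from .regions import make_regions
from .residence import cv_sweep, hybrid_cv_sweep, run_residence_cell
from .simulate import simulate_dssa

__all__ = ["build_network", "run_experiment"]

_PARAM_TYPES = {"toggle": ToggleParams, "pfl": PFLParams, "phage": PhageParams}
_BUILDERS = {"toggle": make_toggle, "pfl": make_pfl, "phage": make_phage}


def build_network(model_cfg: dict):
    """Construct a model network from a config block like
    ``{"name": "pfl", "alpha": 5.0}``."""
    cfg = dict(model_cfg)
    try:
        name = cfg.pop("name")
    except KeyError as exc:
        raise ValueError("model config needs a 'name' (toggle|pfl|phage)") from exc
    if name not in _BUILDERS:
        raise ValueError(f"unknown model {name!r}; expected toggle, pfl or phage")
    params = _PARAM_TYPES[name](**cfg)
    return _BUILDERS[name](params)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_experiment(config: dict, out: str | Path | None = None) -> dict:
    """Run one configured experiment; write artifacts; return the summary.

    Writes ``metadata.json`` (resolved parameters, seeds, version),
    ``summary.json`` and, where applicable, ``residences.csv`` /
    ``sweep.csv`` into the output directory.
    """
    kind = config.get("experiment")
    out = Path(out or config.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seeds = list(config.get("seeds", [0, 1]))
    stop = dict(config.get("stop", {}))
    min_res = int(stop.get("min_residences", 100))
    max_events = int(float(stop.get("max_events", 4e9)))
    reg_cfg = dict(config.get("regions", {}))

    meta = {
        "version": __version__,
        "experiment": kind,
        "config": config,
        "seeds": seeds,
    }
    summary: dict = {"experiment": kind}

    if kind == "steady_states":
        net = build_network(config["model"])
        stable, unstable = find_steady_states(net, return_unstable=True)
        summary["stable"] = [list(map(float, s)) for s in stable]
        summary["unstable"] = [list(map(float, s)) for s in unstable]
        meta["network"] = net.metadata
    elif kind == "simulate":
        net = build_network(config["model"])
        kcfg = config.get("kernel", {"family": "fixed", "mean": 3.0, "cv": 0.0})
        kernels = {
            ref: make_kernel(kcfg["family"], kcfg["mean"], kcfg.get("cv", 0.0))
            for ref in net.kernel_refs()
        }
        traj = simulate_dssa(
            net,
            kernels,
            t_max=float(config.get("t_max", 1000.0)),
            seed=seeds[0],
            max_events=max_events,
        )
        traj.to_csv(out / "trajectory.csv")
        summary.update(
            {"t_final": traj.t_final, "n_events": traj.n_events,
             "final_state": traj.final_state.tolist()}
        )
        meta["network"] = net.metadata
    elif kind == "cv_sweep":
        net = build_network(config["model"])
        regions = make_regions(net, **reg_cfg)
        kcfg = config["kernel"]
        sweep = config.get("sweep", {})
        df = cv_sweep(
            net,
            family=kcfg.get("family", "gamma"),
            mean=float(kcfg["mean"]),
            cv_grid=sweep.get("cv_grid", [0.0, 0.3, 1.0, 2.0]),
            min_residences=min_res,
            seeds=seeds,
            regions=regions,
            per_state=bool(config.get("per_state", net.metadata.get("model") == "pfl")),
            max_events=max_events,
        )
        df.to_csv(out / "sweep.csv", index=False)
        summary["table"] = df.to_dict(orient="records")
        meta["network"] = net.metadata
    elif kind in ("hybrid_heatmap", "attempt_analysis"):
        net = build_network(config["model"])
        regions = make_regions(net, **reg_cfg)
        kcfg = config.get("kernel", {"mean": 3.0})
        sweep = config.get("sweep", {})
        df = hybrid_cv_sweep(
            net,
            mu=float(kcfg["mean"]),
            r_grid=sweep.get("r_grid", [1.0, 16.0, 256.0]),
            cv_grid=sweep.get("cv_grid", [0.0, 0.3, 0.6]),
            min_residences=min_res,
            seeds=seeds,
            regions=regions,
            max_events=max_events,
            want_attempts=(kind == "attempt_analysis"),
        )
        df.to_csv(out / "sweep.csv", index=False)
        summary["table"] = df.to_dict(orient="records")
        meta["network"] = net.metadata
    elif kind == "rm_report":
        from . import reduced as rd

        rng = np.random.default_rng(seeds[0])
        rates = rd.sample_rm3_rates(rng)
        mu = 1.5 / rates.exit_rate_I("H")
        tau = mu
        sim = rd.rm_discrete_simulate(rates, tau, K=128, n=10**5, seed=seeds[0])
        summary.update(
            {
                "tau": tau,
                "fail_probability_closed": rd.rm_fail_probability(rates, tau),
                "fail_probability_sim": sim["fail_probability"],
                "expected_loop_time_closed": rd.rm_expected_loop_time(rates, tau),
                "expected_loop_time_sim": float(sim["loop_times"].mean()),
                "residence_estimate": rd.rm_residence_estimate(rates, tau),
                "assumptions": rd.check_rm_assumptions(rates, tau),
                "jensen_monotone": all(
                    rd.averaged_fail_ratio(rates, mu, s2)
                    < rd.averaged_fail_ratio(rates, mu, s1)
                    for s1, s2 in zip(
                        np.linspace(0, 0.9, 10) * mu, np.linspace(0.1, 1.0, 10) * mu * 0.99
                    )
                ),
                "rates": asdict(rates),
            }
        )
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")

    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary
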