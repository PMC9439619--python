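"""Replicate orchestration, scenario presets, and run artifacts.

A *scenario* is a named preset encoding one of the canonical experiment
parameterizations (the visibility sweep; the three rewiring experiments;
the four contagion simulations), optionally overridden by flat key-value
parameters. :func:`run_scenario` executes ``replicates`` independent runs
with child seeds derived deterministically from the master seed, writes
tidy CSV artifacts plus a JSON summary and a manifest sufficient to re-run
the experiment exactly, and returns the per-replicate summary table.

Seeding scheme: ``child_seed(master, index)`` feeds
``numpy.random.SeedSequence([master, index])`` and keeps the low 31 bits,
so replicate streams are independent, reproducible, and a manifest alone
re-creates every run. Floats are serialized at 9 significant digits for
byte-stable CSV bodies.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .conformity import ConformityConfig, run_learning
from .contagion import ContagionConfig, run_contagion
from .networks import ScoreFieldConfig, SmallWorldConfig
from .panic import PanicConfig, sweep_visibility

__all__ = [
    "PRESETS",
    "child_seed",
    "build_config",
    "run_scenario",
    "summarize",
]

FLOAT_FORMAT = "%.9g"
_pkg_version = "0.1.0"

#: Canonical experiment parameterizations, as flat key-value overrides.
PRESETS: dict[str, dict[str, dict]] = {
    "panic": {
        # equilibrium panic fraction vs visibility, v from 0.01 to 2 in steps of 0.01
        "fig2": {"v_grid": [round(0.01 * i, 2) for i in range(1, 201)]},
    },
    "conformity": {
        "exp1": {"rewiring_prob": 0.1},
        "exp2": {"rewiring_prob": 0.2},
        "exp3": {"rewiring_prob": 0.3},
    },
    "contagion": {
        "sim1": {},
        "sim2": {"assortative_prob": 0.2},
        "sim3": {"constant_recovery": True},
        "sim4": {"cumulative_influence": True},
    },
}

_NETWORK_KEYS = {"n_nodes", "degree", "rewiring_prob"}
_SCORE_KEYS = {"anti_fraction_target", "smoothness", "amplitude", "mean_level"}


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic 31-bit child seed for replicate ``index``."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _field_names(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def build_config(model: str, params: dict, seed: int = 0):
    """Build the model's config object from flat key-value parameters.

    For the conformity model, network keys (n_nodes, degree, rewiring_prob)
    and score-field keys (anti_fraction_target, smoothness, amplitude,
    mean_level) are routed into the nested configs. For the panic model a
    ``v_grid`` key, if present, is returned alongside the config.
    """
    params = dict(params)
    if model == "panic":
        v_grid = params.pop("v_grid", None)
        if "v" in params:
            params["visibility"] = params.pop("v")
        unknown = set(params) - _field_names(PanicConfig)
        if unknown:
            raise ValueError(f"unknown panic parameters: {sorted(unknown)}")
        return PanicConfig(seed=seed, **params), v_grid
    if model == "conformity":
        net = {k: params.pop(k) for k in list(params) if k in _NETWORK_KEYS}
        sf = {k: params.pop(k) for k in list(params) if k in _SCORE_KEYS}
        unknown = set(params) - (_field_names(ConformityConfig) - {"seed"})
        if unknown:
            raise ValueError(f"unknown conformity parameters: {sorted(unknown)}")
        net_cfg = SmallWorldConfig(
            n_nodes=int(net.get("n_nodes", 500)),
            degree=int(net.get("degree", 10)),
            rewiring_prob=float(net.get("rewiring_prob", 0.1)),
        )
        sf_cfg = ScoreFieldConfig(n_nodes=net_cfg.n_nodes, **sf)
        return ConformityConfig(
            network_config=net_cfg, score_field_config=sf_cfg, seed=seed, **params
        )
    if model == "contagion":
        if "m" in params:
            params["assortative_prob"] = params.pop("m")
        unknown = set(params) - _field_names(ContagionConfig)
        if unknown:
            raise ValueError(f"unknown contagion parameters: {sorted(unknown)}")
        return ContagionConfig(seed=seed, **params)
    raise ValueError(f"unknown model {model!r}; expected panic|conformity|contagion")


def _resolve_params(model: str, scenario: str | None, overrides: dict | None) -> dict:
    if model not in PRESETS:
        raise ValueError(f"unknown model {model!r}")
    params: dict = {}
    if scenario is not None:
        try:
            params.update(PRESETS[model][scenario])
        except KeyError:
            raise ValueError(
                f"unknown {model} preset {scenario!r}; "
                f"known: {sorted(PRESETS[model])}"
            ) from None
    if overrides:
        params.update(overrides)
    return params


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_scenario(
    model: str,
    scenario: str | None = None,
    overrides: dict | None = None,
    replicates: int = 1,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    quiet: bool = True,
) -> pd.DataFrame:
    """Run one scenario with seeded replicates; write artifacts if asked.

    Returns the tidy per-replicate summary table. With ``replicates=0`` the
    configuration is validated and the manifest written, but nothing is
    simulated (dry run). Identical inputs produce byte-identical CSV bodies.
    """
    if replicates < 0:
        raise ValueError("replicates must be >= 0")
    params = _resolve_params(model, scenario, overrides)
    seeds = [child_seed(master_seed, r) for r in range(replicates)]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # validate the configuration up front (also covers the dry run)
    probe = build_config(model, params, seed=child_seed(master_seed, 0))
    v_grid = probe[1] if model == "panic" else None

    table: pd.DataFrame
    extra_artifacts: dict[str, pd.DataFrame] = {}
    summary: dict = {
        "model": model,
        "scenario": scenario,
        "replicates": replicates,
    }

    if replicates == 0:
        table = pd.DataFrame()
    elif model == "panic":
        cfg, _ = probe
        grid = v_grid if v_grid is not None else [cfg.visibility]
        table = sweep_visibility(grid, replicates, cfg, master_seed=master_seed)
        table.insert(0, "scenario", scenario or "custom")
        means = (
            table.groupby("v")["equilibrium_fraction"].mean().rename("mean").to_frame()
        )
        summary["mean_equilibrium_by_v"] = {
            f"{v:g}": float(m) for v, m in means["mean"].items()
        }
        _log(quiet, f"panic: {len(grid)} visibility values x {replicates} replicates")
    elif model == "conformity":
        rows = []
        traj_rows = []
        agents_frames = []
        for r, seed in enumerate(seeds):
            cfg = build_config(model, params, seed=seed)
            res = run_learning(cfg)
            met = res.metrics()
            rows.append(
                {
                    "scenario": scenario or "custom",
                    "replicate": r,
                    "seed": seed,
                    "n_periods_run": res.n_periods_run,
                    "converged_early": res.converged_early,
                    **{k: v for k, v in met.items() if v is not None},
                }
            )
            for period_idx, frac in enumerate(res.pro_fraction_trajectory):
                traj_rows.append(
                    {
                        "replicate": r,
                        "period": period_idx * cfg.network_config.n_nodes,
                        "pro_fraction": float(frac),
                    }
                )
            agents_frames.append(
                pd.DataFrame(
                    {
                        "replicate": r,
                        "agent": np.arange(res.initial_scores.size),
                        "initial_score": res.initial_scores,
                        "final_score": res.final_scores,
                        "range_low": res.range_low,
                        "range_high": res.range_high,
                    }
                )
            )
            _log(quiet, f"conformity replicate {r}: anti_final={met['fraction_anti_final']:.3f}")
        table = pd.DataFrame(rows)
        extra_artifacts["trajectory.csv"] = pd.DataFrame(traj_rows)
        extra_artifacts["agents.csv"] = pd.concat(agents_frames, ignore_index=True)
        summary["mean_fraction_anti_final"] = float(table["fraction_anti_final"].mean())
        summary["mean_variance_ratio"] = float(table["variance_ratio"].mean())
    elif model == "contagion":
        rows = []
        traj_rows = []
        for r, seed in enumerate(seeds):
            cfg = build_config(model, params, seed=seed)
            rec = run_contagion(cfg)
            rows.append(
                {
                    "scenario": scenario or "custom",
                    "replicate": r,
                    "seed": seed,
                    "final_susceptible": int(rec.susceptible[-1]),
                    "final_infected": rec.final_infected,
                    "final_recovered": int(rec.recovered[-1]),
                    "peak_infected": rec.peak_infected,
                    "extinction_time": (
                        np.nan if rec.extinction_time is None else rec.extinction_time
                    ),
                    "all_susceptible_ever_infected": rec.all_susceptible_ever_infected,
                }
            )
            for t, s, i_, rr in zip(rec.time, rec.susceptible, rec.infected, rec.recovered):
                traj_rows.append(
                    {
                        "replicate": r,
                        "time": float(t),
                        "susceptible": int(s),
                        "infected": int(i_),
                        "recovered": int(rr),
                    }
                )
            _log(quiet, f"contagion replicate {r}: final_infected={rec.final_infected}")
        table = pd.DataFrame(rows)
        extra_artifacts["trajectory.csv"] = pd.DataFrame(traj_rows)
        summary["mean_final_infected"] = float(table["final_infected"].mean())
        summary["mean_peak_infected"] = float(table["peak_infected"].mean())
        ext = table["extinction_time"].dropna()
        summary["extinction_fraction"] = float(len(ext)) / replicates
        summary["mean_extinction_time"] = float(ext.mean()) if len(ext) else None

    if not table.empty:
        summary["per_replicate"] = json.loads(
            table.to_json(orient="records", double_precision=9)
        )

    if out is not None:
        outputs: dict[str, str] = {}
        if not table.empty:
            path = out / "summary.csv"
            table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            outputs["summary.csv"] = str(path)
        for name, frame in extra_artifacts.items():
            path = out / name
            frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            outputs[name] = str(path)
        _write_json(out / "summary.json", summary)
        outputs["summary.json"] = str(out / "summary.json")
        manifest = {
            "model": model,
            "scenario": scenario,
            "parameters": params,
            "resolved_config": _config_dict(probe[0] if model == "panic" else probe),
            "master_seed": int(master_seed),
            "child_seeds": seeds,
            "replicates": replicates,
            "seed_scheme": "SeedSequence([master_seed, replicate_index]) & 0x7fffffff",
            "version": _pkg_version,
            "outputs": sorted(outputs),
        }
        _write_json(out / "manifest.json", manifest)
    return table


def summarize(artifact_paths) -> pd.DataFrame:
    """Aggregate run directories (or summary.json paths) into one tidy table.

    Each input must contain the ``per_replicate`` records written by
    :func:`run_scenario`; rows carry model, scenario, replicate, and every
    outcome metric. Raises ``ValueError`` on an empty input list and
    ``FileNotFoundError``/``KeyError`` on missing or schema-mismatched files.
    """
    paths = list(artifact_paths)
    if not paths:
        raise ValueError("no artifacts to summarize")
    frames = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            p = p / "summary.json"
        if not p.exists():
            raise FileNotFoundError(f"missing artifact {p}")
        doc = json.loads(p.read_text())
        if "per_replicate" not in doc:
            raise KeyError(f"{p} lacks per-replicate records (dry run?)")
        frame = pd.DataFrame(doc["per_replicate"])
        frame.insert(0, "model", doc["model"])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
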