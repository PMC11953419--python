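"""Result persistence: tabular CSV data plus JSON metadata sidecars.

Writing the same result (same configuration and seed) twice produces
byte-identical data files.  Rate time series are downsampled on write
(default every 10 ms); analyses always use the full-resolution arrays in
memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .experiments import BiasResult, SimulationResult

__all__ = ["write_result", "write_table", "read_table", "result_metadata"]


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def result_metadata(result: SimulationResult) -> dict:
    proto = result.protocol
    meta = {
        "software": "pecircuit",
        "version": __version__,
        "seed": result.seed,
        "variant": result.variant,
        "lambda_low": result.lambda_low,
        "lambda_high": result.lambda_high,
        "dt_ms": result.dt_ms,
        "protocol": {
            "n_trials": proto.n_trials,
            "n_values": proto.n_values,
            "steps_per_value": proto.steps_per_value,
            "trial_mean": proto.trial_mean,
            "sigma2_in": proto.sigma2_in,
            "family": proto.family,
            "scalar_variability": proto.scalar_variability,
        },
        "perturbation": (None if result.pert is None else
                         {"targets": result.pert.targets,
                          "scope": result.pert.scope,
                          "onset_trial": result.pert.onset_trial}),
        "counters": result.counters,
    }
    meta["config_hash"] = _hash_dict({k: v for k, v in meta.items()
                                      if k != "counters"})
    return meta


def write_result(
    result: SimulationResult | BiasResult | pd.DataFrame,
    outdir: str | Path,
    name: str = "result",
    stride: int = 10,
) -> list[Path]:
    """Write a result to ``outdir`` with deterministic file naming.

    Simulation results become ``<name>_timeseries.csv`` plus
    ``<name>_meta.json``; bias results ``<name>_bias.csv`` (with slope and
    intercept in the sidecar); plain tables ``<name>.csv``.
    Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(result, SimulationResult):
        data = outdir / f"{name}_timeseries.csv"
        result.to_frame(stride=stride).to_csv(data, index=False,
                                              float_format="%.10g")
        meta = outdir / f"{name}_meta.json"
        meta.write_text(json.dumps(result_metadata(result), indent=2,
                                   default=str))
        written += [data, meta]
    elif isinstance(result, BiasResult):
        data = outdir / f"{name}_bias.csv"
        result.table.to_csv(data, index=False, float_format="%.10g")
        meta = outdir / f"{name}_meta.json"
        meta.write_text(json.dumps({
            "software": "pecircuit", "version": __version__,
            "slope": result.slope, "intercept": result.intercept,
            "magnitude": result.magnitude}, indent=2))
        written += [data, meta]
    elif isinstance(result, pd.DataFrame):
        data = outdir / f"{name}.csv"
        result.to_csv(data, index=False, float_format="%.10g")
        written.append(data)
    else:
        raise TypeError(f"cannot write object of type {type(result)!r}")
    return written


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)
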