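"""Readers, writers and run configuration.

All file formats are plain text: CSV time series with a ``time_h,value``
header and ``# key: value`` comment metadata, YAML model/prior
configuration, CSV chain files (one per chain, header = parameter names)
and JSON sidecars for likelihoods and run provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ParameterSet
from .simulate import ObservedSeries

__all__ = [
    "SCHEMA",
    "RunConfig",
    "read_series",
    "write_series",
    "read_config",
    "write_chain",
    "read_chain",
]

SCHEMA = "dlnafilter-series-v1"

_META_KEYS = ("seed", "snr", "sigma_eps", "kappa", "mean_level", "replicate")


@dataclass
class RunConfig:
    """Validated configuration shared by the CLI subcommands."""

    params: ParameterSet = field(default_factory=ParameterSet)
    dt: float = 0.1
    dt_coarse: float = 0.5
    dt_fine: float = 0.1
    exposure: float = 0.5
    seed: int = 0
    out: Path = Path(".")

    def __post_init__(self) -> None:
        for step, name in ((self.dt, "dt"), (self.dt_fine, "dt_fine"),
                           (self.dt_coarse, "dt_coarse")):
            for big, big_name in ((self.exposure, "exposure"),
                                  (self.params.tau_max, "tau_max")):
                r = big / step
                if abs(r - round(r)) > 1e-6:
                    raise ValueError(f"{name}={step} must divide {big_name}={big}")
        self.out = Path(self.out)


def read_config(path: str | Path) -> dict:
    """Flat key:value (YAML-compatible) model/prior configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} must be a mapping")
    return cfg


def write_series(series: ObservedSeries, path: str | Path) -> None:
    """CSV writer with commented provenance header."""
    path = Path(path)
    lines = [f"# schema: {SCHEMA}", f"# exposure: {series.exposure}"]
    for key in _META_KEYS:
        if key in series.meta:
            lines.append(f"# {key}: {series.meta[key]}")
    if "params" in series.meta:
        lines.append(f"# params: {json.dumps(series.meta['params'])}")
    if "truth" in series.meta:
        truth = ",".join(f"{v:.12g}" for v in series.meta["truth"])
        lines.append(f"# truth: {truth}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        fh.write("time_h,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.12g},{v:.12g}\n")


def read_series(path: str | Path) -> ObservedSeries:
    """Parse a ``time_h,value`` CSV; exposure is inferred from the spacing.

    Comment-header metadata (``# key: value``) is preserved in ``meta``.
    Ragged spacing or duplicated timestamps raise with the offending row.
    """
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = _parse_meta_value(key.strip(), val.strip())
    df = pd.read_csv(path, comment="#")
    if list(df.columns[:2]) != ["time_h", "value"]:
        raise ValueError(f"{path}: expected header time_h,value")
    times = df["time_h"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: non-numeric or non-finite entries")
    if times.size >= 2:
        gaps = np.diff(times)
        bad = np.where(~np.isclose(gaps, gaps[0], rtol=1e-6, atol=1e-9))[0]
        if gaps[0] <= 0:
            raise ValueError(f"{path}: non-increasing time at row 2")
        if bad.size:
            raise ValueError(
                f"{path}: ragged spacing at row {bad[0] + 3} "
                f"(gap {gaps[bad[0]]} vs {gaps[0]})"
            )
        exposure = float(gaps[0])
    else:
        exposure = float(meta.get("exposure", 0.5))
    if "exposure" in meta:
        exposure = float(meta["exposure"])
    return ObservedSeries(times=times, values=values, exposure=exposure, meta=meta)


def _parse_meta_value(key: str, val: str):
    if key == "truth":
        return np.array([float(x) for x in val.split(",")])
    if key == "params":
        return json.loads(val)
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    return val


def write_chain(chain, path: str | Path) -> None:
    df = chain.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# schema: dlnafilter-chain-v1\n")
        fh.write(f"# seed: {chain.seed}\n")
        fh.write(f"# dt_coarse: {chain.dt_coarse}\n")
        fh.write(f"# dt_fine: {chain.dt_fine}\n")
        fh.write(f"# accept_stage1: {chain.accept_stage1}\n")
        fh.write(f"# accept_overall: {chain.accept_overall}\n")
        df.to_csv(fh, index=False)


def read_chain(path: str | Path):
    from .inference import ChainResult

    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    names = [c for c in df.columns if c != "log_posterior"]
    return ChainResult(
        names=names,
        samples=df[names].to_numpy(),
        log_posterior=df["log_posterior"].to_numpy(),
        accept_stage1=float(meta.get("accept_stage1", np.nan)),
        accept_overall=float(meta.get("accept_overall", np.nan)),
        seed=int(meta.get("seed", -1)),
        dt_coarse=float(meta.get("dt_coarse", np.nan)),
        dt_fine=float(meta.get("dt_fine", np.nan)),
    )


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
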