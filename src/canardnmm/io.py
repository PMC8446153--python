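"""Configuration files, serialization and run manifests.

Configs are flat TOML: a ``[params]`` table overriding the bursting
reference set plus arbitrary per-command options.  All serialized times
are SI seconds; dimensionless-time internals never reach disk.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .params import ModelParams, params_from_dict, params_to_dict, table1

__all__ = [
    "RunConfig", "load_config", "dump_config", "write_outputs",
    "timeseries_frame", "timeseries_to_hdf5", "timeseries_from_hdf5",
]

_STATE_COLS = ["v0", "v1", "v2", "v3", "y5", "y6", "y7", "y8"]


@dataclass
class RunConfig:
    params: ModelParams = field(default_factory=table1)
    options: dict = field(default_factory=dict)
    source: str | None = None


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Read a TOML config; an empty or missing file yields the defaults.

    Parameter keys are validated against the model's field list and the
    physical invariants (positive time constants, scale ordering); the
    offending key is named in the error.
    """
    raw: dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())
    pdict = dict(raw.pop("params", {}))
    if overrides:
        pdict.update(overrides)
    try:
        params = params_from_dict({**params_to_dict(table1()), **pdict}) \
            if pdict else table1()
    except (KeyError, ValueError) as err:
        raise ValueError(f"invalid config {path}: {err}") from err
    return RunConfig(params, raw, str(path) if path else None)


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved config as flat TOML (lossless round-trip)."""
    lines = []
    for k, v in sorted(cfg.options.items()):
        lines.append(f"{k} = {_toml_scalar(v)}")
    lines.append("")
    lines.append("[params]")
    for k, v in params_to_dict(cfg.params).items():
        lines.append(f"{k} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_scalar(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(str(v))


def timeseries_frame(t, y) -> pd.DataFrame:
    """States as a table with SI time (columns: time_s, v0..y8)."""
    df = pd.DataFrame(np.asarray(y), columns=_STATE_COLS)
    df.insert(0, "time_s", np.asarray(t))
    return df


def timeseries_to_hdf5(path, t, y, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("time_s", data=np.asarray(t))
        h.create_dataset("states", data=np.asarray(y))
        h["states"].attrs["columns"] = ",".join(_STATE_COLS)
        for k, v in (attrs or {}).items():
            h.attrs[k] = v


def timeseries_from_hdf5(path):
    with h5py.File(path, "r") as h:
        return h["time_s"][...], h["states"][...]


def write_outputs(outdir, tables: dict | None = None,
                  objects: dict | None = None,
                  config: RunConfig | None = None,
                  seed: int | None = None) -> Path:
    """Write CSV tables and JSON objects plus a manifest.

    Deterministic stages reproduce byte-identical CSVs on re-run (fixed
    float format, no index); the manifest records a sha256 per file, the
    seed, and library versions.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in (tables or {}).items():
        fp = out / f"{name}.csv"
        df.to_csv(fp, index=False, float_format="%.12g")
        written[fp.name] = _sha256(fp)
    for name, obj in (objects or {}).items():
        fp = out / f"{name}.json"
        fp.write_text(json.dumps(obj, indent=1, default=_jsonable))
        written[fp.name] = _sha256(fp)
    if config is not None:
        fp = out / "config_resolved.toml"
        dump_config(config, fp)
        written[fp.name] = _sha256(fp)
    manifest = {
        "files": written,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1))
    return mp


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, complex):
        return {"re": o.real, "im": o.imag}
    return str(o)
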