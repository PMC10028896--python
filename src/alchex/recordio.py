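"""RunRecord persistence: JSON manifest + one .npy file per array.

A record directory is self-describing: ``manifest.json`` carries the run
metadata, schema version and the list of stored arrays; each array lives
in its own NumPy file.  Round trips are lossless (bitwise-equal arrays).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .sampling import RunRecord

RECORD_SCHEMA_VERSION = 1


def write_run_record(record: RunRecord, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {"u_kn": record.u_kn, "state_history": record.state_history,
              "dudl": record.dudl}
    for name, series in record.observables.items():
        arrays[f"obs__{name}"] = series
    if record.positions is not None:
        arrays["positions"] = record.positions
    for name, arr in arrays.items():
        np.save(path / f"{name}.npy", np.asarray(arr))
    manifest = {
        "schema_version": RECORD_SCHEMA_VERSION,
        "lambdas": list(record.lambdas),
        "temperature": record.temperature,
        "sampling_interval": record.sampling_interval,
        "seed": record.seed,
        "meta": record.meta,
        "error": record.error,
        "arrays": sorted(arrays),
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_run_record(path) -> RunRecord:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    version = manifest.get("schema_version")
    if version != RECORD_SCHEMA_VERSION:
        raise ValueError(
            f"record schema version {version} not supported (expected "
            f"{RECORD_SCHEMA_VERSION}); no silent migration")
    arrays = {}
    for name in manifest["arrays"]:
        f = path / f"{name}.npy"
        if not f.exists():
            raise ValueError(f"record is truncated: missing array {name!r}")
        arrays[name] = np.load(f)
    observables = {name[len("obs__"):]: arr for name, arr in arrays.items()
                   if name.startswith("obs__")}
    return RunRecord(
        lambdas=tuple(manifest["lambdas"]),
        temperature=manifest["temperature"],
        u_kn=arrays["u_kn"],
        state_history=arrays["state_history"],
        dudl=arrays["dudl"],
        observables=observables,
        positions=arrays.get("positions"),
        sampling_interval=manifest["sampling_interval"],
        seed=manifest["seed"],
        meta=manifest.get("meta", {}),
        error=manifest.get("error"))
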