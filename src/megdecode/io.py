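"""HDF5 dataset container and tabular result output.

Layout of the dataset container (one file per dataset)::

    /                       attrs: time_axis, sampling_step_ms, design (JSON)
    /subjects/<id>/regions/<label>/conditions/<label>/epochs
                            (n_vertices, n_times, n_trials) float array

Result tables are written as CSV with a stable column order plus a JSON run
manifest recording the configuration, seed and package version.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import (
    ConditionDesign,
    PipelineConfig,
    SchemaError,
    SourceDataset,
)

__all__ = ["load_dataset", "save_dataset", "save_results", "file_sha256"]


def save_dataset(dataset: SourceDataset, path: str | Path) -> Path:
    """Write a validated dataset to an HDF5 container."""
    dataset.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["time_axis"] = np.asarray(dataset.time_axis, dtype=float)
        f.attrs["sampling_step_ms"] = float(dataset.sampling_step_ms)
        f.attrs["design"] = json.dumps(dataset.design.to_dict())
        f.attrs["subject_order"] = json.dumps(dataset.subjects)
        f.attrs["region_order"] = json.dumps(dataset.regions)
        subs = f.create_group("subjects")
        for subj in dataset.subjects:
            sgrp = subs.create_group(subj)
            regs = sgrp.create_group("regions")
            for region in dataset.regions:
                rgrp = regs.create_group(region)
                conds = rgrp.create_group("conditions")
                for cond in dataset.design.labels:
                    key = (subj, region, cond)
                    if key not in dataset.epochs:
                        continue
                    cgrp = conds.create_group(cond)
                    cgrp.create_dataset("epochs", data=dataset.epochs[key])
    return path


def load_dataset(path: str | Path) -> SourceDataset:
    """Read and validate a dataset container; metadata round-trips exactly."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"container {path} does not exist")
    with h5py.File(path, "r") as f:
        for attr in ("time_axis", "sampling_step_ms", "design"):
            if attr not in f.attrs:
                raise SchemaError(f"container missing root attribute {attr!r}")
        time_axis = np.asarray(f.attrs["time_axis"], dtype=float)
        step = float(f.attrs["sampling_step_ms"])
        design = ConditionDesign.from_dict(json.loads(f.attrs["design"]))
        if "subjects" not in f:
            raise SchemaError("container missing group /subjects")
        epochs: dict[tuple[str, str, str], np.ndarray] = {}
        if "subject_order" in f.attrs:
            subjects = json.loads(f.attrs["subject_order"])
        else:
            subjects = sorted(f["subjects"], key=str)
        stored_regions = (json.loads(f.attrs["region_order"])
                          if "region_order" in f.attrs else None)
        regions: list[str] = []
        for subj in subjects:
            sgrp = f["subjects"][subj]
            if "regions" not in sgrp:
                raise SchemaError(
                    f"container missing group /subjects/{subj}/regions")
            for region in sorted(sgrp["regions"], key=str):
                if region not in regions:
                    regions.append(region)
                rgrp = sgrp["regions"][region]
                if "conditions" not in rgrp:
                    raise SchemaError(
                        f"missing /subjects/{subj}/regions/{region}/conditions")
                for cond in rgrp["conditions"]:
                    cgrp = rgrp["conditions"][cond]
                    if "epochs" not in cgrp:
                        raise SchemaError(
                            f"missing epochs dataset for ({subj}, {region}, "
                            f"{cond})")
                    epochs[(subj, region, cond)] = cgrp["epochs"][()]
    if stored_regions is not None and set(stored_regions) == set(regions):
        regions = stored_regions
    ds = SourceDataset(
        subjects=subjects, regions=regions, time_axis=time_axis,
        sampling_step_ms=step, design=design, epochs=epochs)
    ds.validate()
    return ds


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_results(tables: dict[str, pd.DataFrame], path: str | Path,
                 config: PipelineConfig | None = None,
                 extra_manifest: dict | None = None) -> list[Path]:
    """Write result tables as CSV plus a JSON run manifest.

    The manifest is byte-stable across reruns of the same configuration and
    seed except for its timestamp field.
    """
    from . import __version__

    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    hashes: dict[str, str] = {}
    for name, table in tables.items():
        target = out_dir / f"{name}.csv"
        table.to_csv(target, index=False)
        hashes[target.name] = file_sha256(target)
        written.append(target)
    manifest = {
        "version": __version__,
        "config": config.to_dict() if config is not None else None,
        "seed": config.rng_seed if config is not None else None,
        "outputs": hashes,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    written.append(manifest_path)
    return written
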