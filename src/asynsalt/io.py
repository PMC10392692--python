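"""Plate/trajectory file formats, plain-text configs and run manifests.

Everything is tab-delimited text: plates in wide format (``time_h`` column
plus one column per well), well metadata as a separate sheet, fit results
and profiles as TSV, MC configurations as ``key = value`` files and the
per-invocation manifest as JSON.  Times are hours, concentrations µM/mM as
on the experimental axes.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fitting import ThTTrace

__all__ = [
    "write_plate",
    "read_plate",
    "read_config",
    "write_config",
    "write_manifest",
    "write_trajectory",
]

_META_COLUMNS = ("well", "monomer_uM", "seed_uM", "salt_mM", "replicate")


def write_plate(
    plate: pd.DataFrame, meta: pd.DataFrame, plate_path, meta_path
) -> None:
    """Write a wide-format plate table and its metadata sheet as TSV."""
    if "time_h" not in plate.columns:
        raise ValueError("plate table must have a time_h column")
    missing = set(_META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata sheet lacks columns: {sorted(missing)}")
    plate.to_csv(plate_path, sep="\t", index=False)
    meta.to_csv(meta_path, sep="\t", index=False)


def read_plate(path, meta_path) -> list[ThTTrace]:
    """Read a plate + metadata pair into one trace per well.

    Wells without a metadata row are an error (named explicitly); duplicate
    well ids in the metadata are rejected.
    """
    plate = pd.read_csv(path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t")
    if "time_h" not in plate.columns:
        raise ValueError(f"{path}: first column must be time_h")
    if plate.isna().any().any():
        raise ValueError(f"{path}: ragged rows (missing values)")
    if meta["well"].duplicated().any():
        dups = sorted(meta.loc[meta["well"].duplicated(), "well"])
        raise ValueError(f"{meta_path}: duplicate well ids {dups}")
    meta_by_well = meta.set_index("well")
    wells = [c for c in plate.columns if c != "time_h"]
    orphans = sorted(set(wells) - set(meta_by_well.index))
    if orphans:
        raise ValueError(
            f"wells missing from metadata sheet: {', '.join(orphans)}"
        )
    t = plate["time_h"].to_numpy(dtype=float)
    traces = []
    for well in wells:
        row = meta_by_well.loc[well]
        traces.append(
            ThTTrace(
                t=t,
                F=plate[well].to_numpy(dtype=float),
                monomer_uM=float(row["monomer_uM"]),
                seed_uM=float(row["seed_uM"]),
                salt_mM=float(row["salt_mM"]),
                replicate_id=f"{well}/r{int(row['replicate'])}",
            )
        )
    return traces


def read_config(path) -> dict[str, str]:
    """Plain-text ``key = value`` config; values stay strings."""
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def write_config(cfg: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def write_manifest(
    out_dir,
    command: str,
    seeds: Sequence[int],
    inputs: Sequence = (),
    outputs: Sequence = (),
    extra: dict | None = None,
) -> Path:
    """One manifest per CLI invocation: command, seeds, input hashes, paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "rng_seeds": list(map(int, seeds)),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            str(p): _hash_file(Path(p)) for p in inputs if Path(p).is_file()
        },
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def write_trajectory(
    out_dir,
    tag: str,
    result,
) -> tuple[Path, Path]:
    """Write per-sample observables as TSV and the final frame as XYZ.

    The TSV has one row per sample: index, z_cm, dipole components, net
    charges and configurational energy.  The XYZ frame holds the final bead
    coordinates with one-letter residue names.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{tag}_samples.tsv"
    rows = ["sample\tz_cm\tmu_x\tmu_y\tmu_z\tq_free\tq_tail_mean\tenergy_kT"]
    for i in range(len(result.z_cm)):
        mu = result.dipole[i]
        rows.append(
            f"{i}\t{result.z_cm[i]:.4f}\t{mu[0]:.4f}\t{mu[1]:.4f}\t"
            f"{mu[2]:.4f}\t{result.q_free[i]:.3f}\t"
            f"{result.q_tail_mean[i]:.4f}\t{result.energy[i]:.6f}"
        )
    tsv.write_text("\n".join(rows) + "\n")

    xyz = out_dir / f"{tag}_final.xyz"
    sys_ = result.system
    lines = [str(sys_.n_beads), f"{tag} final frame (Angstrom)"]
    for res, p in zip(sys_.residues, sys_.pos):
        lines.append(f"{res} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}")
    xyz.write_text("\n".join(lines) + "\n")
    return tsv, xyz
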