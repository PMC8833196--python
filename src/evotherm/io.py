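"""TSV/JSON readers and writers for the package's desk-scale artifacts.

All tabular artifacts are tab-separated UTF-8 with a header line; floats
are written with 12 significant digits (%.12g), which round-trips
bit-exactly through the paired reader for 12-significant-digit decimals.
Structured results are JSON with sorted keys and a provenance block, so
identical config + seed yields identical output bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .gibbs import LossTable
from .landscape import GenotypeSpace, Landscape
from .origin_fixation import SimulationConfig, Trajectory

__all__ = [
    "fmt_float",
    "read_loss_table",
    "write_loss_table",
    "read_landscape",
    "write_landscape",
    "read_trajectory",
    "write_trajectory",
    "read_samples",
    "write_samples",
    "read_column_map",
    "write_column_map",
    "write_json_result",
]


def fmt_float(x: float) -> str:
    return format(float(x), ".12g")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str}, encoding="utf-8")


def write_loss_table(table: LossTable, path) -> None:
    lines = ["state\tloss"]
    lines += [f"{s}\t{fmt_float(table.loss[s])}" for s in table.states]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_loss_table(path, label: str = "") -> LossTable:
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["state", "loss"]:
        raise ValueError(f"expected columns state/loss in {path}")
    states = tuple(df["state"].astype(str))
    return LossTable(states, dict(zip(states, df["loss"].astype(float))), label)


def write_landscape(land: Landscape, path) -> None:
    """Landscape TSV `genotype<TAB>F` plus a JSON metadata sidecar
    (<path>.meta.json) holding {L, A, kind, seed, site_effects?,
    constant_sites}."""
    path = Path(path)
    lines = ["genotype\tF"]
    lines += [f"{g}\t{fmt_float(land.F[g])}" for g in land.genotypes]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    meta = {
        "L": land.space.L,
        "A": land.space.A,
        "kind": land.kind,
        "seed": land.seed,
        "constant_sites": sorted(land.space.constant_sites),
    }
    if land.site_effects is not None:
        meta["site_effects"] = [list(row) for row in land.site_effects]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n", "utf-8")


def read_landscape(path) -> Landscape:
    path = Path(path)
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["genotype", "F"]:
        raise ValueError(f"expected columns genotype/F in {path}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text("utf-8"))
    space = GenotypeSpace(
        L=meta["L"], A=meta["A"], constant_sites=frozenset(meta.get("constant_sites", ()))
    )
    F = dict(zip(df["genotype"].astype(str), df["F"].astype(float)))
    eff = meta.get("site_effects")
    return Landscape(
        space=space,
        F=F,
        kind=meta["kind"],
        seed=meta["seed"],
        site_effects=tuple(tuple(r) for r in eff) if eff is not None else None,
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory TSV `step<TAB>genotype` with the config echoed in a
    JSON sidecar (<path>.meta.json)."""
    path = Path(path)
    lines = ["step\tgenotype"]
    lines += [f"{t}\t{g}" for t, g in enumerate(traj.visits)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    cfg = traj.config
    meta = {
        "Ne": cfg.Ne,
        "beta": cfg.beta,
        "kernel": cfg.kernel,
        "steps": cfg.steps,
        "burn_in": cfg.burn_in,
        "seed": cfg.seed,
        "tau": cfg.tau,
        "nu": cfg.nu,
    }
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n", "utf-8")


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str}, encoding="utf-8")
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text("utf-8"))
    cfg = SimulationConfig(**meta)
    return Trajectory(config=cfg, visits=tuple(df["genotype"].astype(str)))


def write_samples(samples, path, column: str = "K") -> None:
    lines = [column] + [fmt_float(x) for x in samples]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_samples(path):
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    return df.iloc[:, 0].astype(float).to_numpy()


def write_column_map(mapping: Mapping[str, float], path, columns=("state", "value")) -> None:
    lines = ["\t".join(columns)]
    lines += [f"{k}\t{fmt_float(v)}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_column_map(path) -> dict[str, float]:
    df = _read_tsv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def write_json_result(payload: dict, path, command: str, seed, params: dict) -> None:
    """Write a JSON result with a provenance block (package version,
    command, seed, echoed params); sorted keys for byte determinism."""
    doc = dict(payload)
    doc["provenance"] = {
        "package": "evotherm",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": {k: params[k] for k in sorted(params)},
    }
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, indent=1, allow_nan=True) + "\n", "utf-8"
    )
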