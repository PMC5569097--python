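"""Run configuration, fixtures and result serialization.

A run is described by a small YAML/JSON config validated against a strict
schema (unknown keys rejected, ranges enforced).  Outputs are tidy CSV
tables plus a JSON manifest recording the resolved configuration, seeds,
package version and content hashes, sufficient to reproduce the run
bit-exactly.  ECM fields round-trip through a plain CSV matrix (or a
compressed ``.npz``) with the generator descriptor stored alongside as
JSON.  ``generate_fixture`` materialises the standard starting conditions
(tiny oracle lattices; homogeneous 0.5; heterogeneous theta=0.1/0.5) for
tests and demos without any external data.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .dynamics import ModelParams, initialize
from .environment import (
    ECMField,
    LatticeDims,
    make_heterogeneous_ecm,
    make_homogeneous_ecm,
)
from .experiments import (
    DEFAULT_GAMMA_GRID,
    DEFAULT_RATIO_GRID,
    EcmSpec,
    ScenarioSpec,
)

__all__ = [
    "RunConfig",
    "load_config",
    "scenario_from_config",
    "EXPERIMENT_PRESETS",
    "generate_fixture",
    "save_field",
    "load_field",
    "write_results",
]


class EcmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["homogeneous", "heterogeneous"] = "heterogeneous"
    level: float = Field(default=0.5, ge=0.0, le=1.0)
    theta: float = Field(default=0.5, ge=0.0, le=1.0)


class ModelConfig(BaseModel):
    """Rule-parameter overrides; defaults follow the standard parameter table."""

    model_config = ConfigDict(extra="forbid")
    alpha: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    beta: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    c_a: float = Field(default=1.0, ge=0.0, le=1.0)
    c_ratio: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    delta: float = Field(default=0.1, ge=0.0, le=1.0)
    kappa: Optional[float] = Field(default=None, ge=0.0)
    n_cells: int = Field(default=50, ge=1)
    mcs: int = Field(default=200, ge=0)
    s1: int = Field(default=100, ge=1)
    s2: int = Field(default=300, ge=2)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str = "fig5b"
    model: ModelConfig = ModelConfig()
    ecm: Optional[EcmConfig] = None
    replicates: Optional[int] = Field(default=None, ge=1)
    seed: int = 0
    output_dir: str = "results"
    log_level: Literal["DEBUG", "INFO", "WARNING"] = "INFO"

    @field_validator("scenario")
    @classmethod
    def _known_scenario(cls, v: str) -> str:
        if v not in EXPERIMENT_PRESETS:
            raise ValueError(
                f"unknown scenario {v!r}; available: {sorted(EXPERIMENT_PRESETS)}"
            )
        return v


# Named presets for the headline experiments.  Values are the scenario-level
# settings; the run seed and replicate count come from the RunConfig.
EXPERIMENT_PRESETS: dict[str, dict] = {
    "fig4a": {"ecm": EcmSpec("homogeneous", level=0.1), "c_ratio": 0.25, "kappa": 1.0},
    "fig4b": {"ecm": EcmSpec("homogeneous", level=0.9), "c_ratio": 0.25, "kappa": 1.0},
    "fig5a": {"ecm": EcmSpec("heterogeneous", theta=0.5), "c_ratio": 0.75, "kappa": 1.0},
    "fig5b": {"ecm": EcmSpec("heterogeneous", theta=0.5), "c_ratio": 0.25, "kappa": 1.0},
    "fig7": {"ecm": EcmSpec("heterogeneous", theta=0.5), "c_ratio": 0.25, "kappa": 1.0},
    "fig8": {"ecm": EcmSpec("heterogeneous", theta=0.5), "c_ratio": 0.25, "kappa": 1.0},
    "critical-scan": {"ecm": EcmSpec("homogeneous", level=0.5), "c_ratio": 0.25,
                      "kappa": 1.0},
    "kappa-scan": {"ecm": EcmSpec("heterogeneous", theta=0.5), "c_ratio": 0.25,
                   "kappa": 1.0},
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig.model_validate(data)


def scenario_from_config(config: RunConfig) -> ScenarioSpec:
    """Resolve a RunConfig into a concrete ScenarioSpec."""
    preset = dict(EXPERIMENT_PRESETS[config.scenario])
    m = config.model
    ecm = preset["ecm"]
    if config.ecm is not None:
        ecm = EcmSpec(config.ecm.kind, level=config.ecm.level, theta=config.ecm.theta)
    return ScenarioSpec(
        ecm=ecm,
        kappa=m.kappa if m.kappa is not None else preset["kappa"],
        c_ratio=m.c_ratio if m.c_ratio is not None else preset["c_ratio"],
        ratio_grid=DEFAULT_RATIO_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        n_cells=m.n_cells,
        mcs=m.mcs,
        replicates=config.replicates or 50,
        base_seed=config.seed,
        dims=LatticeDims(m.s1, m.s2),
        delta=m.delta,
        c_a=m.c_a,
    )


# ---------------------------------------------------------------- fields --

def save_field(field: ECMField, basepath: str | Path, fmt: str = "csv") -> list[Path]:
    """Write a field as ``<base>.csv`` (or ``.npz``) plus ``<base>.meta.json``."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        data_path = basepath.with_suffix(".csv")
        np.savetxt(data_path, field.values, delimiter=",", fmt="%.17g")
    elif fmt == "npz":
        data_path = basepath.with_suffix(".npz")
        np.savez_compressed(data_path, values=field.values)
    else:
        raise ValueError(f"unknown field format {fmt!r}")
    meta_path = basepath.with_suffix(".meta.json")
    meta = {
        "dims": {"s1": field.dims.s1, "s2": field.dims.s2},
        "descriptor": field.descriptor,
        "format": fmt,
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return [data_path, meta_path]


def load_field(basepath: str | Path) -> ECMField:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".meta.json").read_text())
    dims = LatticeDims(meta["dims"]["s1"], meta["dims"]["s2"])
    if meta["format"] == "csv":
        values = np.loadtxt(basepath.with_suffix(".csv"), delimiter=",", ndmin=2)
    else:
        values = np.load(basepath.with_suffix(".npz"))["values"]
    return ECMField(values, dims, meta["descriptor"])


# -------------------------------------------------------------- fixtures --

_FIXTURE_KINDS = ("tiny_lattice", "fig3c", "fig3d", "fig3e")


def generate_fixture(kind: str, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a standard starting condition on disk.

    ``tiny_lattice`` writes a 1×3 single-cell setup used by the exact
    Markov-chain oracle; the ``fig3*`` kinds write the three canonical
    50-cell initial conditions (homogeneous 0.5, heterogeneous theta=0.1,
    heterogeneous theta=0.5).  Returns the written paths.
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; one of {_FIXTURE_KINDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "tiny_lattice":
        dims = LatticeDims(1, 3)
        ecm = make_homogeneous_ecm(dims, 0.3)
        params = ModelParams(switching=False, gamma=0.0, n_cells=1, kappa=0.0,
                             dims=dims)
    else:
        dims = LatticeDims(100, 300)
        if kind == "fig3c":
            ecm = make_homogeneous_ecm(dims, 0.5)
        elif kind == "fig3d":
            ecm = make_heterogeneous_ecm(dims, 0.1, rng)
        else:
            ecm = make_heterogeneous_ecm(dims, 0.5, rng)
        params = ModelParams(alpha=1.0, beta=1.0, switching=True, n_cells=50,
                             dims=dims)
    state = initialize(params, ecm, rng)
    paths = dict(
        zip(("field", "field_meta"), save_field(state.ecm, out / f"{kind}_ecm"))
    )
    cells = pd.DataFrame(
        {
            "cell_id": range(state.n_cells),
            "phenotype": ["M" if p else "A" for p in state.phenotype_code],
            "r1": state.r1 + 1,
            "r2": state.r2 + 1,
        }
    )
    cells_path = out / f"{kind}_cells.csv"
    cells.to_csv(cells_path, index=False)
    paths["cells"] = cells_path
    return paths


# --------------------------------------------------------------- results --

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    frames: dict[str, pd.DataFrame],
    manifest: dict,
    output_dir: str | Path,
) -> dict[str, Path]:
    """Write tidy CSVs plus a manifest with content hashes.

    The manifest is written last so a present manifest implies complete
    outputs; rerunning with identical inputs reproduces identical hashes.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    hashes: dict[str, str] = {}
    for name, df in frames.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
        hashes[p.name] = _sha256(p)
    full_manifest = {
        **manifest,
        "software_version": __version__,
        "written_at": datetime.now(timezone.utc).isoformat(),
        "hashes": hashes,
    }
    mpath = out / "manifest.json"
    tmp = mpath.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(full_manifest, indent=2, sort_keys=True, default=str))
    tmp.replace(mpath)
    paths["manifest"] = mpath
    return paths
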