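"""Readers/writers for the pipeline's tab-separated tables and run config."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimulationConfig

__all__ = [
    "RunConfig",
    "load_expression",
    "write_expression",
    "load_phenotypes",
    "write_phenotypes",
    "load_run_config",
    "write_run_config",
]


@dataclass
class RunConfig:
    """End-to-end run settings: either real input paths or a simulation."""

    statin_path: str | None = None
    control_path: str | None = None
    phenotype_path: str | None = None
    simulation: SimulationConfig | None = None
    k_max: int = 25
    pc_threshold: float = 0.005
    n_top_genes: int = 100
    n_grid_start: int = 70
    n_grid_stop: int = 90
    B: int = 5000
    n_repeats: int = 5000
    seed: int = 0
    output_dir: str = "statinsig_out"
    train_on_discovery: bool = False
    recompute_pca_per_k: bool = False
    s0_method: str = "cv_min"

    def __post_init__(self) -> None:
        real = all(p is not None for p in
                   (self.statin_path, self.control_path, self.phenotype_path))
        if real == (self.simulation is not None):
            raise ValueError("exactly one of {input paths, simulation settings} "
                             "must be active")
        for name in ("k_max", "n_top_genes", "B", "n_repeats",
                     "n_grid_start", "n_grid_stop"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def load_expression(path) -> pd.DataFrame:
    """Genes x samples TSV: gene-id first column, sample-id header row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty data section")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        line = int(np.flatnonzero(df.index.duplicated())[0]) + 2
        raise ValueError(f"{path}: duplicated gene id {dup[0]!r} (line {line})")
    if df.columns.duplicated().any():
        bad = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample id {bad!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cells ({exc})") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite values")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def load_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = dataclasses.asdict(config.simulation)
    return d


def write_run_config(config: RunConfig, path) -> None:
    path = Path(path)
    text = yaml.safe_dump(_config_to_dict(config), sort_keys=True) \
        if path.suffix in (".yml", ".yaml") \
        else json.dumps(_config_to_dict(config), indent=2, sort_keys=True)
    path.write_text(text)


def load_run_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    sim = data.pop("simulation", None)
    config = RunConfig(**data, simulation=None if sim is None
                       else SimulationConfig(**sim))
    return config
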