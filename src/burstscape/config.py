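"""Flat key-value run configuration.

Every tunable of the pipeline lives under a dotted key (``grid.m_max``,
``cluster.n_runs`` ...).  Config files are flat YAML mappings; unknown keys
are rejected before any computation so typos cannot silently fall back to
defaults.  A single master seed drives every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict[str, object] = {
    "seed": 42,
    "grid.theta_on_min": 0.01,
    "grid.theta_on_max": 10.0,
    "grid.theta_on_n": 20,
    "grid.theta_off_min": 0.01,
    "grid.theta_off_max": 100.0,
    "grid.theta_off_n": 20,
    "grid.theta_t_min": 0.1,
    "grid.theta_t_max": 400.0,
    "grid.theta_t_n": 25,
    "grid.m_max": 200,
    "preprocess.m_max": 200,
    "preprocess.min_fraction_expressed": 0.0,
    "preprocess.min_cell_fraction_nonzero": 0.0,
    "preprocess.n_variable_genes": 0,  # 0 keeps every gene
    "cluster.k": 0,  # 0 selects K by the eigengap heuristic
    "cluster.k_max": 10,
    "cluster.n_runs": 50,
    "cluster.max_iter": 100,
    "cluster.greedy_restarts": 10,
    "cluster.kmedoids_restarts": 20,
    "lineage.s_grid_n": 21,
    "lineage.root": 0,  # 0 roots at the smallest mean capture time
    "lineage.max_edges": 0,  # 0 stops once the graph is connected
    "uncertainty.window_fraction": 0.10,
    "uncertainty.n_sd": 3.0,
    "uncertainty.frac_cells": 0.30,
    "landscape.grid_n": 30,
    "landscape.smoothness": 1.0,
    "embedding.method": "pca",
    "stats.n_bins": 20,
    "stats.max_lag_bins": 5,
    "stats.p_threshold": 0.01,
}


class RunConfig:
    """Validated flat configuration with defaults.

    >>> cfg = RunConfig({"cluster.k": 5, "seed": 7})
    >>> cfg["cluster.k"]
    5
    """

    def __init__(self, overrides: dict | None = None) -> None:
        values = dict(DEFAULTS)
        if overrides:
            unknown = set(overrides) - set(DEFAULTS)
            if unknown:
                raise KeyError(
                    f"unknown config keys: {sorted(unknown)}")
            values.update(overrides)
        self._values = values

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a flat key: value mapping")
        return cls(raw)

    def __getitem__(self, key: str):
        return self._values[key]

    def with_overrides(self, **pairs) -> "RunConfig":
        merged = dict(self._values)
        merged.update({k.replace("__", "."): v for k, v in pairs.items()})
        return RunConfig(merged)

    def replace(self, updates: dict) -> "RunConfig":
        merged = dict(self._values)
        merged.update(updates)
        return RunConfig(merged)

    def to_dict(self) -> dict:
        return dict(self._values)

    def sha256(self) -> str:
        payload = json.dumps(self._values, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def save(self, path: str | Path) -> None:
        lines = [f"{k}: {self._values[k]!r}" if isinstance(self._values[k], str)
                 else f"{k}: {self._values[k]}" for k in sorted(self._values)]
        Path(path).write_text("\n".join(lines) + "\n")
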