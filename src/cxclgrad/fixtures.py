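"""Deterministic desk-scale configurations and offline test fixtures.

The full-size study conditions (200-um grid, 24-h days at a 0.1-s
timestep) are expensive; the functions here define the scaled-down
counterparts used throughout the test-suite, the examples and the
acceptance runs, so the scaled study conditions are defined in exactly
one place:

* ``scaled_tumor_config`` -- a 100-um vascularized tumor section
  (1000 voxels, 1/8 the volume): cell counts volume-scaled from the
  200/200/200 baseline to 25 secreting + 25 tissue scavengers, with
  endothelial coverage held at 83% of the lining (100 of 120 voxels);
  0.5-s timestep; gradient shells at 10 um (near) and 40 um (far/radius).

* ``scaled_cluster_config`` -- the two-cluster experiment on the full
  200-um grid (clusters 100 um apart cannot be brought closer without
  touching) at a 0.5-s timestep, a 2-h cap and a steady-state excursion
  threshold of 2e-6 nM/um over 5 min: about 5% of the ~5e-5 nM/um
  gradients the default secretion rate produces, so the detector
  resolves the signal it gates rather than firing on the first window.

``generate_fixtures`` writes these configs plus a canonical cluster
placement table to disk, byte-identical for a fixed seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import SimConfig, save_config
from .geometry import (
    CellType,
    ClusterSpec,
    build_grid,
    placements_to_frame,
    seed_cluster,
)

__all__ = ["scaled_tumor_config", "scaled_cluster_config", "generate_fixtures"]


def scaled_tumor_config(**overrides) -> SimConfig:
    """Desk-scale vascularized tumor section (see module docstring)."""
    data = {
        "grid": {"side_length_um": 100.0},
        "vessel": {"enabled": True},
        "cells": {
            "n_secreting": 25,
            "n_tissue_cxcr7": 25,
            "n_endothelial_cxcr7": 100,  # 83% of the 120-voxel lining
        },
        "schedule": {
            "dt_s": 0.5,
            "record_interval_s": 60.0,
            "stage1_max_h": 2.0,
            "stage2_duration_h": 2.0,
        },
        "sampling": {
            "near_um": 10.0,
            "far_um": 40.0,
            "blood_tissue_radius_um": 40.0,
        },
    }
    _deep_update(data, overrides)
    return SimConfig(**data)


def scaled_cluster_config(**overrides) -> SimConfig:
    """Desk-scale two-cluster (source/sink) experiment."""
    data = {
        "grid": {"side_length_um": 200.0},
        "vessel": {"enabled": False},
        "schedule": {
            "dt_s": 0.5,
            "record_interval_s": 30.0,
            "setup1_max_h": 2.0,
            "steady_threshold_nM_per_um": 2e-6,
        },
    }
    _deep_update(data, overrides)
    return SimConfig(**data)


def _deep_update(base: dict, overrides: dict) -> None:
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write deterministic fixture files for fully offline testing.

    Emits the two desk-scale configs and a canonical placement table of
    a 100-cell secreting cluster and a 100-cell scavenger cluster
    100 um apart on the 200-um grid.  Identical bytes for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tumor = scaled_tumor_config(seed=seed)
    paths["tumor_config"] = out / "scaled_tumor.yaml"
    save_config(tumor, paths["tumor_config"])

    cluster = scaled_cluster_config(seed=seed)
    paths["cluster_config"] = out / "scaled_cluster.yaml"
    save_config(cluster, paths["cluster_config"])

    grid = build_grid(200.0, 10.0)
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(2))
    source = seed_cluster(
        grid, ClusterSpec((50.0, 100.0, 100.0), 60.0, 100), CellType.SECRETING, rng_a
    )
    sink = seed_cluster(
        grid, ClusterSpec((150.0, 100.0, 100.0), 60.0, 100), CellType.CXCR7_TISSUE, rng_b
    )
    paths["cluster_placements"] = out / "setup1_pair.csv"
    placements_to_frame(source + sink).to_csv(paths["cluster_placements"], index=False)
    return paths
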