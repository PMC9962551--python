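"""Flat key-value configuration with defaults for every tunable threshold.

Config files are flat YAML mappings; unknown keys are rejected to catch
typos. Every default is the value used in the reference analysis where one
was reported (0.53 nm substrate threshold, 0.3 nm cluster cutoff,
alpha = 0.05, 5000-frame series) or common geometric practice where the
upstream tooling did not expose one (H-bond 0.35 nm / 120 deg, hydrophobic
0.40 nm, BLOSUM62 with gap open 10 / extend 0.5).
"""

from __future__ import annotations

import yaml

DEFAULTS: dict = {
    # substrate classification
    "threshold_nm": 0.53,
    # conformational clustering
    "cluster_cutoff_nm": 0.3,
    "cluster_rmsd_selection": "resname=SAF",
    "cluster_fit_selection": "name=CA",
    "max_cluster_frames": 150,  # RMSD matrix is O(n^2); even stride above this
    # group statistics
    "alpha": 0.05,
    # interaction profile
    "hbond_d_max_nm": 0.35,
    "hbond_angle_min_deg": 120.0,
    "hydrophobic_d_max_nm": 0.40,
    # homolog mining
    "min_identity_pct": 50.0,
    "substitution_matrix": "BLOSUM62",
    "gap_open": 10.0,
    "gap_extend": 0.5,
    # geometry
    "pbc_mode": "none",
    # synthetic generator
    "ou_tau": 50.0,
    "n_frames": 5000,
    "seed": 0,
}

__all__ = ["DEFAULTS", "load_config", "merge_config"]


def merge_config(overrides: dict | None = None) -> dict:
    """Defaults overlaid with ``overrides``; unknown keys raise."""
    cfg = dict(DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
    return cfg


def load_config(path) -> dict:
    """Read a flat YAML mapping and merge it over the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return merge_config(data)
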