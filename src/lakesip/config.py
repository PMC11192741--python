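"""Run configuration: a single YAML document with all constants overridable.

``load_config`` merges a user file over :data:`DEFAULT_CONFIG`; the default
document alone specifies a complete synthetic end-to-end run whose
generating truths are the rates measured in the source lake study, so a
bare ``lakesip report`` exercises every pipeline stage.
"""
from __future__ import annotations

import copy
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "lakesip_out",
    "constants": {
        "diffusivity_cm2_s": 0.27,
        "natural_abundance_13c": 0.011,
        "natural_abundance_15n": 0.0036,
        "molar_mass_c": 12.011,
        "poisson_error_threshold": 0.05,
        "n_points": 5,
        "nitrate_per_methane": 1.6,  # 8 NO3- : 5 CH4
        "ch4_label_fraction": 0.98,
        "no3_label_fraction": 0.5,
    },
    "synthetic": {
        "times": [0, 1, 2, 5, 8, 12],
        "bottles": [
            {"name": "hypoxic_135m_mo", "observable": "co2_ratio",
             "true_rate": 1.17, "condition": "hypoxic", "depth_m": 135},
            {"name": "hypoxic_160m_mo", "observable": "co2_ratio",
             "true_rate": 1.20, "condition": "hypoxic", "depth_m": 160},
            {"name": "anoxic_135m_mo", "observable": "co2_ratio",
             "true_rate": 0.18, "condition": "anoxic", "depth_m": 135},
            {"name": "anoxic_135m_denit", "observable": "n30_headspace",
             "true_rate": 0.41, "label_fraction": 0.5,
             "condition": "anoxic", "depth_m": 135},
            {"name": "anoxic_160m_denit", "observable": "n30_headspace",
             "true_rate": 0.46, "label_fraction": 0.5,
             "condition": "anoxic", "depth_m": 160},
            {"name": "hypoxic_160m_assim", "observable": "biomass_atpct",
             "true_rate": 2.15, "condition": "hypoxic", "depth_m": 160},
        ],
    },
    "rates": {
        # printed (assimilation, oxidation) pairs per depth/condition
        "assimilation_pairs": [
            {"label": "hypoxic_135m", "assimilation": 1.29, "oxidation": 1.17},
            {"label": "hypoxic_160m", "assimilation": 2.15, "oxidation": 1.20},
            {"label": "anoxic_135m", "assimilation": 0.23, "oxidation": 0.18},
            {"label": "anoxic_160m", "assimilation": 0.09, "oxidation": 0.06},
        ],
        "stoichiometry": [
            {"label": "anoxic_135m", "mo": 0.18, "denitrification": 0.41},
            {"label": "anoxic_160m", "mo": 0.06, "denitrification": 0.46},
        ],
    },
    "profile": {
        # three-zone methane profile, steepest at depth (40 uM at 180 m)
        "knots": [[120, 0.05], [135, 0.6], [160, 10.0], [180, 41.0]],
        "breakpoints": [120, 135, 160, 180],
        "noise_sd": 0.0,
    },
    "cells": {
        "t_days": 1.0,
        "growth_model": "exponential",
        # effective label fraction for growth rates; null -> calibrate from
        # the (excess, growth_rate) pairs below if given, else 1.0
        "label_fraction_growth": None,
        "table": [
            {"morphotype": "filament", "volume_um3": 55.3,
             "excess_atfrac": 0.29, "condition": "hypoxic"},
            {"morphotype": "large_rod", "volume_um3": 7.4,
             "excess_atfrac": 0.24, "condition": "hypoxic"},
            {"morphotype": "coccus", "volume_um3": 3.2,
             "excess_atfrac": 0.23, "condition": "hypoxic"},
            {"morphotype": "small_rod", "volume_um3": 1.6,
             "excess_atfrac": 0.21, "condition": "hypoxic"},
            {"morphotype": "large_rod", "volume_um3": 7.4,
             "excess_atfrac": 0.21, "condition": "anoxic"},
        ],
        "growth_calibration_pairs": [
            [0.29, 0.49], [0.24, 0.39], [0.23, 0.38], [0.21, 0.34],
        ],
        "per_cell_from_bulk": [
            {"label": "anoxic_large_rod", "bulk_rate_uM_d": 0.18,
             "cell_density_per_ml": 2.0e4},
        ],
    },
    "counts": {
        "records": [
            {"morphotype": "large_rod", "cells_counted": 100,
             "fields_screened": 40, "filter_area_fraction": 2.5e-4,
             "volume_filtered_ml": 10.0, "depth_m": 160},
        ],
        "growth": [
            {"morphotype": "large_rod", "times_d": [0, 8],
             "densities_per_ml": [1.4e4, 3.7e4]},
        ],
    },
}


def merge_config(base: dict, override: Optional[dict]) -> dict:
    """Recursive dict merge; override values win, lists are replaced whole."""
    out = copy.deepcopy(base)
    if not override:
        return out
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> dict:
    """Load a YAML config over the defaults; ``None`` gives the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULT_CONFIG, user)
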