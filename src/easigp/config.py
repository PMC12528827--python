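"""Run configuration: defaults, YAML loading, deep-merge of overrides."""

from __future__ import annotations

import copy

import yaml

DEFAULTS = {
    "data": {
        "dataset": None,           # CSV path
        "map": None,               # genetic map TSV
        "annotations": None,       # optional annotation TSV
        "phenotype": None,         # phenotype column (default: last non-marker column)
    },
    "preprocess": {
        "max_missing_frac": 0.10,
        "ld": {"window": 30000, "step": 5, "r2_threshold": 0.8},
        "ld_per_scenario": True,
    },
    "scenarios": {
        "populations": None,       # default: all populations in the dataset
        "ratios": [0.8, 0.65, 0.5],
        "repeats": 500,
        "base_seed": 0,
    },
    "models": {
        "list": ["rrBLUP", "BayesB", "RKHS", "RF", "SVR", "GAT"],
        "use_replicate": True,
        "rrBLUP": {},
        "BayesB": {"n_iter": 12000, "burn_in": 2000},
        "RKHS": {"h": 1.0},
        "RF": {"n_trees": 1000},
        "SVR": {},
        "GAT": {"channels": 20, "epochs": 50, "batch": 8, "lr": 0.005,
                "weight_decay": 0.0},
    },
    "attribution": {
        "shapley_n_samples": 30,
        "shapley_max_test": 20,
        "max_background": 20,
        "ig_m": 64,
        "ig_baseline": "mean",
        "interaction_n_samples": 8,
        "interaction_screen_top": 15,
    },
    "circos": {
        "pad_cM": 0.2,
        "top_link_fraction": 0.0001,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=False)
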