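"""YAML run configuration.

Flat or nested keys are accepted; nested sections (``model:``, ``loss:``,
``roi:``, ``train:``) are flattened onto the estimator/CLI parameter names,
e.g. ``roi: {canny_threshold: 300}`` becomes ``canny_threshold``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["load_config", "flatten_config"]

_SECTION_ALIASES = {
    "roi.grid_points": "roi_grid_points",
    "roi.sigma": "roi_sigma",
    "roi.alpha": "roi_alpha",
    "roi.edge_filter": "edge_filter",
    "roi.canny_threshold": "canny_threshold",
    "loss.lambda1": "lambda1", "loss.lambda2": "lambda2",
    "loss.lambda3": "lambda3", "loss.lambda4": "lambda4",
    "loss.lambda5": "lambda5", "loss.lambda6": "lambda6",
    "loss.lambda7": "lambda7",
    "loss.style": "lambda_style", "loss.cycle": "lambda_cycle",
    "model.base_channels": "base_channels", "model.n_res": "n_res",
    "model.n_down": "n_down", "model.disc_channels": "disc_channels",
    "model.nce_dim": "nce_dim", "model.n_patches": "n_patches",
    "model.n_negatives": "n_negatives",
    "train.iterations": "iterations", "train.batch_size": "batch_size",
    "train.lr": "lr", "train.seed": "seed", "train.pool_size": "pool_size",
}


def flatten_config(cfg: dict) -> dict:
    flat = {}
    for key, val in cfg.items():
        if isinstance(val, dict):
            for k2, v2 in val.items():
                dotted = f"{key}.{k2}"
                flat[_SECTION_ALIASES.get(dotted, k2)] = v2
        else:
            flat[key] = val
    return flat


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return flatten_config(cfg)
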