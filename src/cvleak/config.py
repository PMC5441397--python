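"""Run configuration and metadata sidecars for the command-line experiments.

A run is configured by a declarative YAML file merged with command-line
flag overrides (flags win).  Unknown keys are rejected so typos fail loudly.
Every run writes a ``run_metadata.json`` capturing the resolved parameters
and seeds, which is enough to reproduce its artifacts byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ParameterError

EXPERIMENTS = ("toy", "bias-grid", "har-sweep", "fixture", "review")

ALLOWED_KEYS = {
    "toy": set(),
    "bias-grid": {"b_values", "c_values", "subject_counts", "n_repetitions",
                  "holdout_subjects", "n_trees"},
    "har-sweep": {"subject_counts", "fold_counts", "n_repetitions", "n_trees",
             "har_dir", "fixture_subjects", "fixture_records_per_class",
             "fixture_features", "class_separation", "subject_signature_strength"},
    "fixture": {"n_subjects", "n_records_per_subject_per_class", "n_features",
                "class_separation", "subject_signature_strength"},
    "review": {"table", "column_map"},
}


def load_config(path: str | Path | None, experiment: str,
                overrides: dict | None = None) -> dict:
    """Load a YAML config for ``experiment`` and apply flag overrides."""
    if experiment not in EXPERIMENTS:
        raise ParameterError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")
    config: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        config.update(loaded)
    config.update({k: v for k, v in (overrides or {}).items() if v is not None})
    unknown = set(config) - ALLOWED_KEYS[experiment]
    if unknown:
        raise ParameterError(
            f"unknown config keys for {experiment!r}: {sorted(unknown)}; "
            f"allowed: {sorted(ALLOWED_KEYS[experiment])}")
    return config


def write_metadata(out_dir: str | Path, experiment: str, resolved: dict) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_metadata.json"
    path.write_text(json.dumps({"experiment": experiment, **resolved},
                               indent=2, sort_keys=True, default=str) + "\n")
    return path
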