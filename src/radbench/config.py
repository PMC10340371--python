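"""Run configuration: nested defaults, YAML loading, seed fan-out.

A single global seed fans out to per-stage child seeds derived by hashing
the stage name, so any stage can be rerun in isolation and still reproduce
its output.  Unknown configuration keys are rejected; every run writes a
resolved-config snapshot next to its outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULTS: dict = {
    "outdir": "radbench_out",
    "seed": 0,
    "groups": None,           # None = every non-empty group
    "simulation": {
        "n_genes": 1000,
        "n_lines": 60,
        "n_patients_per_cohort": 150,
        "probes_per_gene": 5,
        "frac_prognostic": 0.15,
        "effect_sd": 0.2,
        "censoring_target": 0.5,
        "array_scale_sd": 0.25,
        "array_nonlinearity_amp": 0.3,
        "probe_affinity_sd": 0.5,
        "noise_sd": 0.1,
        "rt_specific_frac": 0.0,
        "n_factors": 3,
        "factor_var": 0.1,
        "sf2_factor_coef": 0.6,
        "hazard_factor_coef": 0.3,
        "biology_seed": None,  # None = derived from the global seed
        "cohort_spec": None,  # None = the bundled multi-cohort layout
    },
    "signatures": {
        "n_rank_linear_genes": 10,
        "n_pcr_genes": 31,
        "coef_sd": 0.2,
        "sf2_intercept": 0.0,
        "sf2_link": "logistic",
        "variance_threshold": 0.8,
        "max_components": 10,
        "rank_scope": "signature",
    },
    "resample": {
        "n_signatures": 100,
        "sizes": [10, 31, 100],
        "alpha": 0.05,
    },
    "normalization": {
        "n_agreement_arrays": 60,
        "trim_frac": 0.02,
        "target": 500.0,
        "invariant_frac": 0.9,
        "n_prune_iters": 3,
    },
    "covariate": {
        "enabled": True,
        "cohorts": None,      # None = first OS cohort in the spec
        "gene": None,         # None = first gene of the universe
        "name": "mgmt_like",
    },
    "enrichment": {
        "n_sets": 50,
        "min_size": 10,
        "max_size": 60,
        "min_overlap": 2,
        "weight_p": 1.0,
        "n_perm": 1000,
        "min_set": 5,
        "max_set": 500,
        "similarity_threshold": 0.7,
        "alpha": 0.05,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


class RunConfig:
    """Resolved run configuration (defaults overlaid with user values)."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge(DEFAULTS, overrides or {})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(loaded)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = RunConfig()
        cfg.data = copy.deepcopy(self.data)
        cfg.data["seed"] = int(seed)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def snapshot(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.data, "config_hash": self.hash()},
                      fh, indent=2, sort_keys=True)


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global one."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
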