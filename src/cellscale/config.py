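"""Run configuration: defaults, validation, and normalization.

The configuration is a flat, human-editable YAML mapping with at most one
level of nesting per pipeline stage.  :func:`validate_config` fills
defaults, type- and range-checks every key, rejects unknown keys, and
returns a normalized copy; all problems are reported at once.
"""

from __future__ import annotations

import copy
import math
from typing import Any, Dict, List, Optional

import yaml

from .datatypes import ValidationError

DEFAULTS: Dict[str, Any] = {
    "mode": "simulate",  # simulate | paths
    "seed": 0,
    "inputs": {
        "sample_table": None,
        "gene_matrix": None,
        "metabolite_matrix": None,
        "gene_sets": None,
        "network": None,
        "lipid_classes": None,
    },
    "simulate": {
        "n_replicates": 3,
        "group_radii": [1.0, 1.05, 1.3, 2.5],
        "radius_cv": 0.05,
        "n_genes_positive": 300,
        "n_genes_negative": 120,
        "n_genes_null": 580,
        "n_metabolites_positive": 90,
        "n_metabolites_negative": 36,
        "n_metabolites_null": 174,
        "slope_positive": 1.0,
        "slope_negative": -1.0,
        "noise_sd": 0.25,
        "n_genotype_shifted": 40,
        "genotype_log2fc": 2.5,
        "set_overlap_fraction": 0.0,
        "network_p_within": 0.3,
        "network_p_background": 0.02,
    },
    "correlation": {
        "ci_level": 0.90,
        "log2_transform": False,
        "pseudocount_gene": 1.0,
        "pseudocount_metabolite": 0.0,
        "bin_width": 0.1,
        "n_strata": 5,
    },
    "sets": {
        "background": "annotated_union",
        "bin_width": 0.1,
        "min_set_size": 2,
        "statistic_mode": "correlation",
        "exclude_set_from_background": False,
    },
    "lipids": {
        "min_class_size": 5,
    },
    "network": {
        "alpha": 0.05,
        "n_iterations": 1000,
        "universe": "network_nodes",  # network_nodes | measured_features
    },
    "overlap": {
        "timepoint": "pre",
        "fc_threshold": math.log2(1.5),
        "alpha": 0.05,
    },
}

_RANGE_CHECKS = {
    ("seed",): lambda v: isinstance(v, int) and 0 <= v < 2**31,
    ("mode",): lambda v: v in ("simulate", "paths"),
    ("simulate", "n_replicates"): lambda v: isinstance(v, int) and v >= 1,
    ("simulate", "group_radii"): lambda v: (
        isinstance(v, (list, tuple))
        and len(v) == 4
        and all(isinstance(x, (int, float)) and x > 0 for x in v)
    ),
    ("simulate", "radius_cv"): lambda v: isinstance(v, (int, float)) and v >= 0,
    ("simulate", "noise_sd"): lambda v: isinstance(v, (int, float)) and v >= 0,
    ("simulate", "set_overlap_fraction"): lambda v: isinstance(v, (int, float))
    and 0 <= v <= 1,
    ("simulate", "network_p_within"): lambda v: isinstance(v, (int, float))
    and 0 <= v <= 1,
    ("simulate", "network_p_background"): lambda v: isinstance(v, (int, float))
    and 0 <= v <= 1,
    ("correlation", "ci_level"): lambda v: isinstance(v, (int, float)) and 0 < v < 1,
    ("correlation", "bin_width"): lambda v: isinstance(v, (int, float)) and 0 < v <= 2,
    ("correlation", "n_strata"): lambda v: isinstance(v, int) and v >= 1,
    ("sets", "background"): lambda v: v in ("annotated_union", "all_features"),
    ("sets", "statistic_mode"): lambda v: v in ("correlation", "log2fc"),
    ("sets", "bin_width"): lambda v: isinstance(v, (int, float)) and v > 0,
    ("sets", "min_set_size"): lambda v: isinstance(v, int) and v >= 1,
    ("lipids", "min_class_size"): lambda v: isinstance(v, int) and v >= 1,
    ("network", "alpha"): lambda v: isinstance(v, (int, float)) and 0 < v <= 1,
    ("network", "n_iterations"): lambda v: isinstance(v, int) and v >= 1,
    ("network", "universe"): lambda v: v in ("network_nodes", "measured_features"),
    ("overlap", "timepoint"): lambda v: v in ("pre", "post", "both"),
    ("overlap", "alpha"): lambda v: isinstance(v, (int, float)) and 0 < v <= 1,
    ("overlap", "fc_threshold"): lambda v: isinstance(v, (int, float)) and v >= 0,
}

_COUNT_KEYS = [
    "n_genes_positive",
    "n_genes_negative",
    "n_genes_null",
    "n_metabolites_positive",
    "n_metabolites_negative",
    "n_metabolites_null",
    "n_genotype_shifted",
]
for _k in _COUNT_KEYS:
    _RANGE_CHECKS[("simulate", _k)] = lambda v: isinstance(v, int) and v >= 0

_REQUIRED_INPUTS = ("sample_table", "gene_matrix")


def validate_config(config: Optional[Dict[str, Any]] = None) -> Dict[str, Any]:
    """Merge a user configuration over the defaults and validate it.

    Raises a single :class:`ValidationError` listing every problem found:
    unknown keys, type/range violations, and (in ``paths`` mode) missing
    required input paths.
    """
    user = config or {}
    if not isinstance(user, dict):
        raise ValidationError("configuration must be a mapping")
    merged = copy.deepcopy(DEFAULTS)
    problems: List[str] = []
    for section, value in user.items():
        if section not in merged:
            problems.append(f"unknown key {section!r}")
            continue
        if isinstance(merged[section], dict):
            if not isinstance(value, dict):
                problems.append(f"{section!r} must be a mapping")
                continue
            for key, v in value.items():
                if key not in merged[section]:
                    problems.append(f"unknown key {section}.{key}")
                else:
                    merged[section][key] = v
        else:
            merged[section] = value

    for path, check in _RANGE_CHECKS.items():
        node: Any = merged
        for part in path:
            node = node[part]
        if not check(node):
            problems.append(f"{'.'.join(path)} = {node!r} fails its type/range check")

    if merged["mode"] == "paths":
        for key in _REQUIRED_INPUTS:
            if not merged["inputs"][key]:
                problems.append(f"mode 'paths' requires inputs.{key}")
    if problems:
        raise ValidationError(
            "invalid configuration:\n  - " + "\n  - ".join(problems)
        )
    merged["simulate"]["group_radii"] = [float(x) for x in merged["simulate"]["group_radii"]]
    return merged


def load_config(path) -> Dict[str, Any]:
    """Read a YAML config file and validate it."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return validate_config(data)


def dump_config(config: Dict[str, Any], path) -> None:
    """Echo a normalized configuration to a YAML file (stable key order)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True, default_flow_style=False)
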