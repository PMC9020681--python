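"""Shared fixtures: packaged base case plus degenerate configurations."""

import copy

import numpy as np
import pytest
import yaml

from nvaf_cea.parameters import (LifeTable, build_parameter_set,
                                 default_config_path, load_parameters)


@pytest.fixture(scope="session")
def params():
    """The packaged base case (calibrated synthetic life table)."""
    return load_parameters()


@pytest.fixture(scope="session")
def raw_config():
    with open(default_config_path()) as fh:
        return yaml.safe_load(fh)


@pytest.fixture()
def config(raw_config):
    """A mutable copy of the packaged configuration."""
    return copy.deepcopy(raw_config)


def zero_life_table(age_min=50, age_max=110):
    ages = np.arange(age_min, age_max + 1)
    return LifeTable(ages=ages, qx=np.zeros_like(ages, dtype=float))


def make_null_config(cfg):
    """No events, no mortality, utility 1: engine closed forms apply."""
    cfg = copy.deepcopy(cfg)
    cfg["model"]["discount_rate"] = 0.0
    cfg["clinical_rates"] = {k: 0.0 for k in ("is", "gi", "ich", "mi")}
    cfg["clinical_rates"]["minor_is_fraction"] = 0.41
    cfg.pop("cycle_probabilities")
    cfg["mortality"] = {
        "acute_case_fatality": {k: 0.0 for k in ("minor_is", "major_is", "mi", "ich", "gi")},
        "post_excess_per_cycle": {k: 0.0 for k in ("post_major_is", "post_mi", "post_ich")},
    }
    cfg["utilities"] = {k: 1.0 for k in cfg["utilities"]}
    return cfg


@pytest.fixture()
def null_params(raw_config):
    """Cohort that never dies and never has events, undiscounted."""
    return build_parameter_set(make_null_config(raw_config), zero_life_table())


@pytest.fixture()
def null_params_discounted(raw_config):
    cfg = make_null_config(raw_config)
    cfg["model"]["discount_rate"] = 0.03
    return build_parameter_set(cfg, zero_life_table())


def collapse_ranges(cfg):
    """Set every dsa range to [base, base] (tornado collapse property)."""
    cfg = copy.deepcopy(cfg)

    def walk(node, derived=None):
        if isinstance(node, dict):
            if "dsa" in node:
                if "value" in node:
                    node["dsa"] = [node["value"], node["value"]]
                else:
                    del node["dsa"]
                    node.pop("psa", None)
            for v in node.values():
                walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)

    walk(cfg)
    return cfg
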