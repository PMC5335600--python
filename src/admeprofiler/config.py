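"""Packaged configuration data: filter thresholds, radar ranges, egg geometry.

Thresholds of the rule-based filters are data, not code constants, so users
can adjust them (e.g. the radar lipophilicity ceiling, or the default
bioavailability-score class probability) without touching the library.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

_DATA = resources.files("admeprofiler") / "data"


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(str(_DATA / name))


@lru_cache(maxsize=None)
def load_defaults() -> dict:
    """The packaged default configuration (filters, radar, egg, score classes)."""
    return yaml.safe_load(data_path("config_defaults.yaml").read_text())


def filter_thresholds(name: str) -> dict:
    return dict(load_defaults()["filters"][name])


def radar_ranges() -> dict:
    return {k: tuple(v) for k, v in load_defaults()["radar"].items()}


def bioavailability_classes() -> dict:
    return dict(load_defaults()["bioavailability_score"])


def default_egg_geometry():
    from .solubility_pk import EggGeometry

    return EggGeometry.from_dict(load_defaults()["boiled_egg"])


def default_fragment_logp_table():
    from .lipophilicity import FragmentTable

    return FragmentTable.from_file(data_path("fragment_logp_synthetic.tsv"))


def default_fragment_logs_table():
    from .lipophilicity import FragmentTable

    return FragmentTable.from_file(data_path("fragment_logs_synthetic.tsv"))
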