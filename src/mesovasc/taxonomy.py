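"""Canonical feature vocabulary and multiscale taxonomy.

The morphometry pipeline emits 64 features per image: 16 per subgroup, over
the four subgroups (epidermal/SVP vs dermal layer) x (2D MIP vs 3D volume).
Each feature key has the form ``{name}__{layer}__{domain}``, e.g.
``n_j2j_branches__dermal__2d``.

Every feature is assigned one of three scales of architectural detail:

* microscale  (<100 um)      — single-vessel dimensions (diameter, length, ...)
* mesoscale   (~100–1000 um) — network organization (vessel/junction/branch counts)
* macroscale  (>1000 um)     — whole-region geometry (layer area/thickness, totals)

For the 32 published diabetes-relevant features the scale labels ship as a
versioned JSON resource and are returned verbatim; the remaining keys fall
back to the rule above.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

LAYERS = ("epi_svp", "dermal")
DOMAINS = ("2d", "3d")

MICRO, MESO, MACRO = "microscale", "mesoscale", "macroscale"

#: the 16 per-subgroup feature names, in canonical order.  The single-vessel
#: size slot is an area in 2D and a volume in 3D.
FEATURE_BASES_2D = (
    "n_vessels", "n_junctions", "n_j2j_branches", "n_j2e_branches",
    "n_endpoints", "avg_vessel_length", "avg_branch_length",
    "total_skeleton_length", "avg_vessel_area", "total_vessel_area",
    "avg_vessel_diameter", "vessel_density", "layer_area", "layer_thickness",
    "junction_density", "endpoint_density",
)
FEATURE_BASES_3D = tuple(
    "avg_vessel_volume" if b == "avg_vessel_area" else b for b in FEATURE_BASES_2D
)

_COUNT_BASES = {"n_vessels", "n_junctions", "n_j2j_branches", "n_j2e_branches",
                "n_endpoints"}
_MICRO_BASES = {"avg_vessel_length", "avg_branch_length", "avg_vessel_area",
                "avg_vessel_volume", "avg_vessel_diameter"}
_MACRO_BASES = {"total_skeleton_length", "total_vessel_area", "layer_area",
                "layer_thickness"}
_MESO_BASES = _COUNT_BASES | {"vessel_density", "junction_density",
                              "endpoint_density"}

_UNITS = {
    "n_vessels": "count", "n_junctions": "count", "n_j2j_branches": "count",
    "n_j2e_branches": "count", "n_endpoints": "count",
    "avg_vessel_length": "um", "avg_branch_length": "um",
    "total_skeleton_length": "um", "avg_vessel_area": "um^2",
    "avg_vessel_volume": "um^3", "avg_vessel_diameter": "um",
    "vessel_density": "fraction", "junction_density": "1/um^2-or-3",
    "endpoint_density": "1/um^2-or-3",
}
_UNITS_2D = {"total_vessel_area": "um^2", "layer_area": "um^2",
             "layer_thickness": "um"}
_UNITS_3D = {"total_vessel_area": "um^3", "layer_area": "um^3",
             "layer_thickness": "um"}


def feature_bases(domain: str) -> tuple[str, ...]:
    if domain == "2d":
        return FEATURE_BASES_2D
    if domain == "3d":
        return FEATURE_BASES_3D
    raise ValueError(f"unknown domain {domain!r}")


def make_key(base: str, layer: str, domain: str) -> str:
    return f"{base}__{layer}__{domain}"


def split_key(key: str) -> tuple[str, str, str]:
    base, layer, domain = key.rsplit("__", 2)
    if layer not in LAYERS or domain not in DOMAINS:
        raise KeyError(f"malformed feature key {key!r}")
    return base, layer, domain


@lru_cache(maxsize=1)
def all_feature_keys() -> tuple[str, ...]:
    """The canonical 64 keys: 2D subgroups first, then 3D, epi/SVP before dermal."""
    keys = []
    for domain in DOMAINS:
        for layer in LAYERS:
            keys.extend(make_key(b, layer, domain) for b in feature_bases(domain))
    return tuple(keys)


def feature_unit(key: str) -> str:
    base, _, domain = split_key(key)
    extra = _UNITS_2D if domain == "2d" else _UNITS_3D
    return _UNITS.get(base) or extra[base]


@lru_cache(maxsize=1)
def load_taxonomy() -> dict:
    """The shipped JSON resource with the 32 published features and stage trends."""
    with resources.files("mesovasc.data").joinpath("feature_taxonomy.json").open() as f:
        return json.load(f)


@lru_cache(maxsize=1)
def selected_feature_scales() -> dict[str, str]:
    """Hard-coded scale label per published feature key (rank order preserved)."""
    return {row["key"]: row["scale"] for row in load_taxonomy()["selected_features"]}


@lru_cache(maxsize=1)
def selected_feature_keys() -> tuple[str, ...]:
    return tuple(row["key"] for row in load_taxonomy()["selected_features"])


def stage_trend_directions() -> dict[str, str]:
    """Published monotone stage trends: feature key -> increase|decrease."""
    return {row["key"]: row["direction"] for row in load_taxonomy()["stage_trends"]}


def diabetes_change_directions() -> dict[str, str]:
    """Published healthy-vs-diabetes change direction per selected feature."""
    return {row["key"]: row["diabetes_change"]
            for row in load_taxonomy()["selected_features"]}


def _rule_scale(base: str) -> str:
    if base in _MICRO_BASES:
        return MICRO
    if base in _MESO_BASES:
        return MESO
    if base in _MACRO_BASES:
        return MACRO
    raise KeyError(f"unknown feature base {base!r}")


def assign_scales(keys) -> dict[str, str]:
    """Scale label per feature key.

    Published features get their tabulated label; the rest use the rule:
    counts/organization -> mesoscale, single-vessel dimensions -> microscale,
    whole-region quantities -> macroscale.
    """
    table = selected_feature_scales()
    out = {}
    for key in keys:
        base, _, _ = split_key(key)  # validates the key
        out[key] = table.get(key) or _rule_scale(base)
    return out
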