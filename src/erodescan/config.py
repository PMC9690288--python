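"""Declarative configuration: one YAML file captures every threshold.

Sections ``filter``, ``roh`` and ``age`` map 1:1 onto the parameter
dataclasses; unknown keys are rejected so typos fail loudly.  ``simulation``
describes a synthetic cohort.  CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .filtering import FilterParams
from .layout import GenomeLayout
from .roh import AgeModel, ROHParams
from .simulate import PopulationSim, SimConfig

__all__ = ["load_params", "sim_config_from_dict", "sim_config_from_yaml"]


def _build(cls, section: dict, overrides: dict):
    allowed = {f.name for f in fields(cls)}
    merged = dict(section)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(merged) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("bin_edges_mb", "bin_labels"):
        if key in merged and isinstance(merged[key], list):
            merged[key] = tuple(merged[key])
    return cls(**merged)


def load_params(path=None, filter_overrides: dict | None = None,
                roh_overrides: dict | None = None,
                age_overrides: dict | None = None):
    """Build (FilterParams, ROHParams, AgeModel) from an optional YAML file."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    return (
        _build(FilterParams, doc.get("filter", {}), filter_overrides or {}),
        _build(ROHParams, doc.get("roh", {}), roh_overrides or {}),
        _build(AgeModel, doc.get("age", {}), age_overrides or {}),
    )


def sim_config_from_dict(doc: dict, seed: int | None = None) -> SimConfig:
    layout_doc = doc["layout"]
    layout = GenomeLayout(
        scaffolds=tuple((str(n), int(l)) for n, l in layout_doc["scaffolds"]),
        masked={k: v for k, v in layout_doc.get("masked", {}).items()},
        min_scaffold_bp=int(layout_doc.get("min_scaffold_bp", 25_000)),
    )
    pops = [PopulationSim(
        name=p["name"], n=int(p["n"]),
        theta_bg=float(p.get("theta_bg", 0.25)),
        froh_targets=tuple(p.get("froh_targets", (0.0, 0.0, 0.0))),
        f_load=float(p.get("f_load", 0.0)),
        depth_mean=float(p.get("depth_mean", 25.0)),
        error_rate=float(p.get("error_rate", 0.001)),
    ) for p in doc["populations"]]
    age = _build(AgeModel, doc.get("age", {}), {})
    kwargs = dict(
        layout=layout, populations=pops, age_model=age,
        bin_ages=tuple(doc.get("bin_ages", (150.0, 25.0, 10.0))),
        snp_spacing_bp=float(doc.get("snp_spacing_bp", 1000.0)),
        deleterious={k: (int(m), float(p))
                     for k, (m, p) in doc.get("deleterious", {}).items()},
        n_structure_sites=int(doc.get("n_structure_sites", 0)),
        structure_fst=float(doc.get("structure_fst", 0.1)),
        seed=int(doc.get("seed", 0)),
    )
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)


def sim_config_from_yaml(path, seed: int | None = None) -> SimConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return sim_config_from_dict(doc.get("simulation", doc), seed=seed)
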