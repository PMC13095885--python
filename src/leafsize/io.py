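"""File formats: leaf-record CSV, profile CSV and parameter-set YAML/JSON.

The leaf-record CSV is the exchange format for observed (or simulated)
measurements — one row per plant x leaf position:

    plant_id,species,genotype,tln,position,blade_length_mm,blade_width_mm

Missing measurements are empty fields.  All dimensions are millimetres.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .params import (
    SpeciesId,
    SpeciesParameterSet,
    TlnLinearRule,
    TlnPlateauRule,
    TlnSegmentedRule,
    Trait,
    TraitParams,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_leaf_csv",
    "write_leaf_csv",
    "write_profile_csv",
    "read_parameter_sets",
    "write_parameter_sets",
    "load_default_parameters",
    "default_parameter_set",
]

logger = logging.getLogger("leafsize")

REQUIRED_COLUMNS = [
    "plant_id",
    "species",
    "genotype",
    "tln",
    "position",
    "blade_length_mm",
    "blade_width_mm",
]

_SPECIES_VOCAB = {s.value for s in SpeciesId}


def read_leaf_csv(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a leaf-record CSV.

    Rows violating the schema (unknown species, non-integer tln/position,
    position outside 1..tln, non-positive measurements) are rejected with
    line-numbered messages: in strict mode the first pass raises
    :class:`SchemaError` listing all offending lines, in lenient mode bad
    rows are dropped and logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"plant_id": str, "genotype": str, "species": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    # line number in the file: header is line 1, first data row line 2
    lines = df.index.to_numpy() + 2
    problems: list[str] = []
    bad = np.zeros(len(df), dtype=bool)

    def flag(mask, message):
        nonlocal bad
        mask = np.asarray(mask) & ~bad
        for ln in lines[mask]:
            problems.append(f"line {ln}: {message}")
        bad |= mask

    flag(~df["species"].isin(_SPECIES_VOCAB), "unknown species")
    for col in ("tln", "position"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        flag(numeric.isna() | (numeric != numeric.round()), f"{col} is not an integer")
    with np.errstate(invalid="ignore"):
        tln = pd.to_numeric(df["tln"], errors="coerce")
        pos = pd.to_numeric(df["position"], errors="coerce")
        flag((pos < 1) | (pos > tln), "position outside 1..tln")
        for col in ("blade_length_mm", "blade_width_mm"):
            vals = pd.to_numeric(df[col], errors="coerce")
            flag(df[col].notna() & ~(vals > 0), f"{col} is not positive")

    if problems:
        if strict:
            raise SchemaError(
                f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
            )
        for msg in problems:
            logger.warning("%s: skipped %s", path, msg)
        df = df.loc[~bad]

    df = df.astype({"tln": int, "position": int})
    return df.reset_index(drop=True)


def write_leaf_csv(records: pd.DataFrame, path) -> None:
    """Write leaf records in the canonical dialect (sorted, fixed format)."""
    out = records.loc[:, REQUIRED_COLUMNS].sort_values(
        ["species", "genotype", "plant_id", "position"], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format="%.4f")


def write_profile_csv(profile, path) -> None:
    """Write a predicted profile as CSV (4 significant digits)."""
    profile.to_frame().to_csv(path, index=False, float_format="%.4g")


# ---------------------------------------------------------------------------
# parameter-set serialization


def _rule_to_dict(tp: TraitParams) -> dict:
    se = tp.std_errors
    out = {}
    for name in ("L1", "cm", "rm", "tb", "dsl"):
        entry = {"value": getattr(tp, name)}
        if name in se:
            entry["se"] = se[name]
        out[name] = entry

    def coef(key, value):
        entry = {"value": value}
        if key in se:
            entry["se"] = se[key]
        return entry

    if isinstance(tp.xs_rule, TlnSegmentedRule):
        out["xs_rule"] = {
            "type": "segmented",
            "a": coef("xs.a", tp.xs_rule.intercept),
            "b": coef("xs.b", tp.xs_rule.slope_low),
            "c": coef("xs.c", tp.xs_rule.slope_high),
            "bp": coef("xs.bp", tp.xs_rule.breakpoint),
        }
    else:
        out["xs_rule"] = {
            "type": "linear",
            "a": coef("xs.a", tp.xs_rule.intercept),
            "b": coef("xs.b", tp.xs_rule.slope),
        }
    out["dr_rule"] = {
        "a": coef("dr.a", tp.dr_rule.intercept),
        "b": coef("dr.b", tp.dr_rule.slope),
        "xs": coef("dr.xs", tp.dr_rule.breakpoint),
    }
    return out


def _trait_from_dict(d: dict) -> TraitParams:
    se: dict[str, float] = {}

    def val(entry, key):
        if "se" in entry:
            se[key] = float(entry["se"])
        return float(entry["value"])

    fixed = {name: val(d[name], name) for name in ("L1", "cm", "rm", "tb", "dsl")}
    xs = d["xs_rule"]
    if xs.get("type") == "segmented":
        xs_rule = TlnSegmentedRule(
            intercept=val(xs["a"], "xs.a"),
            slope_low=val(xs["b"], "xs.b"),
            slope_high=val(xs["c"], "xs.c"),
            breakpoint=val(xs["bp"], "xs.bp"),
        )
    else:
        xs_rule = TlnLinearRule(intercept=val(xs["a"], "xs.a"), slope=val(xs["b"], "xs.b"))
    dr = d["dr_rule"]
    dr_rule = TlnPlateauRule(
        intercept=val(dr["a"], "dr.a"),
        slope=val(dr["b"], "dr.b"),
        breakpoint=val(dr["xs"], "dr.xs"),
    )
    return TraitParams(**fixed, xs_rule=xs_rule, dr_rule=dr_rule, std_errors=se)


def _sets_from_document(doc: dict) -> dict[SpeciesId, SpeciesParameterSet]:
    factors = doc.get("shape_factors", {})
    tln_range = tuple(doc.get("tln_range", (8, 45)))
    sets = {}
    for species_name, traits_doc in doc["species"].items():
        species = SpeciesId(species_name)
        traits = {
            Trait(trait_name): _trait_from_dict(trait_doc)
            for trait_name, trait_doc in traits_doc.items()
        }
        sets[species] = SpeciesParameterSet(
            species=species,
            traits=traits,
            shape_factor_standard=float(factors.get("standard", 0.71)),
            shape_factor_flag=float(factors.get("flag", 0.635)),
            tln_range=tln_range,
        ).validate()
    return sets


def read_parameter_sets(path) -> dict[SpeciesId, SpeciesParameterSet]:
    """Read parameter sets from a YAML or JSON document."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _sets_from_document(doc)


def write_parameter_sets(sets, path) -> None:
    """Write parameter sets (mapping or single set) as YAML or JSON."""
    if isinstance(sets, SpeciesParameterSet):
        sets = {sets.species: sets}
    first = next(iter(sets.values()))
    doc = {
        "shape_factors": {
            "standard": first.shape_factor_standard,
            "flag": first.shape_factor_flag,
        },
        "tln_range": list(first.tln_range),
        "species": {
            species.value: {
                trait.value: _rule_to_dict(tp) for trait, tp in pset.traits.items()
            }
            for species, pset in sets.items()
        },
    }
    path = Path(path)
    with path.open("w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_default_parameters() -> dict[SpeciesId, SpeciesParameterSet]:
    """Load the packaged generic parameter sets for all three species."""
    text = resources.files("leafsize").joinpath("data/default_parameters.yaml").read_text()
    return _sets_from_document(yaml.safe_load(text))


def default_parameter_set(species) -> SpeciesParameterSet:
    """The packaged generic parameter set for one species."""
    return load_default_parameters()[SpeciesId(species)]
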