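"""Table I/O, SBML Level 3 exchange, and run configuration.

Tables are UTF-8 TSV or CSV (delimiter sniffed); every reader validates
against a named schema and reports the file, row and column of the first
problem.  All concentrations are serialized in nM except where a column
header says µM (the PC table), preventing silent 1000x unit errors.

The SBML writer emits a Level 3 Version 1 core document with one species
per metabolite (PC as a constant boundary species), one reaction per
R1..R12 whose kinetic-law MathML matches the implemented forms, enzyme
activities as global parameters ``u_<id>``, and kinetic constants as
global parameters ``<rid>_<name>``.  The reader reconstructs an identical
model; float values survive the round trip exactly via shortest
round-trip decimal representations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from lxml import etree

from .model import (
    ENZYME_IDS,
    METABOLITE_IDS,
    STRAINS,
    EnzymeActivity,
    KineticModel,
    Metabolite,
    ModelConsistencyError,
    RateLaw,
    Reaction,
    StrainCondition,
    load_conditions,
)

__all__ = [
    "SchemaError",
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "conditions_from_table",
    "export_sbml",
    "import_sbml",
    "RunConfig",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SchemaError(ValueError):
    """A table failed schema validation; names file, row, and column."""


#: column kinds: float / int are parsed, numstr is validated-but-kept-verbatim
TABLE_SCHEMAS: dict[str, dict] = {
    "constants": {
        "columns": {"reaction": "str", "form": "str", "parameter": "str",
                    "value": "numstr", "unit": "str"},
        "key": ("reaction", "parameter"),
    },
    "conditions": {
        # numstr keeps the printed decimal strings verbatim for round trips
        "columns": {"symbol": "str", "AJ_control": "numstr", "AJ_DDC": "numstr",
                    "B6_control": "numstr", "B6_DDC": "numstr",
                    "PWD_control": "numstr", "PWD_DDC": "numstr"},
        "key": ("symbol",),
    },
    "measurements": {
        "columns": {"strain": "str", "treatment": "str", "metabolite": "str",
                    "median_nM": "float", "mad_nM": "float", "n_replicates": "int"},
        "key": ("strain", "treatment", "metabolite"),
    },
    "expression": {
        "columns": {"gene": "str", "strain": "str", "control_rpkm": "float",
                    "ddc_rpkm": "float", "padj": "float"},
        "key": ("gene", "strain"),
    },
    "protein": {
        "columns": {"analyte": "str", "strain": "str", "ratio": "float"},
        "key": ("analyte", "strain"),
    },
    "pc": {
        "columns": {"strain": "str", "treatment": "str", "pc_concentration": "float"},
        "key": ("strain", "treatment"),
        "aliases": {"pc_um": "pc_concentration"},
    },
    "bounds": {
        "columns": {"reaction": "str", "parameter": "str",
                    "lower": "float", "upper": "float"},
        "key": ("reaction", "parameter"),
    },
}


def _sniff_delimiter(sample: str) -> str:
    # TSV preferred; fall back to comma when the header has no tabs
    first = sample.splitlines()[0] if sample else ""
    return "\t" if "\t" in first else ","


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV/CSV table against a named schema."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    path = Path(path)
    spec = TABLE_SCHEMAS[schema]
    text = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(text)
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise SchemaError(f"{path}: file is empty")
    header = [spec.get("aliases", {}).get(h, h) for h in rows[0]]
    missing = set(spec["columns"]) - set(header)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, list] = {h: [] for h in header}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SchemaError(f"{path}, row {lineno}: expected {len(header)} fields, got {len(row)}")
        for col, raw in zip(header, row):
            kind = spec["columns"].get(col, "str")
            if kind in ("float", "int", "numstr"):
                try:
                    v = float(raw)
                except ValueError:
                    raise SchemaError(
                        f"{path}, row {lineno}, column {col!r}: unparsable number {raw!r}"
                    ) from None
                if kind == "float":
                    out[col].append(v)
                elif kind == "int":
                    out[col].append(int(v))
                else:
                    out[col].append(raw)
            else:
                out[col].append(raw)
    df = pd.DataFrame(out)
    key = list(spec["key"])
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate key {tuple(first[k] for k in key)} in columns {key}"
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV; verbatim for string columns, shortest
    round-trip decimal representation for floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def conditions_from_table(path: str | Path) -> dict[tuple[str, str], StrainCondition]:
    """Six strain x treatment conditions from an initial-values table file."""
    df = read_table(path, "conditions")
    rows = df.to_dict("records")
    return load_conditions([{k: str(v) for k, v in r.items()} for r in rows])


# ---------------------------------------------------------------------------
# SBML Level 3 export / import
# ---------------------------------------------------------------------------

def _num(x: float) -> str:
    return repr(float(x))


def _mathml(reaction: Reaction) -> etree._Element:
    """Kinetic-law MathML for one reaction's implemented rate form."""
    math = etree.Element(f"{{{MATHML_NS}}}math")
    rl = reaction.rate_law

    def ci(parent, name):
        el = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
        el.text = f" {name} "
        return el

    def apply(parent, op):
        ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
        etree.SubElement(ap, f"{{{MATHML_NS}}}{op}")
        return ap

    if rl.form == "first_order_decay":
        times = apply(math, "times")
        ci(times, f"{reaction.id}_k_cat")
        ci(times, rl.substrate)
        return math
    if rl.form == "activated_linear":
        times = apply(math, "times")
        ci(times, f"{reaction.id}_v_max")
        for a in rl.activators:
            ci(times, f"u_{a}")
        ci(times, rl.substrate)
        return math
    # activated_inhibited_mm: v_max * prod(u) * S / ((k_m + S) * (k_i + I))
    divide = apply(math, "divide")
    num = apply(divide, "times")
    ci(num, f"{reaction.id}_v_max")
    for a in rl.activators:
        ci(num, f"u_{a}")
    ci(num, rl.substrate)
    den = apply(divide, "times")
    km_plus = apply(den, "plus")
    ci(km_plus, f"{reaction.id}_k_m")
    ci(km_plus, rl.substrate)
    ki_plus = apply(den, "plus")
    ci(ki_plus, f"{reaction.id}_k_i")
    if rl.inhibitor is not None:
        ci(ki_plus, rl.inhibitor)
    return math


def export_sbml(
    model: KineticModel,
    path: str | Path,
    condition: StrainCondition | None = None,
    model_id: str = "aa_eicosanoid_metabolism",
) -> None:
    """Write the model (optionally under one condition) as SBML L3V1."""
    acts = model.activity_map()
    pc_nM = model.pc_nM
    if condition is not None:
        acts.update(condition.activity_ratios)
        pc_nM = condition.pc_nM

    E = lambda parent, tag, **attrs: etree.SubElement(parent, f"{{{SBML_NS}}}{tag}", **attrs)  # noqa: E731
    root = etree.Element(f"{{{SBML_NS}}}sbml", level="3", version="1")
    mdl = E(root, "model", id=model_id)
    comps = E(mdl, "listOfCompartments")
    E(comps, "compartment", id="liver", spatialDimensions="3", size="1", constant="true")
    species = E(mdl, "listOfSpecies")
    for met in model.metabolites:
        conc = pc_nM if met.fixed else met.concentration
        E(
            species, "species",
            id=_species_id(met.id), name=met.name or met.id, compartment="liver",
            initialConcentration=_num(conc),
            hasOnlySubstanceUnits="false",
            boundaryCondition="true" if met.fixed else "false",
            constant="true" if met.fixed else "false",
        )
    params = E(mdl, "listOfParameters")
    for aid in sorted(acts):
        E(params, "parameter", id=f"u_{aid}", value=_num(acts[aid]), constant="true")
    for rxn in model.reactions:
        rl = rxn.rate_law
        for name in ("v_max", "k_m", "k_i", "k_cat"):
            v = getattr(rl, name)
            if v is not None:
                E(params, "parameter", id=f"{rxn.id}_{name}", value=_num(v), constant="true")
    rxns = E(mdl, "listOfReactions")
    for rxn in model.reactions:
        rel = E(rxns, "reaction", id=rxn.id, reversible="false")
        reactants = E(rel, "listOfReactants")
        E(reactants, "speciesReference", species=_species_id(rxn.substrate),
          stoichiometry="1", constant="true")
        if rxn.product is not None:
            products = E(rel, "listOfProducts")
            E(products, "speciesReference", species=_species_id(rxn.product),
              stoichiometry="1", constant="true")
        if rxn.rate_law.inhibitor is not None:
            mods = E(rel, "listOfModifiers")
            E(mods, "modifierSpeciesReference", species=_species_id(rxn.rate_law.inhibitor))
        kl = E(rel, "kineticLaw")
        kl.append(_mathml_with_species_ids(rxn))
    tree = etree.ElementTree(root)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _species_id(met_id: str) -> str:
    # SBML SIds cannot contain '-'
    return "M_" + met_id.replace("-", "_")


def _met_id(species_id: str) -> str:
    body = species_id[2:] if species_id.startswith("M_") else species_id
    for mid in METABOLITE_IDS:
        if mid.replace("-", "_") == body:
            return mid
    raise ModelConsistencyError(f"unknown species id {species_id!r} in SBML document")


def _mathml_with_species_ids(rxn: Reaction) -> etree._Element:
    math = _mathml(rxn)
    for ci in math.iter(f"{{{MATHML_NS}}}ci"):
        name = ci.text.strip()
        if name in METABOLITE_IDS:
            ci.text = f" {_species_id(name)} "
    return math


def import_sbml(path: str | Path) -> tuple[KineticModel, dict[str, float]]:
    """Read an SBML document written by :func:`export_sbml`.

    Returns the reconstructed model and the activity-ratio map embedded in
    its ``u_*`` parameters.
    """
    tree = etree.parse(str(path))
    ns = {"s": SBML_NS, "m": MATHML_NS}
    mdl = tree.getroot().find("s:model", ns)
    if mdl is None:
        raise ModelConsistencyError(f"{path}: no <model> element")
    metabolites = []
    for sp in mdl.findall("s:listOfSpecies/s:species", ns):
        metabolites.append(
            Metabolite(
                id=_met_id(sp.get("id")),
                name=sp.get("name", ""),
                concentration=float(sp.get("initialConcentration", "0")),
                fixed=sp.get("boundaryCondition") == "true",
            )
        )
    order = {mid: k for k, mid in enumerate(METABOLITE_IDS)}
    metabolites.sort(key=lambda m: order[m.id])
    params: dict[str, float] = {}
    for p in mdl.findall("s:listOfParameters/s:parameter", ns):
        params[p.get("id")] = float(p.get("value"))
    activities = tuple(
        EnzymeActivity(aid, params[f"u_{aid}"]) for aid in ENZYME_IDS if f"u_{aid}" in params
    )
    reactions = []
    for rel in mdl.findall("s:listOfReactions/s:reaction", ns):
        rid = rel.get("id")
        sub = _met_id(rel.find("s:listOfReactants/s:speciesReference", ns).get("species"))
        prod_el = rel.find("s:listOfProducts/s:speciesReference", ns)
        prod = _met_id(prod_el.get("species")) if prod_el is not None else None
        cis = [
            ci.text.strip()
            for ci in rel.findall("s:kineticLaw/m:math//m:ci", ns)
        ]
        acts = tuple(c[2:] for c in cis if c.startswith("u_"))
        mod = rel.find("s:listOfModifiers/s:modifierSpeciesReference", ns)
        inhibitor = _met_id(mod.get("species")) if mod is not None else None
        p = {name: params.get(f"{rid}_{name}") for name in ("v_max", "k_m", "k_i", "k_cat")}
        if p["k_cat"] is not None:
            form = "first_order_decay"
        elif p["k_m"] is not None:
            form = "activated_inhibited_mm"
        else:
            form = "activated_linear"
        reactions.append(
            Reaction(rid, sub, prod, RateLaw(
                form=form, substrate=sub, v_max=p["v_max"], k_m=p["k_m"],
                k_i=p["k_i"], k_cat=p["k_cat"], activators=acts, inhibitor=inhibitor,
            ))
        )
    reactions.sort(key=lambda r: int(r.id[1:]))
    model = KineticModel(tuple(metabolites), tuple(reactions), activities)
    ratios = {a.id: a.ratio_u for a in activities}
    return model, ratios


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated settings mirroring the CLI flags (CLI takes precedence)."""

    constants: str | None = None
    measurements: str | None = None
    expression: str | None = None
    protein: str | None = None
    pc: str | None = None
    strain: str = "B6"
    treatment: str = "DDC"
    steady_state_tol: float = 1e-6
    population: int = 50
    generations: int = 500
    seed: int = 0
    bounds: str | None = None
    threshold: float = 1.5
    out: str = "."
    verbose: int = 0

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"strain must be one of {STRAINS}, got {self.strain!r}")
        if self.treatment not in ("control", "DDC"):
            raise ValueError(f"treatment must be control or DDC, got {self.treatment!r}")
        if not self.steady_state_tol > 0:
            raise ValueError("steady_state_tol must be > 0")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not self.threshold > 1:
            raise ValueError("threshold must be > 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load from a YAML or JSON key-value file; unknown keys rejected.

        Keyword overrides (e.g. parsed CLI flags) take precedence over the
        file contents.
        """
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
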