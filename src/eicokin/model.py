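"""Domain types and rate kinetics of the arachidonic-acid/eicosanoid network.

The network has eight metabolites (phosphatidylcholine, PC, held fixed;
arachidonic acid, AA; 5-HPETE; LTA4; 15-HPETE; 15-HETE; PGH2; PGD2), twelve
reactions R1..R12 arranged in three branches (leukotriene, 15-LOX,
prostaglandin), and ten enzyme/regulator activities that enter the rate laws
as dimensionless DDC-vs-control fold changes multiplying the corresponding
V_max term.

Rate-law forms
--------------
``activated_inhibited_mm``
    v = V_max * (prod of activator ratios) * [S] / ((K_m + [S]) * (K_i + [I]))
    Michaelis-Menten kinetics with linear activator scaling and
    non-competitive product inhibition.
``first_order_decay``
    v = k_cat * [S]  (degradation sinks; mass leaves the open system)
``activated_linear``
    v = V_max * (activator ratio) * [S]
    First-order conversion scaled by the activator; V_max acts as an
    effective rate constant in 1/s.

All concentrations are handled internally in nM.  Quantities tabulated in
µM (the PC concentration and R1's Michaelis constant for PC) are converted
on ingestion (×1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "EnzymeActivity",
    "RateLaw",
    "Reaction",
    "KineticModel",
    "StrainCondition",
    "ModelConsistencyError",
    "METABOLITE_IDS",
    "STATE_IDS",
    "ENZYME_IDS",
    "STRAINS",
    "TREATMENTS",
    "build_paper_model",
    "load_constants",
    "load_conditions",
    "evaluate_rate",
    "rhs",
]

#: canonical ordering; PC is the single fixed (clamped) species
METABOLITE_IDS = ("PC", "AA", "5-HPETE", "LTA4", "15-HPETE", "15-HETE", "PGH2", "PGD2")
#: dynamic state variables, i.e. all non-fixed metabolites
STATE_IDS = METABOLITE_IDS[1:]
ENZYME_IDS = (
    "PLA2", "PERK", "PTGS1", "PTGDS", "ALOX5",
    "ALOX5AP", "ALOX15", "PKCD", "PSTAT3", "GPX",
)
STRAINS = ("AJ", "B6", "PWD")
TREATMENTS = ("control", "DDC")

#: units for which values are rescaled to nM on ingestion
_UNIT_TO_NM = {"nM": 1.0, "uM": 1000.0}


class ModelConsistencyError(ValueError):
    """An id referenced by a rate law or condition does not resolve."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    concentration: float = 0.0  # nM
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration for {self.id}")


@dataclass(frozen=True)
class EnzymeActivity:
    """Unitless DDC/control scaling factor u; basal concentration 1 nM."""

    id: str
    ratio_u: float = 1.0
    basal_concentration: float = 1.0  # nM

    def __post_init__(self) -> None:
        if not self.ratio_u > 0:
            raise ValueError(f"activity ratio for {self.id} must be > 0")


@dataclass(frozen=True)
class RateLaw:
    form: str  # activated_inhibited_mm | first_order_decay | activated_linear
    substrate: str
    v_max: float | None = None
    k_m: float | None = None   # nM
    k_i: float | None = None   # nM
    k_cat: float | None = None  # 1/s
    activators: tuple[str, ...] = ()
    inhibitor: str | None = None
    # unit annotations are bookkeeping, not part of kinetic identity
    units: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("v_max", "k_m", "k_i", "k_cat"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"kinetic constant {name} must be > 0, got {v}")
        if self.form not in ("activated_inhibited_mm", "first_order_decay", "activated_linear"):
            raise ValueError(f"unknown rate-law form {self.form!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    substrate: str
    product: str | None  # None for degradation sinks
    rate_law: RateLaw


@dataclass(frozen=True)
class StrainCondition:
    """One strain x treatment state from the initial-values table."""

    strain: str
    treatment: str
    activity_ratios: Mapping[str, float]
    pc_concentration: float  # µM, converted to nM where it enters the model

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        missing = set(ENZYME_IDS) - set(self.activity_ratios)
        if missing:
            raise ModelConsistencyError(f"condition lacks activity ratios for {sorted(missing)}")
        if self.treatment == "control":
            off = {k: v for k, v in self.activity_ratios.items() if v != 1.0}
            if off:
                raise ValueError(f"control condition must have all ratios 1.0, got {off}")
        bad = {k: v for k, v in self.activity_ratios.items() if not v > 0}
        if bad:
            raise ValueError(f"activity ratios must be > 0: {bad}")

    @property
    def pc_nM(self) -> float:
        return self.pc_concentration * 1000.0


@dataclass(frozen=True)
class KineticModel:
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    activities: tuple[EnzymeActivity, ...]

    def __post_init__(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        act_ids = {a.id for a in self.activities}
        for rxn in self.reactions:
            rl = rxn.rate_law
            refs = {rxn.substrate, rl.substrate} | set([rxn.product] if rxn.product else [])
            if rl.inhibitor:
                refs.add(rl.inhibitor)
            unresolved = refs - met_ids
            if unresolved:
                raise ModelConsistencyError(f"{rxn.id}: unknown metabolite ids {sorted(unresolved)}")
            missing_act = set(rl.activators) - act_ids
            if missing_act:
                raise ModelConsistencyError(f"{rxn.id}: unknown activity ids {sorted(missing_act)}")

    @property
    def fixed_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if m.fixed)

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if not m.fixed)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ModelConsistencyError(f"no reaction {rid!r}")

    def activity_map(self) -> dict[str, float]:
        return {a.id: a.ratio_u for a in self.activities}

    def with_activities(self, ratios: Mapping[str, float]) -> "KineticModel":
        """Return a copy with the given activity ratios substituted."""
        unknown = set(ratios) - {a.id for a in self.activities}
        if unknown:
            raise ModelConsistencyError(f"unknown activity ids {sorted(unknown)}")
        acts = tuple(
            replace(a, ratio_u=float(ratios.get(a.id, a.ratio_u))) for a in self.activities
        )
        return replace(self, activities=acts)

    def with_parameter(self, rid: str, name: str, value: float) -> "KineticModel":
        """Return a copy with one kinetic constant of reaction `rid` replaced."""
        rxns = []
        found = False
        for r in self.reactions:
            if r.id == rid:
                if getattr(r.rate_law, name, None) is None:
                    raise ModelConsistencyError(f"{rid} has no parameter {name!r}")
                rxns.append(replace(r, rate_law=replace(r.rate_law, **{name: float(value)})))
                found = True
            else:
                rxns.append(r)
        if not found:
            raise ModelConsistencyError(f"no reaction {rid!r}")
        return replace(self, reactions=tuple(rxns))

    def with_pc(self, pc_nM: float) -> "KineticModel":
        """Return a copy with the fixed PC species clamped at `pc_nM`."""
        mets = tuple(
            replace(m, concentration=float(pc_nM)) if m.id == "PC" else m
            for m in self.metabolites
        )
        return replace(self, metabolites=mets)

    @property
    def pc_nM(self) -> float:
        for m in self.metabolites:
            if m.id == "PC":
                return m.concentration
        raise ModelConsistencyError("model has no PC species")


def _read_packaged_tsv(name: str) -> list[dict[str, str]]:
    text = resources.files("eicokin.data").joinpath(name).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_constants(rows: Iterable[Mapping[str, str]] | None = None) -> dict[str, dict]:
    """Parse the kinetic-constants table into {reaction: {form, params, units}}.

    `rows` defaults to the packaged table mirroring the published constants;
    a user-supplied table with the same schema (reaction, form, parameter,
    value, unit) overrides it.  Values with unit µM are converted to nM.
    """
    if rows is None:
        rows = _read_packaged_tsv("table2_constants.tsv")
    out: dict[str, dict] = {}
    for row in rows:
        rid, form, pname = row["reaction"], row["form"], row["parameter"]
        unit = row["unit"]
        try:
            value = float(row["value"])
        except ValueError as exc:
            raise ValueError(f"unparsable constant {rid}/{pname}: {row['value']!r}") from exc
        scale = 1.0
        base = unit.split(".")[0].split("^")[0]
        if base in _UNIT_TO_NM:
            scale = _UNIT_TO_NM[base]
        entry = out.setdefault(rid, {"form": form, "params": {}, "units": {}, "raw": {}})
        if entry["form"] != form:
            raise ValueError(f"conflicting forms for {rid}")
        entry["params"][pname] = value * scale
        entry["units"][pname] = unit
        entry["raw"][pname] = row["value"]
    return out


#: reaction topology: (substrate, product, activators, inhibitor)
_TOPOLOGY = {
    "R1": ("PC", "AA", ("PLA2", "PERK"), "AA"),
    "R2": ("AA", "5-HPETE", ("ALOX5", "ALOX5AP"), "5-HPETE"),
    "R3": ("5-HPETE", None, (), None),
    "R4": ("5-HPETE", "LTA4", ("ALOX5", "ALOX5AP"), "LTA4"),
    "R5": ("LTA4", None, (), None),
    "R6": ("AA", "15-HPETE", ("ALOX15", "PKCD", "PSTAT3"), "15-HPETE"),
    "R7": ("15-HPETE", "15-HETE", ("GPX",), "15-HETE"),
    "R8": ("15-HETE", None, (), None),
    "R9": ("AA", "PGH2", ("PTGS1",), "PGH2"),
    "R10": ("PGH2", "PGD2", ("PTGDS",), None),
    "R11": ("PGD2", None, (), None),
    "R12": ("AA", None, (), None),
}

_FULL_NAMES = {
    "PC": "phosphatidylcholine",
    "AA": "arachidonic acid",
    "5-HPETE": "5-hydroperoxyeicosatetraenoic acid",
    "LTA4": "leukotriene A4",
    "15-HPETE": "15-hydroperoxyeicosatetraenoic acid",
    "15-HETE": "15-hydroxyeicosatetraenoic acid",
    "PGH2": "prostaglandin H2",
    "PGD2": "prostaglandin D2",
}


def build_paper_model(
    constants: Mapping[str, Mapping] | None = None,
    r7_catalyst: str = "GPX",
    pc_nM: float = 0.0,
) -> KineticModel:
    """Construct the published 12-reaction model.

    Parameters
    ----------
    constants
        Output of :func:`load_constants`; defaults to the packaged table.
    r7_catalyst
        Which activity scales the 15-HPETE -> 15-HETE conversion.  The
        published sources disagree: the pathway diagram and the knockdown
        results attribute R7 to glutathione peroxidase ("GPX", the default),
        while the kinetic-parameter table prints ALOX15.  Pass "ALOX15" for
        the alternative reading.
    pc_nM
        Initial clamp for the fixed PC species (overridden per condition).
    """
    if r7_catalyst not in ("GPX", "ALOX15"):
        raise ValueError("r7_catalyst must be 'GPX' or 'ALOX15'")
    consts = load_constants() if constants is None else constants
    metabolites = tuple(
        Metabolite(mid, _FULL_NAMES[mid], concentration=pc_nM if mid == "PC" else 0.0,
                   fixed=(mid == "PC"))
        for mid in METABOLITE_IDS
    )
    reactions = []
    for rid, (sub, prod, acts, inh) in _TOPOLOGY.items():
        if rid == "R7" and r7_catalyst == "ALOX15":
            acts = ("ALOX15",)
        if rid not in consts:
            raise ModelConsistencyError(f"constants table lacks reaction {rid}")
        entry = consts[rid]
        p = dict(entry["params"])
        law = RateLaw(
            form=entry["form"],
            substrate=sub,
            v_max=p.get("v_max"),
            k_m=p.get("k_m"),
            k_i=p.get("k_i"),
            k_cat=p.get("k_cat"),
            activators=tuple(acts),
            inhibitor=inh,
            units=dict(entry["units"]),
        )
        reactions.append(Reaction(rid, sub, prod, law))
    activities = tuple(EnzymeActivity(eid) for eid in ENZYME_IDS)
    return KineticModel(metabolites, tuple(reactions), activities)


def load_conditions(rows: Iterable[Mapping[str, str]] | None = None) -> dict[tuple[str, str], StrainCondition]:
    """Build the six strain x treatment conditions from the initial-values table.

    The table mirrors the published layout: one row per enzyme symbol plus a
    PC row (µM).  The p-ERK activity has no row of its own — the published
    table folds the p-ERK RPPA fold change into the PLA2 row — so PERK is
    assigned the PLA2 row's value (both derive from the same measurement).
    """
    if rows is None:
        rows = _read_packaged_tsv("table1_conditions.tsv")
    table: dict[str, dict[str, float]] = {}
    for row in rows:
        sym = row["symbol"]
        table[sym] = {}
        for strain in STRAINS:
            for treat in TREATMENTS:
                table[sym][(strain, treat)] = float(row[f"{strain}_{treat}"])
    out = {}
    for strain in STRAINS:
        for treat in TREATMENTS:
            ratios = {}
            for eid in ENZYME_IDS:
                src = "PLA2" if eid == "PERK" else eid
                if src not in table:
                    raise ModelConsistencyError(f"conditions table lacks row {src!r}")
                ratios[eid] = table[src][(strain, treat)]
            pc = table["PC"][(strain, treat)]
            out[(strain, treat)] = StrainCondition(strain, treat, ratios, pc)
    return out


def evaluate_rate(
    reaction: Reaction,
    concentrations: Mapping[str, float],
    activities: Mapping[str, float],
) -> float:
    """Instantaneous flux of one reaction in nM/s.

    Raises
    ------
    ModelConsistencyError
        if a referenced metabolite or activity id is missing.
    ValueError
        if a referenced concentration or ratio is negative.
    """
    rl = reaction.rate_law
    if rl.substrate not in concentrations:
        raise ModelConsistencyError(f"{reaction.id}: no concentration for {rl.substrate!r}")
    s = concentrations[rl.substrate]
    if s < 0:
        raise ValueError(f"{reaction.id}: negative substrate concentration {s}")
    if rl.form == "first_order_decay":
        return rl.k_cat * s
    a = 1.0
    for aid in rl.activators:
        if aid not in activities:
            raise ModelConsistencyError(f"{reaction.id}: no activity ratio for {aid!r}")
        u = activities[aid]
        if u < 0:
            raise ValueError(f"{reaction.id}: negative activity ratio for {aid}")
        a *= u
    if rl.form == "activated_linear":
        return rl.v_max * a * s
    # activated_inhibited_mm
    if rl.inhibitor is not None:
        if rl.inhibitor not in concentrations:
            raise ModelConsistencyError(f"{reaction.id}: no concentration for {rl.inhibitor!r}")
        i = concentrations[rl.inhibitor]
        if i < 0:
            raise ValueError(f"{reaction.id}: negative inhibitor concentration {i}")
    else:
        i = 0.0
    return rl.v_max * a * s / ((rl.k_m + s) * (rl.k_i + i))


def _compile(model: KineticModel):
    """Precompute index arrays for fast repeated RHS evaluation."""
    idx = {mid: k for k, mid in enumerate(model.state_ids)}
    plan = []
    for rxn in model.reactions:
        rl = rxn.rate_law
        plan.append((
            rxn,
            idx.get(rxn.substrate, -1),          # -1 => fixed species (PC)
            idx.get(rxn.product) if rxn.product else None,
            idx.get(rl.inhibitor) if rl.inhibitor else None,
        ))
    return idx, plan


def rhs(
    model: KineticModel,
    state: Sequence[float],
    activities: Mapping[str, float] | None = None,
    pc_nM: float | None = None,
) -> np.ndarray:
    """Time derivative d[x]/dt (nM/s) for the non-fixed metabolites.

    `state` follows :data:`STATE_IDS` order.  The fixed PC clamp contributes
    to fluxes but carries no state entry.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (len(model.state_ids),):
        raise ValueError(
            f"state must have length {len(model.state_ids)}, got shape {y.shape}"
        )
    acts = model.activity_map() if activities is None else dict(activities)
    pc = model.pc_nM if pc_nM is None else pc_nM
    yc = np.maximum(y, 0.0)
    dydt = np.zeros_like(yc)
    _, plan = _compile(model)
    for rxn, si, pi, ii in plan:
        rl = rxn.rate_law
        s = pc if si < 0 else yc[si]
        if rl.form == "first_order_decay":
            v = rl.k_cat * s
        else:
            a = 1.0
            for aid in rl.activators:
                a *= acts[aid]
            if rl.form == "activated_linear":
                v = rl.v_max * a * s
            else:
                i = yc[ii] if ii is not None else 0.0
                v = rl.v_max * a * s / ((rl.k_m + s) * (rl.k_i + i))
        if si >= 0:
            dydt[si] -= v
        if pi is not None:
            dydt[pi] += v
    return dydt


def make_rhs_function(model: KineticModel, activities: Mapping[str, float] | None = None,
                      pc_nM: float | None = None):
    """Return a fast closure f(t, y) -> dy/dt for ODE solvers.

    All rate constants and the activator products are folded into plain
    floats so the inner function does only arithmetic.
    """
    acts = model.activity_map() if activities is None else dict(activities)
    pc = model.pc_nM if pc_nM is None else pc_nM
    idx = {mid: k for k, mid in enumerate(model.state_ids)}
    terms = []
    for rxn in model.reactions:
        rl = rxn.rate_law
        si = idx.get(rxn.substrate, -1)
        pi = idx.get(rxn.product) if rxn.product else None
        if rl.form == "first_order_decay":
            terms.append(("decay", rl.k_cat, si, pi, None, None, None))
        else:
            a = math.prod(acts[aid] for aid in rl.activators)
            if rl.form == "activated_linear":
                terms.append(("lin", rl.v_max * a, si, pi, None, None, None))
            else:
                ii = idx.get(rl.inhibitor) if rl.inhibitor else None
                terms.append(("mm", rl.v_max * a, si, pi, rl.k_m, rl.k_i, ii))
    n = len(idx)

    def f(t, y):
        yc = np.maximum(y, 0.0)
        d = np.zeros(n)
        for kind, c, si, pi, km, ki, ii in terms:
            s = pc if si < 0 else yc[si]
            if kind == "mm":
                i = yc[ii] if ii is not None else 0.0
                v = c * s / ((km + s) * (ki + i))
            else:
                v = c * s
            if si >= 0:
                d[si] -= v
            if pi is not None:
                d[pi] += v
        return d

    return f
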