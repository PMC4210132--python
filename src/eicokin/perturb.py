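"""Enzyme-reversion and in-silico drug-inhibition screens.

The reversion screen asks which subsets of the six DDC-perturbed activities
(ALOX5AP, GPX, PKCD, PTGS1, PERK, PSTAT3), when reset to their control value
of 1.0, bring the DDC steady state back to a reference state in which every
enzyme activity is normal (PC stays at its DDC value: it is a measured
concentration, not one of the reverted enzyme activities).

The drug screen divides one activity ratio at a time by a fold factor
(3, 6, 9) and classifies each metabolite against the unperturbed DDC steady
state with the same symmetric 1.5-fold band used for fold changes.

The PERK and PLA2 activity ratios both derive from the single p-ERK RPPA
measurement (the initial-values table prints it under PLA2, the rate law
lists p-ERK as a separate activator), so perturbing "PERK" reverts or
inhibits the coupled pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import KineticModel, StrainCondition, build_paper_model
from .simulate import (
    DEFAULT_TOL,
    SteadyStateResult,
    classify_ratio,
    simulate_condition,
)

__all__ = [
    "SCREEN_ENZYMES",
    "ReversionScreenResult",
    "DrugScreenResult",
    "revert_enzymes",
    "reversion_screen",
    "drug_screen",
    "all_subsets",
]

#: the six perturbed activities screened by the reversion analysis
SCREEN_ENZYMES = ("ALOX5AP", "GPX", "PKCD", "PTGS1", "PERK", "PSTAT3")

#: activities driven by the same underlying measurement (p-ERK RPPA ratio)
_COUPLED = {"PERK": ("PERK", "PLA2")}


def _expand(enzymes: Iterable[str]) -> list[str]:
    out: list[str] = []
    for e in enzymes:
        out.extend(_COUPLED.get(e, (e,)))
    return out


@dataclass(frozen=True)
class ReversionScreenResult:
    """Per subset: metabolite -> restored/not_restored (+ overall verdict)."""

    per_subset: Mapping[frozenset, Mapping[str, str]]
    overall_restored: Mapping[frozenset, bool]
    failed_subsets: tuple[frozenset, ...]
    reference: SteadyStateResult
    tolerance: float


@dataclass(frozen=True)
class DrugScreenResult:
    """Per (enzyme, factor): metabolite -> up/down/unchanged vs DDC baseline."""

    classifications: Mapping[tuple[str, float], Mapping[str, str]]
    baseline: SteadyStateResult
    threshold: float


def revert_enzymes(
    ddc: StrainCondition,
    control: StrainCondition,
    subset: Iterable[str],
    model: KineticModel | None = None,
    tol: float = DEFAULT_TOL,
) -> SteadyStateResult:
    """Steady state of the DDC condition with `subset` activities reset to
    their control ratios (1.0).  PC remains at the DDC value."""
    subset = set(subset)
    bad = subset - set(SCREEN_ENZYMES)
    if bad:
        raise ValueError(
            f"the reversion screen is defined only on {SCREEN_ENZYMES}, got {sorted(bad)}"
        )
    model = build_paper_model() if model is None else model
    ratios = dict(ddc.activity_ratios)
    for e in _expand(subset):
        ratios[e] = control.activity_ratios[e]
    cond = StrainCondition(ddc.strain, ddc.treatment, ratios, ddc.pc_concentration)
    return simulate_condition(model, cond, tol=tol)


def all_subsets(enzymes: Sequence[str] = SCREEN_ENZYMES) -> list[frozenset]:
    """All 2^n - 1 non-empty subsets, smallest first."""
    out: list[frozenset] = []
    n = len(enzymes)
    for mask in range(1, 2 ** n):
        out.append(frozenset(e for k, e in enumerate(enzymes) if mask >> k & 1))
    out.sort(key=lambda s: (len(s), sorted(s)))
    return out


def reversion_screen(
    ddc: StrainCondition,
    control: StrainCondition,
    subsets: Sequence[Iterable[str]] | None = None,
    reference_tolerance: float = 0.10,
    model: KineticModel | None = None,
    tol: float = DEFAULT_TOL,
) -> ReversionScreenResult:
    """Classify each subset's steady state against the all-normal reference.

    A metabolite is "restored" when its reverted steady-state concentration
    lies within `reference_tolerance` (relative) of the reference state; a
    subset is overall restored when every metabolite is.  Subsets whose
    steady state fails to converge are flagged and skipped.
    """
    if subsets is None:
        subsets = all_subsets()
    subsets = [frozenset(s) for s in subsets]
    if not subsets:
        raise ValueError("subsets must be a non-empty list")
    model = build_paper_model() if model is None else model
    # reference: all six enzymes reverted (every activity normal, PC at DDC)
    reference = revert_enzymes(ddc, control, SCREEN_ENZYMES, model=model, tol=tol)
    per_subset: dict[frozenset, dict[str, str]] = {}
    overall: dict[frozenset, bool] = {}
    failed: list[frozenset] = []
    for subset in subsets:
        res = revert_enzymes(ddc, control, subset, model=model, tol=tol)
        if not res.converged:
            failed.append(subset)
            continue
        calls = {}
        for m, ref in reference.concentrations.items():
            v = res.concentrations[m]
            dev = abs(v - ref) / ref if ref > 0 else (0.0 if v == 0 else float("inf"))
            calls[m] = "restored" if dev <= reference_tolerance else "not_restored"
        per_subset[subset] = calls
        overall[subset] = all(c == "restored" for c in calls.values())
    return ReversionScreenResult(per_subset, overall, tuple(failed), reference, reference_tolerance)


def drug_screen(
    ddc: StrainCondition,
    enzymes: Sequence[str] | None = None,
    factors: Sequence[float] = (3.0, 6.0, 9.0),
    threshold: float = 1.5,
    model: KineticModel | None = None,
    tol: float = DEFAULT_TOL,
) -> DrugScreenResult:
    """Knock each enzyme activity down by the given fold factors.

    For each (enzyme e, factor k) the DDC ratio of e is divided by k, the
    steady state recomputed, and every metabolite classified against the
    unperturbed DDC steady state with the symmetric `threshold` band.
    """
    if any(f < 1 for f in factors):
        raise ValueError("inhibition factors must be >= 1")
    enzymes = list(SCREEN_ENZYMES) if enzymes is None else list(enzymes)
    model = build_paper_model() if model is None else model
    known = {a.id for a in model.activities}
    bad = set(enzymes) - known
    if bad:
        raise ValueError(f"unknown enzyme ids {sorted(bad)}")
    baseline = simulate_condition(model, ddc, tol=tol)
    out: dict[tuple[str, float], dict[str, str]] = {}
    for e in enzymes:
        for k in factors:
            ratios = dict(ddc.activity_ratios)
            for ce in _expand([e]):
                ratios[ce] = ratios[ce] / k
            cond = StrainCondition(ddc.strain, ddc.treatment, ratios, ddc.pc_concentration)
            res = simulate_condition(model, cond, tol=tol)
            calls = {
                m: classify_ratio(res.concentrations[m] / baseline.concentrations[m], threshold)
                for m in baseline.concentrations
            }
            out[(e, float(k))] = calls
    return DrugScreenResult(out, baseline, threshold)
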