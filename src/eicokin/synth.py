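"""Synthetic ground-truth scenarios, measurements, and omics tables.

A scenario fixes a ground-truth parameterization of the kinetic model (the
published constants, optionally jittered log-normally), the six strain x
treatment conditions, and a measurement noise model.  From it the module
generates

* metabolite measurement tables: replicates drawn log-normally around the
  model-implied steady states, summarized as per-group median and median
  absolute deviation (the convention of the underlying MS profiling, three
  biological replicates per group);
* expression/protein/PC tables, including decoy Gpx isoenzyme rows, that
  map back onto exactly the scenario's conditions.

Everything is deterministic per seed, so calibration and screen tests can
close the loop without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import METABOLITE_SET_M, ObjectiveSpec, default_parameter_space
from .model import (
    ENZYME_IDS,
    STRAINS,
    TREATMENTS,
    KineticModel,
    StrainCondition,
    build_paper_model,
    load_conditions,
)
from .simulate import simulate_condition

__all__ = [
    "SyntheticScenario",
    "generate_scenario",
    "simulate_measurements",
    "generate_omics_tables",
    "make_objective_spec",
]

#: designated true Gpx isoenzyme and its decoys (gene, padj, control RPKM)
_GPX_DECOYS = (
    ("Gpx1", 1.2e-3, 140.0),
    ("Gpx2", 0.32, 2.1),
    ("Gpx6", 0.77, 0.3),
    ("Gpx7", 0.08, 5.4),
)
_GPX_TRUE = ("Gpx3", 2.66e-41, 85.0)


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int
    true_parameters: Mapping[tuple[str, str], float]
    conditions: Mapping[tuple[str, str], StrainCondition]
    noise_cv: float = 0.2
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def true_model(self) -> KineticModel:
        model = build_paper_model()
        for (rxn, name), value in self.true_parameters.items():
            model = model.with_parameter(rxn, name, value)
        return model


def generate_scenario(
    seed: int,
    perturbation_scale: float = 0.0,
    noise_cv: float = 0.2,
    replicates: int = 3,
) -> SyntheticScenario:
    """Ground-truth scenario with log-normally jittered kinetic constants.

    Each constant is multiplied by exp(N(0, perturbation_scale)); scale 0
    reproduces the published values exactly.  Conditions are the published
    initial-values table.  Deterministic and bit-identical per seed.
    """
    if perturbation_scale < 0:
        raise ValueError("perturbation_scale must be >= 0")
    rng = np.random.default_rng(seed)
    model = build_paper_model()
    params: dict[tuple[str, str], float] = {}
    for rxn in model.reactions:
        for name in ("v_max", "k_m", "k_i", "k_cat"):
            v = getattr(rxn.rate_law, name)
            if v is None:
                continue
            factor = float(np.exp(rng.normal(0.0, perturbation_scale))) if perturbation_scale else 1.0
            params[(rxn.id, name)] = v * factor
    return SyntheticScenario(
        seed=seed,
        true_parameters=params,
        conditions=load_conditions(),
        noise_cv=noise_cv,
        replicates=replicates,
    )


def simulate_measurements(scenario: SyntheticScenario) -> pd.DataFrame:
    """Noisy metabolite measurement table for all six conditions.

    Replicates are drawn log-normally centred (in the median sense) on the
    model-implied steady state with the scenario's coefficient of
    variation; the table reports per-group median and median absolute
    deviation.  Raises if any condition fails to reach steady state.
    """
    rng = np.random.default_rng(scenario.seed)
    model = scenario.true_model()
    sigma = float(np.sqrt(np.log1p(scenario.noise_cv ** 2)))
    rows = []
    for strain in STRAINS:
        for treatment in TREATMENTS:
            cond = scenario.conditions[(strain, treatment)]
            res = simulate_condition(model, cond)
            if not res.converged:
                raise RuntimeError(
                    f"scenario rejected: no steady state for {strain}/{treatment} "
                    f"(residual {res.residual_norm:.2e})"
                )
            for met, ss in res.concentrations.items():
                draws = ss * np.exp(sigma * rng.standard_normal(scenario.replicates))
                med = float(np.median(draws))
                mad = float(np.median(np.abs(draws - med)))
                rows.append(
                    dict(strain=strain, treatment=treatment, metabolite=met,
                         median_nM=med, mad_nM=mad, n_replicates=scenario.replicates)
                )
    return pd.DataFrame(rows)


def generate_omics_tables(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression, protein, and PC tables that reproduce the conditions.

    The expression table uses unit control RPKM for the mapped genes, so the
    DDC column is numerically the fold change and the mapping round-trips
    exactly.  Decoy Gpx isoenzymes with larger adjusted p-values exercise
    the isoenzyme-selection rule; low-expressed non-differential genes
    (Alox5, Alox15, Ptgds, Pla2g4a) are included below the 1-RPKM floor.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    expr_rows, prot_rows, pc_rows = [], [], []
    for strain in STRAINS:
        ddc = scenario.conditions[(strain, "DDC")]
        r = ddc.activity_ratios
        # genes mapped 1:1; control RPKM 1.0 makes the ratio round-trip exact
        expr_rows += [
            dict(gene="Ptgs1", strain=strain, control_rpkm=1.0, ddc_rpkm=r["PTGS1"], padj=1e-12),
            dict(gene="Alox5ap", strain=strain, control_rpkm=1.0, ddc_rpkm=r["ALOX5AP"], padj=1e-20),
            dict(gene="Prkcd", strain=strain, control_rpkm=1.0, ddc_rpkm=r["PKCD"], padj=1e-15),
        ]
        gene, padj, _ = _GPX_TRUE
        expr_rows.append(
            dict(gene=gene, strain=strain, control_rpkm=1.0, ddc_rpkm=r["GPX"], padj=padj)
        )
        for gene, dpadj, rpkm in _GPX_DECOYS:
            decoy_ratio = float(np.round(np.exp(rng.normal(0.0, 0.3)), 4))
            expr_rows.append(
                dict(gene=gene, strain=strain, control_rpkm=rpkm,
                     ddc_rpkm=rpkm * decoy_ratio, padj=dpadj)
            )
        for gene in ("Alox5", "Alox15", "Ptgds", "Pla2g4a"):
            expr_rows.append(
                dict(gene=gene, strain=strain, control_rpkm=0.4, ddc_rpkm=0.4, padj=0.6)
            )
        prot_rows += [
            dict(analyte="p-ERK", strain=strain, ratio=r["PERK"]),
            dict(analyte="p-STAT3", strain=strain, ratio=r["PSTAT3"]),
        ]
        for treatment in TREATMENTS:
            pc_rows.append(
                dict(strain=strain, treatment=treatment,
                     pc_um=scenario.conditions[(strain, treatment)].pc_concentration)
            )
    return pd.DataFrame(expr_rows), pd.DataFrame(prot_rows), pd.DataFrame(pc_rows)


def make_objective_spec(
    scenario: SyntheticScenario,
    measurements: pd.DataFrame,
    strain: str = "B6",
    parameter_space: Sequence[tuple[str, str, float, float]] | None = None,
) -> ObjectiveSpec:
    """Objective specification for one strain from a measurement table."""
    if parameter_space is None:
        parameter_space = default_parameter_space()

    def group(treatment: str) -> dict[str, float]:
        sub = measurements[
            (measurements["strain"] == strain) & (measurements["treatment"] == treatment)
        ]
        table = dict(zip(sub["metabolite"], sub["median_nM"]))
        return {m: float(table[m]) for m in METABOLITE_SET_M}

    return ObjectiveSpec(
        experimental_control=group("control"),
        experimental_ddc=group("DDC"),
        control_condition=scenario.conditions[(strain, "control")],
        ddc_condition=scenario.conditions[(strain, "DDC")],
        parameter_space=tuple(parameter_space),
    )
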