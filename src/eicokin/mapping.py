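"""Mapping omics tables onto enzyme-activity ratios of a condition.

Gene-expression (RPKM + adjusted p-value), protein-ratio (RPPA-style) and
phosphatidylcholine tables are converted into the activity ratios of a
:class:`~eicokin.model.StrainCondition`:

* PTGS1, ALOX5AP, PKCD map from the genes Ptgs1, Alox5ap, Prkcd;
* GPX maps from the most significantly differentially expressed Gpx
  isoenzyme (isoenzyme-selection rule);
* PERK and PSTAT3 map from the p-ERK / p-STAT3 protein ratios;
* PLA2 also carries the p-ERK protein ratio (the published initial-values
  table prints the p-ERK fold change in its PLA2 row: the PLA2 transcript
  itself is expressed below 1 RPKM and not differentially, so the
  phosphoprotein signal stands in for the activity of the pair);
* ALOX5, ALOX15 and PTGDS are low-expressed and non-differential and map
  to ratio 1.0;
* PC comes from the measured phosphatidylcholine concentration (µM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import ENZYME_IDS, STRAINS, TREATMENTS, StrainCondition

__all__ = [
    "ExpressionRecord",
    "ProteinRecord",
    "GENE_MAP",
    "GPX_CANDIDATES",
    "select_isoenzyme",
    "activity_ratio",
    "build_condition",
]

log = logging.getLogger(__name__)

#: enzymes mapped directly from one gene's expression ratio
GENE_MAP = {"PTGS1": "Ptgs1", "ALOX5AP": "Alox5ap", "PKCD": "Prkcd"}
#: candidate isoenzymes for glutathione peroxidase
GPX_CANDIDATES = ("Gpx1", "Gpx2", "Gpx3", "Gpx6", "Gpx7")
#: enzymes fixed at 1.0 (low-expressed, non-differential transcripts)
NON_DIFFERENTIAL = {"ALOX5": "Alox5", "ALOX15": "Alox15", "PTGDS": "Ptgds"}
#: enzymes mapped from phosphoprotein ratios
PROTEIN_MAP = {"PERK": "p-ERK", "PSTAT3": "p-STAT3", "PLA2": "p-ERK"}

#: RPKM floor under which a gene counts as low-expressed
LOW_EXPRESSION_RPKM = 1.0


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    control_rpkm: float
    ddc_rpkm: float
    padj: float

    def __post_init__(self) -> None:
        if self.control_rpkm < 0 or self.ddc_rpkm < 0:
            raise ValueError(f"negative RPKM for {self.gene}")
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"p-value for {self.gene} outside [0, 1]: {self.padj}")

    @property
    def mean_rpkm(self) -> float:
        return 0.5 * (self.control_rpkm + self.ddc_rpkm)


@dataclass(frozen=True)
class ProteinRecord:
    analyte: str
    ratio: float  # DDC/control

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError(f"protein ratio for {self.analyte} must be > 0")


def select_isoenzyme(
    candidates: Sequence[ExpressionRecord],
    significance_cutoff: float = 0.05,
) -> str:
    """Pick the most significantly differentially expressed isoenzyme.

    Smallest adjusted p-value wins; ties break by higher mean expression,
    then lexicographic gene symbol.  `significance_cutoff` is only used for
    logging a warning when even the winner is non-significant.
    """
    if not candidates:
        raise ValueError("isoenzyme candidate list is empty")
    ranked = sorted(candidates, key=lambda r: (r.padj, -r.mean_rpkm, r.gene))
    winner = ranked[0]
    if winner.padj > significance_cutoff:
        log.warning(
            "isoenzyme winner %s is not significant (padj=%.3g)", winner.gene, winner.padj
        )
    if len(ranked) > 1 and ranked[1].padj == winner.padj:
        log.info(
            "isoenzyme tie at padj=%.3g broken by expression: %s over %s",
            winner.padj, winner.gene, ranked[1].gene,
        )
    return winner.gene


def activity_ratio(treated_value: float, control_value: float) -> float:
    """DDC/control fold change; control maps to 1 by construction.

    A non-positive control value cannot be mapped: the ratio falls back to
    1.0 (non-differential assumption) with a warning.
    """
    if control_value <= 0:
        warnings.warn(
            "control value <= 0 is unmappable; falling back to ratio 1.0",
            stacklevel=2,
        )
        return 1.0
    return treated_value / control_value


def _expr_records(expression: pd.DataFrame, strain: str) -> dict[str, ExpressionRecord]:
    sub = expression[expression["strain"] == strain]
    out = {}
    for row in sub.itertuples(index=False):
        out[row.gene] = ExpressionRecord(
            row.gene, float(row.control_rpkm), float(row.ddc_rpkm), float(row.padj)
        )
    return out


def build_condition(
    expression: pd.DataFrame,
    protein: pd.DataFrame,
    pc: pd.DataFrame,
    strain: str,
    treatment: str,
) -> StrainCondition:
    """Assemble one strain x treatment condition from the three omics tables.

    Expected columns — expression: gene, strain, control_rpkm, ddc_rpkm,
    padj; protein: analyte, strain, ratio; pc: strain, treatment, pc_um.
    Control conditions map every ratio to exactly 1.0.
    """
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")

    pc_col = "pc_um" if "pc_um" in pc.columns else "pc_concentration"
    pc_rows = pc[(pc["strain"] == strain) & (pc["treatment"] == treatment)]
    if len(pc_rows) != 1:
        raise ValueError(
            f"pc table must have exactly one row for ({strain}, {treatment}), "
            f"found {len(pc_rows)}"
        )
    pc_um = float(pc_rows[pc_col].iloc[0])

    if treatment == "control":
        ratios = {e: 1.0 for e in ENZYME_IDS}
        return StrainCondition(strain, treatment, ratios, pc_um)

    expr = _expr_records(expression, strain)
    prot = {
        row.analyte: ProteinRecord(row.analyte, float(row.ratio))
        for row in protein[protein["strain"] == strain].itertuples(index=False)
    }

    unmapped: list[str] = []
    ratios = {}
    for enzyme, gene in GENE_MAP.items():
        if gene not in expr:
            unmapped.append(f"{enzyme} (gene {gene})")
            continue
        rec = expr[gene]
        ratios[enzyme] = activity_ratio(rec.ddc_rpkm, rec.control_rpkm)

    gpx_candidates = [expr[g] for g in GPX_CANDIDATES if g in expr]
    if not gpx_candidates:
        unmapped.append("GPX (no Gpx isoenzyme rows)")
    else:
        gene = select_isoenzyme(gpx_candidates)
        rec = expr[gene]
        ratios["GPX"] = activity_ratio(rec.ddc_rpkm, rec.control_rpkm)
        log.info("GPX mapped from isoenzyme %s (padj=%.3g)", gene, rec.padj)

    for enzyme, gene in NON_DIFFERENTIAL.items():
        rec = expr.get(gene)
        if rec is not None and rec.mean_rpkm >= LOW_EXPRESSION_RPKM and rec.padj < 0.05:
            log.warning(
                "gene %s mapped as non-differential but looks differential "
                "(mean %.2f RPKM, padj %.3g); ratio kept at 1.0",
                gene, rec.mean_rpkm, rec.padj,
            )
        ratios[enzyme] = 1.0

    for enzyme, analyte in PROTEIN_MAP.items():
        if analyte not in prot:
            unmapped.append(f"{enzyme} (analyte {analyte})")
            continue
        ratios[enzyme] = prot[analyte].ratio

    if unmapped:
        raise ValueError(f"unmapped enzymes for {strain}/{treatment}: {unmapped}")
    return StrainCondition(strain, treatment, ratios, pc_um)
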