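"""Mutation-context and patient-level (tumor microenvironment) features.

Per-mutation: RNA-level validation of the DNA-called variant and the
coverage-damped fraction of mutated transcripts.  Per-patient, from bulk
tumor RNA-seq: cytolytic activity (CYT), marker-gene abundance scores
for ten immune/stromal cell populations with their mean (the overall
infiltration estimate), and class-I HLA expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


@dataclass
class MutationRNACounts:
    """Read support for one somatic variant in tumor RNA-seq."""

    peptide_id: str
    n_variant_reads: int
    n_coverage_reads: int

    def __post_init__(self) -> None:
        if self.n_variant_reads < 0 or self.n_coverage_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_variant_reads > self.n_coverage_reads:
            raise ValueError("variant reads cannot exceed coverage")


@dataclass
class PatientProfile:
    """Per-patient expression map plus survival follow-up."""

    patient_id: str
    expression: dict[str, float] = field(default_factory=dict)
    survival_time: Optional[float] = None
    survival_event: Optional[int] = None
    cohort: str = ""


def val_mut_rna_coef(n_variant: int, n_coverage: int) -> float:
    """Coverage-damped mutant-transcript fraction: v / (c + 100).

    The +100 pseudo-coverage shrinks the fraction toward 0 at low read
    depth, so poorly covered variants cannot claim full RNA support.
    """
    if n_variant < 0 or n_coverage < 0:
        raise ValueError("read counts must be non-negative")
    if n_variant > n_coverage:
        raise ValueError("variant reads cannot exceed coverage")
    return n_variant / (n_coverage + 100)


def rna_validation_status(
    n_variant: int, n_coverage: int, min_coverage: int = 1
) -> str:
    """Trichotomy: variant seen in RNA, absent despite coverage, or untestable."""
    if n_coverage < min_coverage:
        return "insufficient"
    return "validated" if n_variant >= 1 else "not_found"


def cytolytic_activity(
    gzma_tpm: float, prf1_tpm: float, pseudocount: float = 0.01
) -> float:
    """CYT: geometric mean of GZMA and PRF1 expression (TPM)."""
    if gzma_tpm < 0 or prf1_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    return math.sqrt((gzma_tpm + pseudocount) * (prf1_tpm + pseudocount))


#: Illustrative marker sets for the ten cell populations scored by
#: marker-based deconvolution.  Synthetic stand-in for a curated marker
#: list: real analyses should supply their own population -> genes map.
DEFAULT_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "T cells": ("CD3D", "CD3G"),
    "CD8 T cells": ("CD8A", "CD8B"),
    "Cytotoxic lymphocytes": ("GZMB", "KLRD1"),
    "NK cells": ("NCR1", "KIR2DL3"),
    "B lineage": ("CD79A", "MS4A1"),
    "Monocytic lineage": ("CD14", "CSF1R"),
    "Myeloid dendritic cells": ("CD1C", "FLT3"),
    "Neutrophils": ("FCGR3B", "CEACAM3"),
    "Endothelial cells": ("PECAM1", "VWF"),
    "Fibroblasts": ("COL1A1", "DCN"),
}

DEFAULT_HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")


def marker_population_scores(
    expression: Mapping[str, float],
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    log_transform: bool = True,
) -> dict[str, Optional[float]]:
    """Per-population mean marker expression (log2(TPM+1) by default).

    A population whose markers are all absent from the expression map
    scores None rather than 0: "not measured" is not "not infiltrated".
    """
    marker_sets = DEFAULT_MARKER_SETS if marker_sets is None else marker_sets
    if not marker_sets:
        raise ValueError("marker configuration is empty")
    scores: dict[str, Optional[float]] = {}
    for population, genes in marker_sets.items():
        if not genes:
            raise ValueError(f"population {population!r} has no marker genes")
        values = [expression[g] for g in genes if g in expression]
        if not values:
            scores[population] = None
            continue
        if log_transform:
            values = [math.log2(v + 1.0) for v in values]
        scores[population] = sum(values) / len(values)
    return scores


def mcp_mean(scores: Mapping[str, Optional[float]]) -> Optional[float]:
    """Mean over non-missing population scores; the infiltration summary.

    Collapsing correlated population estimates into one mean gives the
    forest a single uncorrelated infiltration covariate.
    """
    values = [v for v in scores.values() if v is not None]
    if not values:
        return None
    return sum(values) / len(values)


def hla_expression(
    expression: Mapping[str, float],
    hla_genes: Sequence[str] = DEFAULT_HLA_GENES,
) -> Optional[float]:
    """Summed TPM over class-I HLA loci; None if none are measured."""
    values = [expression[g] for g in hla_genes if g in expression]
    if not values:
        return None
    return float(sum(values))


TME_FEATURES = ("CYT", "MCPmean", "HLAexp")


def compute_tme_features(
    profile: PatientProfile,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    log_transform: bool = True,
    pseudocount: float = 0.01,
) -> dict[str, Optional[float]]:
    """CYT, MCPmean and HLAexp for one patient's expression profile."""
    expr = profile.expression
    if "GZMA" in expr and "PRF1" in expr:
        cyt: Optional[float] = cytolytic_activity(
            expr["GZMA"], expr["PRF1"], pseudocount
        )
    else:
        cyt = None
    scores = marker_population_scores(expr, marker_sets, log_transform)
    return {
        "CYT": cyt,
        "MCPmean": mcp_mean(scores),
        "HLAexp": hla_expression(expr),
    }
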