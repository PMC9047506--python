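"""Conjunctive BSA x BSR step: segregation test, gene intersection, ddCt.

The final candidate genes are those that both carry a consequential
variant inside a BSA candidate region and are shared DEGs (same direction
in all three contrasts) — the row shape of a candidate-gene report table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .effect_annotation import AnnotatedGene
from .synthetic_data import GROUPS

logger = logging.getLogger(__name__)


@dataclass
class SegregationTest:
    """Pearson chi-square goodness of fit to a Mendelian ratio, df = 1."""

    n_fertile: int
    n_sterile: int
    ratio: tuple[int, int]
    chi2: float
    p: float
    critical: float
    consistent: bool
    alpha: float = 0.05


def chi_square_segregation(
    n_fertile: int,
    n_sterile: int,
    ratio: tuple[int, int] = (3, 1),
    alpha: float = 0.05,
    yates: bool = False,
) -> SegregationTest:
    """Test observed fertile:sterile counts against an expected ratio.

    Plain Pearson chi-square, df = 1, no continuity correction by default;
    ``consistent`` compares the statistic with the chi-square critical
    value at ``alpha`` (3.84 for alpha = 0.05).
    """
    total = n_fertile + n_sterile
    if total <= 0 or n_fertile < 0 or n_sterile < 0:
        raise ValueError("counts must be non-negative with a positive total")
    r_f, r_s = ratio
    if r_f <= 0 or r_s <= 0:
        raise ValueError("ratio components must be positive")
    expected = (total * r_f / (r_f + r_s), total * r_s / (r_f + r_s))
    observed = (n_fertile, n_sterile)
    correction = 0.5 if yates else 0.0
    chi2 = sum(
        (max(abs(o - e) - correction, 0.0)) ** 2 / e
        for o, e in zip(observed, expected)
    )
    critical = float(stats.chi2.ppf(1 - alpha, df=1))
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(
        n_fertile=n_fertile,
        n_sterile=n_sterile,
        ratio=ratio,
        chi2=float(chi2),
        p=p,
        critical=critical,
        consistent=bool(chi2 < critical),
        alpha=alpha,
    )


@dataclass
class CandidateGene:
    """A BSA x BSR candidate: in-region consequential variant + shared DEG."""

    gene_id: str
    chrom: str
    start: int
    end: int
    worst_effect: str
    direction: str  # 'up' | 'down' (in the sterile bulk)
    expression: dict[str, float] = field(default_factory=dict)
    n_variant_sites: int = 0


def integrate_bsa_bsr(
    annotated_genes: list[AnnotatedGene],
    shared_up: set[str],
    shared_down: set[str],
    expression_summary: pd.DataFrame | None = None,
) -> list[CandidateGene]:
    """Intersect BSA candidate genes with the shared-DEG sets.

    ``expression_summary`` is an optional genes x groups matrix (mean
    normalized counts or FPKM) whose rows are copied onto the output.
    Returns genes sorted by chromosome then position. Warns when both
    inputs are nonempty yet share no identifier — the symptom of a gene-id
    namespace mismatch between the variant and expression stages.
    """
    shared = shared_up | shared_down
    bsa_ids = {g.gene_id for g in annotated_genes}
    if annotated_genes and shared and not (bsa_ids & shared):
        warnings.warn(
            "no overlap between BSA genes and shared DEGs; id namespaces may "
            f"differ (BSA e.g. {sorted(bsa_ids)[:2]}, DEG e.g. {sorted(shared)[:2]})",
            stacklevel=2,
        )
    out: list[CandidateGene] = []
    for gene in annotated_genes:
        if gene.gene_id not in shared:
            continue
        direction = "up" if gene.gene_id in shared_up else "down"
        expr: dict[str, float] = {}
        if expression_summary is not None and gene.gene_id in expression_summary.index:
            row = expression_summary.loc[gene.gene_id]
            expr = {g: float(row[g]) for g in GROUPS if g in row.index}
        out.append(
            CandidateGene(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                start=gene.start,
                end=gene.end,
                worst_effect=gene.worst_effect,
                direction=direction,
                expression=expr,
                n_variant_sites=len(gene.effects),
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def relative_expression_ddct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - (Ct_target,cal - Ct_reference,cal);
    the calibrator condition therefore maps to 1.0.
    """
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0**-ddct)


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "gene_id": c.gene_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "worst_effect": c.worst_effect,
            "direction": c.direction,
            "n_variant_sites": c.n_variant_sites,
        }
        for g in GROUPS:
            row[f"expr_{g}"] = c.expression.get(g, float("nan"))
        rows.append(row)
    columns = [
        "gene_id", "chrom", "start", "end", "worst_effect", "direction",
        "n_variant_sites", *(f"expr_{g}" for g in GROUPS),
    ]
    return pd.DataFrame(rows, columns=columns)
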