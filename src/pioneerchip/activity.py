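"""Expression-based activity classification and occupancy-activity links.

Genes are classified from qPCR delta-Ct relative expression: a gene is
"weak or silent" when its expression falls below one ten-thousandth of
the albumin analog's in the same tissue. Regions are linked to genes by
nearest TSS, proximal binding (within 5 kb) is cross-tabulated against
activity, and ChIP-chip calls are validated against locus-specific
ChIP-qPCR with a 2-fold-over-background positivity rule.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ACTIVITY_CUTOFF = 1e-4     # fraction of albumin-analog expression
PROXIMAL_CUTOFF = 5000     # bases from the TSS
POSITIVITY_FOLD = 2.0      # qPCR fold over background


def delta_ct(ct_gene, ct_ref):
    """Relative expression 2^-(Ct_gene - Ct_ref)."""
    return 2.0 ** -(np.asarray(ct_gene, dtype=np.float64) - np.asarray(ct_ref, dtype=np.float64))


def classify_activity(records: pd.DataFrame, albumin_gene: str,
                      cutoff: float = ACTIVITY_CUTOFF) -> pd.Series:
    """Label each gene active or silent relative to the albumin analog.

    ``records`` needs columns gene, ct_gene, ct_ref. A gene is silent iff
    rel_expression / rel_albumin < cutoff (strictly; the boundary value is
    active). Labels are invariant to common rescaling of all expressions.
    """
    if albumin_gene not in set(records["gene"]):
        raise ValueError(f"albumin analog {albumin_gene!r} missing from the table")
    rel = delta_ct(records["ct_gene"].to_numpy(), records["ct_ref"].to_numpy())
    rel_alb = rel[(records["gene"] == albumin_gene).to_numpy()][0]
    labels = np.where(rel / rel_alb < cutoff, "silent", "active")
    return pd.Series(labels, index=records["gene"].to_numpy(), name="label")


def nearest_tss_assignment(regions, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each region to its nearest TSS with a signed distance.

    distance = region midpoint - TSS, sign flipped for minus-strand genes
    (positive = downstream of the TSS in the gene's orientation). Nearest
    is by absolute distance; ties go to the lexicographically smaller gene
    name. Regions on chromosomes absent from the annotation are skipped
    with a log message.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    ann = annotation.sort_values(["chrom", "tss", "gene"])
    rows = []
    for i, region in enumerate(regions):
        sub = ann[ann["chrom"] == region.chrom]
        if len(sub) == 0:
            logger.info("region %s:%d-%d on unannotated chromosome; unassigned",
                        region.chrom, region.start, region.end)
            continue
        mid = region.midpoint
        d = mid - sub["tss"].to_numpy()
        signed = np.where(sub["strand"].to_numpy() == "-", -d, d)
        order = np.lexsort((sub["gene"].to_numpy(), np.abs(signed)))
        j = order[0]
        rows.append({"region_index": i,
                     "region": f"{region.chrom}:{region.start}-{region.end}",
                     "gene": sub["gene"].iloc[j], "distance": int(signed[j])})
    return pd.DataFrame(rows, columns=["region_index", "region", "gene", "distance"])


def proximal_activity_table(assignments: pd.DataFrame, labels: pd.Series,
                            proximal_cutoff: int = PROXIMAL_CUTOFF) -> tuple[pd.DataFrame, float]:
    """2x2 table of proximal/distal binding vs active/silent genes.

    Returns the table and the odds ratio (Haldane 0.5 correction applied
    when any cell is zero).
    """
    if len(assignments) == 0:
        raise ValueError("no assignments")
    lab = labels.reindex(assignments["gene"]).to_numpy()
    prox = np.abs(assignments["distance"].to_numpy()) <= proximal_cutoff
    table = pd.DataFrame(
        [[int(np.sum(prox & (lab == "active"))), int(np.sum(prox & (lab == "silent")))],
         [int(np.sum(~prox & (lab == "active"))), int(np.sum(~prox & (lab == "silent")))]],
        index=["proximal", "distal"], columns=["active", "silent"])
    a, b, c, d = table.to_numpy().ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return table, float((a * d) / (b * c))


def occupancy_activity_correlation(x, y, method: str = "pearson") -> float:
    """Correlation between two occupancy/activity signal vectors.

    Pearson by default (``method='spearman'`` for the rank variant);
    returns NaN when either vector has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero-variance input: correlation undefined")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def qpcr_percent_input(ct_input, ct_chip, efficiency: float = 2.0,
                       dilution_factor: float = 1.0) -> float:
    """ChIP signal as percent of input: E^(Ct_input - Ct_chip) x dilution x 100."""
    return float(efficiency ** (np.asarray(ct_input) - np.asarray(ct_chip))
                 * dilution_factor * 100.0)


def validation_concordance(called: set, validated: list,
                           positivity_fold: float = POSITIVITY_FOLD) -> tuple[float, float]:
    """Sensitivity/specificity of array calls against locus ChIP-qPCR.

    ``validated`` holds (region_id, fold_over_background) pairs; a locus
    is qPCR-positive when fold >= positivity_fold. Sensitivity is the
    fraction of positives that were called; specificity the fraction of
    negatives that were not. A metric with an empty denominator is NaN.
    """
    if not validated:
        raise ValueError("no validated loci")
    pos = [rid for rid, fold in validated if fold >= positivity_fold]
    neg = [rid for rid, fold in validated if fold < positivity_fold]
    sensitivity = sum(r in called for r in pos) / len(pos) if pos else float("nan")
    specificity = sum(r not in called for r in neg) / len(neg) if neg else float("nan")
    if not pos or not neg:
        logger.warning("one validation class is empty; its metric is undefined")
    return sensitivity, specificity
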