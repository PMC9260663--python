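"""Editing-efficiency matrices, group comparisons, and expression summaries.

Expression math follows the standard definitions: FPKM = count x 10^9 /
(gene length in bp x total mapped reads); log fold change is log2 of the
pseudocounted FPKM ratio; relative qPCR quantification uses the 2^-ddCt
method with the reference-gene Ct subtracted within each condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import EditingSite
from .io_formats import AlignedRead, GeneModel


def efficiency_matrix(
    sites: Sequence[EditingSite], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Sites x samples matrix of editing efficiencies.

    Rows are the union of sites across samples, labeled
    ``contig:position:ref>alt``; cells are NaN where a sample lacks the call
    (e.g. depth below threshold or site absent).
    """
    if samples is None:
        samples = sorted({s.sample for s in sites})
    rows: dict[str, dict[str, float]] = {}
    for s in sites:
        label = f"{s.contig}:{s.position}:{s.ref_base}>{s.alt_base}"
        rows.setdefault(label, {})
        if s.efficiency is not None:
            rows[label][s.sample] = s.efficiency
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(samples)
    )
    matrix = matrix.sort_index()
    matrix.index.name = "site"
    return matrix


def cluster_row_order(matrix: pd.DataFrame) -> list[str]:
    """Hierarchical-clustering row order for heatmap export (average linkage
    on euclidean distance; missing cells imputed with the row mean)."""
    from scipy.cluster import hierarchy

    if len(matrix) < 3:
        return list(matrix.index)
    filled = matrix.apply(lambda r: r.fillna(r.mean()), axis=1).fillna(0.0)
    link = hierarchy.linkage(filled.to_numpy(), method="average")
    order = hierarchy.leaves_list(link)
    return [matrix.index[i] for i in order]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_efficiency(
    group_a: Iterable[float], group_b: Iterable[float]
) -> tuple[float, float, str]:
    """Welch two-sided t-test between two efficiency groups.

    Each group needs at least two non-missing values.  Two exactly constant
    groups are compared degenerately: equal means give p = 1, different
    means p = 0 (the zero-variance limit of the t statistic).
    """
    a = np.asarray([x for x in group_a if x is not None and not np.isnan(x)])
    b = np.asarray([x for x in group_b if x is not None and not np.isnan(x)])
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 non-missing values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "ns"
        return float("inf"), 0.0, "***"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), significance_stars(float(p))


# ---------------------------------------------------------------------------
# Expression


def fpkm(count: float, length_bp: float, total_mapped: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if length_bp <= 0 or total_mapped <= 0:
        raise ValueError("gene length and library size must be positive")
    return count * 1e9 / (length_bp * total_mapped)


def log_fold_change(
    fpkm_treated: float, fpkm_control: float, pseudo: float = 1.0
) -> float:
    """log2 ratio of pseudocounted FPKM values (treated over control)."""
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((fpkm_treated + pseudo) / (fpkm_control + pseudo)))


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    raw_count: int
    gene_length: int
    total_mapped: int
    fpkm: float
    logfc: float | None = None


@dataclass(frozen=True)
class QpcrRecord:
    """One relative-quantification result.

    ``ddct`` = (Ct_target - Ct_reference) under treatment minus the same
    difference under control; ``fold_change`` = 2^-ddct (conventional sign;
    set ``exponent_sign=+1`` to follow the unsigned-exponent notation).
    """

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float
    ddct: float
    fold_change: float


def ddct(
    ct_target_treated: float | Sequence[float],
    ct_reference_treated: float | Sequence[float],
    ct_target_control: float | Sequence[float],
    ct_reference_control: float | Sequence[float],
    exponent_sign: int = -1,
) -> QpcrRecord:
    """2^-ddCt relative expression; replicate Ct vectors are averaged on the
    Ct scale before differencing."""
    tt = float(np.mean(ct_target_treated))
    rt = float(np.mean(ct_reference_treated))
    tc = float(np.mean(ct_target_control))
    rc = float(np.mean(ct_reference_control))
    delta_delta = (tt - rt) - (tc - rc)
    fold = float(2.0 ** (exponent_sign * delta_delta))
    return QpcrRecord(tt, rt, tc, rc, delta_delta, fold)


def count_reads_per_gene(
    alignments: Iterable[AlignedRead], gene_models: Sequence[GeneModel]
) -> tuple[dict[str, int], int, int]:
    """Per-gene read counts with an ambiguity rule.

    A read counts for a gene iff its alignment overlaps the gene interval by
    at least 1 bp; reads overlapping two or more genes are discarded as
    ambiguous.  Returns (counts, unassigned, ambiguous).
    """
    genes = [g for g in gene_models if g.feature_kind == "gene"]
    if not genes:
        genes = [g for g in gene_models if g.feature_kind == "CDS"]
    counts = {g.gene_id: 0 for g in genes}
    unassigned = ambiguous = 0
    for read in alignments:
        start = read.position
        end = start + read.reference_span() - 1
        hits = {
            g.gene_id
            for g in genes
            if g.contig == read.contig and start <= g.end and end >= g.start
        }
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unassigned += 1
    return counts, unassigned, ambiguous


def expression_table(
    counts_by_sample: Mapping[str, Mapping[str, int]],
    gene_lengths: Mapping[str, int],
    pairs: Mapping[str, str] | None = None,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """FPKM (and LogFC against a paired control) per gene and sample.

    ``pairs`` maps a treated sample name to its control sample name; library
    size is the sample's total assigned count.
    """
    rows = []
    fpkm_cache: dict[tuple[str, str], float] = {}
    for sample, counts in counts_by_sample.items():
        total = sum(counts.values())
        for gene, count in counts.items():
            value = fpkm(count, gene_lengths[gene], total) if total else 0.0
            fpkm_cache[(sample, gene)] = value
            rows.append(
                {
                    "sample": sample, "gene_id": gene, "raw_count": count,
                    "gene_length": gene_lengths[gene], "total_mapped": total,
                    "fpkm": value,
                }
            )
    frame = pd.DataFrame(rows)
    if pairs:
        frame["logfc"] = [
            log_fold_change(
                row.fpkm, fpkm_cache[(pairs[row.sample], row.gene_id)], pseudo
            )
            if row.sample in pairs
            else np.nan
            for row in frame.itertuples()
        ]
    return frame
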