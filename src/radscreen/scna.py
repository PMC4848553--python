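"""Copy-number features from segmented profiles.

fSCNA — fraction of the measured genome carrying a copy-number
alteration: summed length of segments whose |log2 ratio| exceeds a
threshold (default 0.2, strict), divided by the summed length of all
segments measured. A surrogate for genomic instability.

Gene-level copy number — for each gene, the signed log2 ratio of the
overlapping segment with the maximum absolute segment mean; binarised
into amplification (> 0.7) and deletion (< -0.7) calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticalPreconditionError, ValidationError
from .io import GeneInterval, NamedMatrix, SegmentRecord

FSCNA_THRESHOLD = 0.2
AMP_THRESHOLD = 0.7
DEL_THRESHOLD = -0.7


@dataclass(frozen=True)
class FscnaResult:
    sample_id: str
    fscna: float
    altered_bp: int
    total_bp: int
    threshold: float = FSCNA_THRESHOLD


@dataclass(frozen=True)
class GeneLevelCNA:
    gene: str
    sample_id: str
    value: float

    @property
    def amp_call(self) -> bool:
        return self.value > AMP_THRESHOLD

    @property
    def del_call(self) -> bool:
        return self.value < DEL_THRESHOLD


def _check_no_overlap(segments: Sequence[SegmentRecord]) -> None:
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def fscna(
    segments: Sequence[SegmentRecord],
    threshold: float = FSCNA_THRESHOLD,
    sample_id: str | None = None,
) -> FscnaResult:
    """Fraction of measured genome altered: Σ len(|ratio| > threshold) / Σ len.

    The inequality is strict and applies to the amplitude (both gains and
    losses count). The denominator is the summed length of the segments
    present, not a fixed genome size.
    """
    if not segments:
        raise ValidationError("no segments")
    ids = {s.sample_id for s in segments}
    if sample_id is None:
        if len(ids) != 1:
            raise ValidationError(f"segments from multiple samples: {sorted(ids)}")
        sample_id = next(iter(ids))
    _check_no_overlap(segments)
    total = sum(s.length for s in segments)
    if total <= 0:
        raise ValidationError("zero total segment length")
    altered = sum(s.length for s in segments if abs(s.log2_ratio) > threshold)
    return FscnaResult(
        sample_id=sample_id,
        fscna=altered / total,
        altered_bp=altered,
        total_bp=total,
        threshold=threshold,
    )


def fscna_table(segments: Iterable[SegmentRecord], threshold: float = FSCNA_THRESHOLD) -> pd.DataFrame:
    """Per-sample fSCNA over a multi-sample segment list."""
    grouped: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        grouped.setdefault(s.sample_id, []).append(s)
    rows = [fscna(segs, threshold, sample_id=sid) for sid, segs in grouped.items()]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "fscna": [r.fscna for r in rows],
            "altered_bp": [r.altered_bp for r in rows],
            "total_bp": [r.total_bp for r in rows],
        }
    )


def gene_level_cna(
    segments: Sequence[SegmentRecord],
    gene_coordinates: Sequence[GeneInterval],
    sample_id: str | None = None,
) -> dict[str, GeneLevelCNA]:
    """Reduce a segment profile to per-gene signed values.

    value = log2 ratio of the overlapping segment maximising |log2 ratio|;
    ties break toward the segment with larger overlap, then the leftmost.
    Genes with no overlapping segment are absent from the result.
    """
    if not segments:
        raise ValidationError("no segments")
    ids = {s.sample_id for s in segments}
    if sample_id is None:
        if len(ids) != 1:
            raise ValidationError(f"segments from multiple samples: {sorted(ids)}")
        sample_id = next(iter(ids))
    _check_no_overlap(segments)
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
    out: dict[str, GeneLevelCNA] = {}
    for gene in gene_coordinates:
        best: tuple[float, int, int] | None = None  # (|ratio|, overlap, -start)
        best_value: float | None = None
        for seg in by_chrom.get(gene.chromosome, []):
            if seg.end <= gene.start:
                continue
            if seg.start >= gene.end:
                break
            overlap = min(seg.end, gene.end) - max(seg.start, gene.start)
            key = (abs(seg.log2_ratio), overlap, -seg.start)
            if best is None or key > best:
                best, best_value = key, seg.log2_ratio
        if best_value is not None:
            out[gene.gene] = GeneLevelCNA(gene=gene.gene, sample_id=sample_id, value=best_value)
    return out


def gene_level_cna_matrix(
    segments: Iterable[SegmentRecord],
    gene_coordinates: Sequence[GeneInterval],
) -> NamedMatrix:
    """Gene x sample matrix of gene-level copy number (NaN where no overlap)."""
    grouped: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        grouped.setdefault(s.sample_id, []).append(s)
    samples = list(grouped)
    genes = [g.gene for g in gene_coordinates]
    values = np.full((len(genes), len(samples)), np.nan)
    for j, sid in enumerate(samples):
        per_gene = gene_level_cna(grouped[sid], gene_coordinates, sample_id=sid)
        for i, g in enumerate(genes):
            if g in per_gene:
                values[i, j] = per_gene[g].value
    return NamedMatrix(row_ids=genes, column_ids=samples, values=values,
                       value_kind="copy_number")


def binarize_cna(
    gene_values: NamedMatrix,
    amp_threshold: float = AMP_THRESHOLD,
    del_threshold: float = DEL_THRESHOLD,
) -> tuple["BinaryFeatureMatrix", "BinaryFeatureMatrix", int]:
    """Binarise gene-level copy number into amp (> 0.7) and del (< -0.7) calls.

    Inequalities are strict; missing values become 0 and their count is
    returned alongside the two matrices.
    """
    from .association import BinaryFeatureMatrix

    v = gene_values.values
    n_missing = int(np.sum(~np.isfinite(v)))
    amp = (np.nan_to_num(v, nan=0.0) > amp_threshold).astype(np.int8)
    dele = (np.nan_to_num(v, nan=0.0) < del_threshold).astype(np.int8)
    amp_m = BinaryFeatureMatrix(
        feature_ids=[f"{g}_amp" for g in gene_values.row_ids],
        sample_ids=list(gene_values.column_ids),
        calls=amp,
    )
    del_m = BinaryFeatureMatrix(
        feature_ids=[f"{g}_del" for g in gene_values.row_ids],
        sample_ids=list(gene_values.column_ids),
        calls=dele,
    )
    return amp_m, del_m, n_missing


# ---------------------------------------------------------------------------
# segment-expression correlation and the direction contrast
# ---------------------------------------------------------------------------

def segment_expression_correlation(
    feature_segments: Mapping[str, tuple[str, Sequence[str]]],
    expression: NamedMatrix,
    phenotype: Mapping[str, float],
) -> pd.DataFrame:
    """Spearman correlation of in-segment gene expression with the phenotype.

    ``feature_segments`` maps a segment label to (group, gene list), where
    group tags the segment's direction/association class (e.g.
    "amplified_resistant"). Genes absent from the expression matrix or with
    constant expression are excluded and flagged in the table.
    """
    sample_ids = [s for s in expression.column_ids if s in phenotype]
    if len(sample_ids) < 3:
        raise StatisticalPreconditionError("need >=3 samples with phenotype")
    pheno = np.array([phenotype[s] for s in sample_ids])
    cols = [expression.column_ids.index(s) for s in sample_ids]
    rows = []
    for seg_label, (group, genes) in feature_segments.items():
        for gene in genes:
            if gene not in expression.row_ids:
                rows.append((seg_label, group, gene, np.nan, "absent"))
                continue
            expr = expression.values[expression.row_ids.index(gene)][cols]
            if np.all(expr == expr[0]):
                rows.append((seg_label, group, gene, np.nan, "constant"))
                continue
            rho = float(stats.spearmanr(expr, pheno).statistic)
            rows.append((seg_label, group, gene, rho, "ok"))
    return pd.DataFrame(rows, columns=["segment", "group", "gene", "spearman_rho", "status"])


def compare_direction_groups(
    grouped: Mapping[str, Sequence[float]],
    confidence_level: float = 0.95,
) -> pd.DataFrame:
    """One-way ANOVA plus all pairwise Tukey HSD intervals across groups.

    Returns a table with one row per pairwise contrast: group means,
    mean difference, Tukey-adjusted p and the confidence interval, with
    the overall ANOVA F and p repeated on every row.
    """
    names = list(grouped)
    values = [np.asarray(grouped[n], dtype=float) for n in names]
    if len(names) < 2 or any(v.size < 2 for v in values):
        raise StatisticalPreconditionError("need >=2 groups with >=2 values each")
    f_stat, f_p = stats.f_oneway(*values)
    tukey = stats.tukey_hsd(*values)
    ci = tukey.confidence_interval(confidence_level)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_a": float(np.mean(values[i])),
                    "mean_b": float(np.mean(values[j])),
                    "mean_diff": float(np.mean(values[i]) - np.mean(values[j])),
                    "tukey_p": float(tukey.pvalue[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "anova_f": float(f_stat),
                    "anova_p": float(f_p),
                }
            )
    return pd.DataFrame(rows)
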