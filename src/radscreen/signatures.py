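"""Single-sample gene-set projection (ssGSEA) and signature summary scores.

ssGSEA scores one sample's expression profile against one gene set as
the integrated (summed) difference between two empirical cumulative
distribution functions walked down the expression-ranked gene list: the
in-set ECDF is weighted by rank^alpha (alpha = 0.25 by default, ranks
descending so the top gene carries the largest weight), the out-of-set
ECDF is uniform. The score depends only on expression ranks, is positive
when set members concentrate among highly expressed genes and negative
when they concentrate at the bottom.

Signature summary scores follow a simpler median/SD recipe: each gene's
expression is normalised to standard deviations from the cohort median,
averaged over the signature's genes per sample, and the per-sample means
are re-normalised to SDs-from-median across the cohort; with several
signatures the summary is the average of the per-signature normalised
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticalPreconditionError, ValidationError
from .io import GeneSet, NamedMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_SET_SIZE = 5


@dataclass(frozen=True)
class SsgseaScore:
    set_name: str
    sample_id: str
    score: float
    n_set_genes_used: int


def ssgsea_score(
    expression: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    sample_id: str = "",
) -> SsgseaScore:
    """ssGSEA enrichment of one gene set in one sample's expression vector."""
    if isinstance(expression, Mapping):
        expression = pd.Series(expression, dtype=float)
    genes = expression.index.to_numpy()
    values = expression.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set.members))
    n_in = int(in_set.sum())
    if n_in < min_set_size:
        raise StatisticalPreconditionError(
            f"set {gene_set.name!r}: only {n_in} members in the expression "
            f"vector (minimum {min_set_size})"
        )
    if n_in == genes.size:
        raise ValidationError(f"set {gene_set.name!r} covers every gene; empty complement")
    score = _ssgsea_from_arrays(values, in_set, alpha)
    return SsgseaScore(
        set_name=gene_set.name, sample_id=sample_id, score=score, n_set_genes_used=n_in
    )


def _ssgsea_from_arrays(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    # rank weights: highest expression -> rank N (ties share the average rank)
    ranks = stats.rankdata(values, method="average")
    order = np.argsort(-values, kind="stable")  # walk from highest expression down
    in_ordered = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ordered, w, 0.0)
    denom_in = w_in.sum()
    ecdf_in = np.cumsum(w_in) / denom_in
    out_ordered = ~in_ordered
    ecdf_out = np.cumsum(out_ordered) / out_ordered.sum()
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_project(
    expression: NamedMatrix,
    collection: Sequence[GeneSet],
    alpha: float = DEFAULT_ALPHA,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> tuple[NamedMatrix, list[str]]:
    """Project a gene x sample matrix onto a gene-set collection.

    Returns a set x sample score matrix (rows in input set order) plus
    the names of rejected sets (too few members present). Raises when no
    set is admissible.
    """
    genes = np.asarray(expression.row_ids)
    rejected: list[str] = []
    admissible: list[tuple[GeneSet, np.ndarray]] = []
    for gs in collection:
        in_set = np.isin(genes, list(gs.members))
        n_in = int(in_set.sum())
        if n_in < min_set_size or n_in == genes.size:
            rejected.append(gs.name)
            logger.warning("gene set %s rejected (%d members usable)", gs.name, n_in)
            continue
        admissible.append((gs, in_set))
    if not admissible:
        raise StatisticalPreconditionError("no admissible gene set in the collection")
    scores = np.empty((len(admissible), len(expression.column_ids)))
    for j in range(len(expression.column_ids)):
        col = expression.values[:, j]
        for i, (_, in_set) in enumerate(admissible):
            scores[i, j] = _ssgsea_from_arrays(col, in_set, alpha)
    return (
        NamedMatrix(
            row_ids=[gs.name for gs, _ in admissible],
            column_ids=list(expression.column_ids),
            values=scores,
            value_kind="generic",
        ),
        rejected,
    )


# ---------------------------------------------------------------------------
# median/SD signature summary
# ---------------------------------------------------------------------------

@dataclass
class SignatureSummary:
    signature_name: str
    sample_ids: list[str]
    scores: np.ndarray                      # SDs-from-median units, median 0
    component_scores: pd.DataFrame | None = None  # per-signature breakdown

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.sample_ids, map(float, self.scores)))


def _normalized_signature_score(
    expression: NamedMatrix, genes: Sequence[str], signature_name: str
) -> np.ndarray:
    present = [g for g in genes if g in expression.row_ids]
    if not present:
        raise StatisticalPreconditionError(
            f"signature {signature_name!r}: no gene present in the matrix"
        )
    rows = np.array([expression.row_ids.index(g) for g in present])
    x = expression.values[rows]                         # genes x samples
    med = np.median(x, axis=1, keepdims=True)
    sd = np.std(x, axis=1, ddof=1, keepdims=True)
    usable = sd[:, 0] > 0
    if not usable.all():
        logger.warning(
            "signature %s: %d zero-SD genes excluded",
            signature_name, int((~usable).sum()),
        )
    if not usable.any():
        raise StatisticalPreconditionError(
            f"signature {signature_name!r}: all genes have zero SD"
        )
    z = (x[usable] - med[usable]) / sd[usable]
    per_sample = z.mean(axis=0)
    spread = np.std(per_sample, ddof=1)
    if spread == 0:
        raise StatisticalPreconditionError(
            f"signature {signature_name!r}: per-sample means are constant"
        )
    return (per_sample - np.median(per_sample)) / spread


def signature_summary(
    expression: NamedMatrix,
    signatures: Mapping[str, Sequence[str]],
    summary_name: str = "summary",
) -> SignatureSummary:
    """Median/SD-normalised signature score, averaged over signatures.

    Per gene: z = (x - median)/SD across samples. Per sample: mean z over
    the signature's genes, re-normalised to SDs-from-median across
    samples (so each signature's cohort median is exactly 0). With
    several signatures the summary is their per-sample average.
    """
    if len(expression.column_ids) < 2:
        raise StatisticalPreconditionError("signature scores need >=2 samples")
    if not signatures:
        raise ValidationError("no signatures supplied")
    per_sig = {
        name: _normalized_signature_score(expression, genes, name)
        for name, genes in signatures.items()
    }
    components = pd.DataFrame(per_sig, index=list(expression.column_ids))
    summary = components.to_numpy().mean(axis=1)
    return SignatureSummary(
        signature_name=summary_name,
        sample_ids=list(expression.column_ids),
        scores=summary,
        component_scores=components,
    )


def signature_vs_phenotype(
    summary: SignatureSummary,
    phenotype: Mapping[str, float],
    lineages: Mapping[str, str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Correlate signature activity with integral survival.

    Returns (pearson_r, r_squared, scatter table); the table carries the
    per-sample values (and lineage labels when given) for plotting or
    per-lineage stratification.
    """
    paired = [
        (s, score, phenotype[s])
        for s, score in zip(summary.sample_ids, summary.scores)
        if s in phenotype
    ]
    if len(paired) < 3:
        raise StatisticalPreconditionError(f"need >=3 paired samples, have {len(paired)}")
    table = pd.DataFrame(paired, columns=["sample_id", "signature_score", "phenotype"])
    if lineages is not None:
        table["lineage"] = [lineages.get(s, "") for s in table["sample_id"]]
    r = float(stats.pearsonr(table["signature_score"], table["phenotype"]).statistic)
    return r, r * r, table
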