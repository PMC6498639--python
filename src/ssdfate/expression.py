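"""Expression transforms, filtering, distances and tissue specificity.

All downstream comparisons work on log2(TPM+1) values.  Genes whose
transformed value is below 1 in every tissue are treated as transcriptional
noise and removed; retention is inclusive at the boundary (a gene with
log2(TPM+1) >= 1 in at least one tissue stays).

Tissue specificity is Yanai's index

    tau = sum_i (1 - x_i) / (N - 1)

with x_i the expression in tissue i normalised by the maximal value over
the N tissues: tau = 0 for uniform expression, 1 for single-tissue
expression.
"""

from __future__ import annotations

from typing import NamedTuple, Set, Union

import numpy as np

from .io import ExpressionMatrix, ExpressionProfile

__all__ = [
    "log_transform",
    "filter_low_expression",
    "euclidean_distance",
    "tissue_specificity_tau",
    "primary_tissue",
    "PrimaryTissue",
]

LOW_EXPRESSION_THRESHOLD = 1.0


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every TPM value v by log2(v+1); guards against double transform."""
    return matrix.log2p1()


def filter_low_expression(
    matrix: ExpressionMatrix, threshold: float = LOW_EXPRESSION_THRESHOLD
) -> Set[str]:
    """Genes retained by the low-expression filter (on a transformed matrix).

    A gene is retained iff its maximum over tissues of log2(TPM+1) is
    >= ``threshold``.
    """
    if not matrix.transformed:
        raise ValueError("filter operates on a log-transformed matrix")
    if len(matrix) == 0:
        return set()
    keep = matrix.data.max(axis=1) >= threshold
    return set(matrix.data.index[keep])


def _values(p: Union[ExpressionProfile, np.ndarray]) -> np.ndarray:
    return p.values if isinstance(p, ExpressionProfile) else np.asarray(p, dtype=float)


def _check_tissues(p, q) -> None:
    if isinstance(p, ExpressionProfile) and isinstance(q, ExpressionProfile):
        if p.tissues != q.tissues:
            raise ValueError(
                "tissue mismatch between %s and %s" % (p.gene, q.gene)
            )


def euclidean_distance(
    p: Union[ExpressionProfile, np.ndarray], q: Union[ExpressionProfile, np.ndarray]
) -> float:
    """Euclidean distance between two expression profiles over the same tissues."""
    _check_tissues(p, q)
    a, b = _values(p), _values(q)
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths: %d vs %d" % (a.size, b.size))
    return float(np.linalg.norm(a - b))


class TissueSpecificityResult(NamedTuple):
    gene: str
    tau: float


def tissue_specificity_tau(p: Union[ExpressionProfile, np.ndarray]) -> TissueSpecificityResult:
    """Tissue specificity index tau in [0, 1].

    Undefined (raises) for all-zero profiles and for fewer than two tissues.
    Invariant under multiplication of the profile by a positive scalar.
    """
    x = _values(p)
    gene = p.gene if isinstance(p, ExpressionProfile) else "<array>"
    if x.size < 2:
        raise ValueError("tau requires at least two tissues")
    m = x.max()
    if m <= 0:
        raise ValueError("tau undefined for all-zero profile %s" % gene)
    tau = float(np.sum(1.0 - x / m) / (x.size - 1))
    return TissueSpecificityResult(gene=gene, tau=tau)


class PrimaryTissue(NamedTuple):
    tissue: str
    tied: bool


def primary_tissue(p: ExpressionProfile) -> PrimaryTissue:
    """Tissue of maximal expression; exact ties resolve to the first tissue
    in canonical (input) order and are flagged."""
    x = p.values
    if x.max() <= 0:
        raise ValueError("primary tissue undefined for all-zero profile %s" % p.gene)
    idx = int(np.argmax(x))
    tied = bool(np.sum(x == x[idx]) > 1)
    return PrimaryTissue(tissue=p.tissues[idx], tied=tied)
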