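"""Retention-mechanism classification of duplicate gene trios.

The approach compares the expression profile of the single-copy ancestral
proxy gene (A, in the sister species) with the profiles of the parent (P)
and child (C) duplicate copies in the focal species, all on the
log2(TPM+1) scale.  Four Euclidean distances are computed per trio:
E_P,A, E_C,A and E_P+C,A (the combined duplicate profile vs the ancestor),
and the background distribution of distances between single-copy ortholog
pairs (E_S1,S2) calibrates a divergence cutoff E_div.  The rule table:

    E_P,A <= E_div and E_C,A <= E_div                      -> conservation
    exactly one of E_P,A, E_C,A exceeds E_div              -> neofunctionalization
                                                              (the exceeding copy is the diverged one)
    both exceed and E_P+C,A <= E_div                       -> subfunctionalization
    both exceed and E_P+C,A  > E_div                       -> specialization

The rules are exhaustive and mutually exclusive over non-negative
distances; "<= E_div" is the not-diverged side of every boundary.

The combined profile is formed by summing raw TPM of the two copies
before re-applying the log transform: abundances are additive on the raw
scale, and the combination correctly collapses to the parent profile when
the child is silent.

``RetentionModel`` bundles the data (trios plus the two species' raw TPM
matrices and the single-copy ortholog list); ``fit`` calibrates E_div at a
quantile of the ortholog-distance distribution (default q = 0.95, exposed
as primary configuration and recorded in the results) and classifies every
trio that passes the expression filter.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import (
    LOW_EXPRESSION_THRESHOLD,
    euclidean_distance,
    log_transform,
)
from .family import DuplicateTrio
from .io import ExpressionMatrix, ExpressionProfile

log = logging.getLogger(__name__)

__all__ = [
    "MECHANISMS",
    "CutoffModel",
    "RetentionCall",
    "ExcludedTrio",
    "compute_divergence_cutoff",
    "combine_profiles",
    "classify_retention",
    "RetentionModel",
    "RetentionResults",
]

MECHANISMS = (
    "conservation",
    "neofunctionalization",
    "subfunctionalization",
    "specialization",
)


@dataclass
class CutoffModel:
    """The single-copy divergence distribution and the cutoff E_div drawn from it."""

    distances: np.ndarray
    method: str = "quantile"
    q: float = 0.95
    e_div: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "q": self.q,
                "e_div": self.e_div,
                "n_pairs": int(self.distances.size),
                "distances": [round(float(d), 6) for d in self.distances],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CutoffModel":
        d = json.loads(text)
        return cls(
            distances=np.asarray(d["distances"], dtype=float),
            method=d["method"],
            q=d["q"],
            e_div=d["e_div"],
        )


def compute_divergence_cutoff(
    ortholog_pairs: Sequence[Tuple[ExpressionProfile, ExpressionProfile]],
    method: str = "quantile",
    q: float = 0.95,
    e_div: Optional[float] = None,
) -> CutoffModel:
    """Calibrate E_div from single-copy ortholog expression divergence.

    ``method='quantile'`` sets E_div to the empirical q-quantile of the
    E_S1,S2 distances; ``method='fixed'`` stores a user-supplied cutoff
    alongside the distribution.
    """
    if len(ortholog_pairs) == 0:
        raise ValueError("cannot calibrate a cutoff from an empty ortholog set")
    if len(ortholog_pairs) < 30:
        warnings.warn(
            "only %d ortholog pairs; the divergence cutoff will be noisy"
            % len(ortholog_pairs),
            stacklevel=2,
        )
    dist = np.array([euclidean_distance(p, s) for p, s in ortholog_pairs])
    return cutoff_from_distances(dist, method=method, q=q, e_div=e_div)


def cutoff_from_distances(
    distances: np.ndarray,
    method: str = "quantile",
    q: float = 0.95,
    e_div: Optional[float] = None,
) -> CutoffModel:
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distance distribution")
    if method == "quantile":
        if not 0 < q <= 1:
            raise ValueError("quantile q must lie in (0, 1], got %r" % q)
        e_div = float(np.quantile(distances, q))
    elif method == "fixed":
        if e_div is None:
            raise ValueError("method='fixed' requires an explicit e_div")
        e_div = float(e_div)
    else:
        raise ValueError("unknown cutoff method %r" % method)
    if e_div == 0:
        warnings.warn("divergence cutoff E_div is 0; every trio will look diverged", stacklevel=2)
    return CutoffModel(distances=distances, method=method, q=q, e_div=e_div)


def combine_profiles(parent: ExpressionProfile, child: ExpressionProfile) -> ExpressionProfile:
    """Combined duplicate profile: per tissue log2(TPM_P + TPM_C + 1).

    Inputs must be log2(TPM+1) profiles over the same tissues; raw TPM is
    recovered as 2**x - 1, summed, and re-transformed.  Symmetric in the
    two copies; an all-zero child leaves the parent profile unchanged.
    """
    if parent.tissues != child.tissues:
        raise ValueError("tissue mismatch between %s and %s" % (parent.gene, child.gene))
    if not (parent.log_scale and child.log_scale):
        raise ValueError("combine_profiles expects log-transformed profiles")
    tpm = (2.0 ** parent.values - 1.0) + (2.0 ** child.values - 1.0)
    return ExpressionProfile(
        gene="%s+%s" % (parent.gene, child.gene),
        tissues=parent.tissues,
        values=np.log2(tpm + 1.0),
        log_scale=True,
    )


def classify_retention(
    e_pa: float, e_ca: float, e_pca: float, e_div: float
) -> Tuple[str, Optional[str]]:
    """Apply the rule table; returns (mechanism, diverged copy).

    ``diverged`` is 'parent' or 'child' for neofunctionalization (the copy
    whose distance exceeds E_div) and None otherwise.
    """
    for name, v in (("e_pa", e_pa), ("e_ca", e_ca), ("e_pca", e_pca)):
        if v < 0 or not np.isfinite(v):
            raise ValueError("%s must be a finite non-negative distance, got %r" % (name, v))
    p_div = e_pa > e_div
    c_div = e_ca > e_div
    if not p_div and not c_div:
        return "conservation", None
    if p_div != c_div:
        return "neofunctionalization", "parent" if p_div else "child"
    if e_pca <= e_div:
        return "subfunctionalization", None
    return "specialization", None


@dataclass
class RetentionCall:
    trio_id: str
    parent: str
    child: str
    e_pa: float
    e_ca: float
    e_pca: float
    e_div: float
    mechanism: str
    diverged: Optional[str]  # 'parent' | 'child' | None
    age_class: Optional[int] = None

    @property
    def mechanism_detail(self) -> str:
        """Mechanism with the neofunctionalized copy spelled out."""
        if self.mechanism == "neofunctionalization":
            return "neofunctionalization_%s" % self.diverged
        return self.mechanism


@dataclass(frozen=True)
class ExcludedTrio:
    trio_id: str
    reason: str


class RetentionModel:
    """Retention-mechanism classifier for a batch of duplicate trios.

    Parameters
    ----------
    trios
        Polarised duplicate trios (parent/child set; unresolved trios are
        excluded at fit time).
    focal, sister
        Raw-TPM expression matrices for the focal species (carrying the
        duplicate copies) and the sister species (carrying the ancestral
        proxies).  The model applies the log2(TPM+1) transform itself so
        that raw abundances remain available for profile combination.
    ortholog_pairs
        (focal gene, sister gene) single-copy ortholog pairs used to
        calibrate E_div.
    """

    def __init__(
        self,
        trios: Sequence[DuplicateTrio],
        focal: ExpressionMatrix,
        sister: ExpressionMatrix,
        ortholog_pairs: Sequence[Tuple[str, str]],
    ):
        if focal.tissues != sister.tissues:
            raise ValueError("focal and sister matrices must share the tissue list")
        self.trios = list(trios)
        self.focal_raw = focal
        self.sister_raw = sister
        self.ortholog_pairs = list(ortholog_pairs)
        if focal.transformed or sister.transformed:
            raise ValueError("supply raw TPM matrices; the model transforms internally")
        self.focal = log_transform(focal)
        self.sister = log_transform(sister)

    def fit(
        self,
        q: float = 0.95,
        method: str = "quantile",
        e_div: Optional[float] = None,
        expression_threshold: float = LOW_EXPRESSION_THRESHOLD,
    ) -> "RetentionResults":
        """Calibrate E_div and classify every admissible trio."""
        pairs = []
        for fg, sg in self.ortholog_pairs:
            if fg in self.focal and sg in self.sister:
                pairs.append((self.focal.profile(fg), self.sister.profile(sg)))
        cutoff = compute_divergence_cutoff(pairs, method=method, q=q, e_div=e_div)

        calls: List[RetentionCall] = []
        excluded: List[ExcludedTrio] = []
        for trio in self.trios:
            if trio.parent is None or trio.child is None:
                excluded.append(ExcludedTrio(trio.trio_id, "unresolved polarity"))
                continue
            missing = [
                g
                for g, m in (
                    (trio.parent, self.focal),
                    (trio.child, self.focal),
                    (trio.ancestral_gene, self.sister),
                )
                if g not in m
            ]
            if missing:
                excluded.append(
                    ExcludedTrio(trio.trio_id, "missing from expression matrix: %s" % ",".join(missing))
                )
                continue
            p = self.focal.profile(trio.parent)
            c = self.focal.profile(trio.child)
            a = self.sister.profile(trio.ancestral_gene)
            if min(p.values.max(), c.values.max(), a.values.max()) < expression_threshold:
                excluded.append(ExcludedTrio(trio.trio_id, "lowly expressed"))
                continue
            e_pa = euclidean_distance(p, a)
            e_ca = euclidean_distance(c, a)
            e_pca = euclidean_distance(combine_profiles(p, c), a)
            mech, diverged = classify_retention(e_pa, e_ca, e_pca, cutoff.e_div)
            calls.append(
                RetentionCall(
                    trio_id=trio.trio_id,
                    parent=trio.parent,
                    child=trio.child,
                    e_pa=e_pa,
                    e_ca=e_ca,
                    e_pca=e_pca,
                    e_div=cutoff.e_div,
                    mechanism=mech,
                    diverged=diverged,
                    age_class=trio.age_class,
                )
            )
        return RetentionResults(self, cutoff, calls, excluded)


class RetentionResults:
    """Classification results: calls, exclusions and the calibrated cutoff."""

    def __init__(
        self,
        model: RetentionModel,
        cutoff: CutoffModel,
        calls: List[RetentionCall],
        excluded: List[ExcludedTrio],
    ):
        self.model = model
        self.cutoff = cutoff
        self.calls = calls
        self.excluded = excluded

    @property
    def e_div(self) -> float:
        return self.cutoff.e_div

    def calls_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trio_id": c.trio_id,
                "parent": c.parent,
                "child": c.child,
                "E_PA": c.e_pa,
                "E_CA": c.e_ca,
                "E_PCA": c.e_pca,
                "E_div": c.e_div,
                "mechanism": c.mechanism,
                "diverged": c.diverged or "",
                "age_class": c.age_class,
            }
            for c in self.calls
        ]
        return pd.DataFrame(rows)

    def counts(self) -> pd.Series:
        """Trio counts per mechanism, neofunctionalization split by diverged copy."""
        idx = [
            "conservation",
            "neofunctionalization_parent",
            "neofunctionalization_child",
            "subfunctionalization",
            "specialization",
        ]
        out = pd.Series(0, index=idx, dtype=int)
        for c in self.calls:
            out[c.mechanism_detail] += 1
        return out

    def confusion(self, truth: Mapping[str, str]) -> pd.DataFrame:
        """Confusion matrix (rows: true mechanism, columns: called) over
        classified trios with a truth label."""
        mat = pd.DataFrame(0, index=list(MECHANISMS), columns=list(MECHANISMS), dtype=int)
        for c in self.calls:
            t = truth.get(c.trio_id)
            if t is not None:
                mat.loc[t, c.mechanism] += 1
        return mat

    def recall(self, truth: Mapping[str, str]) -> pd.Series:
        mat = self.confusion(truth)
        totals = mat.sum(axis=1)
        with np.errstate(invalid="ignore"):
            rec = pd.Series(np.diag(mat) / totals.to_numpy(), index=mat.index)
        return rec

    def summary(self) -> str:
        counts = self.counts()
        n = counts.sum()
        lines = [
            "Retention-mechanism classification",
            "=" * 50,
            "Trios classified: %5d    excluded: %d" % (n, len(self.excluded)),
            "E_div = %.4f  (%s, q=%.2f, %d ortholog pairs)"
            % (self.e_div, self.cutoff.method, self.cutoff.q, self.cutoff.distances.size),
            "-" * 50,
        ]
        for mech, cnt in counts.items():
            pct = 100.0 * cnt / n if n else 0.0
            lines.append("%-28s %5d  (%5.1f%%)" % (mech, cnt, pct))
        lines.append("=" * 50)
        return "\n".join(lines)
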