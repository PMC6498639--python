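"""End-to-end orchestration: polarity -> classification -> mechanism -> stats.

``run_pipeline`` wires the library stages together for in-memory inputs;
``run_synthetic`` generates a synthetic dataset, runs the pipeline on it,
and scores the results against the generator's truth table.
"""

from __future__ import annotations

import io as _io
import logging
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as st
from .classify import RetentionModel, RetentionResults
from .expression import filter_low_expression, log_transform, primary_tissue
from .family import DuplicateTrio
from .io import ExpressionMatrix, OrthologEvidence, count_exons
from .mechanism import MechanismCall, call_mechanisms
from .polarity import PolarityCall, polarize_trios
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_synthetic", "evaluate_against_truth"]


@dataclass
class PipelineResult:
    polarity_calls: List[PolarityCall]
    retention: RetentionResults
    mechanism_calls: List[MechanismCall]
    mechanism_skipped: List[str]
    mechanism_table: pd.DataFrame
    mechanism_tests: List[st.EnrichmentResult]
    age_class_tests: List[st.EnrichmentResult]
    tissue_tests: List[st.BinomialEnrichment]
    correlations: List[st.CorrelationResult]
    n_unknown_mechanism: int = 0

    def run_summary(self) -> Dict:
        """JSON-serialisable summary of the run."""
        ret = self.retention
        return {
            "e_div": ret.e_div,
            "cutoff_method": ret.cutoff.method,
            "cutoff_q": ret.cutoff.q,
            "n_ortholog_pairs": int(ret.cutoff.distances.size),
            "n_classified": len(ret.calls),
            "n_excluded": len(ret.excluded),
            "n_unresolved_polarity": sum(1 for c in self.polarity_calls if not c.resolved),
            "retention_counts": {k: int(v) for k, v in ret.counts().items()},
            "n_unknown_duplication_mechanism": self.n_unknown_mechanism,
            "mechanism_tests": [
                {
                    "mechanism": r.label,
                    "observed": [int(v) for v in r.observed],
                    "expected": [round(float(v), 2) for v in r.expected],
                    "chi2": round(r.chi2, 4),
                    "p": round(r.p, 4),
                }
                for r in self.mechanism_tests
            ],
            "tissue_tests": [
                {
                    "tissue": r.tissue,
                    "observed": r.successes,
                    "expected": round(r.expected, 2),
                    "direction": r.direction,
                    "p": r.p,
                    "p_adjusted": r.p_adjusted,
                }
                for r in self.tissue_tests
            ],
            "correlations": [
                {"pair": c.label, "r": round(c.r, 4), "n": c.n, "t": round(c.t, 4), "p": c.p}
                for c in self.correlations
            ],
        }


def _mechanism_by_retention(
    retention: RetentionResults, mech_calls: Sequence[MechanismCall]
) -> Tuple[pd.DataFrame, int]:
    """Observed retention-mechanism x DNA/RNA table; unknown pairs excluded."""
    mech_of = {m.pair_id: m.mechanism for m in mech_calls}
    rows = [
        "conservation",
        "neofunctionalization_parent",
        "neofunctionalization_child",
        "subfunctionalization",
        "specialization",
    ]
    table = pd.DataFrame(0, index=rows, columns=["DNA", "RNA"], dtype=int)
    n_unknown = 0
    for call in retention.calls:
        m = mech_of.get(call.trio_id)
        if m is None:
            continue
        if m == "unknown":
            n_unknown += 1
            continue
        table.loc[call.mechanism_detail, m] += 1
    return table, n_unknown


def run_pipeline(
    trios: Sequence[DuplicateTrio],
    focal: ExpressionMatrix,
    sister: ExpressionMatrix,
    ortholog_pairs: Sequence[Tuple[str, str]],
    evidence: Sequence[OrthologEvidence],
    gff3_text: Optional[str] = None,
    gff3_path=None,
    divergence: Optional[pd.DataFrame] = None,
    q: float = 0.95,
    e_div: Optional[float] = None,
) -> PipelineResult:
    """Run polarity, retention classification, mechanism calls and statistics."""
    polarity_calls = polarize_trios(trios, evidence)
    model = RetentionModel(trios, focal, sister, ortholog_pairs)
    method = "fixed" if e_div is not None else "quantile"
    retention = model.fit(q=q, method=method, e_div=e_div)

    # duplication mechanism from exon counts
    mech_calls: List[MechanismCall] = []
    mech_skipped: List[str] = []
    if gff3_text is not None or gff3_path is not None:
        if gff3_path is None:
            with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
                fh.write(gff3_text)
                gff3_path = fh.name
        gene_ids = [g for t in trios for g in t.copies]
        exons = count_exons(gff3_path, gene_ids)
        mech_calls, mech_skipped = call_mechanisms(trios, exons)

    mech_table, n_unknown = _mechanism_by_retention(retention, mech_calls)
    tested = mech_table.loc[mech_table.sum(axis=1) > 0]
    # the enrichment contrast needs every category represented somewhere
    if len(tested) and (tested.sum(axis=0) > 0).all():
        mech_tests = st.row_enrichment_tests(tested)
    else:
        mech_tests = []

    # age classes
    try:
        age_tests = st.age_class_test(retention.calls)
    except ValueError:
        age_tests = []

    # tissue enrichment: duplicates vs single-copy genes of the focal species
    dup_genes = {g for t in trios for g in t.copies}
    tissue_tests: List[st.BinomialEnrichment] = []
    logf = log_transform(focal)
    expressed = filter_low_expression(logf)
    dup_primary: Dict[str, int] = {t: 0 for t in focal.tissues}
    sc_primary: Dict[str, int] = {t: 0 for t in focal.tissues}
    for gene in expressed:
        tissue = primary_tissue(logf.profile(gene)).tissue
        (dup_primary if gene in dup_genes else sc_primary)[tissue] += 1
    if sum(dup_primary.values()) and sum(sc_primary.values()):
        tissue_tests = st.tissue_enrichment(dup_primary, sc_primary)

    # divergence correlations (one record per duplicate copy, Ks < 3)
    correlations: List[st.CorrelationResult] = []
    if divergence is not None and len(divergence):
        usable = st.filter_saturated(divergence)
        for col, label in (("ka", "Ka"), ("ks", "Ks"), ("ka_ks", "Ka/Ks")):
            correlations.append(
                st.pearson_test(
                    usable["expression_divergence"], usable[col],
                    label="expression_divergence~%s" % label,
                )
            )

    return PipelineResult(
        polarity_calls=polarity_calls,
        retention=retention,
        mechanism_calls=mech_calls,
        mechanism_skipped=mech_skipped,
        mechanism_table=mech_table,
        mechanism_tests=mech_tests,
        age_class_tests=age_tests,
        tissue_tests=tissue_tests,
        correlations=correlations,
        n_unknown_mechanism=n_unknown,
    )


def evaluate_against_truth(result: PipelineResult, dataset: SyntheticDataset) -> Dict:
    """Score pipeline output against the generator's truth table."""
    truth = dataset.truth
    retention = result.retention
    recall = retention.recall(truth.mechanism)
    confusion = retention.confusion(truth.mechanism)

    trio_by_id = {t.trio_id: t for t in dataset.trios}
    n_pol = n_pol_correct = 0
    for call in result.polarity_calls:
        if not call.resolved:
            continue
        true_parent = truth.parent.get(call.pair_id)
        if true_parent is None:
            continue
        n_pol += 1
        n_pol_correct += int(call.parent == true_parent)

    mech_truth = truth.duplication_mechanism
    n_mech = n_mech_correct = 0
    for m in result.mechanism_calls:
        t = mech_truth.get(m.pair_id)
        if t is None:
            continue
        n_mech += 1
        n_mech_correct += int(m.mechanism == t)

    # diverged-copy agreement among correctly-called neofunctionalization trios
    n_div = n_div_correct = 0
    for c in retention.calls:
        if c.mechanism != "neofunctionalization":
            continue
        true_div = truth.diverged_copy.get(c.trio_id)
        if true_div is None:
            continue
        n_div += 1
        called_gene = c.parent if c.diverged == "parent" else c.child
        n_div_correct += int(called_gene == true_div)

    return {
        "recall": recall.to_dict(),
        "confusion": confusion,
        "polarity_accuracy": n_pol_correct / n_pol if n_pol else float("nan"),
        "n_polarized": n_pol,
        "mechanism_accuracy": n_mech_correct / n_mech if n_mech else float("nan"),
        "diverged_copy_accuracy": n_div_correct / n_div if n_div else float("nan"),
        "n_classified": len(retention.calls),
    }


def run_synthetic(cfg: Optional[SimulationConfig] = None) -> Tuple[SyntheticDataset, PipelineResult, Dict]:
    """Generate, run, and score the default synthetic study."""
    cfg = cfg or SimulationConfig()
    dataset = simulate_dataset(cfg)
    result = run_pipeline(
        trios=dataset.trios,
        focal=dataset.focal,
        sister=dataset.sister,
        ortholog_pairs=dataset.ortholog_pairs,
        evidence=dataset.evidence,
        gff3_text=dataset.gff3_text,
        divergence=dataset.divergence,
    )
    scores = evaluate_against_truth(result, dataset)
    return dataset, result, scores
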