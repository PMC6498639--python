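"""Enrichment and correlation statistics for the duplicate-gene analyses.

Expected counts for a mechanism x category table are built from the
pooled category proportions: expected[row, cat] = row_total *
column_total / grand_total, so each row's expectation preserves its
observed total.  Each row is then tested against its expectation with a
chi-square goodness-of-fit statistic (no continuity correction,
df = cells - 1).  Tissue enrichment of duplicate primary tissues uses an
exact two-tailed binomial test per tissue (small-probability-outcome
convention), Bonferroni-adjusted over the number of tissues tested.
Pearson correlations between expression divergence and sequence
divergence (Ka, Ks, Ka/Ks) are assessed with Student's t with
t = r * sqrt(n-2) / sqrt(1-r^2); records with Ks >= 3 are dropped first
to avoid saturation at synonymous sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "CorrelationResult",
    "BinomialEnrichment",
    "PooledSummary",
    "expected_counts",
    "chi_square_gof",
    "row_enrichment_tests",
    "age_class_test",
    "pearson_test",
    "tissue_enrichment",
    "pooled_summary",
    "filter_saturated",
    "null_rejection_rate",
]

KS_SATURATION = 3.0


@dataclass
class EnrichmentResult:
    label: str
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    p_adjusted: Optional[float] = None


@dataclass
class CorrelationResult:
    label: str
    r: float
    n: int
    t: float
    p: float


@dataclass
class BinomialEnrichment:
    tissue: str
    successes: int
    trials: int
    p_null: float
    expected: float
    direction: int  # +1 over-, -1 under-represented, 0 at expectation
    p: float
    p_adjusted: float


def expected_counts(observed: pd.DataFrame) -> pd.DataFrame:
    """Expected table under independence of row and column labels.

    Rows are retention mechanisms (or age classes), columns categories
    (e.g. DNA-/RNA-mediated).  Row totals are preserved exactly; columns
    sum to the observed column totals.
    """
    arr = observed.to_numpy(dtype=float)
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("observed table must contain non-negative integers")
    grand = arr.sum()
    if grand == 0:
        raise ValueError("observed table is empty (grand total 0)")
    row_tot = arr.sum(axis=1, keepdims=True)
    col_prop = arr.sum(axis=0, keepdims=True) / grand
    return pd.DataFrame(
        row_tot * col_prop, index=observed.index, columns=observed.columns
    )


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float]
) -> Tuple[float, int, float]:
    """Chi-square goodness of fit: sum (o-e)^2/e, df = cells - 1, upper-tail P.

    No continuity correction is applied.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1:
        raise ValueError("observed and expected must be 1-d vectors of equal length")
    if np.any(e <= 0):
        raise ValueError(
            "expected counts must be positive in every cell; pool or drop "
            "empty categories before testing"
        )
    chi2 = float(np.sum((o - e) ** 2 / e))
    df = o.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def row_enrichment_tests(observed: pd.DataFrame) -> List[EnrichmentResult]:
    """Per-row chi-square tests of an observed table against pooled expectations."""
    expected = expected_counts(observed)
    out = []
    for label in observed.index:
        o = observed.loc[label].to_numpy(dtype=float)
        e = expected.loc[label].to_numpy(dtype=float)
        chi2, df, p = chi_square_gof(o, e)
        out.append(EnrichmentResult(str(label), o, e, chi2, df, p))
    return out


def age_class_test(calls: Sequence) -> List[EnrichmentResult]:
    """Mechanism-by-age-class enrichment: one chi-square per mechanism row.

    ``calls`` are RetentionCalls carrying ``age_class``; empty age classes
    are dropped with a warning, and at least two populated classes are
    required.
    """
    rows: Dict[str, Dict[int, int]] = {}
    classes = set()
    for c in calls:
        if c.age_class is None:
            continue
        rows.setdefault(c.mechanism, {}).setdefault(c.age_class, 0)
        rows[c.mechanism][c.age_class] += 1
        classes.add(c.age_class)
    classes = sorted(classes)
    if len(classes) < 2:
        raise ValueError("age-class test requires at least two populated age classes")
    table = pd.DataFrame(
        [[rows[m].get(k, 0) for k in classes] for m in rows],
        index=list(rows),
        columns=classes,
    )
    empty = [k for k in classes if table[k].sum() == 0]
    if empty:
        warnings.warn("dropping empty age class(es) %s" % empty, stacklevel=2)
        table = table.drop(columns=empty)
    return row_enrichment_tests(table)


def pearson_test(x: Sequence[float], y: Sequence[float], label: str = "") -> CorrelationResult:
    """Pearson correlation with a two-sided Student's t test (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson test requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        t = float(np.inf) * np.sign(r)
    else:
        t = float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r))
    return CorrelationResult(label=label, r=r, n=n, t=t, p=float(p))


def filter_saturated(records: pd.DataFrame, ks_column: str = "ks") -> pd.DataFrame:
    """Drop divergence records with Ks >= 3 (synonymous-site saturation)."""
    return records[records[ks_column] < KS_SATURATION].copy()


def tissue_enrichment(
    duplicate_counts: Mapping[str, int],
    single_copy_counts: Mapping[str, int],
) -> List[BinomialEnrichment]:
    """Exact two-tailed binomial tissue enrichment, Bonferroni-adjusted.

    Per tissue: trials = total duplicates, successes = duplicates whose
    primary tissue is the tissue of interest, success probability = the
    tissue's frequency among single-copy genes.  The two-tailed P sums the
    probabilities of all outcomes no more likely than the observed one.
    The Bonferroni factor is the number of tissues tested.
    """
    tissues = list(duplicate_counts)
    if set(tissues) != set(single_copy_counts):
        raise ValueError("duplicate and single-copy counts must cover the same tissues")
    n = int(sum(duplicate_counts.values()))
    sc_total = int(sum(single_copy_counts.values()))
    if n == 0 or sc_total == 0:
        raise ValueError("empty primary-tissue counts")
    m = len(tissues)
    out = []
    for tissue in tissues:
        k = int(duplicate_counts[tissue])
        p_null = single_copy_counts[tissue] / sc_total
        if p_null == 0 and k > 0:
            warnings.warn(
                "tissue %s has zero single-copy frequency but %d duplicates" % (tissue, k),
                stacklevel=2,
            )
        if p_null in (0.0, 1.0):
            p = 0.0 if (k > 0) == (p_null == 0.0) else 1.0
        else:
            p = float(sps.binomtest(k, n, p_null, alternative="two-sided").pvalue)
        expected = n * p_null
        out.append(
            BinomialEnrichment(
                tissue=tissue,
                successes=k,
                trials=n,
                p_null=p_null,
                expected=expected,
                direction=int(np.sign(k - expected)),
                p=p,
                p_adjusted=min(1.0, p * m),
            )
        )
    return out


@dataclass
class PooledSummary:
    percentages: Dict[str, float]  # mechanism -> pooled %, 1 decimal
    child_bias: Dict[str, int]  # species -> % of neofunctionalized genes that are children
    totals: Dict[str, int]


RETENTION_COLUMNS = (
    "conservation",
    "neofunctionalization_parent",
    "neofunctionalization_child",
    "subfunctionalization",
    "specialization",
)


def pooled_summary(counts: pd.DataFrame) -> PooledSummary:
    """Pool per-species retention counts into overall percentages.

    ``counts``: one row per species with the five retention columns
    (neofunctionalization split into parent/child).  An optional
    ``neofunctionalization`` total column is validated against the split.
    Percentages are rounded to one decimal; per-species child bias
    (children / all neofunctionalized) to the nearest percent.
    """
    missing = [c for c in RETENTION_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError("retention counts missing columns %s" % missing)
    arr = counts[list(RETENTION_COLUMNS)].to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative retention counts")
    if arr.sum() == 0:
        raise ValueError("all-zero retention counts")
    if "neofunctionalization" in counts.columns:
        neo = counts["neofunctionalization_parent"] + counts["neofunctionalization_child"]
        if not (neo == counts["neofunctionalization"]).all():
            raise ValueError("parent+child does not match the neofunctionalization total")

    tot = counts[list(RETENTION_COLUMNS)].sum()
    grand = float(tot.sum())
    pooled = {
        "conservation": tot["conservation"],
        "neofunctionalization": tot["neofunctionalization_parent"]
        + tot["neofunctionalization_child"],
        "subfunctionalization": tot["subfunctionalization"],
        "specialization": tot["specialization"],
    }
    percentages = {k: round(100.0 * v / grand, 1) for k, v in pooled.items()}
    child_bias = {}
    for sp, row in counts.iterrows():
        neo_tot = row["neofunctionalization_parent"] + row["neofunctionalization_child"]
        if neo_tot > 0:
            child_bias[str(sp)] = int(round(100.0 * row["neofunctionalization_child"] / neo_tot))
    return PooledSummary(
        percentages=percentages,
        child_bias=child_bias,
        totals={k: int(v) for k, v in pooled.items()},
    )


def null_rejection_rate(
    n_tables: int = 2000,
    row_total: int = 500,
    p: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the chi-square goodness-of-fit test under a simulated null.

    Category labels (e.g. DNA/RNA) are drawn independently of the row
    label with known probability ``p``; each table row is tested against
    its true expectation.  Expected counts use the generating proportion
    rather than a pooled plug-in estimate so the statistic's nominal
    chi-square(1) calibration is what is being checked.
    """
    rng = np.random.default_rng(seed)
    k = rng.binomial(row_total, p, size=n_tables).astype(float)
    e1, e0 = row_total * p, row_total * (1 - p)
    chi2 = (k - e1) ** 2 / e1 + ((row_total - k) - e0) ** 2 / e0
    crit = sps.chi2.isf(alpha, df=1)
    return float(np.mean(chi2 > crit))
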