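"""Readers and writers for the external formats the pipeline touches.

Expression matrices, gene-family size tables, ortholog-evidence tables and
sequence-divergence tables travel as tab-delimited text with a header row;
trees as Newick; genome annotation as GFF3.  Validation happens on read so
that downstream modules can assume canonical, well-formed containers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import gffutils
import numpy as np
import pandas as pd

from .tree import SpeciesTree

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ExpressionProfile",
    "FamilyTable",
    "OrthologEvidence",
    "read_expression_matrix",
    "read_family_table",
    "read_ortholog_evidence",
    "read_tree",
    "count_exons",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's abundance vector over named tissues.

    ``values`` is raw TPM when ``log_scale`` is False and log2(TPM+1)
    otherwise; entries are non-negative on either scale.
    """

    gene: str
    tissues: Tuple[str, ...]
    values: np.ndarray
    log_scale: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.tissues),):
            raise ValueError(
                "profile %s: %d values for %d tissues"
                % (self.gene, self.values.size, len(self.tissues))
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("profile %s: negative or non-finite value" % self.gene)


class ExpressionMatrix:
    """Genes x tissues abundance matrix for one species.

    Wraps a pandas DataFrame (index: gene ids, columns: tissue labels).
    ``transformed`` records whether values are log2(TPM+1); constructors
    validate non-negativity, unique gene ids and unique tissue labels.
    Missing values are treated as 0 TPM (the "not expressed" reading) with
    a logged warning.
    """

    def __init__(self, data: pd.DataFrame, species: str, transformed: bool = False):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError("duplicate gene id(s) in %s matrix: %s" % (species, dup))
        if data.columns.duplicated().any():
            raise ValueError("duplicate tissue label(s) in %s matrix" % species)
        if data.isna().any().any():
            n = int(data.isna().sum().sum())
            log.warning("%s matrix: %d missing values treated as 0 TPM", species, n)
            data = data.fillna(0.0)
        values = data.to_numpy(dtype=float, copy=False)
        if np.any(values < 0):
            bad = data.index[(data < 0).any(axis=1)][0]
            raise ValueError(
                "negative expression value in %s matrix (gene %s)" % (species, bad)
            )
        self.data = data.astype(float)
        self.species = species
        self.transformed = transformed

    # -- construction ------------------------------------------------
    @classmethod
    def from_tsv(cls, path, species: str, transformed: bool = False) -> "ExpressionMatrix":
        try:
            # round_trip parsing keeps write/read cycles bit-exact
            df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise ValueError("malformed expression TSV %s: %s" % (path, exc)) from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            raise ValueError("non-numeric expression value in %s" % path)
        return cls(df, species=species, transformed=transformed)

    def to_tsv(self, path) -> None:
        # %.17g keeps the write/read round trip bit-exact
        self.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")

    # -- access ------------------------------------------------------
    @property
    def tissues(self) -> List[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def profile(self, gene: str) -> ExpressionProfile:
        if gene not in self.data.index:
            raise KeyError("gene %r not in %s matrix" % (gene, self.species))
        return ExpressionProfile(
            gene=gene,
            tissues=tuple(self.data.columns),
            values=self.data.loc[gene].to_numpy(dtype=float),
            log_scale=self.transformed,
        )

    def log2p1(self) -> "ExpressionMatrix":
        """Return a log2(TPM+1)-transformed copy; refuses to double-transform."""
        if self.transformed:
            raise ValueError("matrix for %s is already log-transformed" % self.species)
        out = ExpressionMatrix(np.log2(self.data + 1.0), self.species, transformed=True)
        return out


@dataclass
class FamilyTable:
    """Gene-family sizes: family id -> per-species copy number."""

    counts: pd.DataFrame  # index: family id, columns: species, int

    def __post_init__(self):
        df = self.counts
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0):
            raise ValueError("family counts must be non-negative integers")
        if np.any(arr != np.floor(arr)):
            raise ValueError("family counts must be integers")
        self.counts = df.astype(int)

    @property
    def species(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> List[str]:
        return list(self.counts.index.astype(str))

    def row(self, family: str) -> Dict[str, int]:
        return self.counts.loc[family].to_dict()

    @classmethod
    def from_tsv(cls, path) -> "FamilyTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family")


@dataclass
class OrthologEvidence:
    """One source's gene-to-ortholog mapping between two species.

    ``priority``: lower rank = higher priority when sources conflict.
    ``pairs`` maps a focal-species gene to the set of sister-species genes
    the source links it to.
    """

    source: str
    priority: int
    pairs: Dict[str, Set[str]] = field(default_factory=dict)

    def links(self, gene: str, other: str) -> bool:
        return other in self.pairs.get(gene, ())

    def add(self, gene: str, other: str) -> None:
        self.pairs.setdefault(gene, set()).add(other)

    @classmethod
    def from_tsv(cls, path, source: str, priority: int) -> "OrthologEvidence":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("evidence TSV %s needs two gene columns" % path)
        ev = cls(source=source, priority=priority)
        for a, b in df.iloc[:, :2].itertuples(index=False):
            ev.add(str(a), str(b))
        return ev

    def to_tsv(self, path) -> None:
        rows = [(g, o) for g, os_ in sorted(self.pairs.items()) for o in sorted(os_)]
        pd.DataFrame(rows, columns=["gene", "ortholog"]).to_csv(
            path, sep="\t", index=False
        )


def validate_evidence_priorities(evidence: Sequence[OrthologEvidence]) -> None:
    ranks = [e.priority for e in evidence]
    if len(set(ranks)) != len(ranks):
        raise ValueError("evidence priority ranks must be unique: %s" % ranks)


# -- module-level reader functions ------------------------------------

def read_expression_matrix(path, species: str) -> ExpressionMatrix:
    """Read a genes x tissues TPM table (TSV, header row of tissue labels)."""
    return ExpressionMatrix.from_tsv(path, species=species)


def read_family_table(path) -> FamilyTable:
    return FamilyTable.from_tsv(path)


def read_ortholog_evidence(path, source: str, priority: int) -> OrthologEvidence:
    return OrthologEvidence.from_tsv(path, source=source, priority=priority)


def read_tree(path, family_table: Optional[FamilyTable] = None) -> SpeciesTree:
    """Read a rooted Newick tree; optionally validate leaves against a family table."""
    tree = SpeciesTree.from_newick(str(path), is_path=True)
    if family_table is not None:
        tree.validate_leaves(family_table.species)
    return tree


def count_exons(path, gene_ids: Sequence[str]) -> Dict[str, Optional[int]]:
    """Exon count of the representative transcript for each gene in a GFF3 file.

    The representative transcript is the mRNA with the most exons; ties are
    broken toward the longest genomic span.  Genes absent from the
    annotation map to ``None`` rather than raising.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: Dict[str, Optional[int]] = {}
    for gid in gene_ids:
        try:
            gene = db[gid]
        except gffutils.FeatureNotFoundError:
            out[gid] = None
            continue
        best: Optional[Tuple[int, int]] = None  # (exons, span)
        for mrna in db.children(gene, featuretype="mRNA"):
            n = sum(1 for _ in db.children(mrna, featuretype="exon"))
            span = mrna.end - mrna.start + 1
            if best is None or (n, span) > best:
                best = (n, span)
        out[gid] = best[0] if best else None
    return out
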