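"""Synthetic-data generation with known truth for every pipeline stage.

The generator emulates the statistical structure of the real inputs —
two sister species' nine-tissue TPM matrices with correlated single-copy
ortholog expression, duplicate trios planted under each of the four
retention mechanisms, gene-family size evolution by gains and losses
along a species tree, minimal GFF3 annotation with a controllable
RNA-mediated (single-exon child) fraction, corrupted ortholog evidence,
and Ka/Ks values correlated with realized expression divergence.

Expression model
----------------
Ancestral profiles are sparse log-normal mixtures: per-gene total
abundance is log-normal and spread over tissues with Dirichlet weights
whose concentration controls the tissue-specificity (tau) distribution.
Each extant observation adds independent Gaussian noise of scale sigma_o
on the log2 scale, truncated at zero.  For a duplicate pair, a fraction
``drift_share`` of the noise variance is a lineage component shared by
both copies (young conserved duplicates retain a common cis-regulatory
state and trans environment, so their profiles are strongly correlated);
the copy-specific residual makes up the rest.  Marginally each copy still
diverges from the ancestral proxy on the single-copy calibration scale.

Planted mechanisms
------------------
conservation          both copies = ancestor + sigma_o noise
neofunctionalization  one copy conserved; the other re-drawn, pushed to
                      at least delta away from the ancestor
subfunctionalization  complementary partition of the ancestral raw-TPM
                      profile between the copies (sums reconstruct the
                      ancestor exactly before noise)
specialization        both copies re-drawn >= delta away, with the
                      combined profile also >= delta away

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .family import BranchTarget, DuplicateTrio
from .io import ExpressionMatrix, FamilyTable, OrthologEvidence
from .tree import SpeciesTree

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SyntheticDataset",
    "simulate_single_copy_orthologs",
    "simulate_trios",
    "simulate_family_evolution",
    "simulate_annotations_and_divergence",
    "simulate_dataset",
]

#: the nine tissues assayed in the grass expression data
DEFAULT_TISSUES = (
    "leaf",
    "anther",
    "endosperm",
    "early_inflorescence",
    "emerging_inflorescence",
    "pistil",
    "embryo",
    "seed_5dap",
    "seed_10dap",
)

MECHANISMS = (
    "conservation",
    "neofunctionalization",
    "subfunctionalization",
    "specialization",
)

# 16-taxon species tree for family-size evolution: the focal/sister pair is
# embedded among outgroups so that duplications on most branches are
# polarisable (an event on a root-adjacent branch is inherently confounded
# with a root-state change plus loss and cannot be recovered by parsimony)
DEFAULT_NEWICK = (
    "(((((focal,sister),out01),(out02,out03)),((out04,out05),(out06,out07))),"
    "(((out08,out09),(out10,out11)),((out12,out13),out14)));"
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    sigma_o
        Per-observation expression noise on the log2(TPM+1) scale; 0.5
        gives single-copy ortholog distances centred near the low units,
        comparable to nine-tissue log-TPM profiles of diverged sisters.
    delta
        Minimum planted expression divergence of a neofunctionalized /
        specialized copy, default 5 * sigma_o.
    drift_share
        Fraction of a duplicate copy's divergence variance shared between
        the two copies of a pair (lineage drift); the residual is
        copy-specific.
    concentration
        Dirichlet concentration of tissue weights; smaller values give
        sparser, more tissue-specific profiles.
    """

    seed: int = 0
    n_tissues: int = 9
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    n_single_copy: int = 3000
    n_trios_per_mechanism: int = 100
    sigma_o: float = 0.5
    delta: float = 2.5
    rna_fraction: float = 0.1
    evidence_error: float = 0.05
    gain_rate: float = 0.01
    loss_rate: float = 0.02
    concentration: float = 0.5
    mean_tpm: float = 50.0
    log_tpm_sd: float = 1.0
    drift_share: float = 0.7
    subf_min_minor_tpm: float = 15.0
    ka_target_r: float = 0.45
    ks_target_r: float = 0.40
    ks_saturated_fraction: float = 0.04
    focal_species: str = "focal"
    sister_species: str = "sister"

    def __post_init__(self):
        if self.sigma_o <= 0 or self.delta <= 0:
            raise ValueError("noise and divergence scales must be positive")
        if not 0 <= self.rna_fraction <= 1:
            raise ValueError("rna_fraction must lie in [0, 1]")
        if not 0 <= self.evidence_error <= 1:
            raise ValueError("evidence_error must lie in [0, 1]")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("event rates must be non-negative")
        if len(self.tissues) != self.n_tissues:
            self.tissues = tuple("tissue%d" % (i + 1) for i in range(self.n_tissues))
        if self.delta <= self.sigma_o:
            warnings.warn(
                "delta <= sigma_o: planted divergence is within the noise scale "
                "and mechanism classes will not be identifiable",
                stacklevel=2,
            )


@dataclass
class TruthTable:
    """Ground truth for every emitted synthetic record."""

    mechanism: Dict[str, str] = field(default_factory=dict)  # trio -> mechanism
    diverged_copy: Dict[str, Optional[str]] = field(default_factory=dict)  # trio -> gene id
    parent: Dict[str, str] = field(default_factory=dict)  # trio -> parent gene id
    duplication_mechanism: Dict[str, str] = field(default_factory=dict)  # trio -> DNA/RNA/unknown
    family_event_branch: Dict[str, str] = field(default_factory=dict)  # family -> branch

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trio_id": t,
                "mechanism": self.mechanism[t],
                "diverged_copy": self.diverged_copy.get(t) or "",
                "parent": self.parent.get(t, ""),
                "duplication_mechanism": self.duplication_mechanism.get(t, ""),
            }
            for t in self.mechanism
        ]
        return pd.DataFrame(rows)


# -- low-level profile machinery --------------------------------------

def _ancestral_profiles(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Log2(TPM+1) profiles: sparse log-normal mixture over tissues."""
    w = rng.dirichlet(np.full(cfg.n_tissues, cfg.concentration), size=n)
    total = rng.lognormal(np.log(cfg.mean_tpm), cfg.log_tpm_sd, size=n)
    return np.log2(total[:, None] * w + 1.0)


def _observe(rng: np.random.Generator, log_profiles: np.ndarray, sigma: float) -> np.ndarray:
    """Add truncated Gaussian observation noise on the log scale."""
    return np.maximum(0.0, log_profiles + rng.normal(0.0, sigma, log_profiles.shape))


def _to_tpm(log_profiles: np.ndarray) -> np.ndarray:
    return 2.0 ** log_profiles - 1.0


def _push_away(
    rng: np.random.Generator, anc: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """Re-draw a profile and guarantee distance >= delta from ``anc``."""
    for _ in range(100):
        r = _ancestral_profiles(rng, 1, cfg)[0]
        d = r - anc
        nrm = float(np.linalg.norm(d))
        if nrm < cfg.delta:
            if nrm == 0:
                r = anc.copy()
                r[rng.integers(cfg.n_tissues)] += cfg.delta
            else:
                r = np.maximum(0.0, anc + d * (cfg.delta / nrm))
        if np.linalg.norm(r - anc) >= cfg.delta:
            return r
    return r  # pragma: no cover - the loop virtually always exits early


# -- public generators -------------------------------------------------

def simulate_single_copy_orthologs(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[ExpressionMatrix, ExpressionMatrix, List[Tuple[str, str]]]:
    """Two species' expression matrices for correlated single-copy orthologs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    anc = _ancestral_profiles(rng, cfg.n_single_copy, cfg)
    sp1 = _observe(rng, anc, cfg.sigma_o)
    sp2 = _observe(rng, anc, cfg.sigma_o)
    genes_f = ["sc%04d_F" % i for i in range(cfg.n_single_copy)]
    genes_s = ["sc%04d_S" % i for i in range(cfg.n_single_copy)]
    mat_f = ExpressionMatrix(
        pd.DataFrame(_to_tpm(sp1), index=genes_f, columns=list(cfg.tissues)),
        species=cfg.focal_species,
    )
    mat_s = ExpressionMatrix(
        pd.DataFrame(_to_tpm(sp2), index=genes_s, columns=list(cfg.tissues)),
        species=cfg.sister_species,
    )
    return mat_f, mat_s, list(zip(genes_f, genes_s))


def _subf_ancestor(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Ancestral profile with at least two appreciably expressed tissues.

    Subfunctionalization is only observable for genes whose expression can
    be divided: the second-ranked tissue must carry enough raw abundance
    that losing it moves the copy past the divergence cutoff.
    """
    for _ in range(500):
        a = _ancestral_profiles(rng, 1, cfg)[0]
        tpm = np.sort(_to_tpm(a))
        if tpm[-2] >= cfg.subf_min_minor_tpm:
            return a
    raise RuntimeError(
        "could not draw a partitionable ancestral profile; "
        "lower subf_min_minor_tpm or raise mean_tpm"
    )


def simulate_trios(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, List[DuplicateTrio], TruthTable]:
    """Plant trios under each mechanism.

    Returns (focal-species TPM frame for the duplicate copies, sister TPM
    frame for the ancestral proxies, trio descriptors, truth table).  Trio
    copy ids carry no polarity information; the truth table records which
    copy is the parent and, for neofunctionalization, which diverged.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n = cfg.n_trios_per_mechanism
    sigma = cfg.sigma_o
    s_shared = sigma * np.sqrt(cfg.drift_share)
    s_copy = sigma * np.sqrt(1.0 - cfg.drift_share)

    focal_rows: Dict[str, np.ndarray] = {}
    sister_rows: Dict[str, np.ndarray] = {}
    trios: List[DuplicateTrio] = []
    truth = TruthTable()

    idx = 0
    for mech in MECHANISMS:
        for _ in range(n):
            tid = "trio%04d" % idx
            g1, g2, ga = "dup%04da" % idx, "dup%04db" % idx, "anc%04d" % idx
            idx += 1
            anc = (
                _subf_ancestor(rng, cfg)
                if mech == "subfunctionalization"
                else _ancestral_profiles(rng, 1, cfg)[0]
            )
            # ancestral proxy observed in the sister species
            a_obs = _observe(rng, anc[None, :], sigma)[0]
            shared = rng.normal(0.0, s_shared, anc.shape)

            def observe_copy(base: np.ndarray) -> np.ndarray:
                return np.maximum(
                    0.0, base + shared + rng.normal(0.0, s_copy, base.shape)
                )

            if mech == "conservation":
                c1, c2 = observe_copy(anc), observe_copy(anc)
                diverged = None
            elif mech == "neofunctionalization":
                far = _push_away(rng, anc, cfg)
                if rng.random() < 0.5:
                    c1, c2, diverged = observe_copy(far), observe_copy(anc), g1
                else:
                    c1, c2, diverged = observe_copy(anc), observe_copy(far), g2
            elif mech == "subfunctionalization":
                tpm = _to_tpm(anc)
                order = np.argsort(-tpm, kind="stable")
                mask = np.zeros(cfg.n_tissues, dtype=bool)
                mask[order[::2]] = True  # alternate tissues by abundance rank
                part1 = np.log2(tpm * mask + 1.0)
                part2 = np.log2(tpm * ~mask + 1.0)
                c1, c2 = observe_copy(part1), observe_copy(part2)
                diverged = None
            else:  # specialization
                for _ in range(100):
                    f1 = _push_away(rng, anc, cfg)
                    f2 = _push_away(rng, anc, cfg)
                    comb = np.log2(_to_tpm(f1) + _to_tpm(f2) + 1.0)
                    if np.linalg.norm(comb - anc) >= cfg.delta:
                        break
                c1, c2 = observe_copy(f1), observe_copy(f2)
                diverged = None

            # the parent is the copy at the ancestral locus; polarity truth
            # is independent of expression fate
            parent = g1 if rng.random() < 0.5 else g2
            focal_rows[g1] = _to_tpm(c1)
            focal_rows[g2] = _to_tpm(c2)
            sister_rows[ga] = _to_tpm(a_obs)
            trios.append(
                DuplicateTrio(
                    trio_id=tid,
                    family_id="fam_" + tid,
                    branch="focal",
                    focal_species=cfg.focal_species,
                    sister_species=cfg.sister_species,
                    copy1=g1,
                    copy2=g2,
                    ancestral_gene=ga,
                    age_class=int(rng.integers(1, 4)),
                )
            )
            truth.mechanism[tid] = mech
            truth.diverged_copy[tid] = diverged
            truth.parent[tid] = parent

    focal = pd.DataFrame.from_dict(focal_rows, orient="index", columns=list(cfg.tissues))
    sister = pd.DataFrame.from_dict(sister_rows, orient="index", columns=list(cfg.tissues))
    return focal, sister, trios, truth


def simulate_family_evolution(
    tree: SpeciesTree,
    cfg: SimulationConfig,
    n_families: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[FamilyTable, TruthTable]:
    """Evolve family sizes from a single root copy by per-branch gains/losses.

    On each branch a gain (+1) occurs with probability ``gain_rate`` and,
    independently, a loss (-1, floored at zero copies) with probability
    ``loss_rate``.  The truth table records the event branch for families
    that experienced exactly one gain and no losses.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    truth = TruthTable()
    leaves = tree.leaves
    counts = np.zeros((n_families, len(leaves)), dtype=int)
    for i in range(n_families):
        node_count = {tree.root: 1}
        events: List[Tuple[str, str]] = []
        for node in tree.preorder():
            if node == tree.root:
                continue
            c = node_count[tree.parent(node)]
            if rng.random() < cfg.gain_rate:
                c += 1
                events.append(("gain", node))
            if rng.random() < cfg.loss_rate and c > 0:
                c -= 1
                events.append(("loss", node))
            node_count[node] = c
        counts[i] = [node_count[sp] for sp in leaves]
        fam = "fam%05d" % i
        gains = [b for ev, b in events if ev == "gain"]
        if len(gains) == 1 and all(ev != "loss" for ev, _ in events):
            truth.family_event_branch[fam] = gains[0]
    table = FamilyTable(
        pd.DataFrame(counts, index=["fam%05d" % i for i in range(n_families)], columns=leaves)
    )
    return table, truth


def _gff3_for_gene(gene: str, n_exons: int, start: int) -> Tuple[List[str], int]:
    """Minimal gene/mRNA/exon records; returns lines and the next free coordinate."""
    exon_len, gap = 200, 100
    span = n_exons * exon_len + (n_exons - 1) * gap
    end = start + span - 1
    lines = [
        "chr1\tsim\tgene\t%d\t%d\t.\t+\t.\tID=%s" % (start, end, gene),
        "chr1\tsim\tmRNA\t%d\t%d\t.\t+\t.\tID=%s.1;Parent=%s" % (start, end, gene, gene),
    ]
    pos = start
    for j in range(n_exons):
        lines.append(
            "chr1\tsim\texon\t%d\t%d\t.\t+\t.\tID=%s.1.exon%d;Parent=%s.1"
            % (pos, pos + exon_len - 1, gene, j + 1, gene)
        )
        pos += exon_len + gap
    return lines, end + 1000


def simulate_annotations_and_divergence(
    trios: Sequence[DuplicateTrio],
    truth: TruthTable,
    expression_divergence: Dict[str, float],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, List[OrthologEvidence], pd.DataFrame]:
    """Exon-structure GFF3, corrupted ortholog evidence, and Ka/Ks records.

    ``expression_divergence`` maps each duplicate gene id to its realized
    log-scale Euclidean distance from the ancestral proxy; Ka and Ks are
    drawn from a bivariate construction targeting the configured
    correlations with that divergence.  A fraction of records receives
    Ks >= 3 (saturated) to exercise the exclusion filter.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)

    # --- GFF3: parent exon structure multi-exon; child single-exon with
    # probability rna_fraction (the RNA-mediated truth)
    lines = ["##gff-version 3"]
    pos = 1000
    for trio in trios:
        parent = truth.parent[trio.trio_id]
        child = trio.copy2 if parent == trio.copy1 else trio.copy1
        p_exons = int(rng.integers(2, 10)) if rng.random() < 0.95 else 1
        c_exons = 1 if rng.random() < cfg.rna_fraction else int(rng.integers(2, 10))
        if p_exons == 1:
            truth.duplication_mechanism[trio.trio_id] = "unknown"
        elif c_exons == 1:
            truth.duplication_mechanism[trio.trio_id] = "RNA"
        else:
            truth.duplication_mechanism[trio.trio_id] = "DNA"
        for gene, n_ex in ((parent, p_exons), (child, c_exons)):
            glines, pos = _gff3_for_gene(gene, n_ex, pos)
            lines.extend(glines)
    gff3_text = "\n".join(lines) + "\n"

    # --- ortholog evidence: three prioritized sources, each linking the true
    # parent to the ancestral gene, corrupted (swapped to the child) at rate
    # evidence_error independently per source
    sources = [("OrthoMCL", 1), ("i-ADHoRE", 2), ("TribeMCL", 3)]
    evidence = [OrthologEvidence(source=s, priority=p) for s, p in sources]
    for trio in trios:
        parent = truth.parent[trio.trio_id]
        child = trio.copy2 if parent == trio.copy1 else trio.copy1
        for ev in evidence:
            linked = child if rng.random() < cfg.evidence_error else parent
            ev.add(linked, trio.ancestral_gene)

    # --- Ka/Ks records, one per duplicate copy
    genes, dvals = [], []
    trio_of = {}
    for trio in trios:
        for g in trio.copies:
            if g in expression_divergence:
                genes.append(g)
                dvals.append(expression_divergence[g])
                trio_of[g] = trio.trio_id
    d = np.asarray(dvals)
    z = (d - d.mean()) / (d.std() if d.std() > 0 else 1.0)

    def correlated(target_r, median, log_sd):
        # log-normal draw correlated with divergence on the log scale; the
        # raw-scale Pearson r lands close to the log-scale target
        eta = rng.normal(size=z.size)
        return np.exp(
            np.log(median) + log_sd * (target_r * z + np.sqrt(1 - target_r**2) * eta)
        )

    ka = correlated(cfg.ka_target_r, 0.12, 0.55)
    ks = correlated(cfg.ks_target_r, 0.80, 0.45)
    saturated = rng.random(z.size) < cfg.ks_saturated_fraction
    ks = np.where(saturated, rng.uniform(3.0, 6.0, z.size), ks)
    records = pd.DataFrame(
        {
            "gene": genes,
            "trio_id": [trio_of[g] for g in genes],
            "ka": ka,
            "ks": ks,
            "ka_ks": ka / ks,
            "expression_divergence": d,
        }
    )
    return gff3_text, evidence, records


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the truth to score against."""

    config: SimulationConfig
    newick: str
    focal: ExpressionMatrix
    sister: ExpressionMatrix
    ortholog_pairs: List[Tuple[str, str]]
    trios: List[DuplicateTrio]
    evidence: List[OrthologEvidence]
    gff3_text: str
    divergence: pd.DataFrame
    family_table: FamilyTable
    truth: TruthTable

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.focal.to_tsv(out / "expression_focal.tsv")
        self.sister.to_tsv(out / "expression_sister.tsv")
        (out / "tree.nwk").write_text(self.newick + "\n")
        pd.DataFrame(self.ortholog_pairs, columns=["focal", "sister"]).to_csv(
            out / "ortholog_pairs.tsv", sep="\t", index=False
        )
        rows = [
            {
                "trio_id": t.trio_id,
                "family_id": t.family_id,
                "branch": t.branch,
                "copy1": t.copy1,
                "copy2": t.copy2,
                "ancestral_gene": t.ancestral_gene,
                "age_class": t.age_class,
            }
            for t in self.trios
        ]
        pd.DataFrame(rows).to_csv(out / "trios.tsv", sep="\t", index=False)
        for ev in self.evidence:
            ev.to_tsv(out / ("evidence_%s.tsv" % ev.source.replace("-", "")))
        (out / "annotation.gff3").write_text(self.gff3_text)
        self.divergence.to_csv(out / "divergence.tsv", sep="\t", index=False)
        self.family_table.to_tsv(out / "families.tsv")
        self.truth.to_frame().to_csv(out / "truth_trios.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.family_event_branch.items()),
            columns=["family", "branch"],
        ).to_csv(out / "truth_family_events.tsv", sep="\t", index=False)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study: matrices, trios, tree, families,
    annotation, evidence and divergence records, all seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    mat_f, mat_s, pairs = simulate_single_copy_orthologs(cfg, rng)
    focal_dup, sister_anc, trios, truth = simulate_trios(cfg, rng)

    focal = ExpressionMatrix(
        pd.concat([mat_f.data, focal_dup]), species=cfg.focal_species
    )
    sister = ExpressionMatrix(
        pd.concat([mat_s.data, sister_anc]), species=cfg.sister_species
    )

    # realized log-scale divergence of each duplicate copy from its proxy
    logf = np.log2(focal.data + 1.0)
    logs = np.log2(sister.data + 1.0)
    div: Dict[str, float] = {}
    for t in trios:
        a = logs.loc[t.ancestral_gene].to_numpy()
        for g in t.copies:
            div[g] = float(np.linalg.norm(logf.loc[g].to_numpy() - a))

    gff3_text, evidence, records = simulate_annotations_and_divergence(
        trios, truth, div, cfg, rng
    )
    tree = SpeciesTree.from_newick(DEFAULT_NEWICK, is_path=False)
    family_table, fam_truth = simulate_family_evolution(tree, cfg, rng=rng)
    truth.family_event_branch = fam_truth.family_event_branch
    return SyntheticDataset(
        config=cfg,
        newick=DEFAULT_NEWICK,
        focal=focal,
        sister=sister,
        ortholog_pairs=pairs,
        trios=trios,
        evidence=evidence,
        gff3_text=gff3_text,
        divergence=records,
        family_table=family_table,
        truth=truth,
    )
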