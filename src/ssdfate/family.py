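"""Ancestral gene-family sizes by asymmetric Wagner parsimony.

Family copy numbers observed at the leaves of the species tree are pushed
back in time with a Sankoff-style dynamic programme over integer states
0..max_count.  A change of +k copies along a branch costs
``k * gain_penalty`` and a change of -k costs ``k * loss_penalty``; the
optimum is the ancestral assignment minimising the total penalised change.
Independent gains are typically rarer than losses, hence the asymmetric
default ``gain_penalty=2, loss_penalty=1``.  Among co-optimal states the
smallest copy number is chosen, which is conservative against inferring
phantom ancient copies and makes output deterministic.

Small-scale duplication (SSD) events are then read off designated branches:
a family going from one copy at the branch's parent node to two copies at
its child node, with the designated sister species retaining a single copy
(the ancestral proxy), yields one parent/child/ancestor candidate trio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .tree import SpeciesTree

__all__ = [
    "FamilyReconstruction",
    "SsdEvent",
    "BranchTarget",
    "DuplicateTrio",
    "SkippedFamily",
    "wagner_parsimony",
    "reconstruct_families",
    "extract_ssd_pairs",
    "assign_age_class",
]


@dataclass
class FamilyReconstruction:
    """Minimum-cost ancestral assignment for one family."""

    family_id: str
    node_counts: Dict[str, int]
    branch_events: Dict[str, Tuple[int, int]]  # branch -> (gains, losses)
    cost: float

    def events_on(self, branch: str) -> Tuple[int, int]:
        return self.branch_events.get(branch, (0, 0))


@dataclass(frozen=True)
class SsdEvent:
    family_id: str
    branch: str
    parent_count: int
    child_count: int
    age_class: Optional[int] = None


@dataclass(frozen=True)
class BranchTarget:
    """A branch on which SSD-derived pairs are harvested.

    ``focal_species``: the extant species carrying the duplicate pair;
    ``sister_species``: the species whose single remaining copy proxies
    the ancestral gene; ``age_class``: 1 (youngest) to 3 (oldest).
    """

    branch: str
    focal_species: str
    sister_species: str
    age_class: int


@dataclass
class DuplicateTrio:
    """A duplicate pair plus its single-copy ancestral proxy."""

    trio_id: str
    family_id: str
    branch: str
    focal_species: str
    sister_species: str
    copy1: str
    copy2: str
    ancestral_gene: str
    age_class: Optional[int] = None
    parent: Optional[str] = None  # filled by the polarity step
    child: Optional[str] = None

    @property
    def copies(self) -> Tuple[str, str]:
        return (self.copy1, self.copy2)


@dataclass(frozen=True)
class SkippedFamily:
    family_id: str
    branch: str
    reason: str


def wagner_parsimony(
    tree: SpeciesTree,
    leaf_counts: Mapping[str, int],
    gain_penalty: float = 2.0,
    loss_penalty: float = 1.0,
    max_count: Optional[int] = None,
    family_id: str = "family",
) -> FamilyReconstruction:
    """Reconstruct ancestral copy numbers for one family.

    ``max_count`` bounds the DP state space; it defaults to the maximum
    observed leaf count (states above it cannot be optimal with positive
    penalties).
    """
    if gain_penalty <= 0 or loss_penalty <= 0:
        raise ValueError("penalties must be positive")
    tree.validate_leaves(list(leaf_counts))
    for sp, c in leaf_counts.items():
        if not float(c).is_integer() or c < 0:
            raise ValueError("leaf count for %s must be a non-negative integer, got %r" % (sp, c))
    observed_max = max(int(c) for c in leaf_counts.values())
    if max_count is None:
        max_count = observed_max
    elif max_count < observed_max:
        raise ValueError("max_count %d below maximum observed count %d" % (max_count, observed_max))
    n_states = max_count + 1

    states = np.arange(n_states)
    diff = states[None, :] - states[:, None]  # child - parent
    trans = np.where(diff > 0, gain_penalty * diff, -loss_penalty * diff).astype(float)

    # bottom-up: minimal subtree cost per node and state
    subtree: Dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            vec = np.full(n_states, np.inf)
            vec[int(leaf_counts[node])] = 0.0
            subtree[node] = vec
        else:
            total = np.zeros(n_states)
            for ch in tree.children(node):
                # cost of subtree(ch) given this node's state a:
                # min_b trans[a, b] + subtree[ch][b]
                total = total + np.min(trans + subtree[ch][None, :], axis=1)
            subtree[node] = total

    # top-down backtrack; np.argmin returns the first (= smallest) optimum
    node_counts: Dict[str, int] = {}
    root_vec = subtree[tree.root]
    node_counts[tree.root] = int(np.argmin(root_vec))
    cost = float(root_vec[node_counts[tree.root]])
    branch_events: Dict[str, Tuple[int, int]] = {}
    for node in tree.preorder():
        if node == tree.root:
            continue
        a = node_counts[tree.parent(node)]
        b = int(np.argmin(trans[a] + subtree[node]))
        node_counts[node] = b
        change = b - a
        branch_events[node] = (max(change, 0), max(-change, 0))

    return FamilyReconstruction(
        family_id=family_id,
        node_counts=node_counts,
        branch_events=branch_events,
        cost=cost,
    )


def reconstruct_families(
    tree: SpeciesTree,
    table,  # FamilyTable
    gain_penalty: float = 2.0,
    loss_penalty: float = 1.0,
) -> List[FamilyReconstruction]:
    return [
        wagner_parsimony(
            tree,
            table.row(fam),
            gain_penalty=gain_penalty,
            loss_penalty=loss_penalty,
            family_id=str(fam),
        )
        for fam in table.families
    ]


def extract_ssd_pairs(
    reconstructions: Iterable[FamilyReconstruction],
    tree: SpeciesTree,
    targets: Sequence[BranchTarget],
    membership: Mapping[str, Mapping[str, Sequence[str]]],
) -> Tuple[List[DuplicateTrio], List[SkippedFamily]]:
    """Harvest candidate parent/child/ancestor trios on the target branches.

    A family qualifies on a branch when the reconstruction goes 1 -> 2
    across it and the designated sister species retains exactly one copy.
    Families violating the simple-pair pattern are skipped with a reason so
    ambiguous cases are surfaced rather than silently polarised.
    """
    for t in targets:
        if t.branch not in tree.nodes or t.branch == tree.root:
            raise ValueError("target branch %r not a branch of the tree" % t.branch)

    trios: List[DuplicateTrio] = []
    skipped: List[SkippedFamily] = []
    for rec in reconstructions:
        for t in targets:
            parent_count = rec.node_counts[tree.parent(t.branch)]
            child_count = rec.node_counts[t.branch]
            if parent_count != 1 or child_count == 1:
                continue  # no duplication inferred on this branch
            if child_count != 2:
                skipped.append(
                    SkippedFamily(rec.family_id, t.branch, "not a simple 1->2 duplication (1->%d)" % child_count)
                )
                continue
            genes = membership.get(rec.family_id, {})
            focal = list(genes.get(t.focal_species, ()))
            sister = list(genes.get(t.sister_species, ()))
            if len(sister) != 1:
                skipped.append(
                    SkippedFamily(rec.family_id, t.branch, "no single-copy ancestral proxy (%d copies in %s)" % (len(sister), t.sister_species))
                )
                continue
            if len(focal) != 2:
                skipped.append(
                    SkippedFamily(rec.family_id, t.branch, "expected 2 focal-species gene ids, found %d" % len(focal))
                )
                continue
            trios.append(
                DuplicateTrio(
                    trio_id="%s@%s" % (rec.family_id, t.branch),
                    family_id=rec.family_id,
                    branch=t.branch,
                    focal_species=t.focal_species,
                    sister_species=t.sister_species,
                    copy1=focal[0],
                    copy2=focal[1],
                    ancestral_gene=sister[0],
                    age_class=t.age_class,
                )
            )
    return trios, skipped


def assign_age_class(event: SsdEvent, class_map: Mapping[str, int]) -> int:
    """Look up the age class (1-3) for an SSD event's branch."""
    if event.branch not in class_map:
        raise ValueError("branch %r has no age-class assignment" % event.branch)
    return int(class_map[event.branch])
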