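"""Parent/child polarity of duplicate pairs by prioritised majority vote.

For each duplicate pair, every ortholog-evidence source casts a vote: the
copy it links to the single-copy ancestral gene is the parent.  A source
linking both (or neither) copy to the ancestor abstains.  With a strict
majority among informative sources the majority wins; ties fall to the
highest-priority source (default order: OrthoMCL > i-ADHoRE > TribeMCL);
with no informative source the pair is unresolved and excluded downstream,
since mispolarised pairs would corrupt the parent/child asymmetry
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .family import DuplicateTrio
from .io import OrthologEvidence, validate_evidence_priorities

__all__ = ["PolarityCall", "assign_polarity", "polarize_trios", "DEFAULT_PRIORITY"]

#: default source priority, highest first
DEFAULT_PRIORITY = ("OrthoMCL", "i-ADHoRE", "TribeMCL")


@dataclass
class PolarityCall:
    pair_id: str
    parent: Optional[str]
    child: Optional[str]
    votes: Dict[str, Optional[str]] = field(default_factory=dict)
    rule: str = "unresolved"  # majority | priority | unresolved

    @property
    def resolved(self) -> bool:
        return self.rule != "unresolved"


def assign_polarity(
    copy1: str,
    copy2: str,
    ancestral_gene: str,
    evidence: Sequence[OrthologEvidence],
    pair_id: Optional[str] = None,
) -> PolarityCall:
    """Infer which copy is the parent (ancestral locus).

    Deterministic in the evidence content: sources are processed in
    priority order regardless of input order.
    """
    if copy1 == copy2:
        raise ValueError("duplicate pair must consist of two distinct genes")
    if not evidence:
        raise ValueError("at least one evidence source is required")
    validate_evidence_priorities(evidence)
    ordered = sorted(evidence, key=lambda e: e.priority)

    votes: Dict[str, Optional[str]] = {}
    for src in ordered:
        l1 = src.links(copy1, ancestral_gene) or src.links(ancestral_gene, copy1)
        l2 = src.links(copy2, ancestral_gene) or src.links(ancestral_gene, copy2)
        if l1 == l2:
            votes[src.source] = None  # abstain: both or neither linked
        else:
            votes[src.source] = copy1 if l1 else copy2

    pid = pair_id or "%s|%s" % (copy1, copy2)
    n1 = sum(1 for v in votes.values() if v == copy1)
    n2 = sum(1 for v in votes.values() if v == copy2)
    if n1 == n2 == 0:
        return PolarityCall(pid, None, None, votes, "unresolved")
    if n1 != n2:
        parent = copy1 if n1 > n2 else copy2
        return PolarityCall(pid, parent, copy2 if parent == copy1 else copy1, votes, "majority")
    # tie among informative sources: highest-priority informative source decides
    for src in ordered:
        v = votes[src.source]
        if v is not None:
            other = copy2 if v == copy1 else copy1
            return PolarityCall(pid, v, other, votes, "priority")
    raise AssertionError("unreachable")  # pragma: no cover


def polarize_trios(
    trios: Sequence[DuplicateTrio],
    evidence: Sequence[OrthologEvidence],
) -> List[PolarityCall]:
    """Assign polarity in place for each trio; unresolved trios keep parent=None."""
    calls = []
    for trio in trios:
        call = assign_polarity(
            trio.copy1, trio.copy2, trio.ancestral_gene, evidence, pair_id=trio.trio_id
        )
        trio.parent, trio.child = call.parent, call.child
        calls.append(call)
    return calls
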