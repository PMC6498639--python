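"""DNA- vs RNA-mediated duplication calls from exon counts.

Retroposition of a processed transcript yields an intronless child, so a
multi-exon parent with a single-exon child is called RNA-mediated; two
multi-exon copies are DNA-mediated; two single-exon copies are unknown
(the rule cannot discriminate).  A single-exon parent with a multi-exon
child matches no rule and is likewise left unknown and counted separately
rather than forced into either class, which would bias the enrichment
test.  Unknown pairs are excluded from the mechanism-enrichment analysis;
the exclusion count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .family import DuplicateTrio

__all__ = ["MechanismCall", "call_mechanism", "call_mechanisms"]


@dataclass(frozen=True)
class MechanismCall:
    pair_id: str
    parent_exons: int
    child_exons: int
    mechanism: str  # 'DNA' | 'RNA' | 'unknown'


def call_mechanism(parent_exons: int, child_exons: int) -> str:
    """Apply the exon-count rule; counts must be >= 1."""
    if parent_exons < 1 or child_exons < 1:
        raise ValueError(
            "exon counts must be >= 1, got parent=%r child=%r"
            % (parent_exons, child_exons)
        )
    if parent_exons > 1 and child_exons == 1:
        return "RNA"
    if parent_exons > 1 and child_exons > 1:
        return "DNA"
    return "unknown"


def call_mechanisms(
    trios: Sequence[DuplicateTrio],
    exon_counts: Mapping[str, Optional[int]],
) -> Tuple[List[MechanismCall], List[str]]:
    """Call the duplication mechanism for every polarised trio.

    Trios whose parent or child lacks an exon count (absent from the
    annotation) are skipped; their ids are returned separately.
    """
    calls: List[MechanismCall] = []
    skipped: List[str] = []
    for trio in trios:
        if trio.parent is None or trio.child is None:
            skipped.append(trio.trio_id)
            continue
        pe = exon_counts.get(trio.parent)
        ce = exon_counts.get(trio.child)
        if pe is None or ce is None:
            skipped.append(trio.trio_id)
            continue
        calls.append(
            MechanismCall(
                pair_id=trio.trio_id,
                parent_exons=pe,
                child_exons=ce,
                mechanism=call_mechanism(pe, ce),
            )
        )
    return calls, skipped
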