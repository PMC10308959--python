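"""Full-length KS domain extraction by terminal anchor motifs.

A type I KS domain is treated as full length when it spans from the conserved
IAIVG start motif through the GTNAH end motif.  Some degeneracy is tolerated
at these positions: each 5-residue anchor may mismatch at up to
``max_mismatch`` positions (default 1).  Domains missing either anchor, or
with the anchors out of order, are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .classify import DomainCall
from .seqio import SequenceRecord

START_ANCHOR = "IAIVG"
END_ANCHOR = "GTNAH"


@dataclass
class FullLengthDomain:
    """A KS domain clipped from start-anchor through end-anchor, inclusive."""

    call: DomainCall
    residues: str
    anchor_start_pos: int  # 1-based on the searched domain peptide
    anchor_end_pos: int
    mismatches_start: int
    mismatches_end: int

    @property
    def id(self) -> str:
        return self.call.domain_id

    def __len__(self) -> int:
        return len(self.residues)


def _mismatches(window: str, anchor: str) -> int:
    # X is ambiguity, never a match
    return sum(1 for a, b in zip(window, anchor) if a != b or a == "X")


def find_anchor(
    residues: str, anchor_motif: str, max_mismatch: int = 1, prefer: str = "leftmost"
) -> tuple[int, int] | None:
    """Best anchor window with <= ``max_mismatch`` mismatches, or None.

    Returns (1-based position, mismatch count).  Among equally good windows
    the leftmost wins for start anchors and the rightmost for end anchors
    (``prefer``).
    """
    k = len(anchor_motif)
    if k > len(residues):
        return None
    best: tuple[int, int] | None = None
    for i in range(len(residues) - k + 1):
        mm = _mismatches(residues[i : i + k], anchor_motif)
        if mm > max_mismatch:
            continue
        if best is None or mm < best[1] or (mm == best[1] and prefer == "rightmost"):
            best = (i + 1, mm)
    return best


def extract_full_length(
    calls: Iterable[DomainCall], max_mismatch: int = 1
) -> list[FullLengthDomain]:
    """Clip full-length domains: those with a start anchor before an end anchor.

    Anchors are searched on the called domain interval.  Non-spanning domains
    are silently excluded (callers may compare input/output lengths to log
    the count).
    """
    out: list[FullLengthDomain] = []
    for call in calls:
        region = call.residues
        start = find_anchor(region, START_ANCHOR, max_mismatch, prefer="leftmost")
        end = find_anchor(region, END_ANCHOR, max_mismatch, prefer="rightmost")
        if start is None or end is None:
            continue
        s_pos, s_mm = start
        e_pos, e_mm = end
        if e_pos <= s_pos:
            continue
        clipped = region[s_pos - 1 : e_pos + len(END_ANCHOR) - 1]
        out.append(
            FullLengthDomain(
                call=call,
                residues=clipped,
                anchor_start_pos=s_pos,
                anchor_end_pos=e_pos,
                mismatches_start=s_mm,
                mismatches_end=e_mm,
            )
        )
    return out


def full_length_records(domains: Sequence[FullLengthDomain]) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=d.id, residues=d.residues, alphabet="protein",
                       description=f"leaf={d.call.leaf_label}")
        for d in domains
    ]
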