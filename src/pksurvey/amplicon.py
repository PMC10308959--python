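"""Amplicon-truncation concordance: does a short KS amplicon classify like
its full-length parent?

Full-length domains (~420 aa) are trimmed to a next-generation amplicon
length (default 138 aa), either anchored at the located KS2F primer site or
centered, then re-classified.  Because a 138-aa query cannot satisfy the
200-aa full-length match floor, re-classification of trimmed sequences uses
a lowered minimum match length (default 100 aa).  Concordance is the
fraction of domains whose leaf classification survives trimming, reported
per KS group and overall; trimmed sequences yielding no call count as
discordant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classify import DomainCall, ReferenceEntry, classify_domains
from .fulllength import FullLengthDomain
from .primers import KS2F, AminoAcidPattern, DegeneratePrimer, locate_primer_site, translate_degenerate
from .seqio import SequenceRecord

TRIMMED_MIN_MATCH_AA = 100


@dataclass
class TrimSpec:
    length_aa: int = 138
    placement: str = "primer_site"  # "primer_site" | "center"

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError("length_aa must be positive")
        if self.placement not in ("primer_site", "center"):
            raise ValueError("placement must be 'primer_site' or 'center'")


@dataclass
class ConcordanceResult:
    overall_fraction: float
    overall_n: int
    per_group: dict[str, tuple[int, float]]  # group -> (n, fraction concordant)
    trim_length: int


def _center_start(domain_len: int, length_aa: int) -> int:
    return (domain_len - length_aa) // 2 + 1


def trim_to_amplicon(
    domain: FullLengthDomain | SequenceRecord,
    spec: TrimSpec,
    pattern: AminoAcidPattern | None = None,
) -> SequenceRecord:
    """Cut an amplicon-length window from a full-length domain.

    ``primer_site`` placement starts the window at the located KS2F site
    (shifted left if needed to fit, and falling back to a centered window
    when no confident site exists); ``center`` placement centers it.
    """
    if isinstance(domain, FullLengthDomain):
        residues, rid = domain.residues, domain.id
    else:
        residues, rid = domain.residues, domain.id
    n = len(residues)
    if n < spec.length_aa:
        raise ValueError(f"domain {rid!r} ({n} aa) shorter than trim length {spec.length_aa}")
    if spec.placement == "center":
        start = _center_start(n, spec.length_aa)
    else:
        if pattern is None:
            pattern = translate_degenerate(DegeneratePrimer(*KS2F))
        site = locate_primer_site(pattern, residues)
        start = _center_start(n, spec.length_aa) if site.low_confidence else site.position
        start = min(start, n - spec.length_aa + 1)
    return SequenceRecord(
        id=rid,
        residues=residues[start - 1 : start - 1 + spec.length_aa],
        alphabet="protein",
        description=f"trimmed to {spec.length_aa} aa ({spec.placement}, start {start})",
    )


def concordance(
    full_calls: Mapping[str, DomainCall],
    trimmed_calls: Mapping[str, DomainCall | None],
) -> ConcordanceResult:
    """Fraction of paired domains with an identical leaf label after trimming.

    Inputs are keyed by domain id; every full call needs a (possibly None)
    trimmed counterpart.  Groups follow the full-length call's KS group.
    """
    if not full_calls:
        raise ValueError("concordance requires at least one paired domain")
    missing = set(full_calls) ^ set(trimmed_calls)
    if missing:
        raise ValueError(f"unpaired domain ids: {sorted(missing)[:5]} ...")
    per_group_counts: dict[str, list[int]] = {}
    trim_len = 0
    for did, full in sorted(full_calls.items()):
        trimmed = trimmed_calls[did]
        same = trimmed is not None and trimmed.leaf_label == full.leaf_label
        n_same = per_group_counts.setdefault(full.ssn_group, [0, 0])
        n_same[0] += 1
        n_same[1] += same
    per_group = {g: (n, s / n) for g, (n, s) in per_group_counts.items()}
    total = sum(n for n, _ in per_group_counts.values())
    hits = sum(s for _, s in per_group_counts.values())
    return ConcordanceResult(
        overall_fraction=hits / total,
        overall_n=total,
        per_group=per_group,
        trim_length=trim_len,
    )


def trim_and_reclassify(
    domains: Sequence[FullLengthDomain],
    refdb: Sequence[ReferenceEntry],
    spec: TrimSpec,
    min_match_aa: int = TRIMMED_MIN_MATCH_AA,
    max_evalue: float = 1e-30,
) -> ConcordanceResult:
    """End-to-end truncation experiment on a set of full-length domains."""
    pattern = translate_degenerate(DegeneratePrimer(*KS2F))
    full_calls = {d.id: d.call for d in domains}
    records = [trim_to_amplicon(d, spec, pattern) for d in domains]
    reclassified = classify_domains(
        records, refdb, min_match_aa=min(min_match_aa, spec.length_aa),
        max_evalue=max_evalue, assign_phyla=False,
    )
    by_query: dict[str, DomainCall | None] = {d.id: None for d in domains}
    for call in reclassified:
        if by_query.get(call.query_id) is None:
            by_query[call.query_id] = call
    result = concordance(full_calls, by_query)
    result.trim_length = spec.length_aa
    return result
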