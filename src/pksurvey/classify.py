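"""Ketosynthase (KS) domain detection and top-hit classification.

Query peptides are searched against a labeled KS reference collection; the
best-scoring reference that survives the match-length (>= 200 aa) and
E-value (<= 1e-30) thresholds classifies the domain.  Each KS leaf class maps
deterministically onto a coarser functional group (cis-AT, trans-AT,
iterative cis-AT, FAS) and onto the similarity-network group used for
composition and primer analyses.  A phylum is assigned from the closest
reference by E-value, with matches under 75% identity flagged as tentative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentResult, align_local, local_score
from .seqio import SequenceRecord, read_fasta

#: The 11 type I KS leaf classes (plus-FAS vocabulary used throughout).
LEAF_LABELS = (
    "modular cis-AT",
    "cis-loading module",
    "olefin synthase",
    "iterative aromatic",
    "iterative PTM",
    "trans-AT",
    "hybrid trans-AT",
    "hybrid cis-AT",
    "PUFA",
    "enediyne",
    "FAS",
)

#: leaf -> (group, similarity-network group)
_LEAF_MAP = {
    "modular cis-AT": ("cis-AT", "cis-AT/iterative"),
    "cis-loading module": ("cis-AT", "cis-AT/iterative"),
    "olefin synthase": ("cis-AT", "cis-AT/iterative"),
    "iterative aromatic": ("iterative cis-AT", "cis-AT/iterative"),
    "iterative PTM": ("iterative cis-AT", "cis-AT/iterative"),
    "trans-AT": ("trans-AT", "trans-AT"),
    "hybrid trans-AT": ("trans-AT", "trans-AT"),
    "hybrid cis-AT": ("cis-AT", "hybrid cis-AT"),
    "PUFA": ("iterative cis-AT", "PUFA"),
    "enediyne": ("iterative cis-AT", "enediyne"),
    "FAS": ("FAS", "FAS"),
}

GROUP_LABELS = ("cis-AT", "trans-AT", "iterative cis-AT", "FAS")
SSN_GROUPS = ("cis-AT/iterative", "hybrid cis-AT", "trans-AT", "PUFA", "enediyne", "FAS")

TENTATIVE_IDENTITY = 0.75


class VocabularyError(KeyError):
    pass


class ConfigurationError(ValueError):
    pass


def map_leaf(leaf_label: str) -> tuple[str, str]:
    """Map a KS leaf class to its (group, similarity-network group)."""
    try:
        return _LEAF_MAP[leaf_label]
    except KeyError:
        raise VocabularyError(
            f"unknown KS leaf label {leaf_label!r}; expected one of {LEAF_LABELS}"
        ) from None


@dataclass
class ReferenceEntry:
    """A labeled reference KS sequence used for classification and taxonomy."""

    id: str
    residues: str
    leaf_label: str
    phylum: str

    def __post_init__(self) -> None:
        if self.leaf_label not in _LEAF_MAP:
            raise VocabularyError(f"reference {self.id!r}: unknown leaf label {self.leaf_label!r}")

    @property
    def group_label(self) -> str:
        return _LEAF_MAP[self.leaf_label][0]

    @property
    def ssn_group(self) -> str:
        return _LEAF_MAP[self.leaf_label][1]


@dataclass
class DomainCall:
    """A detected KS domain on a query peptide, classified by its top hit."""

    query_id: str
    q_start: int
    q_end: int
    top_ref_id: str
    leaf_label: str
    group_label: str
    ssn_group: str
    alignment: AlignmentResult
    residues: str
    phylum_call: str = ""
    phylum_identity: float = float("nan")
    phylum_tentative: bool = False

    @property
    def domain_id(self) -> str:
        return f"{self.query_id}:{self.q_start}-{self.q_end}"


def load_reference(fasta_path: str | Path, metadata_path: str | Path) -> list[ReferenceEntry]:
    """Load a reference collection from FASTA plus tab-separated metadata.

    Metadata columns: id, leaf_label, phylum (group/ssn assignments are
    derived from the leaf and need not be supplied).
    """
    records = {r.id: r for r in read_fasta(fasta_path, alphabet="protein")}
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"id", "leaf_label", "phylum"}
    if not required <= set(meta.columns):
        raise ConfigurationError(
            f"{metadata_path}: metadata must contain columns {sorted(required)}"
        )
    entries = []
    for row in meta.itertuples(index=False):
        if row.id not in records:
            raise ConfigurationError(f"metadata id {row.id!r} absent from {fasta_path}")
        entries.append(
            ReferenceEntry(
                id=row.id,
                residues=records[row.id].residues,
                leaf_label=row.leaf_label,
                phylum=row.phylum,
            )
        )
    if not entries:
        raise ConfigurationError("empty reference collection")
    return entries


def _best_reference(
    query: str, refdb: Sequence[ReferenceEntry], search_space_n: int
) -> tuple[ReferenceEntry, AlignmentResult] | None:
    """Best hit by raw score; ties broken by identity then lexicographic id.

    Returns None when no reference aligns with positive score (e.g. a fully
    masked query).
    """
    scores = [(local_score(query, ref.residues), ref) for ref in refdb]
    top = max(s for s, _ in scores)
    if top <= 0:
        return None
    tied = sorted((ref for s, ref in scores if s == top), key=lambda r: r.id)
    if len(tied) == 1:
        ref = tied[0]
        return ref, align_local(query, ref.residues, search_space_n)
    best = None
    for ref in tied:
        aln = align_local(query, ref.residues, search_space_n)
        key = (-aln.identity_fraction, ref.id)
        if best is None or key < best[0]:
            best = (key, ref, aln)
    return best[1], best[2]


def _overlap_ok(q_start: int, q_end: int, existing: list[tuple[int, int]], max_frac: float = 0.5) -> bool:
    for (s, e) in existing:
        ov = min(q_end, e) - max(q_start, s) + 1
        if ov <= 0:
            continue
        shorter = min(q_end - q_start + 1, e - s + 1)
        if ov >= max_frac * shorter:
            return False
    return True


def classify_domains(
    peptides: Iterable[SequenceRecord],
    refdb: Sequence[ReferenceEntry],
    min_match_aa: int = 200,
    max_evalue: float = 1e-30,
    max_domains_per_query: int = 8,
    assign_phyla: bool = True,
) -> list[DomainCall]:
    """Detect and classify KS domains in query peptides by best reference hit.

    A hit is retained iff its alignment spans >= ``min_match_aa`` columns with
    E-value <= ``max_evalue``.  Several non-overlapping domains per peptide
    (tandem KS domains of multimodular PKSs) are found greedily by score:
    after each accepted call, the called query interval is masked and the
    search repeated; a new hit is accepted only when it overlaps every
    previous call by less than half of the shorter interval.
    """
    refdb = list(refdb)
    if not refdb:
        raise ConfigurationError("classify_domains requires a non-empty reference collection")
    search_space_n = sum(len(r.residues) for r in refdb)
    calls: list[DomainCall] = []
    for pep in peptides:
        masked = pep.residues
        taken: list[tuple[int, int]] = []
        for _ in range(max_domains_per_query):
            hit = _best_reference(masked, refdb, search_space_n)
            if hit is None:
                break
            ref, aln = hit
            if aln.aln_columns < min_match_aa or aln.evalue > max_evalue:
                break
            if not _overlap_ok(aln.q_start, aln.q_end, taken):
                break
            group, ssn = map_leaf(ref.leaf_label)
            call = DomainCall(
                query_id=pep.id,
                q_start=aln.q_start,
                q_end=aln.q_end,
                top_ref_id=ref.id,
                leaf_label=ref.leaf_label,
                group_label=group,
                ssn_group=ssn,
                alignment=aln,
                residues=pep.residues[aln.q_start - 1 : aln.q_end],
            )
            if assign_phyla:
                call = assign_phylum(call, refdb, search_space_n)
            calls.append(call)
            taken.append((aln.q_start, aln.q_end))
            masked = masked[: aln.q_start - 1] + "X" * (aln.q_end - aln.q_start + 1) + masked[aln.q_end :]
    return calls


def assign_phylum(
    call: DomainCall, refdb: Sequence[ReferenceEntry], search_space_n: int | None = None
) -> DomainCall:
    """Assign a phylum from the reference closest by E-value to the domain.

    With a fixed search space, E-value ranking equals raw-score ranking; ties
    are broken by higher identity, then lexicographic reference id.  Matches
    below 75% identity are flagged tentative.
    """
    if search_space_n is None:
        search_space_n = sum(len(r.residues) for r in refdb)
    hit = _best_reference(call.residues, refdb, search_space_n)
    if hit is None:  # cannot happen for a call that passed thresholds
        return call
    ref, aln = hit
    return replace(
        call,
        phylum_call=ref.phylum,
        phylum_identity=aln.identity_fraction,
        phylum_tentative=aln.identity_fraction < TENTATIVE_IDENTITY,
    )


def calls_to_frame(calls: Sequence[DomainCall]) -> pd.DataFrame:
    """Serialize domain calls as a flat table (one row per call)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "domain_id": c.domain_id,
                "query_id": c.query_id,
                "q_start": c.q_start,
                "q_end": c.q_end,
                "top_ref_id": c.top_ref_id,
                "leaf_label": c.leaf_label,
                "group_label": c.group_label,
                "ssn_group": c.ssn_group,
                "bitscore": c.alignment.bitscore,
                "evalue": c.alignment.evalue,
                "identity": c.alignment.identity_fraction,
                "aln_columns": c.alignment.aln_columns,
                "phylum": c.phylum_call,
                "phylum_identity": c.phylum_identity,
                "phylum_tentative": c.phylum_tentative,
            }
        )
    return pd.DataFrame(rows)
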