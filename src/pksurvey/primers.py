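"""In-silico evaluation of degenerate KS PCR primers against protein domains.

A degenerate primer (IUPAC nucleotide codes) is translated into an ordered
amino-acid pattern: each codon expands to the set of amino acids its
concrete expansions encode, with stop codons removed.  Reverse primers are
reverse-complemented before translation, so pattern position 1 corresponds
to the primer's 3'-proximal codon.  A trailing partial codon is right-padded
with N.

The widely used type I KS primer pair is bundled: KS2F
5'-GCNATGGAYCCNCARCARMGNVT-3' (AMDPQQ(RS)(ILMV)) and KS2R
5'-GTNCNNGTNCCRTGNSCYTCNAC-3' (VE(AG)HGT(CGRSW)T).  Primer sites are placed
on domains by a best-match sliding window; per-position percent-match
profiles by KS group quantify how much of environmental diversity each
primer can amplify, and candidate base modifications can be evaluated as
enlarged residue sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

IUPAC_NT = set("ACGTRYSWKMBDHVN")

#: canonical residue order used when rendering a position set
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

KS2F = ("KS2F", "GCNATGGAYCCNCARCARMGNVT", "forward")
KS2R = ("KS2R", "GTNCNNGTNCCRTGNSCYTCNAC", "reverse")


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    nt_sequence: str  # 5' -> 3'
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        seq = self.nt_sequence.upper()
        object.__setattr__(self, "nt_sequence", seq)
        bad = set(seq) - IUPAC_NT
        if bad:
            raise PrimerError(f"primer {self.name}: non-IUPAC characters {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError("orientation must be 'forward' or 'reverse'")


@dataclass
class AminoAcidPattern:
    """Ordered amino-acid sets translated from a degenerate primer."""

    positions: list[frozenset[str]]
    name: str = ""
    orientation: str = "forward"
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    def three_prime_offset(self, position: int) -> int:
        """1-based codon distance of ``position`` (1-based) from the primer 3' end."""
        if self.orientation == "reverse":
            return position
        return len(self.positions) - position + 1

    def render(self) -> str:
        """Canonical string: single residues bare, larger sets parenthesized,
        set members in a fixed canonical amino-acid order."""
        out = []
        for pos in self.positions:
            letters = "".join(sorted(pos, key=_AA_ORDER.index))
            out.append(letters if len(letters) == 1 else f"({letters})")
        return "".join(out)


def parse_pattern_string(text: str) -> list[frozenset[str]]:
    """Parse a rendering like ``AMDPQQ(RS)(LIMV)`` into position sets."""
    sets: list[frozenset[str]] = []
    for token in re.findall(r"\(([A-Z]+)\)|([A-Z])", text.strip()):
        sets.append(frozenset(token[0] or token[1]))
    return sets


def patterns_equivalent(a: AminoAcidPattern | str, b: AminoAcidPattern | str) -> bool:
    """Order-insensitive-within-position comparison of two patterns/renderings."""
    sa = a.positions if isinstance(a, AminoAcidPattern) else parse_pattern_string(a)
    sb = b.positions if isinstance(b, AminoAcidPattern) else parse_pattern_string(b)
    return list(map(frozenset, sa)) == list(map(frozenset, sb))


def _codon_amino_set(codon: str) -> frozenset[str]:
    aas = set()
    for b1 in ambiguous_dna_values[codon[0]]:
        for b2 in ambiguous_dna_values[codon[1]]:
            for b3 in ambiguous_dna_values[codon[2]]:
                concrete = b1 + b2 + b3
                if concrete in standard_dna_table.stop_codons:
                    continue
                aas.add(standard_dna_table.forward_table[concrete])
    return frozenset(aas)


def translate_degenerate(primer: DegeneratePrimer) -> AminoAcidPattern:
    """Expand a degenerate primer to its per-codon amino-acid sets.

    Reverse primers are reverse-complemented first.  Length not divisible by
    3 is right-padded with N; stop codons are dropped from every set, and a
    position whose expansions are all stops is an error.
    """
    notes = []
    seq = primer.nt_sequence
    if primer.orientation == "reverse":
        seq = str(Seq(seq).reverse_complement())
        notes.append("reverse-complemented before translation")
    if len(seq) % 3:
        pad = 3 - len(seq) % 3
        seq += "N" * pad
        notes.append(f"right-padded with {pad} N to complete the final codon")
    positions = []
    for i in range(0, len(seq), 3):
        aas = _codon_amino_set(seq[i : i + 3])
        if not aas:
            raise PrimerError(
                f"primer {primer.name}: codon {seq[i:i+3]} at position {i // 3 + 1} "
                "encodes only stop codons"
            )
        positions.append(aas)
    notes.append("stop codons removed from degenerate sets")
    return AminoAcidPattern(
        positions=positions,
        name=primer.name,
        orientation=primer.orientation,
        provenance="; ".join(notes),
    )


@dataclass
class SiteMatch:
    position: int  # 1-based window start on the domain
    matched: int  # pattern positions whose domain residue is in the set
    low_confidence: bool


def locate_primer_site(pattern: AminoAcidPattern, domain_residues: str) -> SiteMatch:
    """Place the pattern on a domain by maximal per-position matches.

    Sliding window, leftmost among ties; flagged low-confidence when fewer
    than half the positions match anywhere.
    """
    k = len(pattern)
    n = len(domain_residues)
    if k > n:
        raise PrimerError(f"pattern ({k} positions) longer than domain ({n} aa)")
    best_pos, best_matched = 1, -1
    for i in range(n - k + 1):
        matched = sum(
            1 for j, s in enumerate(pattern.positions) if domain_residues[i + j] in s
        )
        if matched > best_matched:
            best_pos, best_matched = i + 1, matched
    return SiteMatch(
        position=best_pos,
        matched=best_matched,
        low_confidence=best_matched < 0.5 * k,
    )


@dataclass
class MatchProfile:
    """Per-position primer match fractions for one KS group."""

    group: str
    n_domains: int
    position_fractions: list[float]  # pattern order
    full_match_fraction: float
    three_prime_offsets: list[int]  # codon distance from the primer 3' end, per position
    n_low_confidence: int = 0


def match_profile(
    pattern: AminoAcidPattern,
    domains_by_group: Mapping[str, Sequence[str]],
) -> dict[str, MatchProfile]:
    """Per-group, per-position fraction of domains matching the primer pattern.

    For each domain the primer site is located first; a position matches when
    the domain residue at the sited offset belongs to the position's set.
    ``full_match_fraction`` requires all positions simultaneously.  Empty
    groups are omitted.
    """
    profiles: dict[str, MatchProfile] = {}
    k = len(pattern)
    for group in sorted(domains_by_group):
        domains = [d for d in domains_by_group[group] if len(d) >= k]
        if not domains:
            continue
        hits = [0] * k
        full = 0
        low = 0
        for dom in domains:
            site = locate_primer_site(pattern, dom)
            low += site.low_confidence
            window = dom[site.position - 1 : site.position - 1 + k]
            ok = [window[j] in pattern.positions[j] for j in range(k)]
            for j, o in enumerate(ok):
                hits[j] += o
            full += all(ok)
        n = len(domains)
        profiles[group] = MatchProfile(
            group=group,
            n_domains=n,
            position_fractions=[h / n for h in hits],
            full_match_fraction=full / n,
            three_prime_offsets=[pattern.three_prime_offset(j + 1) for j in range(k)],
            n_low_confidence=low,
        )
    return profiles


def apply_modification(
    pattern: AminoAcidPattern, modifications: Sequence[tuple[int, str]]
) -> AminoAcidPattern:
    """Enlarge position sets, e.g. also target H and E at position 6.

    ``modifications`` is a list of (1-based position, residues-to-add).
    """
    positions = list(pattern.positions)
    for pos, residues in modifications:
        if not 1 <= pos <= len(positions):
            raise PrimerError(f"position {pos} outside pattern of length {len(positions)}")
        residues = residues.upper()
        bad = set(residues) - set(_AA_ORDER)
        if bad:
            raise PrimerError(f"invalid residue letters {sorted(bad)}")
        positions[pos - 1] = positions[pos - 1] | frozenset(residues)
    return replace(
        pattern,
        positions=positions,
        provenance=(pattern.provenance + "; modified sets: "
                    + ", ".join(f"+{r}@{p}" for p, r in modifications)).strip("; "),
    )


def profiles_to_frame(profiles: Mapping[str, MatchProfile]) -> pd.DataFrame:
    rows = []
    for group, prof in profiles.items():
        for j, frac in enumerate(prof.position_fractions):
            rows.append(
                {
                    "group": group,
                    "position": j + 1,
                    "three_prime_offset": prof.three_prime_offsets[j],
                    "fraction_matching": frac,
                    "n_domains": prof.n_domains,
                    "full_match_fraction": prof.full_match_fraction,
                }
            )
    return pd.DataFrame(rows)


def bundled_primers() -> list[DegeneratePrimer]:
    return [DegeneratePrimer(*KS2F), DegeneratePrimer(*KS2R)]
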