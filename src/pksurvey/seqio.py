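"""Sequence and hit-table I/O: FASTA reading/writing, contig length filtering,
six-frame translation, and BLAST-style tabular hit parsing.

Assembled metagenome contigs enter the pipeline here.  Contigs shorter than
600 nt are discarded before domain detection (short contigs cannot contain a
meaningful fraction of a ~420 aa ketosynthase domain), and nucleotide contigs
are translated in all six reading frames so that domains can be detected
regardless of strand or frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = set("ACGTURYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"


class FastaParseError(ValueError):
    """Raised when a FASTA or tabular file violates the expected format."""


class AlphabetError(ValueError):
    """Raised when a record's alphabet does not match the operation's contract."""


@dataclass
class SequenceRecord:
    """A single named sequence.

    ``alphabet`` is ``"nucleotide"`` or ``"protein"``; residues are stored
    uppercase.  Protein residues are the 20 standard amino acids plus ``X``
    for ambiguity; nucleotide residues may use any IUPAC code.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = PROTEIN

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == NUCLEOTIDE else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} outside the "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TabularHit:
    """One row of a 12-column BLAST-style (outfmt 6) hit table."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _guess_alphabet(residues: str) -> str:
    letters = set(residues.upper())
    if letters <= NUCLEOTIDE_ALPHABET:
        return NUCLEOTIDE
    return PROTEIN


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; duplicate ids are rejected.  If ``alphabet`` is None
    each record's alphabet is guessed (a sequence over ACGTUN/IUPAC nucleotide
    codes only is called nucleotide).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if current_id is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"{path}: record {current_id!r} has an empty sequence "
                                  f"(before line {line_no})")
        records.append(
            SequenceRecord(
                id=current_id,
                residues=residues,
                description=current_desc,
                alphabet=alphabet or _guess_alphabet(residues),
            )
        )

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
                parts = header.split(None, 1)
                current_id = parts[0]
                current_desc = parts[1] if len(parts) > 1 else ""
                if current_id in seen:
                    raise FastaParseError(f"{path}:{line_no}: duplicate id {current_id!r}")
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(f"{path}:{line_no}: sequence data before first header")
                chunks.append(line)
    _flush(line_no=-1)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def filter_contigs(records: Sequence[SequenceRecord], min_nt: int = 600) -> list[SequenceRecord]:
    """Keep nucleotide contigs of length >= ``min_nt`` (boundary inclusive)."""
    for rec in records:
        if rec.alphabet != NUCLEOTIDE:
            raise AlphabetError(f"filter_contigs expects nucleotide records; {rec.id!r} is {rec.alphabet}")
    return [rec for rec in records if len(rec) >= min_nt]


def six_frame_translate(record: SequenceRecord, min_peptide_aa: int = 60) -> list[SequenceRecord]:
    """Translate a nucleotide contig in all six frames and split at stops.

    Peptides shorter than ``min_peptide_aa`` are dropped.  Each peptide id
    encodes the source id, the frame (+1..+3 / -1..-3) and the 1-based start
    of its first codon on the *forward* strand, e.g. ``contig7|+2|14``.
    Ambiguous codons translate to ``X`` unless every expansion agrees.
    """
    if record.alphabet != NUCLEOTIDE:
        raise AlphabetError(f"six_frame_translate expects a nucleotide record; got {record.alphabet}")
    n = len(record.residues)
    fwd = Seq(record.residues.replace("U", "T"))
    rev = fwd.reverse_complement()
    peptides: list[SequenceRecord] = []
    for strand, seq in ((1, fwd), (-1, rev)):
        for offset in range(3):
            frame = strand * (offset + 1)
            sub = seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) == 0:
                continue
            aa = str(sub.translate())
            pos = 0
            for piece in aa.split("*"):
                if len(piece) >= min_peptide_aa:
                    # first codon of the peptide, 0-based on the translated strand
                    codon0 = offset + 3 * pos
                    if strand == 1:
                        nt_start = codon0 + 1
                    else:
                        # codon0 counts from the 3' end of the forward strand
                        nt_start = n - codon0 - 2
                    pid = f"{record.id}|{'+' if strand == 1 else '-'}{offset + 1}|{nt_start}"
                    peptides.append(
                        SequenceRecord(id=pid, residues=piece, alphabet=PROTEIN,
                                       description=f"frame={frame} source={record.id}")
                    )
                pos += len(piece) + 1
    return peptides


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse a 12-column tab-separated BLAST-style hit table, in file order."""
    path = Path(path)
    hits: list[TabularHit] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FastaParseError(
                    f"{path}:{line_no}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    TabularHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FastaParseError(f"{path}:{line_no}: {exc}") from exc
    return hits


def read_manifest(path: str | Path):
    """Read the per-metagenome manifest (metagenome_id, biome, size_gbp), tab-separated."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"metagenome_id": str, "biome": str})
    required = {"metagenome_id", "biome", "size_gbp"}
    missing = required - set(df.columns)
    if missing:
        raise FastaParseError(f"{path}: manifest missing columns {sorted(missing)}")
    if (df["size_gbp"] <= 0).any():
        raise ValueError(f"{path}: size_gbp must be positive")
    return df
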