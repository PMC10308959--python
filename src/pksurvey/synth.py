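"""Synthetic biome-structured KS metagenome generator with truth labels.

Real surveys of this kind run on hundreds of Gbp of assembled metagenomes
searched against a curated KS reference database; neither fits a test
suite.  This module builds the whole study world synthetically and
deterministically:

* a labeled reference collection — per KS leaf class, a handful of lineage
  "seed" domains (~420 aa) that all begin with the IAIVG anchor and end with
  GTNAH, with different leaf classes essentially unrelated and lineages
  within a leaf roughly 60-65% identical;
* environmental domains — drawn from per-biome mixtures over the 11 leaf
  classes, mutated away from their lineage seed to a controlled amino acid
  identity (substitutions only, anchors protected), with a tunable fraction
  left full length and the rest truncated so an anchor is lost;
* nucleotide contigs — back-translated domains embedded in random flanks,
  exercising the six-frame translation path.

Every generated sequence carries a truth record (leaf, lineage, realized
identity, biome, full-length status) so recovery rates of the downstream
pipeline can be measured exactly.  All randomness flows through an
explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .classify import LEAF_LABELS, ReferenceEntry
from .fulllength import END_ANCHOR, START_ANCHOR
from .seqio import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_DOMAIN_LENGTH = 420
REFERENCE_SEED = 20230605  # pinned so the bundled reference is reproducible

#: dominant phyla per leaf class, echoing taxonomic patterns typical of each
#: KS type (soil actinobacterial assembly lines, cyanobacterial hybrids,
#: deltaproteobacterial PUFA synthases, ...)
_LEAF_PHYLA = {
    "modular cis-AT": ["Actinobacteria", "Cyanobacteria", "Proteobacteria"],
    "cis-loading module": ["Actinobacteria", "Proteobacteria"],
    "olefin synthase": ["Cyanobacteria", "Actinobacteria"],
    "iterative aromatic": ["Actinobacteria", "Proteobacteria"],
    "iterative PTM": ["Proteobacteria", "Verrucomicrobia", "Planctomycetes"],
    "trans-AT": ["Gammaproteobacteria", "Firmicutes", "Proteobacteria"],
    "hybrid trans-AT": ["Firmicutes", "Gammaproteobacteria"],
    "hybrid cis-AT": ["Cyanobacteria", "Proteobacteria", "Actinobacteria"],
    "PUFA": ["Deltaproteobacteria", "Gammaproteobacteria"],
    "enediyne": ["Actinobacteria", "Deltaproteobacteria"],
    "FAS": ["Proteobacteria", "Firmicutes"],
}


@dataclass
class BiomeProfile:
    """Generating conditions for one biome's KS domain pool."""

    name: str
    weights: dict[str, float]  # leaf label -> mixture weight, sums to 1
    lineage_count: int = 4  # lineage seeds used per leaf
    identity_target: float = 0.9  # realized identity to the lineage seed
    full_length_fraction: float = 0.8

    def __post_init__(self) -> None:
        bad = set(self.weights) - set(LEAF_LABELS)
        if bad:
            raise ValueError(f"biome {self.name}: unknown leaf labels {sorted(bad)}")
        total = sum(self.weights.values())
        if any(w < 0 for w in self.weights.values()) or abs(total - 1) > 1e-9:
            raise ValueError(f"biome {self.name}: weights must be non-negative and sum to 1")
        if not 0.5 < self.identity_target <= 1:
            raise ValueError("identity_target must be in (0.5, 1]")
        if not 0 <= self.full_length_fraction <= 1:
            raise ValueError("full_length_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    sequence_id: str
    leaf_label: str
    lineage_id: str
    realized_identity: float
    biome: str
    is_full_length: bool


def _random_domain(rng: np.random.Generator, length: int = DEFAULT_DOMAIN_LENGTH) -> str:
    core = rng.choice(list(AA), size=length - 10)
    return START_ANCHOR + "".join(core) + END_ANCHOR


_SUB_PROBS: dict[str, tuple[np.ndarray, np.ndarray]] | None = None


def _substitution_proposal() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-residue replacement distribution, weighted 2**(BLOSUM62/2)."""
    global _SUB_PROBS
    if _SUB_PROBS is None:
        blosum = substitution_matrices.load("BLOSUM62")
        table = {}
        for a in AA:
            others = [b for b in AA if b != a]
            w = np.array([2.0 ** (blosum[a, b] / 2.0) for b in others])
            table[a] = (np.array(others), w / w.sum())
        _SUB_PROBS = table
    return _SUB_PROBS


def mutate_to_identity(
    seed_sequence: str,
    identity_target: float,
    rng: np.random.Generator,
    protect_anchors: bool = True,
) -> tuple[str, float]:
    """Substitute residues until identity to the seed hits the target (+-0.03).

    Substitutions only (no indels) at distinct positions outside the two
    5-residue anchor windows, drawn from a BLOSUM62-weighted proposal, so the
    realized global identity is exactly (L - n_substitutions) / L.
    """
    if not 0.5 < identity_target <= 1:
        raise ValueError("identity_target must be in (0.5, 1]")
    length = len(seed_sequence)
    n_sub = round((1 - identity_target) * length)
    protected = set(range(5)) | set(range(length - 5, length)) if protect_anchors else set()
    available = [i for i in range(length) if i not in protected]
    if n_sub > len(available):
        raise ValueError(
            f"cannot place {n_sub} substitutions in {len(available)} mutable positions"
        )
    realized = (length - n_sub) / length
    if abs(realized - identity_target) > 0.03:
        raise ValueError("sequence too short to realize the identity target within 0.03")
    proposal = _substitution_proposal()
    positions = rng.choice(len(available), size=n_sub, replace=False)
    residues = list(seed_sequence)
    for p in positions:
        i = available[p]
        orig = residues[i]
        choices, probs = proposal.get(orig, (np.array(list(AA)), np.full(20, 0.05)))
        residues[i] = str(rng.choice(choices, p=probs))
    return "".join(residues), realized


def synthetic_reference(
    seed: int = REFERENCE_SEED,
    lineages_per_leaf: int = 8,
    length: int = DEFAULT_DOMAIN_LENGTH,
    leaf_labels: Sequence[str] = LEAF_LABELS,
    lineage_identity: float = 0.82,
) -> list[ReferenceEntry]:
    """Generate the labeled synthetic reference collection.

    Per leaf class, an unrelated base domain is drawn and ``lineages_per_leaf``
    lineage seeds are mutated from it at ``lineage_identity``, leaving
    within-leaf lineages ~60-65% identical to each other and cross-leaf
    identity at random-background level.  This is a synthetic stand-in for a
    curated KS reference database: its labels and anchor structure are
    faithful, its absolute sequence content is not.
    """
    rng = np.random.default_rng(seed)
    entries: list[ReferenceEntry] = []
    for leaf_idx, leaf in enumerate(leaf_labels):
        base = _random_domain(rng, length)
        phyla = _LEAF_PHYLA.get(leaf, ["Proteobacteria"])
        slug = leaf.replace(" ", "_").replace("/", "-")
        for k in range(lineages_per_leaf):
            seq, _ = mutate_to_identity(base, lineage_identity, rng)
            entries.append(
                ReferenceEntry(
                    id=f"ref_{slug}_{k:02d}",
                    residues=seq,
                    leaf_label=leaf,
                    phylum=phyla[k % len(phyla)],
                )
            )
    return entries


def reference_by_leaf(refdb: Sequence[ReferenceEntry]) -> dict[str, list[ReferenceEntry]]:
    out: dict[str, list[ReferenceEntry]] = {}
    for entry in refdb:
        out.setdefault(entry.leaf_label, []).append(entry)
    return out


def generate_biome(
    profile: BiomeProfile,
    n_sequences: int,
    rng: np.random.Generator,
    refdb: Sequence[ReferenceEntry],
    id_prefix: str | None = None,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Draw a biome's KS domain pool from its mixture profile.

    Leaf labels follow the mixture weights; each sequence mutates a randomly
    chosen lineage seed of its leaf to the profile's identity target.  A
    ``full_length_fraction`` subset keeps both anchors; the rest lose one
    anchor by truncation (start or end, coin flip).
    """
    seeds = reference_by_leaf(refdb)
    leaves = sorted(profile.weights)
    weights = np.array([profile.weights[l] for l in leaves])
    for leaf in leaves:
        if profile.weights[leaf] > 0 and leaf not in seeds:
            raise ValueError(f"biome {profile.name}: no reference seeds for leaf {leaf!r}")
    prefix = id_prefix or profile.name.replace(" ", "_").replace("/", "-")
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for i in range(n_sequences):
        leaf = leaves[rng.choice(len(leaves), p=weights)]
        lineage_pool = seeds[leaf][: profile.lineage_count]
        lineage = lineage_pool[rng.integers(len(lineage_pool))]
        seq, realized = mutate_to_identity(lineage.residues, profile.identity_target, rng)
        full = bool(rng.random() < profile.full_length_fraction)
        if not full:
            cut = int(rng.integers(8, 25))
            seq = seq[cut:] if rng.random() < 0.5 else seq[:-cut]
        sid = f"{prefix}_{i:05d}"
        records.append(SequenceRecord(id=sid, residues=seq, alphabet="protein",
                                      description=f"biome={profile.name}"))
        truths.append(
            TruthRecord(
                sequence_id=sid,
                leaf_label=leaf,
                lineage_id=lineage.id,
                realized_identity=realized,
                biome=profile.name,
                is_full_length=full,
            )
        )
    return records, truths


_CODONS_FOR_AA: dict[str, list[str]] | None = None


def _codons_for_aa() -> dict[str, list[str]]:
    global _CODONS_FOR_AA
    if _CODONS_FOR_AA is None:
        table: dict[str, list[str]] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            table.setdefault(aa, []).append(codon)
        _CODONS_FOR_AA = table
    return _CODONS_FOR_AA


def back_translate(
    protein_record: SequenceRecord, rng: np.random.Generator, flank_nt: int = 300
) -> SequenceRecord:
    """Embed a protein in a nucleotide contig: uniform synonymous codons plus
    random flanks, so six-frame translation recovers it in one frame."""
    codons = _codons_for_aa()
    body = "".join(str(rng.choice(codons.get(aa, ["NNN"]))) for aa in protein_record.residues)
    left = "".join(rng.choice(list("ACGT"), size=flank_nt))
    right = "".join(rng.choice(list("ACGT"), size=flank_nt))
    return SequenceRecord(
        id=f"{protein_record.id}_contig",
        residues=left + body + right,
        alphabet="nucleotide",
        description=f"back-translated from {protein_record.id} (+{flank_nt} nt flanks)",
    )


def load_bundled_reference() -> list[ReferenceEntry]:
    """Load the synthetic labeled reference collection shipped with the package.

    Identical to ``synthetic_reference()`` at its pinned seed; the files
    exist so external tools (or a user's own aligner) can consume the same
    collection.
    """
    from importlib.resources import files

    from .classify import load_reference

    data = files("pksurvey") / "data"
    return load_reference(
        str(data / "synthetic_reference.faa"),
        str(data / "synthetic_reference_metadata.tsv"),
    )


def load_biome_profiles(path: str | None = None) -> list[BiomeProfile]:
    """Load biome mixture profiles from YAML (default: the bundled eight)."""
    import yaml
    from importlib.resources import files

    if path is None:
        path = str(files("pksurvey") / "data" / "biome_profiles.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        BiomeProfile(
            name=item["name"],
            weights=item["weights"],
            lineage_count=item.get("lineage_count", 4),
            identity_target=item.get("identity_target", 0.9),
            full_length_fraction=item.get("full_length_fraction", 0.8),
        )
        for item in raw
    ]


def default_biome_profiles(
    lineage_count: int = 4,
    identity_target: float = 0.9,
    full_length_fraction: float = 0.8,
) -> list[BiomeProfile]:
    """Eight illustrative biome mixtures.

    Qualitative structure only: marine biomes are enriched in PUFA and
    enediyne KS domains, soils in modular and hybrid cis-AT domains, with
    the remaining classes spread thinly.  The exact weights are this
    package's choice of plausible conditions, not measurements.
    """
    base = {leaf: 0.02 for leaf in LEAF_LABELS}

    def mk(name, **over):
        w = dict(base)
        w.update(over)
        total = sum(w.values())
        w = {k: v / total for k, v in w.items()}
        return BiomeProfile(
            name=name, weights=w, lineage_count=lineage_count,
            identity_target=identity_target, full_length_fraction=full_length_fraction,
        )

    return [
        mk("forest_agricultural_soil", **{"modular cis-AT": 0.42, "hybrid cis-AT": 0.22,
                                          "iterative PTM": 0.08}),
        mk("rhizosphere", **{"modular cis-AT": 0.32, "hybrid cis-AT": 0.28, "trans-AT": 0.08}),
        mk("peat_soil", **{"modular cis-AT": 0.30, "hybrid cis-AT": 0.18,
                           "iterative aromatic": 0.12}),
        mk("freshwater", **{"modular cis-AT": 0.18, "PUFA": 0.16, "hybrid cis-AT": 0.16,
                            "olefin synthase": 0.10}),
        mk("freshwater_sediment", **{"PUFA": 0.22, "modular cis-AT": 0.20, "trans-AT": 0.12}),
        mk("seawater", **{"PUFA": 0.38, "enediyne": 0.10, "hybrid cis-AT": 0.14}),
        mk("marine_sediment", **{"PUFA": 0.34, "enediyne": 0.18, "trans-AT": 0.10}),
        mk("host_associated", **{"trans-AT": 0.26, "hybrid trans-AT": 0.14,
                                 "modular cis-AT": 0.18}),
    ]


def generate_survey(
    profiles: Sequence[BiomeProfile],
    metagenomes_per_biome: int = 3,
    sequences_per_metagenome: int = 40,
    seed: int = 0,
    refdb: Sequence[ReferenceEntry] | None = None,
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-biome survey: per-metagenome domain pools + manifest.

    Returns (records per metagenome id, manifest frame with biome and
    size_gbp, truth frame).  Metagenome sizes in Gbp are drawn uniformly
    from 1-3 Gbp, so per-Gbp normalization has something to do.
    """
    if refdb is None:
        refdb = synthetic_reference()
    rng = np.random.default_rng(seed)
    records: dict[str, list[SequenceRecord]] = {}
    manifest_rows = []
    truth_rows = []
    for profile in profiles:
        for m in range(metagenomes_per_biome):
            mg_id = f"{profile.name}_mg{m:02d}"
            recs, truths = generate_biome(
                profile, sequences_per_metagenome, rng, refdb, id_prefix=mg_id
            )
            records[mg_id] = recs
            manifest_rows.append(
                {"metagenome_id": mg_id, "biome": profile.name,
                 "size_gbp": float(np.round(rng.uniform(1.0, 3.0), 3))}
            )
            truth_rows.extend(
                {"sequence_id": t.sequence_id, "leaf_label": t.leaf_label,
                 "lineage_id": t.lineage_id, "realized_identity": t.realized_identity,
                 "biome": t.biome, "is_full_length": t.is_full_length, "metagenome_id": mg_id}
                for t in truths
            )
    return records, pd.DataFrame(manifest_rows), pd.DataFrame(truth_rows)
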