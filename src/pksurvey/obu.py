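"""Operational biosynthetic unit (OBU) clustering and richness statistics.

Full-length KS domains are grouped into OBUs — the biosynthetic analogue of
OTUs — by greedy centroid clustering at a fixed amino acid identity
threshold (typically 70/80/90/95%).  Identity is matches over global
alignment columns (gaps included), appropriate because full-length domains
are homologous end to end.  Richness per biome is estimated with the
bias-corrected Chao1 index, averaged over replicate rarefactions, and
between-biome overlap is summarized by counting OBUs (and the domains inside
them) shared by biome pairs after rarefying every biome to a common depth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import global_identity
from .seqio import SequenceRecord

DEFAULT_THRESHOLDS = (0.70, 0.80, 0.90, 0.95)
DEFAULT_RAREFACTION_DEPTH = 580
DEFAULT_REPLICATES = 10


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class OBUTable:
    """Greedy centroid clustering of a sequence set at one identity threshold."""

    threshold: float
    clusters: list[Cluster]

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def membership(self) -> dict[str, str]:
        """member id -> centroid id"""
        return {m: c.centroid_id for c in self.clusters for m in c.member_ids}


@dataclass
class RichnessEstimate:
    biome: str
    threshold: float
    chao1_mean: float
    chao1_sd: float
    replicates: int
    rarefaction_depth: int


@dataclass
class SharedOBUResult:
    biome_pair: tuple[str, str]
    threshold: float
    shared_obu_count: int
    shared_domain_count: int


def cluster_obus(sequences: Sequence[SequenceRecord], threshold: float) -> OBUTable:
    """Greedy incremental centroid clustering at ``threshold`` identity.

    Sequences are visited in order of decreasing length (ties by id); each
    joins the first existing centroid, in founding order, with global
    identity >= threshold, otherwise it founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(sequences, key=lambda r: (-len(r.residues), r.id))
    clusters: list[Cluster] = []
    centroid_seqs: list[str] = []
    for rec in ordered:
        placed = False
        for cl, cseq in zip(clusters, centroid_seqs):
            lo, hi = sorted((len(rec.residues), len(cseq)))
            if lo / hi < threshold:  # identity can never reach threshold
                continue
            if global_identity(rec.residues, cseq) >= threshold:
                cl.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid_id=rec.id, member_ids=[rec.id]))
            centroid_seqs.append(rec.residues)
    return OBUTable(threshold=threshold, clusters=clusters)


def rarefy_sequences(
    sequences: Sequence[SequenceRecord], depth: int, rng: np.random.Generator
) -> list[SequenceRecord]:
    """Uniform sample of ``depth`` sequences without replacement."""
    if len(sequences) < depth:
        raise ValueError(
            f"cannot rarefy {len(sequences)} sequences to depth {depth}; lower the depth"
        )
    idx = rng.choice(len(sequences), size=depth, replace=False)
    return [sequences[i] for i in idx]


def chao1(obu_sizes: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    if len(obu_sizes) == 0:
        raise ValueError("chao1 requires at least one cluster")
    if any(s <= 0 for s in obu_sizes):
        raise ValueError("cluster sizes must be positive")
    s_obs = len(obu_sizes)
    f1 = sum(1 for s in obu_sizes if s == 1)
    f2 = sum(1 for s in obu_sizes if s == 2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def richness_by_biome(
    biome_domains: Mapping[str, Sequence[SequenceRecord]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> list[RichnessEstimate]:
    """Mean/sd of Chao1 over replicate rarefy -> cluster -> Chao1 runs.

    The rarefaction depth auto-lowers to the smallest biome size (with a
    warning) when a requested depth exceeds it, so that modest synthetic
    runs remain analyzable; biomes smaller than 2 sequences are skipped.
    """
    sizes = {b: len(s) for b, s in biome_domains.items()}
    usable = {b: s for b, s in biome_domains.items() if sizes[b] >= 2}
    if not usable:
        return []
    min_size = min(len(s) for s in usable.values())
    if depth > min_size:
        warnings.warn(
            f"rarefaction depth {depth} exceeds smallest biome ({min_size}); lowering",
            stacklevel=2,
        )
        depth = min_size
    rng = np.random.default_rng(seed)
    out: list[RichnessEstimate] = []
    for biome in sorted(usable):
        seqs = list(usable[biome])
        for thr in thresholds:
            vals = []
            for _ in range(replicates):
                sub = rarefy_sequences(seqs, depth, rng)
                vals.append(chao1(cluster_obus(sub, thr).sizes))
            vals = np.asarray(vals)
            out.append(
                RichnessEstimate(
                    biome=biome,
                    threshold=thr,
                    chao1_mean=float(vals.mean()),
                    chao1_sd=float(vals.std(ddof=1)) if replicates > 1 else 0.0,
                    replicates=replicates,
                    rarefaction_depth=depth,
                )
            )
    return out


def shared_obus(
    biome_domains: Mapping[str, Sequence[SequenceRecord]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    depth: int | None = None,
    seed: int = 0,
) -> list[SharedOBUResult]:
    """Count OBUs (and member domains) shared by each biome pair.

    All biomes are rarefied to a common depth (default: the smallest biome),
    pooled, and clustered once per threshold.  An OBU is shared by a pair
    when it contains at least one member from each; the domain count sums the
    pair's members inside those shared OBUs.
    """
    if len(biome_domains) < 2:
        raise ValueError("shared_obus requires at least two biomes")
    min_size = min(len(s) for s in biome_domains.values())
    if depth is None or depth > min_size:
        if depth is not None:
            warnings.warn(
                f"depth {depth} exceeds smallest biome ({min_size}); lowering", stacklevel=2
            )
        depth = min_size
    rng = np.random.default_rng(seed)
    biome_of: dict[str, str] = {}
    pooled: list[SequenceRecord] = []
    for biome in sorted(biome_domains):
        sub = rarefy_sequences(list(biome_domains[biome]), depth, rng)
        for rec in sub:
            # pooled ids must stay unique across biomes
            tagged = SequenceRecord(
                id=f"{biome}||{rec.id}", residues=rec.residues, alphabet=rec.alphabet
            )
            pooled.append(tagged)
            biome_of[tagged.id] = biome
    results: list[SharedOBUResult] = []
    for thr in thresholds:
        table = cluster_obus(pooled, thr)
        for b1, b2 in itertools.combinations(sorted(biome_domains), 2):
            n_obu = 0
            n_dom = 0
            for cl in table.clusters:
                members = [biome_of[m] for m in cl.member_ids]
                c1 = members.count(b1)
                c2 = members.count(b2)
                if c1 > 0 and c2 > 0:
                    n_obu += 1
                    n_dom += c1 + c2
            results.append(
                SharedOBUResult(
                    biome_pair=(b1, b2),
                    threshold=thr,
                    shared_obu_count=n_obu,
                    shared_domain_count=n_dom,
                )
            )
    return results
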