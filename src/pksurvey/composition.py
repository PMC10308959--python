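"""Biome composition statistics for KS domain class profiles.

Builds samples x KS-leaf-class matrices (raw counts, counts per Gbp of
metagenomic data, or rarefied mean counts), converts them to Bray-Curtis
dissimilarities, ordains them by principal coordinates analysis (PCoA), and
tests biome separation with a permutational multivariate ANOVA (PERMANOVA)
plus per-class one-way ANOVA with Tukey's HSD.

Rarefied composition mirrors the common practice of rarefying each
metagenome to a fixed number of domain calls (default 100) and averaging
class counts over many permutations (default 1,000); permutation means are
kept as fractional values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .classify import LEAF_LABELS, DomainCall


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v


@dataclass
class PCoAResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    p_value: float
    significant: bool


@dataclass
class TukeyResult:
    f_statistic: float
    anova_p: float
    alpha: float
    pairs: list[TukeyPair]


def ks_per_gbp(counts: np.ndarray | Sequence[float], size_gbp: float) -> np.ndarray:
    """KS domain counts normalized per Gbp of metagenome."""
    if size_gbp <= 0:
        raise ValueError("size_gbp must be positive")
    return np.asarray(counts, dtype=float) / size_gbp


def count_matrix(
    calls_by_metagenome: Mapping[str, Sequence[DomainCall]],
    leaf_labels: Sequence[str] = LEAF_LABELS,
) -> pd.DataFrame:
    """Raw samples x leaf-class count matrix."""
    rows = {}
    for mg in sorted(calls_by_metagenome):
        counts = {leaf: 0 for leaf in leaf_labels}
        for call in calls_by_metagenome[mg]:
            if call.leaf_label in counts:
                counts[call.leaf_label] += 1
        rows[mg] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(leaf_labels))


def rarefied_composition(
    calls_by_metagenome: Mapping[str, Sequence[DomainCall]],
    depth: int = 100,
    permutations: int = 1000,
    seed: int = 0,
    leaf_labels: Sequence[str] = LEAF_LABELS,
) -> pd.DataFrame:
    """Mean leaf-class counts of ``permutations`` rarefactions to ``depth``.

    Metagenomes with fewer than ``depth`` calls are excluded with a warning.
    Sampling without replacement from a fixed pool of calls makes each draw
    multivariate hypergeometric, which is sampled directly.
    """
    rng = np.random.default_rng(seed)
    counts = count_matrix(calls_by_metagenome, leaf_labels)
    keep, rows = [], []
    for mg in counts.index:
        c = counts.loc[mg].to_numpy()
        total = int(c.sum())
        if total < depth:
            warnings.warn(
                f"metagenome {mg!r} has {total} calls < depth {depth}; excluded", stacklevel=2
            )
            continue
        if total == depth:
            mean = c.astype(float)
        else:
            draws = rng.multivariate_hypergeometric(c, depth, size=permutations)
            mean = draws.mean(axis=0)
        keep.append(mg)
        rows.append(mean)
    return pd.DataFrame(rows, index=keep, columns=list(leaf_labels))


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    if (values.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis is undefined for all-zero rows")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(ids=list(matrix.index), values=d)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates analysis via Gower double-centering.

    Eigendecomposition of -0.5 * J D^2 J; coordinates are eigenvectors scaled
    by sqrt(eigenvalue) for positive eigenvalues.  Negative eigenvalues are
    reported unchanged and excluded from the proportion-explained
    denominator; no Lingoes/Cailliez correction is applied.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-12 * max(1.0, abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _permanova_stats(d2: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    """(pseudo_F, R2) from a squared-distance matrix and integer group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    g_count = len(uniq)
    ss_between = ss_total - ss_within
    f = (ss_between / (g_count - 1)) / (ss_within / (n - g_count)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str],
    permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free label permutation.

    p = (#{permuted F >= observed F} + 1) / (permutations + 1).
    """
    labels = np.asarray(labels)
    if len(labels) != len(dm.ids):
        raise ValueError("labels length must match the distance matrix")
    uniq, groups = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    for g in range(len(uniq)):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {uniq[g]!r} has fewer than 2 members")
    d2 = dm.values ** 2
    uniq_idx = np.arange(len(uniq))
    f_obs, r2 = _permanova_stats(d2, groups, uniq_idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(groups)
        f_perm, _ = _permanova_stats(d2, perm, uniq_idx)
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2), p_value=float(p),
        n_permutations=permutations, seed=seed,
    )


def anova_tukey(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.01
) -> TukeyResult:
    """One-way ANOVA followed by Tukey's HSD across groups.

    Pairs are flagged at ``alpha`` (default 0.01).  Raises when the pooled
    within-group variance is zero (F undefined).
    """
    names = sorted(values_by_group)
    if len(names) < 2:
        raise ValueError("ANOVA requires at least two groups")
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        raise ValueError("all values identical; F statistic undefined")
    f_stat, p_val = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            p = float(hsd.pvalue[i, k])
            pairs.append(
                TukeyPair(
                    group_a=names[i],
                    group_b=names[k],
                    mean_diff=float(samples[i].mean() - samples[k].mean()),
                    p_value=p,
                    significant=p < alpha,
                )
            )
    return TukeyResult(f_statistic=float(f_stat), anova_p=float(p_val), alpha=alpha, pairs=pairs)
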