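"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive alignment scores, identities and clusterings
from first principles (naive Gotoh dynamic programming, exhaustive scans)
without touching the package's alignment machinery, so they can serve as
ground truth for it.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")

# gap of length k costs OPEN + (k-1)*EXTEND, mirroring blastp's 11/1 as 12/1
GAP_OPEN = 12
GAP_EXTEND = 1

NEG = float("-inf")


def _score(a: str, b: str) -> float:
    return _BLOSUM[a, b]


def _gotoh_matrices(x: str, y: str, local: bool):
    """Full H/E/F matrices (lists of lists)."""
    m, n = len(x), len(y)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in x (consumes y)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in y (consumes x)
    if not local:
        for j in range(1, n + 1):
            E[0][j] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
            H[0][j] = E[0][j]
        for i in range(1, m + 1):
            F[i][0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)
            H[i][0] = F[i][0]
    for i in range(1, m + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        xi = x[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] - GAP_OPEN, Ei[j - 1] - GAP_EXTEND)
            Fi[j] = max(Hi1[j] - GAP_OPEN, Fi1[j] - GAP_EXTEND)
            h = max(Hi1[j - 1] + _score(xi, y[j - 1]), Ei[j], Fi[j])
            if local:
                h = max(0.0, h)
            Hi[j] = h
    return H, E, F


def gotoh_local_score(x: str, y: str) -> float:
    """Smith-Waterman affine-gap optimal score by naive dynamic programming."""
    H, _, _ = _gotoh_matrices(x, y, local=True)
    return max(max(row) for row in H)


def gotoh_global_score(x: str, y: str) -> float:
    """Needleman-Wunsch affine-gap optimal score (end gaps penalized)."""
    H, _, _ = _gotoh_matrices(x, y, local=False)
    return H[len(x)][len(y)]


def gotoh_global_identity(x: str, y: str) -> float:
    """matches / columns from a traceback of the optimal global alignment.

    X never counts as a match; gap columns (including terminal gaps) count
    toward the denominator.
    """
    H, E, F = _gotoh_matrices(x, y, local=False)
    i, j = len(x), len(y)
    matches = 0
    columns = 0
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + _score(x[i - 1], y[j - 1]):
                if x[i - 1] == y[j - 1] and x[i - 1] != "X":
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif j > 0 and H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            close = E[i][j] == H[i][j - 1] - GAP_OPEN
            j -= 1
            if close:
                state = "H"
        else:  # F
            columns += 1
            close = F[i][j] == H[i - 1][j] - GAP_OPEN
            i -= 1
            if close:
                state = "H"
    return matches / columns if columns else 0.0


def greedy_cluster_oracle(records, threshold, identity_fn=gotoh_global_identity):
    """Independent greedy centroid clustering (decreasing length, then id).

    Returns [(centroid_id, [member ids])] in founding order.
    """
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    clusters: list[dict] = []
    for rec in ordered:
        for cl in clusters:
            if identity_fn(rec.residues, cl["seq"]) >= threshold:
                cl["members"].append(rec.id)
                break
        else:
            clusters.append({"seq": rec.residues, "id": rec.id, "members": [rec.id]})
    return [(cl["id"], cl["members"]) for cl in clusters]
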