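"""Cosine vertex similarity and hierarchical clustering of event graphs.

Two contacts are similar when they connect to the same set of contacts: the
similarity of vertices x and y is the cosine of the angle between their rows
of the adjacency matrix,

    sigma_xy = sum_k M_xk M_yk / sqrt(sum_k M_xk^2 * sum_k M_yk^2),

which for binary adjacency reduces to overlap / sqrt(deg_x * deg_y).
Agglomerative clustering on the dissimilarity d = 1 - sigma (average linkage,
deterministic lexicographic tie-breaking) yields a dendrogram per event;
pooled similarity values, binned at 6-decimal precision, summarise how motif
structure differs between seizure phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .graphs import AdjacencyMatrix
from .signal_io import EventAnnotation


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of cosine vertex similarities in [0, 1].

    Vertices with an all-zero adjacency row (no out-edges) have similarity 0
    against everything, including themselves.
    """

    labels: list
    S: np.ndarray
    event: EventAnnotation | None = None


@dataclass
class Dendrogram:
    """Agglomerative merge sequence in scipy linkage convention.

    Leaves are numbered 0..n-1 in ``leaves`` order; the cluster created by
    merge k gets id n+k.  ``merges`` rows are (id_a, id_b, height, new_size)
    with id_a < id_b; heights are nondecreasing dissimilarities in [0, 1].
    """

    leaves: list
    merges: list  # of (int, int, float, int)

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_linkage_frame(self):
        import pandas as pd

        return pd.DataFrame(self.merges, columns=["a", "b", "height", "size"])

    def to_newick(self) -> str:
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        rep = {i: str(self.leaves[i]) for i in range(n)}
        for k, (a, b, h, _s) in enumerate(self.merges):
            la = h - height[a]
            lb = h - height[b]
            rep[n + k] = f"({rep[a]}:{la:.6f},{rep[b]}:{lb:.6f})"
            height[n + k] = h
        return rep[n + len(self.merges) - 1] + ";"


@dataclass
class SimilarityDistribution:
    """Counts of unordered vertex pairs per similarity value (6-decimal bins)."""

    counts: dict  # key: value or (phase, value) -> count
    grouped_by_phase: bool = False
    include_zero: bool = False

    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_frame(self):
        import pandas as pd

        if self.grouped_by_phase:
            rows = [{"phase": k[0], "similarity": k[1], "count": v}
                    for k, v in sorted(self.counts.items())]
        else:
            rows = [{"similarity": k, "count": v}
                    for k, v in sorted(self.counts.items())]
        return pd.DataFrame(rows)


def electrode_of(contact: str) -> str:
    """Electrode name of a contact label: the leading non-digit prefix ('LJ1' -> 'LJ')."""
    i = 0
    while i < len(contact) and not contact[i].isdigit():
        i += 1
    return contact[:i] or contact


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def cosine_similarity(adj: AdjacencyMatrix, symmetrize: bool = False) -> SimilarityMatrix:
    """Cosine similarity between adjacency rows (out-neighbour profiles).

    ``symmetrize`` computes on M + M.T instead, treating in- and out-edges
    alike.
    """
    M = np.asarray(adj.M, dtype=float)
    if np.any(M < 0):
        raise ValueError("adjacency entries must be nonnegative")
    if symmetrize:
        M = M + M.T
    norms = np.sqrt((M ** 2).sum(axis=1))
    G = M @ M.T
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    S = np.clip(S, 0.0, 1.0)
    # exact unit diagonal for nonzero rows; exact zeros for isolated vertices
    np.fill_diagonal(S, 1.0)
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    return SimilarityMatrix(labels=list(adj.labels), S=S)


def agglomerate(S: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration on the dissimilarity d = 1 - sigma.

    Clusters with the smallest average pairwise dissimilarity merge first;
    ties are broken by the lexicographically smallest combined member-label
    tuple, so the dendrogram is reproducible.  Isolated vertices (similarity 0
    to everything) necessarily merge last at height 1.
    """
    labels = list(S.labels)
    n = len(labels)
    if n == 1:
        return Dendrogram(leaves=labels, merges=[])
    # Lance-Williams update for average linkage:
    #   d(a∪b, k) = (|a| d(a,k) + |b| d(b,k)) / (|a| + |b|)
    members = {i: (labels[i],) for i in range(n)}
    size = {i: 1 for i in range(n)}
    D0 = 1.0 - np.asarray(S.S, dtype=float)
    dist = {(i, j): float(D0[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for (a, b), d in dist.items():
            key = (d, tuple(sorted(members[a] + members[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        m = next_id
        next_id += 1
        for k in list(members):
            if k in (a, b):
                continue
            dak = dist.pop((min(a, k), max(a, k)))
            dbk = dist.pop((min(b, k), max(b, k)))
            dist[(k, m)] = (size[a] * dak + size[b] * dbk) / (size[a] + size[b])
        del dist[(a, b)]
        merges.append((a, b, d, size[a] + size[b]))
        members[m] = tuple(sorted(members.pop(a) + members.pop(b)))
        size[m] = size.pop(a) + size.pop(b)
    return Dendrogram(leaves=labels, merges=merges)


def similarity_distribution(S_list, group_by_phase: bool = False,
                            include_zero: bool = False,
                            decimals: int = 6) -> SimilarityDistribution:
    """Histogram of unordered-pair similarity values across events.

    Values are rounded to ``decimals`` places before counting; exact zeros are
    excluded unless ``include_zero`` (the all-zero-pair mass dominates sparse
    baseline graphs and is usually uninformative).
    """
    counts: dict = {}
    for S in S_list:
        n = len(S.labels)
        phase = S.event.phase.value if (group_by_phase and S.event) else None
        for i in range(n):
            for j in range(i + 1, n):
                v = round(float(S.S[i, j]), decimals)
                if v == 0.0 and not include_zero:
                    continue
                key = (phase, v) if group_by_phase else v
                counts[key] = counts.get(key, 0) + 1
    return SimilarityDistribution(counts=counts, grouped_by_phase=group_by_phase,
                                  include_zero=include_zero)


def similarity_vs_h2(S_list, cm_list, different_electrode_only: bool = True):
    """Long table of (pair, seizure, phase, sigma, h²) for scatter analysis.

    Events are joined by (seizure_id, phase); pair h² is the maximum of the
    two directions.  With the flag set, pairs of contacts on the same
    electrode are excluded.
    """
    import pandas as pd

    def key(ev):
        return (ev.seizure_id, ev.phase.value)

    cms = {}
    for cm in cm_list:
        if cm.event is None:
            raise ValueError("coupling matrices must carry their event")
        cms[key(cm.event)] = cm
    rows = []
    for S in S_list:
        if S.event is None:
            raise ValueError("similarity matrices must carry their event")
        if key(S.event) not in cms:
            raise ValueError(f"no coupling matrix for event {key(S.event)}")
        cm = cms[key(S.event)]
        n = len(S.labels)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = S.labels[i], S.labels[j]
                if different_electrode_only and electrode_of(a) == electrode_of(b):
                    continue
                h2max = float(np.nanmax([cm.value(a, b), cm.value(b, a)]))
                rows.append({
                    "pair": f"{a}-{b}",
                    "seizure_id": S.event.seizure_id,
                    "phase": S.event.phase.value,
                    "similarity": float(S.S[i, j]),
                    "h2": h2max,
                })
    return pd.DataFrame(rows, columns=["pair", "seizure_id", "phase",
                                       "similarity", "h2"])
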