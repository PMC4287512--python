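"""Alignment splitting: partition taxa into sub-alignments of size ceil(k/2)..k.

Two strategies are provided.  Random splitting shuffles the taxa and cuts
them into near-equal contiguous chunks.  Tree-based splitting agglomerates
taxa by BIONJ joins on a maximum-likelihood distance matrix, so that each
group corresponds to a clade-like cluster of closely related sequences;
a cluster is emitted as a group when it reaches the size cap k, or when
its best join partner would push it past the cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import Alignment, ValidationError
from .likelihood import distance_matrix
from .model import RateMatrix


@dataclass
class SplitConfig:
    """Splitting parameters: size cap ``k`` (groups get ceil(k/2)..k taxa) and RNG seed."""

    k: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError(f"split size cap must be >= 2, got {self.k}")

    @property
    def min_size(self) -> int:
        return math.ceil(self.k / 2)


@dataclass
class SplitPartition:
    """A disjoint cover of an alignment's taxa."""

    groups: list[list[str]]
    provenance: str = "random"

    @property
    def m(self) -> int:
        return len(self.groups)

    def all_taxa(self) -> set[str]:
        return set(t for g in self.groups for t in g)

    def validate_against(self, aln: Alignment) -> None:
        flat = [t for g in self.groups for t in g]
        if len(flat) != len(set(flat)):
            raise ValidationError("partition groups overlap")
        unknown = set(flat) - set(aln.taxa)
        if unknown:
            raise ValidationError(f"partition names unknown taxa: {sorted(unknown)[:5]}")


# ---------------------------------------------------------------------------
# Random splitting
# ---------------------------------------------------------------------------

def random_split(aln: Alignment, cfg: SplitConfig) -> SplitPartition:
    """Shuffle taxa and cut into ceil(n/k) near-equal contiguous chunks.

    For n <= k a single group is returned.  For n > k every chunk size lies
    in [ceil(k/2), k]: with m = ceil(n/k) groups the smallest chunk has
    floor(n/m) >= ceil(k/2) members.
    """
    n = aln.n
    if n <= cfg.k:
        return SplitPartition(groups=[list(aln.taxa)], provenance="random")
    rng = np.random.default_rng(cfg.seed)
    order = list(rng.permutation(n))
    m = math.ceil(n / cfg.k)
    base, extra = divmod(n, m)
    groups: list[list[str]] = []
    start = 0
    for g in range(m):
        size = base + (1 if g < extra else 0)
        groups.append([aln.taxa[i] for i in order[start : start + size]])
        start += size
    return SplitPartition(groups=groups, provenance="random")


# ---------------------------------------------------------------------------
# Tree-based splitting
# ---------------------------------------------------------------------------

def tree_based_split(aln: Alignment, cfg: SplitConfig, model: RateMatrix) -> SplitPartition:
    """Split along the BIONJ agglomeration of ML pairwise distances under ``model``."""
    if aln.n <= cfg.k:
        return SplitPartition(groups=[list(aln.taxa)], provenance="tree_based")
    D = distance_matrix(aln, model)
    groups = split_by_distances(D, cfg.k)
    return SplitPartition(
        groups=[[aln.taxa[i] for i in g] for g in groups], provenance="tree_based"
    )


def split_by_distances(D: np.ndarray, k: int) -> list[list[int]]:
    """Partition indices 0..n-1 into groups of size ceil(k/2)..k by BIONJ joins.

    Clusters are merged in neighbor-joining order (BIONJ variance-weighted
    reduction).  A cluster is emitted when it reaches size k; when the
    globally best join would exceed k, the larger of the two clusters
    (necessarily of size >= ceil(k/2)) is emitted instead.  A terminal
    cluster smaller than ceil(k/2) is merged into the nearest emitted
    group, splitting that group in two if the cap would be exceeded.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    min_size = math.ceil(k / 2)
    if n <= k:
        return [list(range(n))]

    d = D.astype(float).copy()
    v = D.astype(float).copy()
    members: list[list[int]] = [[i] for i in range(n)]
    order: list[int] = list(range(n))  # creation order for deterministic ties
    emitted: list[list[int]] = []

    def emit(row: int) -> None:
        emitted.append(members[row])
        _drop(row)

    def _drop(row: int) -> None:
        nonlocal d, v
        keep = [x for x in range(len(members)) if x != row]
        d = d[np.ix_(keep, keep)]
        v = v[np.ix_(keep, keep)]
        del members[row]
        del order[row]

    next_id = n
    while len(members) >= 2:
        r = len(members)
        sizes = np.array([len(m) for m in members])
        if r == 2:
            if sizes.sum() <= k:
                merged = members[0] + members[1]
                members = [merged]
                break
            i, j = (0, 1) if sizes[0] >= sizes[1] else (1, 0)
            emit(i)
            continue
        S = d.sum(axis=1)
        Qc = (r - 2) * d - S[:, None] - S[None, :]
        np.fill_diagonal(Qc, np.inf)
        # best join among pairs; tie-break by cluster creation order
        qmin = Qc.min()
        ties = np.argwhere(np.isclose(Qc, qmin, rtol=0, atol=1e-12))
        pairs = sorted(
            {(min(order[a], order[b]), max(order[a], order[b])) for a, b in ties}
        )
        oi, oj = pairs[0]
        i = order.index(oi)
        j = order.index(oj)
        if sizes[i] + sizes[j] > k:
            emit(i if sizes[i] >= sizes[j] else j)
            continue
        # BIONJ reduction of rows i, j into a merged cluster
        dij = d[i, j]
        bi = 0.5 * dij + (S[i] - S[j]) / (2.0 * (r - 2))
        bj = dij - bi
        vij = v[i, j]
        mask = np.ones(r, dtype=bool)
        mask[[i, j]] = False
        if vij > 1e-12:
            lam = 0.5 + (v[j][mask] - v[i][mask]).sum() / (2.0 * (r - 2) * vij)
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        new_d = lam * (d[i] - bi) + (1 - lam) * (d[j] - bj)
        new_v = lam * v[i] + (1 - lam) * v[j] - lam * (1 - lam) * vij
        d[i] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        v[i] = new_v
        v[:, i] = new_v
        v[i, i] = 0.0
        members[i] = members[i] + members[j]
        order[i] = next_id
        next_id += 1
        _drop(j)
        merged_row = i if j > i else i - 1
        if len(members[merged_row]) == k:
            emit(merged_row)

    # terminal leftovers
    if members:
        leftover = members[0]
        if len(leftover) >= min_size or not emitted:
            emitted.append(leftover)
        else:
            emitted = _absorb_leftover(D, emitted, leftover, k, min_size)
    return [sorted(g) for g in emitted]


def _absorb_leftover(D: np.ndarray, groups: list[list[int]], leftover: list[int],
                     k: int, min_size: int) -> list[list[int]]:
    """Merge a too-small terminal cluster into its nearest group (k cap enforced)."""
    def avg_dist(g: list[int]) -> float:
        return float(D[np.ix_(leftover, g)].mean())

    nearest = min(range(len(groups)), key=lambda g: (avg_dist(groups[g]), g))
    merged = groups[nearest] + leftover
    rest = [g for idx, g in enumerate(groups) if idx != nearest]
    if len(merged) <= k:
        return rest + [merged]
    # cap exceeded: split the merged set into two balanced clusters seeded by
    # its two most distant members
    sub = D[np.ix_(merged, merged)]
    a, b = np.unravel_index(np.argmax(sub), sub.shape)
    half = len(merged) // 2
    by_pref = sorted(range(len(merged)), key=lambda x: sub[x, a] - sub[x, b])
    g1 = [merged[x] for x in by_pref[:half]]
    g2 = [merged[x] for x in by_pref[half:]]
    return rest + [g1, g2]


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------

def materialize(aln: Alignment, part: SplitPartition) -> list[Alignment]:
    """Project the alignment onto each group (all columns retained)."""
    part.validate_against(aln)
    if part.m == 1 and set(part.groups[0]) == set(aln.taxa):
        return [aln.subset(part.groups[0], name=aln.name)]
    return [
        aln.subset(group, name=f"{aln.name}.part{g + 1}")
        for g, group in enumerate(part.groups)
    ]
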