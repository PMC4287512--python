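"""Synthetic data generation: random trees and sequence evolution under (Q, gamma).

Used both as the package's test harness and as a stand-alone generator of
training/testing fixture sets.  Simulation uses the same discrete-gamma
rate categories as inference, so parameter recovery is exact in the limit
rather than model-misspecified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import (
    Alignment,
    AlignmentSet,
    AMINO_ACIDS,
    MatrixFile,
    PhyloTree,
    write_alignment,
    write_matrix,
    write_newick,
)
from .model import RateMatrix, RateModel, discrete_gamma


@dataclass
class SimulationSpec:
    """Parameters for one simulated alignment set."""

    n_taxa: int = 16
    s_sites: int = 500
    tree_shape: str = "yule"  # "yule", "balanced" or "clades"
    branch_length_mean: float = 0.1
    branch_length_law: str = "exponential"  # or "constant"
    clade_size: int = 8  # taxa per clade for tree_shape="clades"
    stem_scale: float = 8.0  # backbone branch length multiplier for "clades"
    alpha: float = 1.0
    ncat: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.s_sites < 1:
            raise ValueError("need at least 1 site")
        if self.tree_shape not in ("yule", "balanced", "clades"):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")
        if self.branch_length_law not in ("exponential", "constant"):
            raise ValueError(f"unknown branch length law {self.branch_length_law!r}")
        if self.branch_length_mean <= 0:
            raise ValueError("branch length mean must be positive")


def _draw_lengths(spec: SimulationSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.branch_length_law == "constant":
        return np.full(n, spec.branch_length_mean)
    return rng.exponential(spec.branch_length_mean, size=n)


def random_tree(spec: SimulationSpec, rng: np.random.Generator | None = None,
                taxa: list[str] | None = None) -> PhyloTree:
    """Random topology with i.i.d. branch lengths; deterministic per seed.

    ``yule`` grows the tree by splitting a uniformly chosen extant lineage;
    ``balanced`` builds a perfectly balanced topology (n must be a power of 2);
    ``clades`` joins Yule sub-trees of ``clade_size`` taxa by a Yule backbone
    whose branches are ``stem_scale`` times longer — deep, well-separated
    clades, emulating alignments of divergent protein families.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_taxa
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n)]

    if spec.tree_shape == "clades":
        from dataclasses import replace

        if n % spec.clade_size != 0 or n // spec.clade_size < 2:
            raise ValueError("'clades' needs n_taxa = clade_size * (>= 2 clades)")
        c = n // spec.clade_size
        backbone_spec = replace(
            spec, n_taxa=c, tree_shape="yule",
            branch_length_mean=spec.branch_length_mean * spec.stem_scale,
        )
        backbone = random_tree(backbone_spec, rng,
                               taxa=[f"__clade{i}" for i in range(c)])
        clade_spec = replace(spec, n_taxa=spec.clade_size, tree_shape="yule")
        parent_list = list(backbone.parent)
        blen = list(backbone.blen)
        labels = list(backbone.labels)
        for i in range(c):
            sub = random_tree(clade_spec, rng,
                              taxa=taxa[i * spec.clade_size:(i + 1) * spec.clade_size])
            anchor = labels.index(f"__clade{i}")
            labels[anchor] = None  # becomes the clade's root node
            offset = len(parent_list)
            # graft the sub-tree below the anchor (skip the sub-root, node 0)
            index_map = {0: anchor}
            for v in range(1, sub.n_nodes):
                index_map[v] = offset + v - 1
                parent_list.append(index_map[int(sub.parent[v])])
                blen.append(float(sub.blen[v]))
                labels.append(sub.labels[v])
        return PhyloTree(np.array(parent_list), np.array(blen), labels)

    if spec.tree_shape == "balanced":
        h = int(math.log2(n))
        if 2**h != n:
            raise ValueError("balanced trees require a power-of-two taxon count")
        parent_list: list[int] = []
        labels: list = []
        stack: list[tuple[int, int, int]] = [(-1, 0, n)]  # (parent, lo, hi)
        while stack:
            par, lo, hi = stack.pop()
            me = len(parent_list)
            parent_list.append(par)
            if hi - lo == 1:
                labels.append(taxa[lo])
            else:
                labels.append(None)
                mid = (lo + hi) // 2
                stack.append((me, mid, hi))
                stack.append((me, lo, mid))
        total = len(parent_list)
        blen = np.zeros(total)
        blen[1:] = _draw_lengths(spec, rng, total - 1)
        return PhyloTree(np.array(parent_list), blen, labels)

    # Yule: grow by splitting a uniformly chosen extant lineage.  The root
    # keeps degree 2; a degree-2 root is a harmless no-op for a reversible
    # model and is collapsed on Newick round trips.
    parent_list = [-1, 0, 0]
    labels = [None, 0, 1]  # leaf ids, replaced by names at the end
    extant = [1, 2]
    next_leaf = 2
    while next_leaf < n:
        pick = int(rng.integers(len(extant)))
        node = extant.pop(pick)
        a = len(parent_list)
        parent_list.extend([node, node])
        labels.append(labels[node])  # old leaf id moves to the first child
        labels.append(next_leaf)
        labels[node] = None
        extant.extend([a, a + 1])
        next_leaf += 1
    total = len(parent_list)
    blen = np.zeros(total)
    blen[1:] = _draw_lengths(spec, rng, total - 1)
    final_labels = [taxa[l] if isinstance(l, int) else None for l in labels]
    return PhyloTree(np.array(parent_list), blen, final_labels)


def evolve_alignment(tree: PhyloTree, model: RateMatrix, rates: RateModel,
                     s: int, seed: int, name: str = "sim",
                     missing_rate: float = 0.0) -> Alignment:
    """Evolve ``s`` sites down ``tree`` under ``model`` with discrete-gamma rates.

    Root states are drawn from the equilibrium frequencies; each site keeps
    one rate category for the whole tree; transitions use P(rate * t).
    Optionally masks a uniform fraction of residues as missing ('X').
    """
    rng = np.random.default_rng(seed)
    ncat = rates.ncat
    cats = rng.integers(ncat, size=s)
    states = np.empty((tree.n_nodes, s), dtype=np.int64)
    states[0] = rng.choice(20, size=s, p=model.pi)
    top_down = list(reversed(tree.postorder()))  # parents before children
    for v in top_down:
        if tree.parent[v] < 0:
            continue
        u = tree.parent[v]
        t = tree.blen[v]
        child = np.empty(s, dtype=np.int64)
        for c in range(ncat):
            idx = np.where(cats == c)[0]
            if idx.size == 0:
                continue
            P = model.transition_matrix(rates.rates[c] * t)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u_draw = rng.random(idx.size)
            # first cumulative bin reaching the uniform draw
            child[idx] = (cum[states[u][idx]] < u_draw[:, None]).sum(axis=1)
        states[v] = child

    rows = []
    taxa = []
    for v in range(tree.n_nodes):
        if tree.labels[v] is not None:
            taxa.append(tree.labels[v])
            rows.append("".join(AMINO_ACIDS[x] for x in states[v]))
    if missing_rate > 0:
        mask = rng.random((len(taxa), s)) < missing_rate
        rows = [
            "".join("X" if mask[i, j] else row[j] for j in range(s))
            for i, row in enumerate(rows)
        ]
    return Alignment(name=name, taxa=taxa, rows=rows)


def simulate_set(spec: SimulationSpec, matrix: MatrixFile, n_alignments: int,
                 name_prefix: str = "aln") -> tuple[AlignmentSet, list[PhyloTree]]:
    """Simulate ``n_alignments`` alignments, each on its own random tree."""
    rng = np.random.default_rng(spec.seed)
    model = RateMatrix.from_matrix_file(matrix)
    rates = discrete_gamma(spec.alpha, spec.ncat)
    alns, trees = [], []
    for i in range(n_alignments):
        tree = random_tree(spec, rng)
        aln = evolve_alignment(
            tree, model, rates, spec.s_sites,
            seed=int(rng.integers(2**31)), name=f"{name_prefix}{i + 1:03d}",
        )
        alns.append(aln)
        trees.append(tree)
    return AlignmentSet(alns), trees


def make_fixture_set(spec: SimulationSpec, matrix: MatrixFile, out_dir: str | Path,
                     n_train: int, n_test: int,
                     test_spec: SimulationSpec | None = None):
    """Write a train/test fixture: FASTA files, generating trees, matrix, manifest.

    Returns ``(train_set, test_set, ground_truth_dict)``.
    """
    out_dir = Path(out_dir)
    (out_dir / "train").mkdir(parents=True, exist_ok=True)
    (out_dir / "test").mkdir(parents=True, exist_ok=True)
    (out_dir / "trees").mkdir(parents=True, exist_ok=True)

    test_spec = test_spec or spec
    train, train_trees = simulate_set(spec, matrix, n_train, name_prefix="train")
    test_sp = SimulationSpec(**{**asdict(test_spec), "seed": test_spec.seed + 1})
    test, test_trees = simulate_set(test_sp, matrix, n_test, name_prefix="test")

    for aln in train:
        write_alignment(aln, out_dir / "train" / f"{aln.name}.fasta")
    for aln in test:
        write_alignment(aln, out_dir / "test" / f"{aln.name}.fasta")
    for aln, tree in zip(train, train_trees):
        write_newick(tree, out_dir / "trees" / f"{aln.name}.nwk")
    for aln, tree in zip(test, test_trees):
        write_newick(tree, out_dir / "trees" / f"{aln.name}.nwk")
    write_matrix(matrix, out_dir / "generating_matrix.dat")
    manifest = {
        "train_spec": asdict(spec),
        "test_spec": asdict(test_sp),
        "matrix": matrix.name or "custom",
        "n_train": n_train,
        "n_test": n_test,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    truth = {"matrix": matrix, "train_trees": train_trees, "test_trees": test_trees}
    return train, test, truth
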