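"""Phylogenetic likelihood engine for the 20-state reversible model.

Implements Felsenstein pruning with discrete-gamma rate mixing, expected
sufficient statistics (substitution counts and state dwell times) for
exchangeability estimation, Newton branch-length optimization in a
Gauss-Seidel sweep, gamma-shape optimization, maximum-likelihood pairwise
distances, and BIONJ tree construction.

All per-site computations work on compressed site patterns (unique columns
weighted by multiplicity).  Partial likelihoods are rescaled per site to
avoid underflow; scale factors are tracked in log space.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .io import (
    Alignment,
    MISSING_CODE,
    PhyloTree,
    ValidationError,
    read_newick,
    write_alignment,
)
from .model import RateMatrix, RateModel, discrete_gamma

T_MAX = 10.0  # saturation cap for distances and branch lengths (subs/site)
T_MIN = 1e-8


class UndefinedDistanceError(ValueError):
    """Two sequences share no co-observed site; no distance can be estimated."""


class BuilderError(RuntimeError):
    """An external tree-builder command failed."""


# ---------------------------------------------------------------------------
# Instrumentation
# ---------------------------------------------------------------------------

@dataclass
class OpCounter:
    """Counts likelihood-function evaluations by kind.

    One count is one evaluation of a likelihood objective: a pairwise-distance
    objective, a single-branch objective, or a whole-tree log-likelihood.
    """

    counts: dict = field(default_factory=dict)

    def add(self, kind: str, n: int = 1) -> None:
        self.counts[kind] = self.counts.get(kind, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def reset(self) -> None:
        self.counts.clear()


#: Global evaluation counter used by the engine (reset it around a measurement).
likelihood_evals = OpCounter()


# ---------------------------------------------------------------------------
# Site log-likelihoods container
# ---------------------------------------------------------------------------

@dataclass
class SiteLogLikelihoods:
    """Per-column log-likelihoods and their sum."""

    values: np.ndarray
    total: float

    @property
    def s(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class TreeLikelihood:
    """Likelihood of one alignment on one tree under (Q, discrete-gamma rates).

    The instance owns a copy of the tree; branch-length optimization mutates
    that copy and returns it.
    """

    def __init__(self, aln: Alignment, tree: PhyloTree, model: RateMatrix,
                 rates: RateModel):
        leaf_set = set(tree.leaf_labels)
        if leaf_set != set(aln.taxa):
            raise ValidationError(
                "tree leaves and alignment taxa differ: "
                f"{sorted(leaf_set ^ set(aln.taxa))[:5]} ..."
            )
        self.aln = aln
        self.tree = tree.copy()
        self.model = model
        self.rates = rates

        codes = aln.codes()
        # compress columns into unique site patterns
        patterns, self._pattern_index, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n, p)
        self.pattern_weights = counts.astype(float)
        self.n_patterns = patterns.shape[1]

        self._taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        self._postorder_nodes = self.tree.postorder()
        self._leaf_cache: dict[int, np.ndarray] = {}
        self._buffers: tuple | None = None  # reused (F, logsc, msg) arrays
        # node depths, for rescaling partials every few levels only
        self._depth = np.zeros(self.tree.n_nodes, dtype=np.int64)
        for v in range(1, self.tree.n_nodes):
            self._depth[v] = self._depth[self.tree.parent[v]] + 1

    # -- model plumbing -----------------------------------------------------

    def set_model(self, model: RateMatrix) -> None:
        self.model = model

    def set_rates(self, rates: RateModel) -> None:
        self.rates = rates

    def _leaf_partial(self, node: int) -> np.ndarray:
        """(p, 20) conditional likelihood at a leaf; missing residues -> ones."""
        if node not in self._leaf_cache:
            row = self.patterns[self._taxon_row[self.tree.labels[node]]]
            out = np.zeros((self.n_patterns, 20))
            obs = row != MISSING_CODE
            out[np.arange(self.n_patterns)[obs], row[obs]] = 1.0
            out[~obs] = 1.0
            self._leaf_cache[node] = out
        return self._leaf_cache[node]

    def _edge_P(self, t: float) -> np.ndarray:
        """(ncat, 20, 20) transition matrices P(c_j * t) from the eigenbasis."""
        m = self.model
        et = np.exp(np.outer(self.rates.rates, m.eigenvalues) * t)  # (ncat, 20)
        P = (m.U[None, :, :] * et[:, None, :]) @ m.Uinv
        np.clip(P, 0.0, None, out=P)
        return P

    # -- pruning passes -----------------------------------------------------

    def _postorder_partials(self):
        """Inside (tip-ward) conditionals.

        Returns
        -------
        F : (n_nodes, ncat, p, 20) scaled conditional likelihoods
        logsc : (n_nodes, p) cumulative log scale factors
        msg : (n_nodes, ncat, p, 20) per-edge messages P(c t_v) F_v, child->parent
        """
        nn = self.tree.n_nodes
        ncat, p = self.rates.ncat, self.n_patterns
        if self._buffers is None or self._buffers[0].shape != (nn, ncat, p, 20):
            self._buffers = (
                np.empty((nn, ncat, p, 20)),
                np.zeros((nn, p)),
                np.empty((nn, ncat, p, 20)),
            )
        F, logsc, msg = self._buffers
        for u in self._postorder_nodes:
            if self.tree.is_leaf(u):
                F[u] = self._leaf_partial(u)[None, :, :]
                logsc[u] = 0.0
            else:
                kids = self.tree.children(u)
                acc = F[u]
                np.copyto(acc, msg[kids[0]])
                for v in kids[1:]:
                    acc *= msg[v]
                if self.tree.labels[u] is not None:  # observed internal node
                    acc *= self._leaf_partial(u)[None, :, :]
                sc = logsc[kids[0]].copy()
                for v in kids[1:]:
                    sc += logsc[v]
                # rescale every third level; float64 has ample headroom between
                if self._depth[u] % 3 == 0 or self.tree.parent[u] < 0:
                    m = np.maximum(acc.max(axis=(0, 2)), 1e-300)
                    acc /= m[None, :, None]
                    sc += np.log(m)
                logsc[u] = sc
            if self.tree.parent[u] >= 0:
                P = self._edge_P(self.tree.blen[u])
                np.matmul(F[u], P.transpose(0, 2, 1), out=msg[u])
        return F, logsc, msg

    def _pattern_log_likelihoods(self, F, logsc) -> np.ndarray:
        w = self.rates.weights
        L = np.einsum("c,cpx,x->p", w, F[0], self.model.pi)
        return np.log(np.maximum(L, 1e-300)) + logsc[0]

    def _root_partial(self):
        """Memory-light postorder pass: only the root conditional and scale."""
        partial: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for u in self._postorder_nodes:
            if self.tree.is_leaf(u):
                F = np.broadcast_to(
                    self._leaf_partial(u)[None, :, :],
                    (self.rates.ncat, self.n_patterns, 20),
                )
                sc = 0.0
            else:
                kids = self.tree.children(u)
                F = partial.pop(kids[0])
                sc = scale.pop(kids[0])
                for v in kids[1:]:
                    F = F * partial.pop(v)
                    sc = sc + scale.pop(v)
                if self.tree.labels[u] is not None:  # observed internal node
                    F = F * self._leaf_partial(u)[None, :, :]
                m = np.maximum(F.max(axis=(0, 2)), 1e-300)
                F = F / m[None, :, None]
                sc = sc + np.log(m)
            if self.tree.parent[u] >= 0:
                P = self._edge_P(self.tree.blen[u])
                partial[u] = F @ P.transpose(0, 2, 1)
                scale[u] = sc
            else:
                return F, sc

    def site_log_likelihoods(self) -> SiteLogLikelihoods:
        F_root, sc = self._root_partial()
        w = self.rates.weights
        L = np.einsum("c,cpx,x->p", w, F_root, self.model.pi)
        per_pattern = np.log(np.maximum(L, 1e-300)) + sc
        values = per_pattern[self._pattern_index]
        likelihood_evals.add("tree")
        return SiteLogLikelihoods(values=values, total=float(values.sum()))

    def log_likelihood(self) -> float:
        F_root, sc = self._root_partial()
        w = self.rates.weights
        L = np.einsum("c,cpx,x->p", w, F_root, self.model.pi)
        per_pattern = np.log(np.maximum(L, 1e-300)) + sc
        likelihood_evals.add("tree")
        return float((per_pattern * self.pattern_weights).sum())

    # -- branch-length optimization -----------------------------------------

    def _edge_basis(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Eigen-basis coefficients E[c,j,k] with L_j(t) = sum_ck w_c E e^{lam_k c t}."""
        m = self.model
        return (A @ m.U) * (B @ m.Uinv.T)

    def _optimize_edge(self, E: np.ndarray, t0: float) -> float:
        """Maximize the per-edge log-likelihood by safeguarded Newton iteration."""
        lam = self.model.eigenvalues
        crates = self.rates.rates
        w = self.rates.weights
        wpat = self.pattern_weights
        lamc = np.outer(crates, lam)  # (ncat, 20)

        def fgh(t: float):
            likelihood_evals.add("branch")
            ex = np.exp(lamc * t) * w[:, None]  # (ncat, 20) incl. weights
            L = (E @ ex[:, :, None])[:, :, 0].sum(axis=0)
            L = np.maximum(L, 1e-300)
            L1 = (E @ (ex * lamc)[:, :, None])[:, :, 0].sum(axis=0)
            L2 = (E @ (ex * lamc**2)[:, :, None])[:, :, 0].sum(axis=0)
            f = float((np.log(L) * wpat).sum())
            g = float(((L1 / L) * wpat).sum())
            h = float((((L2 * L - L1**2) / L**2) * wpat).sum())
            return f, g, h

        lo, hi = T_MIN, T_MAX
        t = min(max(t0, lo), hi)
        f, g, h = fgh(t)
        best_t, best_f = t, f
        for _ in range(20):
            if g > 0:
                lo = t
            else:
                hi = t
            if h < 0:
                step = -g / h
                tn = t + step
                if not (lo < tn < hi):
                    tn = 0.5 * (lo + hi)
            else:
                tn = 0.5 * (lo + hi)
            if abs(tn - t) < 1e-8 * (1.0 + t):
                t = tn
                break
            t = tn
            f, g, h = fgh(t)
            if f > best_f:
                best_t, best_f = t, f
            if abs(g) < 1e-10:
                break
        # keep the best point seen (Newton is safeguarded but not monotone)
        f_end = fgh(t)[0]
        if f_end >= best_f:
            return t
        return best_t

    def optimize_branch_lengths(self, tol: float = 1e-4, max_cycles: int = 25) -> PhyloTree:
        """Cycle Newton updates over all edges until the total logL gain < tol.

        Each cycle recomputes all partials, then sweeps the tree in preorder,
        optimizing every edge against partials that reflect all updates made
        earlier in the sweep (Gauss-Seidel).
        """
        tree = self.tree
        ncat, p = self.rates.ncat, self.n_patterns
        prev_ll = -np.inf
        for _ in range(max_cycles):
            F, logsc, msg = self._postorder_partials()
            ll = float((self._pattern_log_likelihoods(F, logsc) * self.pattern_weights).sum())
            if ll - prev_ll < tol:
                break
            prev_ll = ll
            # preorder sweep with up-partials propagated from the root
            up = {0: np.ones((ncat, p, 20))}
            stack = [0]
            while stack:
                u = stack.pop()
                kids = tree.children(u)
                cur_msg = {v: msg[v] for v in kids}
                for v in kids:
                    C = up[u].copy()
                    if tree.labels[u] is not None:  # observed internal node
                        C *= self._leaf_partial(u)[None, :, :]
                    for w_ in kids:
                        if w_ is not v:
                            C *= cur_msg[w_]
                    A = C * self.model.pi[None, None, :]
                    E = self._edge_basis(A, F[v])
                    t_new = self._optimize_edge(E, tree.blen[v])
                    tree.blen[v] = t_new
                    P = self._edge_P(t_new)
                    cur_msg[v] = F[v] @ P.transpose(0, 2, 1)
                    if not tree.is_leaf(v):
                        up_v = C @ P.transpose(0, 2, 1)
                        m = np.maximum(up_v.max(axis=(0, 2)), 1e-300)
                        up[v] = up_v / m[None, :, None]
                        stack.append(v)
                del up[u]
        return tree

    # -- gamma shape optimization -------------------------------------------

    def optimize_alpha(self, bounds: tuple[float, float] = (0.02, 100.0)) -> RateModel:
        """Maximize logL over the gamma shape with the tree fixed (log-scale Brent)."""
        if self.rates.ncat == 1:
            return self.rates
        ncat = self.rates.ncat
        start = self.rates
        ll_start = self.log_likelihood()

        def neg(log_a: float) -> float:
            self.set_rates(discrete_gamma(float(np.exp(log_a)), ncat))
            return -self.log_likelihood()

        res = minimize_scalar(
            neg,
            bounds=(np.log(bounds[0]), np.log(bounds[1])),
            method="bounded",
            options={"xatol": 5e-3},
        )
        alpha = float(np.exp(res.x))
        cand = discrete_gamma(alpha, ncat)
        self.set_rates(cand)
        if self.log_likelihood() < ll_start:  # guard the optimizer contract
            self.set_rates(start)
            return start
        return cand

    # -- expected sufficient statistics -------------------------------------

    def sufficient_statistics(self):
        """Expected substitution counts and dwell times under the posterior.

        Returns ``(C, T, logL)`` where ``C[x, y]`` is the expected number of
        x->y substitutions summed over all branches, categories and sites
        (x != y), ``T[x]`` the expected time spent in state x (in branch-length
        units scaled by category rates), and ``logL`` the total log-likelihood
        at the current parameters.
        """
        m = self.model
        tree = self.tree
        ncat, p = self.rates.ncat, self.n_patterns
        w = self.rates.weights
        wpat = self.pattern_weights

        F, logsc, msg = self._postorder_partials()
        per_pattern = self._pattern_log_likelihoods(F, logsc)
        total_ll = float((per_pattern * wpat).sum())
        likelihood_evals.add("tree")

        C = np.zeros((20, 20))
        T = np.zeros(20)

        up = {0: np.ones((ncat, p, 20))}
        stack = [0]
        while stack:
            u = stack.pop()
            kids = tree.children(u)
            for v in kids:
                Cpart = up[u].copy()
                if tree.labels[u] is not None:  # observed internal node
                    Cpart *= self._leaf_partial(u)[None, :, :]
                for w_ in kids:
                    if w_ is not v:
                        Cpart *= msg[w_]
                A = Cpart * m.pi[None, None, :]
                B = F[v]
                t_e = tree.blen[v]
                P = self._edge_P(t_e)
                M = B @ P.transpose(0, 2, 1)  # (ncat, p, 20)
                L = ((A * M).sum(axis=2) * w[:, None]).sum(axis=0)
                L = np.maximum(L, 1e-300)
                coef = wpat / L  # per-pattern posterior normalizer
                scaledA = A * (coef[None, :, None] * w[:, None, None])
                Wc = scaledA.transpose(0, 2, 1) @ B  # (ncat, 20, 20)
                G = (m.U.T[None] @ Wc) @ m.Uinv.T[None]
                I = np.stack([
                    _interval_integral(m.eigenvalues, self.rates.rates[c] * t_e)
                    for c in range(ncat)
                ])
                Xs = m.Uinv.T @ (G * I).sum(axis=0) @ m.U.T
                C += m.Q * Xs
                T += np.diag(Xs)
                if not tree.is_leaf(v):
                    up_v = Cpart @ P.transpose(0, 2, 1)
                    sc = np.maximum(up_v.max(axis=(0, 2)), 1e-300)
                    up[v] = up_v / sc[None, :, None]
                    stack.append(v)
            del up[u]

        np.fill_diagonal(C, 0.0)
        np.clip(C, 0.0, None, out=C)
        np.clip(T, 0.0, None, out=T)
        return C, T, total_ll


def _interval_integral(lam: np.ndarray, tau: float) -> np.ndarray:
    """I[i, j] = integral_0^tau exp(lam_i s) exp(lam_j (tau - s)) ds."""
    a = lam[:, None] * tau
    b = lam[None, :] * tau
    dl = lam[:, None] - lam[None, :]
    x = 0.5 * (a - b)
    small = np.abs(x) < 1e-5
    safe = np.where(small, 1.0, dl)
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = (np.exp(a) - np.exp(b)) / safe
    series = tau * np.exp(0.5 * (a + b)) * (1.0 + x**2 / 6.0)
    return np.where(small, series, direct)


# ---------------------------------------------------------------------------
# Pairwise maximum-likelihood distances
# ---------------------------------------------------------------------------

def ml_distance(codes1: np.ndarray, codes2: np.ndarray, model: RateMatrix,
                t_max: float = T_MAX) -> float:
    """ML evolutionary distance between two aligned sequences under ``model``.

    Maximizes sum over co-observed sites of log(pi_x P_xy(t)) for t in
    [0, t_max].  Saturated pairs return t_max.
    """
    codes1 = np.asarray(codes1)
    codes2 = np.asarray(codes2)
    if codes1.shape != codes2.shape:
        raise ValidationError("sequences must have equal length")
    ok = (codes1 != MISSING_CODE) & (codes2 != MISSING_CODE)
    if not ok.any():
        raise UndefinedDistanceError("no co-observed sites")
    N = np.zeros((20, 20))
    np.add.at(N, (codes1[ok], codes2[ok]), 1.0)
    if N.sum() == np.trace(N):  # identical where co-observed
        return 0.0

    log_pi = np.log(model.pi)
    const = float((N.sum(axis=1) * log_pi).sum())

    def neg(t: float) -> float:
        likelihood_evals.add("distance")
        P = (model.U * np.exp(model.eigenvalues * t)[None, :]) @ model.Uinv
        np.clip(P, 1e-300, None, out=P)
        return -(const + float((N * np.log(P)).sum()))

    res = minimize_scalar(neg, bounds=(T_MIN, t_max), method="bounded",
                          options={"xatol": 1e-6})
    t_hat = float(res.x)
    # push to the cap when the objective keeps increasing at the boundary
    if t_max - t_hat < 1e-4 or neg(t_max) <= res.fun:
        return t_max
    return t_hat


def distance_matrix(aln: Alignment, model: RateMatrix, t_max: float = T_MAX) -> np.ndarray:
    """Symmetric matrix of pairwise ML distances; undefined pairs get t_max."""
    codes = aln.codes()
    n = aln.n
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = ml_distance(codes[i], codes[j], model, t_max=t_max)
            except UndefinedDistanceError:
                d = t_max
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# BIONJ
# ---------------------------------------------------------------------------

def bionj_tree(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Build an unrooted tree by BIONJ agglomeration.

    Uses the neighbor-joining selection criterion with BIONJ's
    variance-weighted branch estimates and matrix reduction; ties in pair
    selection break toward the lowest index pair; negative branch lengths
    are clamped to zero.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValidationError("distance matrix shape does not match labels")
    if n < 2:
        raise ValidationError("need at least two taxa")
    if n == 2:
        parent = np.array([-1, 0])
        blen = np.array([0.0, max(D[0, 1], 0.0)])
        return PhyloTree(parent, blen, [labels[0], labels[1]])

    # node bookkeeping for the final PhyloTree (children-of lists, joined later)
    nodes: list = [(lbl, None, None, 0.0, 0.0) for lbl in labels]
    # nodes[i] = (label, left, right, bl_left, bl_right); leaves have None children

    d = D.copy()
    v = D.copy()
    active = list(range(n))  # indices into `nodes`
    pos = {i: i for i in range(n)}  # node index -> row in d

    def join(i_row: int, j_row: int, bi: float, bj: float) -> int:
        ni, nj = active[i_row], active[j_row]
        nodes.append((None, ni, nj, max(bi, 0.0), max(bj, 0.0)))
        return len(nodes) - 1

    while len(active) > 3:
        r = len(active)
        sub = d[: r, : r]
        S = sub.sum(axis=1)
        Qc = (r - 2) * sub - S[:, None] - S[None, :]
        np.fill_diagonal(Qc, np.inf)
        flat = np.argmin(Qc)
        qmin = Qc.flat[flat]
        ties = np.argwhere(np.isclose(Qc, qmin, rtol=0, atol=1e-12))
        ties = [(min(a, b), max(a, b)) for a, b in ties]
        i, j = min(ties)
        dij = sub[i, j]
        bi = 0.5 * dij + (S[i] - S[j]) / (2.0 * (r - 2))
        bj = dij - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        # BIONJ weighting
        vij = v[i, j]
        mask = np.ones(r, dtype=bool)
        mask[[i, j]] = False
        if vij > 1e-12:
            lam_w = 0.5 + (v[j, : r][mask] - v[i, : r][mask]).sum() / (2.0 * (r - 2) * vij)
            lam_w = min(max(lam_w, 0.0), 1.0)
        else:
            lam_w = 0.5
        new_d = lam_w * (sub[i, :] - bi) + (1 - lam_w) * (sub[j, :] - bj)
        new_v = lam_w * v[i, : r] + (1 - lam_w) * v[j, : r] - lam_w * (1 - lam_w) * vij
        new_node = join(i, j, bi, bj)

        # overwrite row i with the merged cluster, delete row j
        d[i, : r] = new_d
        d[: r, i] = new_d
        d[i, i] = 0.0
        v[i, : r] = new_v
        v[: r, i] = new_v
        v[i, i] = 0.0
        keep = [x for x in range(r) if x != j]
        d = d[np.ix_(keep, keep)]
        v = v[np.ix_(keep, keep)]
        active[i] = new_node
        del active[j]

    # final three-point join
    i, j, k = 0, 1, 2
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root_children = [(active[i], max(a, 0.0)), (active[j], max(b, 0.0)),
                     (active[k], max(c, 0.0))]

    # flatten to parent arrays
    parent: list[int] = [-1]
    blen: list[float] = [0.0]
    labels_out: list = [None]

    def emit(node_idx: int, parent_idx: int, length: float) -> None:
        stack = [(node_idx, parent_idx, length)]
        while stack:
            nd, pa, ln = stack.pop()
            label, left, right, bl, br = nodes[nd]
            me = len(parent)
            parent.append(pa)
            blen.append(ln)
            labels_out.append(label)
            if left is not None:
                stack.append((left, me, bl))
                stack.append((right, me, br))

    for child, length in root_children:
        emit(child, 0, length)
    return PhyloTree(np.array(parent), np.array(blen), labels_out)


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------

def build_ml_tree(aln: Alignment, model: RateMatrix, ncat: int = 4,
                  alpha0: float = 1.0, optimize_shape: bool = True,
                  external_cmd: str | None = None,
                  max_rounds: int = 3, bl_tol: float = 1e-4,
                  round_tol: float = 0.05):
    """Build a tree and rate model for one alignment.

    Built-in path: ML pairwise distances -> BIONJ topology -> alternating
    branch-length (Newton sweeps) and gamma-shape optimization.  External
    path: run ``external_cmd`` (template with ``{alignment}`` and ``{tree}``
    placeholders) to produce the Newick topology, then fit the shape.

    Returns ``(tree, rates, info)`` with ``info['loglik']`` the final total
    log-likelihood and ``info['loglik_bionj']`` the pre-optimization value.
    """
    rates = discrete_gamma(alpha0, ncat) if ncat > 1 else RateModel(alpha0, 1, np.array([1.0]))

    if external_cmd is not None:
        tree = _run_external_builder(aln, external_cmd)
    else:
        if aln.n == 2:
            codes = aln.codes()
            t = ml_distance(codes[0], codes[1], model)
            tree = PhyloTree(np.array([-1, 0]), np.array([0.0, t]), list(aln.taxa))
            tl = TreeLikelihood(aln, tree, model, rates)
            if optimize_shape and ncat > 1:
                rates = tl.optimize_alpha()
            ll = tl.log_likelihood()
            return tl.tree, rates, {"loglik": ll, "loglik_bionj": ll}
        D = distance_matrix(aln, model)
        tree = bionj_tree(D, list(aln.taxa))

    tl = TreeLikelihood(aln, tree, model, rates)
    ll0 = tl.log_likelihood()
    ll = ll0
    for _ in range(max_rounds):
        tl.optimize_branch_lengths(tol=bl_tol)
        if optimize_shape and ncat > 1:
            rates = tl.optimize_alpha()
        new_ll = tl.log_likelihood()
        if new_ll - ll < round_tol:
            ll = max(new_ll, ll)
            break
        ll = new_ll
    return tl.tree, rates, {"loglik": ll, "loglik_bionj": ll0}


def _run_external_builder(aln: Alignment, cmd_template: str) -> PhyloTree:
    with tempfile.TemporaryDirectory() as td:
        aln_path = Path(td) / "alignment.fasta"
        tree_path = Path(td) / "tree.nwk"
        write_alignment(aln, aln_path)
        cmd = cmd_template.format(alignment=aln_path, tree=tree_path)
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise BuilderError(
                f"external builder exited {proc.returncode}\n"
                f"command: {cmd}\nstderr: {proc.stderr[-2000:]}"
            )
        if not tree_path.exists():
            raise BuilderError(f"external builder wrote no tree file\ncommand: {cmd}")
        try:
            tree = read_newick(tree_path.read_text())
        except Exception as exc:
            raise BuilderError(f"could not parse builder output: {exc}") from exc
    if set(tree.leaf_labels) != set(aln.taxa):
        raise BuilderError("external builder returned a tree over different taxa")
    return tree
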