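"""Exchangeability estimation and the iterative estimation drivers.

The estimator maximizes the joint log-likelihood of a set of alignments with
their trees and rate models held fixed, over the 20x20 symmetric
exchangeability matrix R.  The production algorithm is
expectation-maximization on expected substitution counts and state dwell
times: the E step computes, for every branch, category and site, the
posterior expectation of the number of x->y substitution events (C_xy) and
of the time spent in state x (T_x); the M step is the closed form

    r_xy  <-  (C_xy + C_yx) / (pi_y T_x + pi_x T_y).

With trees fixed, the overall scale of R is a free, likelihood-relevant
parameter, so the inner loop lets it float; the returned matrix is
renormalized to the unit-expected-rate reporting convention (branch lengths
are re-fit under the renormalized matrix at the next tree-building step).

Two drivers wrap the estimator: the standard procedure (build trees on the
full alignments, re-estimate R, iterate) and the split estimation procedure
(split every alignment once into sub-alignments of at most k taxa, then
iterate tree building and estimation over the sub-alignments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .io import (
    Alignment,
    AlignmentSet,
    MatrixFile,
    MISSING_CODE,
    PhyloTree,
    ValidationError,
    lower_triangle,
)
from .likelihood import TreeLikelihood, build_ml_tree
from .model import RateMatrix, RateModel
from .splitting import SplitConfig, materialize, random_split, tree_based_split

logger = logging.getLogger("aamatrix")

_TRIL = np.tril_indices(20, k=-1)


@dataclass
class ConvergenceCriterion:
    """Outer-loop stopping rule for the iterative drivers.

    The loop stops when successive exchangeability vectors are nearly
    identical: Pearson correlation >= ``min_corr`` and maximum relative
    entry change <= ``max_rel_change``; ``max_iter`` caps the iterations.
    """

    min_corr: float = 0.999
    max_rel_change: float = 0.10
    max_iter: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_corr <= 1):
            raise ValidationError("min_corr must be in (0, 1]")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")

    def met(self, r_prev: np.ndarray, r_new: np.ndarray) -> bool:
        v1, v2 = lower_triangle(r_prev), lower_triangle(r_new)
        # compare on a common scale (mean exchangeability 1)
        v1 = v1 / v1.mean()
        v2 = v2 / v2.mean()
        corr = float(pearsonr(v1, v2).statistic)
        # entries below 1% of the mean carry essentially no substitution counts;
        # their change is assessed on an absolute scale to keep the criterion
        # from being driven by sampling noise in unidentifiable entries
        rel = float(np.max(np.abs(v2 - v1) / np.maximum(v1, 1e-2)))
        return corr >= self.min_corr and rel <= self.max_rel_change


@dataclass
class EstimationResult:
    """Outcome of a driver run."""

    matrix: MatrixFile
    iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    trees: list[PhyloTree] = field(default_factory=list)
    rate_models: list[RateModel] = field(default_factory=list)
    alignments: list[Alignment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def empirical_frequencies(alns: AlignmentSet | list[Alignment],
                          pseudocount: float = 0.5) -> np.ndarray:
    """Pooled residue frequencies over all alignments, with a pseudocount.

    Gaps and ambiguity codes are excluded from the counts; each of the 20
    states receives ``pseudocount`` extra observations so that frequencies
    are strictly positive.
    """
    counts = np.zeros(20)
    total_observed = 0
    for aln in alns:
        codes = aln.codes()
        obs = codes[codes != MISSING_CODE]
        total_observed += obs.size
        counts += np.bincount(obs, minlength=20)[:20]
    if total_observed == 0:
        raise ValidationError("no observed residues in the data")
    counts += pseudocount
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Exchangeability estimation (inner loop)
# ---------------------------------------------------------------------------

def _accumulate_stats(alns, trees, rate_models, model):
    """One E step over all alignments: pooled (C, T, total logL)."""
    C = np.zeros((20, 20))
    T = np.zeros(20)
    total = 0.0
    for aln, tree, rates in zip(alns, trees, rate_models):
        tl = TreeLikelihood(aln, tree, model, rates)
        Ci, Ti, ll = tl.sufficient_statistics()
        C += Ci
        T += Ti
        total += ll
    return C, T, total


def estimate_exchangeabilities(alns, trees, rate_models, pi: np.ndarray,
                               R_init: np.ndarray, tol: float = 1e-6,
                               max_iter: int = 200, min_rate: float = 1e-8):
    """Maximum-likelihood exchangeabilities with trees and rate models fixed.

    EM on expected substitution counts and dwell times; the objective (total
    log-likelihood) is non-decreasing at every step.  Stops when the relative
    objective gain falls below ``tol``.

    Returns ``(R_hat, info)`` where ``R_hat`` is normalized to unit expected
    rate under ``pi`` and ``info['loglik_trace']`` holds the EM objective
    per iteration (evaluated at the iterate's parameters).
    """
    alns = list(alns)
    if not (len(alns) == len(trees) == len(rate_models)):
        raise ValidationError("need one tree and one rate model per alignment")
    pi = np.asarray(pi, dtype=float)
    R = np.asarray(R_init, dtype=float).copy()
    trace: list[float] = []
    for _ in range(max_iter):
        model = RateMatrix(R, pi, normalize=False)
        C, T, ll = _accumulate_stats(alns, trees, rate_models, model)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite likelihood during estimation (logL={ll}); "
                "check for zero-length branches with conflicting data"
            )
        trace.append(ll)
        denom = pi[None, :] * T[:, None] + pi[:, None] * T[None, :]
        R_new = np.where(denom > 0, (C + C.T) / np.maximum(denom, 1e-300), R)
        np.fill_diagonal(R_new, 0.0)
        R_new = np.maximum(R_new, min_rate)
        np.fill_diagonal(R_new, 0.0)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-1]):
            R = R_new
            break
        R = R_new
    R_report = _normalize_exchangeabilities(R, pi)
    return R_report, {"loglik_trace": trace, "iterations": len(trace)}


def _normalize_exchangeabilities(R: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Rescale R so the expected substitution rate of Q(R, pi) is 1."""
    rate = float((pi[:, None] * (R * pi[None, :]))[~np.eye(20, dtype=bool)].sum())
    return R / rate


def estimate_exchangeabilities_direct(alns, trees, rate_models, pi: np.ndarray,
                                      R_init: np.ndarray, tol: float = 1e-8,
                                      max_iter: int = 300):
    """Quasi-Newton (L-BFGS-B) estimation over the 190 log-exchangeabilities.

    Cross-check for the EM estimator: uses the analytic gradient
    d logL / d log r_xy = (C_xy + C_yx) - r_xy (pi_y T_x + pi_x T_y),
    derived from the same expected sufficient statistics.
    """
    pi = np.asarray(pi, dtype=float)
    x0 = np.log(np.asarray(R_init, dtype=float)[_TRIL])

    def unpack(x: np.ndarray) -> np.ndarray:
        R = np.zeros((20, 20))
        R[_TRIL] = np.exp(x)
        return R + R.T

    def objective(x: np.ndarray):
        R = unpack(x)
        model = RateMatrix(R, pi, normalize=False)
        C, T, ll = _accumulate_stats(alns, trees, rate_models, model)
        grad_full = (C + C.T) - R * (pi[None, :] * T[:, None] + pi[:, None] * T[None, :])
        return -ll, -grad_full[_TRIL]

    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol})
    R_hat = unpack(res.x)
    return _normalize_exchangeabilities(R_hat, pi), {"loglik": -float(res.fun),
                                                     "converged": bool(res.success)}


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _build_all_trees(alns, model, ncat, alphas, builder_cmd=None):
    trees, rate_models = [], []
    for aln, a0 in zip(alns, alphas):
        if aln.n < 2:
            raise ValidationError(f"alignment {aln.name!r} has fewer than 2 taxa")
        tree, rates, info = build_ml_tree(
            aln, model, ncat=ncat, alpha0=a0, external_cmd=builder_cmd
        )
        trees.append(tree)
        rate_models.append(rates)
    return trees, rate_models


def _iterate(alns, R0, pi, crit, ncat, builder_cmd, em_tol, em_max_iter):
    """Shared outer loop: build trees -> estimate R -> convergence check."""
    R = R0.copy()
    alphas = [1.0] * len(alns)
    trace: list[float] = []
    converged = False
    iterations = 0
    trees: list[PhyloTree] = []
    rate_models: list[RateModel] = []
    for it in range(crit.max_iter):
        iterations = it + 1
        model = RateMatrix(R, pi, normalize=True)
        trees, rate_models = _build_all_trees(alns, model, ncat, alphas, builder_cmd)
        alphas = [rm.alpha for rm in rate_models]
        R_new, info = estimate_exchangeabilities(
            alns, trees, rate_models, pi, R, tol=em_tol, max_iter=em_max_iter
        )
        trace.append(info["loglik_trace"][-1])
        logger.info(
            "outer iteration %d: logL=%.3f (EM iterations: %d)",
            iterations, trace[-1], info["iterations"],
        )
        if crit.met(R, R_new):
            R = R_new
            converged = True
            break
        R = R_new
    return R, iterations, converged, trace, trees, rate_models


def standard_procedure(alns: AlignmentSet, R_init: MatrixFile | np.ndarray,
                       crit: ConvergenceCriterion | None = None, ncat: int = 4,
                       builder_cmd: str | None = None, em_tol: float = 1e-6,
                       em_max_iter: int = 100) -> EstimationResult:
    """Iterative estimation on the full alignments.

    Loop: build a tree and gamma shape for every alignment under the current
    matrix, re-estimate the exchangeabilities with those trees fixed, and
    stop when successive matrices are nearly identical.
    """
    crit = crit or ConvergenceCriterion()
    pi = empirical_frequencies(alns)
    R0 = _as_r_matrix(R_init)
    alns_list = list(alns)
    R, iterations, converged, trace, trees, rate_models = _iterate(
        alns_list, R0, pi, crit, ncat, builder_cmd, em_tol, em_max_iter
    )
    return EstimationResult(
        matrix=MatrixFile.from_r_matrix(R, pi, name="estimated"),
        iterations=iterations, converged=converged, loglik_trace=trace,
        trees=trees, rate_models=rate_models, alignments=alns_list,
    )


def split_estimate(alns: AlignmentSet, R_init: MatrixFile | np.ndarray,
                   cfg: SplitConfig, splitter: str = "tree_based",
                   crit: ConvergenceCriterion | None = None, ncat: int = 4,
                   builder_cmd: str | None = None, em_tol: float = 1e-6,
                   em_max_iter: int = 100,
                   min_split_taxa: int = 4) -> EstimationResult:
    """Split-based estimation: split once, then iterate on the sub-alignments.

    Every alignment with at least ``min_split_taxa`` taxa is split once into
    sub-alignments of at most ``cfg.k`` taxa, using either the random or the
    tree-based splitter; the outer loop (tree building and exchangeability
    estimation) then runs entirely on the sub-alignments.
    """
    if splitter not in ("random", "tree_based"):
        raise ValidationError(f"unknown splitter {splitter!r}")
    crit = crit or ConvergenceCriterion()
    pi = empirical_frequencies(alns)
    R0 = _as_r_matrix(R_init)
    model0 = RateMatrix(R0, pi, normalize=True)

    subs: list[Alignment] = []
    for aln in alns:
        if aln.n < min_split_taxa or aln.n <= cfg.k:
            subs.append(aln)
            continue
        if splitter == "random":
            part = random_split(aln, cfg)
        else:
            part = tree_based_split(aln, cfg, model0)
        subs.extend(materialize(aln, part))
    logger.info("split %d alignments into %d sub-alignments", len(alns), len(subs))

    R, iterations, converged, trace, trees, rate_models = _iterate(
        subs, R0, pi, crit, ncat, builder_cmd, em_tol, em_max_iter
    )
    return EstimationResult(
        matrix=MatrixFile.from_r_matrix(R, pi, name="estimated"),
        iterations=iterations, converged=converged, loglik_trace=trace,
        trees=trees, rate_models=rate_models, alignments=subs,
    )


def _as_r_matrix(R_init: MatrixFile | np.ndarray) -> np.ndarray:
    if isinstance(R_init, MatrixFile):
        return R_init.r_matrix()
    R = np.asarray(R_init, dtype=float)
    if R.shape != (20, 20):
        raise ValidationError("R_init must be a MatrixFile or a 20x20 matrix")
    return R
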