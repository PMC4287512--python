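# Methods

## Model

Amino-acid substitution is modeled as a time-homogeneous, time-reversible
continuous-time Markov chain on the 20 states, independent across sites.
The generator decomposes as `q_xy = r_xy * pi_y` (x != y) with symmetric
exchangeabilities R and equilibrium frequencies Pi; diagonal entries make
rows sum to zero.  Because (R, Pi) is scale-confounded with time, matrices
are reported under the convention that the expected substitution rate at
equilibrium, `-sum_x pi_x q_xx`, equals 1, so branch lengths read as expected
substitutions per site.  Transition matrices are computed by
eigendecomposition of the symmetric similarity transform
`diag(sqrt(pi)) Q diag(1/sqrt(pi))` (real spectrum guaranteed by
reversibility); entries pushed slightly negative by roundoff are clamped
to zero.

Among-site rate variation uses the discrete-gamma approximation: `ncat`
equiprobable categories (default 4), category rate = conditional mean of
Gamma(alpha, 1/alpha) within the quantile bin (bin means, not medians, so
the mixture mean is exactly 1).  No invariant-sites category is modeled.
Gaps and the ambiguity codes X/B/Z are treated as missing data: their
conditional likelihood is 1 for every state, which keeps site counts fixed.

## Likelihood engine

Per-site likelihoods come from Felsenstein pruning over compressed site
patterns, mixing gamma categories with equal weights.  Partial likelihood
vectors are rescaled every third tree level (tracked in log space); float64
headroom makes more frequent rescaling unnecessary for trees up to a few
hundred taxa.  Trees are stored unrooted with an arbitrary stored root;
reversibility makes the likelihood invariant to that choice (tested).

Branch lengths are optimized one edge at a time by safeguarded
Newton-Raphson with analytic first and second derivatives, obtained by
projecting the edge's forward/backward partials onto the eigenbasis (the
per-edge objective is then a sum of exponentials in t, so each trial costs
O(sites x 20) rather than a full pruning pass).  Edges are swept in
preorder; each edge is optimized against partials that already reflect the
updates made earlier in the sweep, and sweeps repeat until the total
log-likelihood gain falls below 1e-4.  Branch lengths live in
[1e-8, 10] substitutions/site; 10 is also the saturation cap for pairwise
distances (far beyond observable divergence).  The gamma shape is fitted by
bounded Brent search on log(alpha) in [0.02, 100].  A derivative-free
per-edge search would need several-fold more likelihood evaluations for the
same tolerance, which is why Newton was chosen.

Pairwise ML distances maximize `sum_sites log(pi_x P_xy(t))` over co-observed
sites (rate-homogeneous, ncat = 1, for speed — a deliberate approximation
for guide distances, not a claim about optimal distance estimation).
Identical sequences get distance 0; pairs with no co-observed sites are
undefined and callers substitute the cap.  Trees are built by BIONJ
(neighbor-joining selection criterion, variance-weighted branch estimates
and reduction), with ties broken toward the lowest index pair and negative
branch estimates clamped to zero.  The built-in builder is BIONJ followed by
alternating branch-length/shape optimization; no NNI/SPR topology search is
performed.  Matrix estimation needs near-optimal trees rather than provably
optimal ones, and users who want search-grade topologies can plug in an
external builder command (template writing Newick; e.g. PhyML or FastTree).

## Exchangeability estimation

With trees and rate models fixed, the joint log-likelihood over all
(sub-)alignments is maximized over R by expectation-maximization on
expected sufficient statistics.  For every branch, the E step computes the
site- and category-weighted joint posterior of the branch's endpoint states
and converts it, through the eigendecomposition integral
`int_0^t P(s) ... P(t-s) ds`, into expected substitution counts C_xy and
expected dwell times T_x.  The M step is closed form:

```
r_xy <- (C_xy + C_yx) / (pi_y T_x + pi_x T_y).
```

Each step cannot decrease the objective (tested); iteration stops at a
relative objective gain below 1e-6 (default cap 100 iterations).

One modeling point deserves emphasis: with branch lengths *fixed*, the
overall scale of R is a likelihood-relevant parameter, not a redundant one —
it is only confounded with time when branch lengths are re-fit.  The inner
loop therefore leaves the scale free (EM estimates it automatically), and
the unit-rate reporting convention is applied once to the returned matrix.
The next outer iteration rebuilds trees under the renormalized matrix, which
re-fits the time scale.  Clamping the scale inside the inner loop would
break EM monotonicity and could exclude the optimum.

A second maximizer — L-BFGS-B over the 190 log-exchangeabilities with the
analytic gradient `d logL / d log r_xy = (C_xy + C_yx) - r_xy (pi_y T_x +
pi_x T_y)` — is provided purely as an independent cross-check and is
compared against EM in the tests.

Frequencies Pi are estimated once from the pooled training data (counts
excluding gaps/ambiguities, pseudocount 0.5 per state) and held fixed across
iterations; re-estimating them each iteration is a documented alternative
the drivers do not take, since the outer loop lists frequency estimation
only in its input step.

## Drivers and convergence

The standard procedure iterates: build a tree and gamma shape per alignment
under the current matrix -> re-estimate R with those trees fixed -> stop
when successive matrices are nearly identical.  The split procedure first
splits every alignment once (alignments with fewer than 4 taxa, or at most
k taxa, are kept whole), then runs the same loop on the sub-alignments;
the loop re-enters at tree building, never at splitting.  Sub-alignments
inherit their parent's fitted shape as the starting value in later
iterations.

"Nearly identical" is made concrete as: Pearson correlation of the
successive 190-vectors >= 0.999 AND maximum relative entry change <= 10%,
with the relative-change denominator floored at 1% of the mean
exchangeability.  The floor exists because entries with essentially no
expected substitutions (rare pairs, at realistic training sizes) fluctuate
arbitrarily in relative terms while being ~1e-4 in absolute value.  The 10%
tolerance reflects a measured property of the procedure: successive matrices
reach correlation 1.000000 by iteration ~3 while individual small entries
keep jittering by ~5-7% from the tree rebuilds; a tolerance inside that
noise band would simply run every loop to the cap.  The cap defaults to 5
outer iterations; in simulations the loop converges by the criterion in 3-4.

## Splitting algorithms

Both splitters produce disjoint groups covering all taxa with sizes in
[ceil(k/2), k] whenever n > k (single group otherwise; default k = 16).

*Random*: shuffle the taxa with the configured seed and cut into
ceil(n/k) contiguous chunks of near-equal size.  Equal chunking (rather
than size-k chunks plus leftover donation) is used because it satisfies the
size bounds for every n and k without a redistribution pass.

*Tree-based*: compute ML pairwise distances under the current matrix and
agglomerate by BIONJ joins.  A cluster is emitted as a group when it reaches
size k exactly, or when the globally best join would push past k — in that
case the larger of the two clusters (provably >= ceil(k/2)) is emitted
instead of joining.  A terminal cluster smaller than ceil(k/2) is merged
into its nearest emitted group; if that would exceed k, the merged set is
re-split into two balanced halves seeded by its most distant members.  The
emission rule is this package's concrete reading of "group sequences in
neighbor-joining order under the size bounds"; it reproduces the expected
clade partitions on clade-structured data (e.g. the four 8-leaf clades of a
balanced 32-taxon tree at k = 8).  The guide clustering is computed once per
run.

## Evaluation

Two matrices are compared on test alignments by building a tree under each
(same builder), then pairing per-site log-likelihood vectors for the
Kishino-Hasegawa test: statistic `mean(delta) / (sd(delta)/sqrt(s))` against
the standard normal, two-sided (the classic normal-approximation variant;
no RELL bootstrap).  By default both matrices are evaluated on the
higher-likelihood of the two trees (shape re-fitted per matrix) so the
difference reflects the matrices rather than the topologies; pairing each
matrix with its own tree is available via `kh_on="own"`.  Winner, per-site
delta and significance all derive from the same vector pair, which makes the
comparison exactly antisymmetric under swapping the matrices.  Topology
difference is unweighted Robinson-Foulds distance > 0.

## Synthetic data

The simulator draws root states from Pi, assigns each site a discrete-gamma
category (the same discretization used in inference, so recovery is
exact-in-the-limit rather than model-misspecified), and evolves states down
random trees (Yule or perfectly balanced; i.i.d. exponential or constant
branch lengths).  No indels are simulated; an optional missingness rate
masks residues uniformly, which exercises the missing-data path of the
likelihood.  Simulated data therefore lack several features of real
alignments — gap structure, alignment error, site-specific profiles,
compositional heterogeneity across clades — so passing tests demonstrate
correctness of the estimator under its own model assumptions, not robustness
to violations of them.

## Problem sizes used by the test suite and acceptance script

These are the package's standard verification sizes, chosen to make the
statistical assertions sharp while keeping a full run on one CPU in the
tens of minutes:

- Exchangeability recovery with known trees: 10 alignments x 16 taxa x
  2000 sites, generating matrix LG, gamma(0.8, 4 categories); the
  acceptance script uses 6 x 16 x 1200 at the same settings.
- Split-vs-standard fidelity: train 10 x 48 x 500 (Yule trees, exponential
  branch lengths mean 0.08), test 20 x 12 x 300; k = 16 (the recommended
  threshold).  The acceptance script runs a reduced edition (6 x 32 x 400
  train, 12 x 10 x 250 test).
- Tree-based vs random splitting replicates: 10 replicates of 3 alignments
  x 24 taxa x 300 sites on clade-structured trees (three 8-taxon Yule clades,
  within-clade branch mean 0.08, backbone branches 8x longer), k = 8.  The
  clade structure is the regime the comparison is about: random groups
  straddle the saturated backbone, clade-guided groups do not.  On
  single-scale Yule trees the contrast disappears or even reverses — clade
  groups then simply span less branch length and estimate rare
  exchangeabilities more noisily — which is itself a documented observation
  from this package's simulations (see the acceptance script's replicate
  block).
- KH null calibration: 500 replicate pairs of independent 4-taxon x
  300-site simulations under one model.
- Cost scaling across k: one 128-taxon x 300-site alignment, k in
  {8, 16, 32}, counting likelihood-objective evaluations during tree
  building.

## Known limitations

- The built-in tree builder performs no topology search beyond BIONJ;
  on very short or very deep alignments its topologies are less accurate
  than PhyML/RAxML ones.  The external-builder hook exists for that case.
- Pi is a point estimate from pooled counts; compositional heterogeneity
  across clades is averaged over, as in the standard empirical-matrix
  workflow.
- Guide-tree distances ignore rate variation (ncat = 1), a speed choice
  that slightly compresses large distances.
- The KH normal approximation is anti-conservative for very short
  alignments (few hundred sites); calibration is verified at s = 300.
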