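# Methods

## Failure model and fragmentation entropy

The unit of damage is *node isolation*: a failed protein keeps its identity
but loses every interaction, persisting as a size-1 component. This is
deliberately different from node *deletion* — isolation keeps the entropy
normalizer N fixed across the whole failure sweep, which is what makes the
two anchors exact: an intact connected network has H_msh = 0, and a fully
isolated one has H_msh = 1.

H_msh is the Shannon diversity of the component-size distribution
normalized by log N. We evaluate it as

    H = 1 − (Σ s·ln s) / (N·ln N)

over component sizes s, which is algebraically identical to
−(1/ln N)·Σ p·ln p but free of the floating-point residue of `log(1/N)`,
so the 0 and 1 anchors hold *exactly* in double precision. The logarithm
base cancels in the ratio; natural log is used throughout. Size-1
components contribute nothing to the sum (the 0·log 0 convention is
automatic), but they do count toward the partition — this is required for
H to reach 1 at complete isolation.

Single-node networks are rejected (log 1 = 0 makes the normalizer
undefined); resilience is defined on the largest connected component (LCC),
which callers extract first.

## Monte-Carlo resilience

R(G) = 1 − ∫ H df is evaluated on the discrete failure grid
{0, step, 2·step, …, 1} (default step 0.01) by the trapezoid rule. At each
grid point, `reps` (default 100) independent uniformly random node subsets
of size m(f) = ⌊f·N + 0.5⌋ are isolated and the entropies averaged.
Round-half-up makes m(1) = N exactly and avoids platform-dependent banker's
rounding. Failure sets are drawn independently per grid point and replicate
(not nested along f); a nested scheme would correlate adjacent grid points
without changing the mean at any single f.

Numerics: component sizes come from a union-find pass over the edge array,
compiled with numba — the per-node sweep below needs on the order of 10⁶
partitions per network, where graph-object overhead would dominate. The
trapezoid rule on a 1 % grid is stable: halving the step changes R of K₁₀
by well under 0.01.

Determinism contract: every simulation takes an integer seed, and identical
inputs give bit-identical outputs. Random streams are numpy `SeedSequence`
substreams, never shared between stages or nodes.

## Node Resilience

NRᵢ deletes node vᵢ (removing it from the node set, unlike the isolation
step inside the entropy sweep — a dead protein no longer contributes a
component to the residual interactome) and computes R of the residual
(N−1)-node graph, *normalized by the residual node count*. Treating the
residual graph as its own reference keeps every NR on the same [0, 1] scale
as R. The residual may be disconnected at f = 0; its entropy curve then
starts above zero, which is exactly the mechanism that depresses the NR of
bridge nodes.

Each node's simulation uses a fresh substream keyed by (seed, rank in
lexicographic node order), so results are independent of iteration order
and the sweep is trivially parallelizable without changing any value. Ranks
are assigned ascending in NR (rank 1 = most critical), ties broken by node
identifier.

Outlier flagging uses the normal-approximation 95 % band
(mean ± 1.959964·sd of the NR column) by default; an empirical-percentile
band is available. Key Component Nodes are the ⌈0.10·N⌉ lowest-NR nodes
(ceiling, so a 187-node network yields a 19-node decile).

## Degradation trajectories and breakpoints

The progressive-failure experiment deletes a random m(f)-subset per outer
replicate, extracts the residual LCC, and scores it with a nested
resilience simulation. Defaults: outer step 0.01 with 100 replicates;
inner step 0.02 with 10 replicates — the inner simulation is an estimate of
a bounded integrand, so a coarser grid and fewer replicates lose little
precision while keeping a full trajectory on a ~10³-node network in the
minutes range. Residuals with fewer than 2 nodes score R = 0 by
convention. A cheap proxy mode (1 − H_msh of the deletion partition, no
nested simulation) is available behind `mode="entropy"` for exploratory
scans.

The breakpoint is estimated by exhaustive search over interior grid points:
at each candidate c the hinge model y = a + b₁·min(f−c, 0) + b₂·max(f−c, 0)
(continuous at c, linear in its parameters) is fit by ordinary least
squares, and the candidate with minimal SSE wins; the first minimum is kept
on exact ties, so the fit is deterministic, and it is invariant to positive
affine rescaling of the y values. Candidates need at least 3 grid points
strictly on each side inside the search window (default [0.05, 0.95], which
avoids boundary artifacts). If the best fit does not steepen to the right
(|b₂| ≤ |b₁| within a relative tolerance of 10⁻⁹, so a perfectly straight
line flags cleanly), the result carries a `no_acceleration` flag instead of
a spurious threshold. Because candidates live on the grid, the estimate's
resolution is one grid step; reported values are percentages.

## Centralities and the NR comparison

DC, BC and CC use the standard normalizations (degree/(N−1); pair
normalization 2/((N−1)(N−2)); (N−1)/Σ distances) via networkx. Eigenvector
centrality is a deterministic power iteration on A + I — the identity shift
leaves eigenvectors unchanged but makes the iteration aperiodic, so it
converges on bipartite graphs such as stars — from a uniform start vector,
unit Euclidean norm, max-norm tolerance 10⁻⁸, cap 1000 iterations.
Exceeding the cap raises a convergence error reporting the eigen-equation
residual; this genuinely happens on highly symmetric modular graphs with
near-degenerate leading eigenvalues (e.g., planted modules at intra-module
density ≳ 0.5), a known limitation of the fixed cap.

NR-vs-centrality correlation defaults to Spearman's rank coefficient: the
NR and BC distributions are heavy-tailed, and rank correlation is invariant
to monotone transforms; Pearson is a flag. Zero-variance columns yield NaN,
reported as undefined rather than erroring. The Key Bridge Nodes are the
⌈0.10·N⌉ highest-BC nodes; the overlap report gives the intersection count,
the fraction |KCN ∩ KBN|/|KCN| and the Jaccard index (reporting both count
and fraction avoids ambiguity — published overlap percentages do not always
equal their printed counts). A multi-network summary aggregates correlation
reports into per-measure quantiles suitable for violin plots; plotting
itself is out of scope (all outputs are TSV/JSON).

## Synthetic networks

The generator provides exact fixtures (star, path, cycle, complete — used
as closed-form oracles throughout the tests), Erdős–Rényi and
preferential-attachment graphs, and the `planted_modular` family that
emulates the architecture the resilience analysis probes: M internally
connected random modules (random recursive spanning tree plus independent
extra edges) joined *only* through dedicated bridge nodes.

Defaults and why:

- `intra_p = 0.15` — with 25-node modules this gives mean intra-module
  degree ≈ 5, matching the edge density of bacterial interactomes (SNAP
  networks range roughly 2.5–9) toward the sparse end, where modules
  genuinely depend on their bridges.
- `attachments = 2` — each bridge links to two random members of every
  module. A single attachment would make that gateway member inherit
  essentially all of the bridge's cross-module shortest-path load *plus*
  its own intra-module load, letting it out-rank the bridge on betweenness;
  two attachments split the cross-traffic so the bridge is unambiguously
  the top-betweenness keystone, for any intra-module density.

What the surrogate does *not* emulate: scale-free degree tails, overlapping
module membership, interaction confidence weights, and network sizes beyond
a few hundred nodes. Passing tests on it therefore demonstrate the
*mechanism* (bridge depletion → fragmentation → low NR, strong negative
NR–BC rank correlation) at desk scale, not numerical agreement with any
particular organism's interactome; analyses of real SNAP edge lists run
through the same API/CLI on user-supplied files.

## Problem sizes in the shipped tests

The test suite and the acceptance script run the full-resolution settings
(1 % grid, 100 replicates) on ~100-node modular surrogates and exact
fixtures, where the complete sweep takes seconds per network; trajectory
simulations use the nested-default inner settings above. Larger networks
use the identical code paths with runtime growing roughly as
N·E·reps/step.
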