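# Methods

## Model

At quasi steady state, the balanced metabolites of a metabolic network
satisfy `S·v = 0`, and every admissible flux distribution is a
nonnegative combination of the network's elementary flux modes (EMs):
`V = E·P` with `P ≥ 0`. Given a measured flux matrix `V_mes`
(`n_mes` fluxes × `n_d` experiments) and a candidate EM matrix, the
package selects, per factor count `k`, the `k`-mode subset whose
decomposition explains the most variance of `V_mes` — the principal
elementary modes. Explained variance is always the uncentered fraction

```
ϑ = 1 − ‖V_mes − V_est‖_F² / ‖V_mes‖_F²
```

computed against the scaled data (see below), so reported values are
not comparable to centered-PCA variance fractions unless the PCA curve
is also computed uncentered (the default here).

## Decomposition estimator

Candidate columns are unit-normalized (`e_n = e/‖e‖₂`; weights scale
back as `p = p_n/‖e‖₂`). A mode's weights on a residual matrix are its
clipped projections `p_n = max(e_nᵀ V_iter, 0)` — negative weights
conflict with the nonnegativity of mode contributions and are zeroed
per experiment independently, so a weight vector can be partially
clipped. Its contribution is the rank-one outer product `e_n p_nᵀ`,
which is subtracted (deflation) before the next mode is scored.
Because each deflation removes exactly `Σp_n²` of squared Frobenius
norm, the cumulative explained variance equals `Σ Σ p_n² / ‖V_mes‖_F²`;
this identity is exercised by tests to 1e-10.

This estimator is sequential (a nonnegative matching pursuit), not a
joint least-squares fit: for non-orthogonal modes the explained
variance of a fixed set depends on deflation order, and even the true
generating set does not reach ϑ = 1 when its modes are mutually
correlated (cross-talk). Both properties are inherent to the method and
surfaced in the result (the order actually scored is recorded).

## Pre-selection

Pipeline: restrict to measured rows → mean-scale → direction filter →
ambiguity grouping → unit normalization.

* **Mean scaling** (default `abs_mean`): every measured flux row of the
  data *and* of the restricted mode matrix is divided by the mean
  magnitude of that flux across experiments, so fluxes of different
  magnitude contribute comparably. The literal signed mean is available
  (`signed_mean`); it can be ~0 for mixed-sign fluxes, in which case the
  row is dropped with a warning, and negative for predominantly negative
  fluxes, in which case dividing also orients the flux positive. Rows
  whose factor magnitude is below 1e-12 are uninformative and dropped.
* **Direction filter** (`global` or `off`): for a flux whose nonzero
  values share one sign across all experiments, a mode with a strictly
  opposite-signed entry for that flux cannot be active (a reaction runs
  in one direction at a time). Mixed-sign fluxes impose no constraint;
  they trigger a warning because a sign inconsistency in the data should
  be fixed upstream, never silently auto-corrected here. Filtering is
  global across experiments; a per-experiment variant would be stricter
  and is deliberately not applied.
* **Ambiguity grouping**: modes whose measured restrictions are
  positively proportional (cosine ≥ 1 − `ambiguity_tol`, default 1e-9)
  cannot be distinguished by any data on these fluxes; one
  representative per group (lowest id, deterministic) is kept and the
  grouping is attached to the result so a selected representative can be
  read as "this mode or anything in its group". Proportionality, not
  entrywise equality, is used because mode vectors are defined only up
  to positive scale. Opposite-sign proportional restrictions behave
  differently under nonnegative weights and are not grouped. Modes whose
  restriction norm is below `ambiguity_tol` times the largest are
  unidentifiable and removed.

Estimating unmeasured fluxes from the stoichiometry before fitting is
out of scope (future work).

## Greedy pass and branch-and-bound search

The greedy ("best first") pass scores all remaining candidates on the
current residual with one matrix product per iteration, picks the
largest gain (ties within `tie_tol` broken by lowest mode id), deflates
and repeats, for at most `min(n_fac, n_mes)` iterations.

The search explores unordered mode combinations: children of a node are
its candidate modes ordered by descending gain on the node's residual,
and each child may only extend with candidates ranked after it, so
every subset is visited exactly once and scored in its greedy-within-set
order. A dedicated search runs per factor count `k` (selections at
different `k` are genuinely different, as the factor tables show); its
incumbent is the better of the greedy prefix and the previous best set
extended by one mode. Nodes are pruned when

```
bound = min(1, ϑ_so_far + sum of the (k − depth) largest single-mode gains on the node residual)
```

cannot beat the incumbent by more than `prune_tol` (default 1e-12;
pruning uses ≤ so exact ties prune). The same bound applied with the
parent's gains prunes whole runs of later siblings at once, since it is
non-increasing across the descending-gain child order.

**Bound validity.** The gain-sum bound is exact when the completing
modes are mutually independent. It is a true upper bound whenever
deflation cannot increase a clipped single-mode gain — guaranteed in
particular when the restricted mode matrix is entrywise nonnegative,
which is the typical situation after direction filtering (all kept
entries share the sign of their flux). With sign-mixed candidates a
deflation can *raise* another mode's clipped gain (subtracting a
contribution can flip a negative projection positive), and the bound
becomes heuristic; `prune=False` forces an exhaustive (slower) search
whose result never differs when the bound is valid — a tested
invariant. Searches on random nonnegative problems agree with
brute-force enumeration to 1e-12.

A node budget (`max_evals`, counting combinations scored plus nodes
expanded) aborts a search with the current incumbent flagged
`proven_optimal = False`; combinatorial explosion at high factor counts
makes this essential for interactive use on ~100-mode problems. For
budgeted searches the incumbent additionally admits the previous best
order extended in place, whose value is the previous ϑ plus a
nonnegative gain — this keeps the reported curve nondecreasing even
when a search is cut off before improving on its incumbent. Exact
(unbudgeted) searches use only canonically scored incumbents so their
result is exactly the enumeration optimum under the same scoring rule.

`BnBStats` records combinations scored (`nodes_evaluated`, compared
against the theoretical count `C(m′, k)`), nodes expanded, subtrees
pruned, the incumbent trace and wall time.

## PCA baseline

The baseline curve is cumulative top-`k` squared singular values over
the squared Frobenius norm of the same scaled data — uncentered by
default so it is directly comparable with ϑ (a `centered` flag covers
the conventional definition; which preprocessing a given published PCA
used is often unstated, so both are available). Since rank-`k` SVD
truncation minimizes residual norm over all rank-`k` reconstructions
and the mode decomposition's estimate has rank ≤ k, the PCA curve
dominates the mode curve pointwise — a tested invariant.

## Plateau detection

The suggested number of principal modes is the smallest `k` whose gain
to `k+1` falls below 0.1 percentage points of explained variance
(configurable). The threshold is chosen to fire on curves that change
only in the second decimal while not firing mid-rise. A caution
inherent to the method: past the plateau the selection starts modeling
noise, and a tiny late increase in ϑ should not be read as evidence
that the extra mode is active.

## Synthetic data generator

`simulate_flux_data` draws nonnegative weights for a declared active
subset (uniform per mode and experiment, optionally sparsified per
experiment or replaced by an explicit weight matrix), forms
`V = E_active·P`, and applies multiplicative Gaussian noise
(`noise_pct` percent of each entry's magnitude; an additive variant is
available). Multiplicative noise was chosen because flux measurement
error typically scales with magnitude.

The `pichia_like` study case emulates a simulation study on a
~100-mode yeast-like central-carbon candidate set: 98 modes over 9
measured exchange fluxes (three substrates, oxygen, carbon dioxide,
biomass and three byproducts), 16 active, 12 cultivation conditions.
Its geometry encodes how curated EM sets are structured:

* modes cluster into pathway families — same signature substrate or
  product flux, different internal routing and hence different side
  yields — rather than scattering uniformly;
* nine of the sixteen active modes are family centers with
  signature-dominated, near-orthogonal footprints, and each of the
  twelve conditions is dominated by one of them (primary weight
  U(0.6, 1)); the other seven actives contribute only minor weights
  (10 % scale), together a few percent of variance;
* family members keep their center's signature flux but differ in side
  fluxes, with similarity to every active center capped at cosine 0.75
  *in the mean-scaled geometry* the solver actually sees — raw-space
  margins are meaningless here because scaling strongly amplifies
  sparse flux rows; families that cannot hold a further distinguishable
  member (fully amplified signatures) contribute generic footprints
  instead.

What passing recovery tests show, and what they do not: under this
identifiable regime — distinct dominant regimes, minor actives below
the plateau threshold, decoys separated from actives — the search
recovers only generating modes at the plateau in ≥ 90 % of seeds and
the selection is robust to 10 % noise. They do not show that recovery
holds for arbitrary candidate geometries: with ~100 unstructured random
candidates in a 9-dimensional measured space, decoys approximate
mixture and residual directions and provably out-score the generating
set under sequential deflation. Identifiability is a property of the
data and candidate set, not of the algorithm.

The brute-force mode enumerator (support enumeration over the
stoichiometric nullspace, both orientations tried against
irreversibility, non-minimal supports discarded) is for ≤ 20-reaction
fixtures only; real enumeration belongs to dedicated tools.

## Problem sizes and budgets

Tests and the acceptance script run the recovery protocol at 20 seeds ×
3 noise levels with a search budget of 50 000 nodes per factor count
(≈ 1–2 s per case), and oracle-equivalence checks at m ≤ 10, k ≤ 4
where exhaustive enumeration is itself cheap. Exactness of budgeted
runs is reported per factor count via `proven_optimal`.

## Known limitations

* Sequential deflation under-reports the variance of correlated mode
  sets (no joint refit); an NNLS refit of the final selection would be
  a natural diagnostic extension.
* The gain-sum bound is heuristic for sign-mixed candidate sets (see
  above); results there should be run with a generous budget or
  `prune=False` when exactness matters.
* Weights are reported both norm-scaled (`p_n`) and un-scaled
  (`p = p_n/‖e‖₂`); published figures may use either convention.
* The direction filter trusts the sign of the data; it warns on
  mixed-sign fluxes instead of correcting them.
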