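"""Branch-and-bound search for the principal elementary modes.

The greedy decomposition is fast but, because candidate modes are not
orthogonal, its selection need not capture the most variance for a given
factor count.  The search here explores combinations of modes: each
unordered combination is visited exactly once (children of a node may
only draw from the candidates ranked after them at that node), and
within a branch modes are appended in descending order of their variance
gain on the node's residual, so every visited set is scored in its
greedy-within-set order.  Subtrees are cut when an upper bound — the
captured variance so far plus the sum of the largest remaining
single-mode gains on the node's residual, capped at one — cannot beat
the incumbent.  The greedy solution initializes the incumbent (a lower
bound), which is raised whenever a better combination is found.

The gain-sum bound is exact when the remaining modes are mutually
independent and is an upper bound whenever deflation cannot increase a
clipped single-mode gain — guaranteed in particular for entrywise
nonnegative restricted mode matrices, the usual situation after
direction filtering.  Sign-mixed candidate sets can in principle defeat
the bound; ``prune=False`` disables pruning for an exhaustive (slower)
search.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .core import (
    GreedyTrace,
    contribution,
    deflate,
    greedy_fit,
    mode_gains,
    project_weights,
)
from .io_model import PEMAConfig, ValidationError
from .preprocess import ScaledProblem

logger = logging.getLogger(__name__)

__all__ = [
    "SearchNode",
    "BnBStats",
    "FactorResult",
    "PEMAResult",
    "score_sequence",
    "score_set",
    "node_upper_bound",
    "branch_and_bound_fit",
    "exhaustive_best",
    "plateau_index",
]


def plateau_index(theta_curve, threshold: float = 1e-3) -> int:
    """Suggested factor count: last one before the variance gain goes flat.

    Returns the smallest ``k`` such that the gain from ``k`` to ``k + 1``
    factors falls below ``threshold`` (a fraction of explained variance;
    the default 1e-3 is 0.1 percentage points).  If no gain is that
    small, returns ``len(theta_curve)``.
    """
    curve = list(theta_curve)
    for k in range(1, len(curve)):
        if curve[k] - curve[k - 1] < threshold:
            return k
    return len(curve)

_PROGRESS_EVERY = 100_000


@dataclass
class SearchNode:
    """A partial combination during the search."""

    depth: int
    chosen_ids: tuple[str, ...]
    residual: np.ndarray
    theta_so_far: float


@dataclass
class BnBStats:
    """Accounting for one branch-and-bound search.

    ``nodes_evaluated`` counts complete factor-count combinations scored;
    it never exceeds ``n_comb_theoretical = C(m', n_fac)``, the number of
    unordered combinations that exhaustive evaluation would require.
    """

    m_prime: int = 0
    n_fac: int = 0
    nodes_evaluated: int = 0
    nodes_expanded: int = 0
    nodes_pruned: int = 0
    n_comb_theoretical: int = 0
    incumbent_history: list = field(default_factory=list)
    elapsed_seconds: float = 0.0
    proven_optimal: bool = True

    def to_dict(self) -> dict:
        return {
            "m_prime": self.m_prime,
            "n_fac": self.n_fac,
            "nodes_evaluated": self.nodes_evaluated,
            "nodes_expanded": self.nodes_expanded,
            "nodes_pruned": self.nodes_pruned,
            "n_comb_theoretical": self.n_comb_theoretical,
            "incumbent_history": [
                {"theta": t, "mode_ids": list(ids)} for t, ids in self.incumbent_history
            ],
            "elapsed_seconds": self.elapsed_seconds,
            "proven_optimal": self.proven_optimal,
        }


@dataclass(frozen=True)
class FactorResult:
    """Best combination found for one factor count."""

    n_fac: int
    selected_ids: tuple[str, ...]     # in the order actually scored
    theta: float
    weights_norm: np.ndarray          # n_fac x n_d
    weights: np.ndarray               # unscaled by column norms
    stats: BnBStats
    ambiguous_with: dict              # selected id -> full ambiguity group (if any)


@dataclass(frozen=True)
class PEMAResult:
    """Per-factor-count selections, explained variance and weights."""

    factors: tuple[FactorResult, ...]
    greedy: GreedyTrace
    mode_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]

    @property
    def theta_curve(self) -> tuple[float, ...]:
        return tuple(f.theta for f in self.factors)

    @property
    def stats(self) -> BnBStats:
        return self.factors[-1].stats

    def to_dict(self) -> dict:
        return {
            "factors": [
                {
                    "n_fac": f.n_fac,
                    "selected_ids": list(f.selected_ids),
                    "theta": f.theta,
                    "weights_norm": np.asarray(f.weights_norm).tolist(),
                    "weights": np.asarray(f.weights).tolist(),
                    "ambiguous_with": {k: list(v) for k, v in f.ambiguous_with.items()},
                    "stats": f.stats.to_dict(),
                }
                for f in self.factors
            ],
            "greedy": {
                "selected_ids": list(self.greedy.selected_ids),
                "theta_curve": list(self.greedy.theta_curve),
            },
            "experiment_ids": list(self.experiment_ids),
        }

    def to_table(self) -> str:
        """Plain-text factor table: rows = factor count, selection and theta."""
        lines = [f"{'n_fac':>5}  {'theta':>8}  selected modes"]
        for f in self.factors:
            lines.append(f"{f.n_fac:>5}  {100 * f.theta:>8.2f}  {' '.join(f.selected_ids)}")
        g = self.greedy
        lines.append(f"{'BF':>5}  {100 * (g.theta_curve[-1] if g.theta_curve else 0.0):>8.2f}  "
                     f"{' '.join(g.selected_ids)}  (best-first greedy)")
        return "\n".join(lines) + "\n"


def score_sequence(problem: ScaledProblem, mode_ids) -> tuple[float, np.ndarray, np.ndarray]:
    """Score an explicit ordered mode sequence by project-clip-deflate.

    Returns ``(theta, weights_norm, residual)``.  The explained variance
    of a fixed set depends on the order in which its members are
    deflated; callers choose the order.
    """
    mode_ids = tuple(mode_ids)
    if len(set(mode_ids)) != len(mode_ids):
        raise ValidationError("duplicate mode id in sequence")
    V = problem.V.copy()
    tss = problem.total_ss
    weights = np.zeros((len(mode_ids), problem.n_d))
    captured = 0.0
    for row, mid in enumerate(mode_ids):
        e = problem.E_norm[:, problem.mode_index(mid)]
        p = project_weights(e, V)
        V = deflate(V, contribution(e, p))
        captured += float(p @ p)
        weights[row] = p
    return captured / tss, weights, V


def score_set(problem: ScaledProblem, mode_ids) -> tuple[float, tuple[str, ...]]:
    """Canonical score of an unordered set: greedy order within the set.

    At each step the member with the largest gain on the current residual
    is deflated next (ties by lowest id).  Returns ``(theta, order)``.
    """
    remaining = sorted(set(mode_ids))
    if len(remaining) != len(tuple(mode_ids)):
        raise ValidationError("duplicate mode id in set")
    V = problem.V.copy()
    captured = 0.0
    order: list[str] = []
    while remaining:
        best_id, best_gain = None, -1.0
        for mid in remaining:  # sorted -> ties resolve to lowest id
            e = problem.E_norm[:, problem.mode_index(mid)]
            p = np.maximum(e @ V, 0.0)
            g = float(p @ p)
            if g > best_gain:
                best_id, best_gain = mid, g
        e = problem.E_norm[:, problem.mode_index(best_id)]
        p = project_weights(e, V)
        V = deflate(V, contribution(e, p))
        captured += float(p @ p)
        order.append(best_id)
        remaining.remove(best_id)
    return captured / problem.total_ss, tuple(order)


def node_upper_bound(
    theta_so_far: float,
    residual: np.ndarray,
    E_norm_remaining: np.ndarray,
    slots: int,
    total_ss: float,
) -> float:
    """Upper bound on the variance attainable by completing a node.

    The sum of the ``slots`` largest single-mode gains on the node's
    residual, added to the variance captured so far and capped at one.
    The cap reflects that no decomposition explains more than the total
    sum of squares; the gain sum is attained when the completing modes
    are mutually independent.
    """
    if slots <= 0 or E_norm_remaining.shape[1] == 0:
        return theta_so_far
    gains = mode_gains(E_norm_remaining, residual)
    top = np.sort(gains)[::-1][:slots]
    return min(1.0, theta_so_far + float(np.sum(top)) / total_ss)


def exhaustive_best(problem: ScaledProblem, k: int) -> tuple[float, tuple[str, ...]]:
    """Brute-force reference: best canonical score over all C(m', k) sets.

    Enumerates every unordered combination with :func:`itertools.combinations`
    and scores each with :func:`score_set`; intended for small problems and
    as an independent check of :func:`branch_and_bound_fit`.
    """
    best_theta, best_order = -np.inf, ()
    for combo in itertools.combinations(sorted(problem.kept_mode_ids), k):
        theta, order = score_set(problem, combo)
        if theta > best_theta:
            best_theta, best_order = theta, order
    return best_theta, best_order


def _search_one_k(
    problem: ScaledProblem,
    k: int,
    incumbent_theta: float,
    incumbent_order: tuple[str, ...],
    prune_tol: float,
    max_evals: int | None,
    prune: bool = True,
) -> tuple[float, tuple[str, ...], BnBStats]:
    """Depth-first canonical-combination search for one factor count."""
    E = problem.E_norm
    ids = problem.kept_mode_ids
    tss = problem.total_ss
    stats = BnBStats(m_prime=problem.m_prime, n_fac=k, n_comb_theoretical=comb(problem.m_prime, k))
    best_capt = incumbent_theta * tss
    best_order = incumbent_order
    stats.incumbent_history.append((incumbent_theta, incumbent_order))
    prune_slack = prune_tol * tss
    aborted = False
    t0 = time.perf_counter()

    def recurse(chosen: tuple[str, ...], cand: np.ndarray, V: np.ndarray, capt: float) -> None:
        nonlocal best_capt, best_order, aborted
        if aborted:
            return
        depth = len(chosen)
        slots = k - depth
        gains = mode_gains(E[:, cand], V)
        if prune:
            # bound on this node: captured so far + top single-mode gains
            top = np.partition(gains, -min(slots, gains.size))[-slots:]
            bound = min(capt + float(np.sum(top)), tss)
            if bound <= best_capt + prune_slack:
                stats.nodes_pruned += 1
                return
        stats.nodes_expanded += 1
        if max_evals is not None and stats.nodes_expanded + stats.nodes_evaluated >= max_evals:
            aborted = True
            return
        if stats.nodes_expanded % _PROGRESS_EVERY == 0:
            logger.info(
                "search k=%d: %d nodes expanded, %d combinations evaluated, incumbent %.6f",
                k, stats.nodes_expanded, stats.nodes_evaluated, best_capt / tss,
            )
        # descending gain, ties by lowest id: canonical child order
        order = sorted(range(len(cand)), key=lambda j: (-gains[j], ids[cand[j]]))
        if slots == 1:
            for j in order:
                stats.nodes_evaluated += 1
                new_capt = capt + float(gains[j])
                if new_capt > best_capt:
                    best_capt = new_capt
                    best_order = chosen + (ids[cand[j]],)
                    stats.incumbent_history.append((best_capt / tss, best_order))
                elif prune:
                    break  # descending gains: no later sibling can improve
            return
        g_sorted = gains[order]
        # parent-side sibling bound: child pos plus the best (slots - 1)
        # gains ranked after it; non-increasing in pos, so one failure
        # prunes all later siblings at once.
        sib_bound = capt + g_sorted + np.concatenate(
            [np.convolve(g_sorted[1:], np.ones(slots - 1), mode="valid"),
             np.full(min(slots - 1, len(g_sorted)), -np.inf)]
        )[: len(g_sorted)]
        for pos, j in enumerate(order):
            if aborted:
                return
            if len(order) - pos - 1 < slots - 1:
                break  # not enough candidates left to complete
            if prune and sib_bound[pos] <= best_capt + prune_slack:
                stats.nodes_pruned += len(order) - pos
                break
            rest = cand[order[pos + 1:]]
            i = cand[j]
            e = E[:, i]
            p = np.maximum(e @ V, 0.0)
            recurse(chosen + (ids[i],), rest, V - np.outer(e, p), capt + float(p @ p))

    recurse((), np.arange(problem.m_prime), problem.V.copy(), 0.0)
    stats.elapsed_seconds = time.perf_counter() - t0
    stats.proven_optimal = not aborted
    if aborted:
        logger.warning(
            "search k=%d aborted at %d evaluated combinations; result not proven optimal",
            k, stats.nodes_evaluated,
        )
    return best_capt / tss, best_order, stats


def branch_and_bound_fit(problem: ScaledProblem, config: PEMAConfig, prune: bool = True) -> PEMAResult:
    """Best combination of modes for every factor count up to ``config.n_fac``.

    A dedicated search runs for each factor count ``k``; its incumbent is
    the better of the greedy prefix of length ``k`` and the previous
    best set extended by one mode, both scored canonically.  The factor
    count is capped at the number of measured fluxes and at the number of
    surviving candidates.
    """
    if problem.m_prime == 0:
        raise ValidationError("problem has no candidate modes")
    k_max = min(config.n_fac, problem.n_mes, problem.m_prime)
    if k_max < config.n_fac:
        logger.warning(
            "n_fac=%d capped to %d (measured fluxes: %d, surviving modes: %d)",
            config.n_fac, k_max, problem.n_mes, problem.m_prime,
        )
    greedy = greedy_fit(problem, k_max, config.tie_tol)
    factors: list[FactorResult] = []
    prev_theta, prev_order = 0.0, ()
    for k in range(1, k_max + 1):
        candidates: list[tuple[float, tuple[str, ...]]] = []
        if len(greedy.selected_ids) >= k:
            candidates.append(score_and_order(problem, greedy.selected_ids[:k]))
        if prev_order:
            ext = _best_extension(problem, prev_order)
            if ext is not None:
                extended = prev_order + (ext,)
                candidates.append(score_and_order(problem, extended))
                if config.max_evals is not None:
                    # budgeted searches may stop at the incumbent, so also
                    # admit the previous order extended in place: its value
                    # is previous theta plus a nonnegative gain, keeping the
                    # reported curve nondecreasing.  Exact searches stay
                    # canonical (every incumbent is a greedy-within-set
                    # score), preserving comparability with enumeration.
                    theta_ext, _, _ = score_sequence(problem, extended)
                    candidates.append((theta_ext, extended))
        if not candidates:
            candidates.append((0.0, ()))
        inc_theta, inc_order = max(candidates, key=lambda c: c[0])
        theta, order, stats = _search_one_k(
            problem, k, inc_theta, inc_order, config.prune_tol, config.max_evals, prune
        )
        _, weights_norm, _ = score_sequence(problem, order)
        norms = np.array([problem.column_norms[problem.mode_index(m)] for m in order])
        ambiguous = {
            m: g for m in order if (g := problem.ambiguity.group_of(m)) is not None
        }
        factors.append(
            FactorResult(
                n_fac=k,
                selected_ids=order,
                theta=theta,
                weights_norm=weights_norm,
                weights=weights_norm / norms[:, None],
                stats=stats,
                ambiguous_with=ambiguous,
            )
        )
        prev_theta, prev_order = theta, order
    return PEMAResult(
        factors=tuple(factors),
        greedy=greedy,
        mode_ids=problem.kept_mode_ids,
        experiment_ids=problem.experiment_ids,
    )


def score_and_order(problem: ScaledProblem, mode_ids) -> tuple[float, tuple[str, ...]]:
    """Canonical (greedy-within-set) score and order of an unordered set."""
    return score_set(problem, mode_ids)


def _best_extension(problem: ScaledProblem, order: tuple[str, ...]) -> str | None:
    """Mode with the largest gain on the residual after deflating *order*."""
    _, _, residual = score_sequence(problem, order)
    remaining = [m for m in problem.kept_mode_ids if m not in order]
    if not remaining:
        return None
    cols = [problem.mode_index(m) for m in remaining]
    gains = mode_gains(problem.E_norm[:, cols], residual)
    return remaining[int(np.argmax(gains))]
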