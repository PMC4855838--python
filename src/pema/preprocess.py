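"""Pre-selection of candidate modes and assembly of the scaled problem.

Measured fluxes are usually a small subset of the network's reactions, so
candidate modes are first restricted to the measured rows.  Three
reductions then apply before any fitting:

* **mean scaling** — each measured flux row (of both the data and the
  restricted mode matrix) is divided by its mean magnitude so that fluxes
  of different magnitude contribute comparably to the variance;
* **direction filtering** — by the non-cancellation principle a reaction
  carries flux in one direction at a time, so a mode whose entry opposes
  the direction consistently observed for a flux cannot be active;
* **ambiguity grouping** — modes whose measured restrictions are zero or
  positively proportional cannot be distinguished by the data; one
  representative per group is kept and the grouping is reported.

Surviving columns are finally normalized to unit 2-norm
(``e_n = e / ||e||_2``), which fixes the scale freedom of mode vectors;
the recorded norms convert fitted weights back to the raw mode scale
(``p = p_n / ||e||_2``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_model import EMSet, FluxData, PEMAConfig, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ScaledProblem",
    "AmbiguityReport",
    "mean_scale",
    "detect_ambiguous",
    "filter_by_direction",
    "build_problem",
]


@dataclass(frozen=True)
class AmbiguityReport:
    """Groups of mode ids indistinguishable on the measured fluxes."""

    groups: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...]

    def group_of(self, mode_id: str) -> tuple[str, ...] | None:
        for g in self.groups:
            if mode_id in g:
                return g
        return None


@dataclass(frozen=True)
class ScaledProblem:
    """The preprocessed decomposition problem handed to the solvers.

    ``E_norm`` holds the measured-row-restricted, mean-scaled, unit-norm
    surviving mode columns; ``V`` the correspondingly scaled flux data.
    ``column_norms[j]`` is the 2-norm the ``j``-th surviving column had
    before normalization (used to un-scale weights).
    """

    V: np.ndarray                     # n_mes x n_d, scaled
    E_norm: np.ndarray                # n_mes x m', unit-norm columns
    column_norms: np.ndarray          # m'
    scale_factors: dict[str, float]   # per kept flux id
    flux_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]
    kept_mode_ids: tuple[str, ...]
    ambiguity: AmbiguityReport
    removed_by_direction: tuple[str, ...]
    removed_zero_measured: tuple[str, ...]
    dropped_flux_ids: tuple[str, ...] = ()

    def __post_init__(self):
        norms = np.linalg.norm(self.E_norm, axis=0)
        if self.E_norm.shape[1] and not np.allclose(norms, 1.0, atol=1e-12):
            raise ValidationError("surviving mode columns must have unit 2-norm")

    @property
    def m_prime(self) -> int:
        return self.E_norm.shape[1]

    @property
    def n_mes(self) -> int:
        return self.V.shape[0]

    @property
    def n_d(self) -> int:
        return self.V.shape[1]

    @property
    def total_ss(self) -> float:
        """Uncentered total sum of squares of the scaled data."""
        return float(np.sum(self.V * self.V))

    def mode_index(self, mode_id: str) -> int:
        return self.kept_mode_ids.index(mode_id)


def mean_scale(flux: FluxData, ems: EMSet, mode: str = "abs_mean"):
    """Scale each measured flux row of the data and the restricted modes.

    Returns ``(V_scaled, E_restricted_scaled, scale_factors, kept_flux_ids)``.
    ``abs_mean`` divides row ``j`` by ``mean(|V[j, :]|)``; ``signed_mean``
    by the arithmetic mean (which may be negative for a predominantly
    negative flux — dividing then also orients the flux positive);
    ``none`` leaves rows untouched.  Rows whose factor magnitude falls
    below 1e-12 carry no usable signal and are dropped with a warning.
    """
    if mode not in ("abs_mean", "signed_mean", "none"):
        raise ValidationError(f"unknown scaling mode {mode!r}")
    V = flux.values
    E = ems.restrict(flux.flux_ids)
    kept_rows, factors = [], {}
    for j, fid in enumerate(flux.flux_ids):
        if mode == "abs_mean":
            f = float(np.mean(np.abs(V[j])))
        elif mode == "signed_mean":
            f = float(np.mean(V[j]))
        else:
            f = 1.0
        if abs(f) < 1e-12:
            logger.warning(
                "flux %r dropped: %s scale factor %.3g is numerically zero", fid, mode, f
            )
            continue
        kept_rows.append(j)
        factors[fid] = f
    if not kept_rows:
        raise ValidationError("all measured fluxes dropped by scaling")
    rows = np.array(kept_rows, dtype=int)
    fvec = np.array([factors[flux.flux_ids[j]] for j in kept_rows])[:, None]
    return V[rows] / fvec, E[rows] / fvec, factors, tuple(flux.flux_ids[j] for j in kept_rows)


def filter_by_direction(
    E_restricted: np.ndarray,
    V_scaled: np.ndarray,
    mode_ids,
    tol: float = 1e-9,
    mode: str = "global",
    flux_ids=None,
):
    """Remove modes whose entries oppose a consistently signed flux.

    For each measured flux whose nonzero values share one sign across all
    experiments, a mode with a strictly opposite-signed entry for that
    flux violates the non-cancellation principle and is removed.  Fluxes
    with mixed signs across experiments impose no constraint (a warning
    is logged, since a sign inconsistency in the data should be resolved
    upstream rather than silently corrected here).

    Returns ``(E_kept, kept_ids, removed_ids)``.
    """
    mode_ids = tuple(mode_ids)
    if mode == "off":
        return E_restricted, mode_ids, ()
    if mode != "global":
        raise ValidationError(f"unknown direction filter mode {mode!r}")
    n_mes, m = E_restricted.shape
    scale = np.max(np.abs(V_scaled)) or 1.0
    escale = np.max(np.abs(E_restricted), axis=0)
    escale[escale == 0] = 1.0
    remove = np.zeros(m, dtype=bool)
    for j in range(n_mes):
        row = V_scaled[j]
        nz = row[np.abs(row) > tol * scale]
        if nz.size == 0:
            continue
        signs = np.unique(np.sign(nz))
        if signs.size > 1:
            fid = flux_ids[j] if flux_ids is not None else f"row {j}"
            logger.warning(
                "flux %s has mixed signs across experiments; no direction constraint applied",
                fid,
            )
            continue
        s = signs[0]
        opposing = (np.sign(E_restricted[j]) == -s) & (np.abs(E_restricted[j]) > tol * escale)
        newly = opposing & ~remove
        if np.any(newly):
            fid = flux_ids[j] if flux_ids is not None else f"row {j}"
            logger.info(
                "direction filter on flux %s removes mode(s): %s",
                fid,
                ", ".join(mode_ids[i] for i in np.flatnonzero(newly)),
            )
        remove |= opposing
    keep = ~remove
    kept_ids = tuple(mode_ids[i] for i in np.flatnonzero(keep))
    removed_ids = tuple(mode_ids[i] for i in np.flatnonzero(remove))
    return E_restricted[:, keep], kept_ids, removed_ids


def detect_ambiguous(E_restricted: np.ndarray, mode_ids, tol: float = 1e-9):
    """Group indistinguishable measured restrictions; keep one per group.

    A mode whose measured restriction has negligible norm (2-norm below
    ``tol`` times the largest column norm) is unidentifiable and removed
    outright.  Remaining columns are grouped when their unit-normalized
    restrictions are positively proportional (cosine similarity at least
    ``1 - tol``); opposite-sign proportional columns behave differently
    under nonnegative weights and are *not* grouped.  The representative
    kept for each group is the lexicographically lowest mode id.

    Returns ``(E_kept, kept_ids, report, removed_zero_ids)``.
    """
    mode_ids = tuple(mode_ids)
    m = E_restricted.shape[1]
    norms = np.linalg.norm(E_restricted, axis=0)
    max_norm = norms.max() if m else 0.0
    zero = norms < tol * max_norm if max_norm > 0 else np.ones(m, dtype=bool)
    removed_zero = tuple(mode_ids[i] for i in np.flatnonzero(zero))
    live = np.flatnonzero(~zero)

    # union-find over positively proportional columns
    parent = {int(i): int(i) for i in live}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if live.size:
        U = E_restricted[:, live] / norms[live]
        C = U.T @ U
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                if C[a, b] >= 1.0 - tol:
                    ra, rb = find(int(live[a])), find(int(live[b]))
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[int, list[int]] = {}
    for i in live:
        clusters.setdefault(find(int(i)), []).append(int(i))

    groups, reps, kept = [], [], []
    for members in clusters.values():
        ids = sorted((mode_ids[i] for i in members))
        rep = ids[0]
        rep_idx = next(i for i in members if mode_ids[i] == rep)
        kept.append(rep_idx)
        if len(members) >= 2:
            groups.append(tuple(ids))
            reps.append(rep)
    kept.sort()  # preserve input column order of representatives
    report = AmbiguityReport(tuple(sorted(groups)), tuple(sorted(reps)))
    kept_ids = tuple(mode_ids[i] for i in kept)
    return E_restricted[:, kept], kept_ids, report, removed_zero


def build_problem(flux: FluxData, ems: EMSet, config: PEMAConfig | None = None) -> ScaledProblem:
    """Run the full preprocessing pipeline and return a :class:`ScaledProblem`.

    Pipeline: restrict the mode matrix to measured rows -> mean-scale
    -> direction-filter -> ambiguity-group -> unit-normalize surviving
    columns, recording the pre-normalization column norms.
    """
    config = config or PEMAConfig()
    V, E, factors, kept_flux = mean_scale(flux, ems, config.scaling_mode)
    dropped_flux = tuple(f for f in flux.flux_ids if f not in kept_flux)
    E, ids, removed_dir = filter_by_direction(
        E, V, ems.mode_ids, config.direction_tol, config.direction_filter_mode, kept_flux
    )
    E, ids, report, removed_zero = detect_ambiguous(E, ids, config.ambiguity_tol)
    if E.shape[1] == 0:
        raise ValidationError("no feasible EM candidates after preprocessing")
    norms = np.linalg.norm(E, axis=0)
    return ScaledProblem(
        V=V,
        E_norm=E / norms,
        column_norms=norms,
        scale_factors=factors,
        flux_ids=kept_flux,
        experiment_ids=flux.experiment_ids,
        kept_mode_ids=ids,
        ambiguity=report,
        removed_by_direction=removed_dir,
        removed_zero_measured=removed_zero,
        dropped_flux_ids=dropped_flux,
    )
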