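"""Domain containers and file I/O for flux-mode analysis.

The central objects mirror the steady-state flux algebra: a metabolic
network with stoichiometric matrix ``S`` (balanced metabolites x
reactions) admits flux distributions ``v`` with ``S @ v = 0``, and every
such distribution is a nonnegative combination ``V = E @ P`` of the
network's elementary flux modes (the columns of ``E``).  :class:`EMSet`
holds ``E``, :class:`FluxData` holds the measured block of ``V``, and
:class:`PEMAConfig` collects the knobs of the decomposition.

File orientation is fixed throughout: rows are reactions/fluxes, columns
are modes/experiments.  Matching between flux data and mode matrices is
always by identifier, never by position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkSpec",
    "EMSet",
    "FluxData",
    "PEMAConfig",
    "ValidationError",
    "read_flux_table",
    "write_flux_table",
    "read_em_matrix",
    "write_em_matrix",
    "write_result",
    "read_result",
]


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dupes.append(i)
    if dupes:
        raise ValidationError(f"duplicate {what} id(s): {', '.join(dupes)}")
    return ids


@dataclass(frozen=True)
class NetworkSpec:
    """A stoichiometric network: balanced metabolites x reactions.

    ``stoichiometry[c, r]`` is the coefficient of metabolite ``c`` in
    reaction ``r`` (products positive, substrates negative).
    ``reversible[r]`` marks reactions allowed to carry negative flux.
    """

    stoichiometry: np.ndarray
    reversible: np.ndarray
    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]

    def __post_init__(self):
        S = np.asarray(self.stoichiometry, dtype=float)
        rev = np.asarray(self.reversible, dtype=bool)
        object.__setattr__(self, "stoichiometry", S)
        object.__setattr__(self, "reversible", rev)
        object.__setattr__(self, "reaction_ids", _check_unique(self.reaction_ids, "reaction"))
        object.__setattr__(self, "metabolite_ids", _check_unique(self.metabolite_ids, "metabolite"))
        if S.ndim != 2:
            raise ValidationError("stoichiometry must be a 2-D matrix")
        if S.shape[1] != len(self.reaction_ids):
            raise ValidationError(
                f"stoichiometry has {S.shape[1]} columns but {len(self.reaction_ids)} reaction ids"
            )
        if S.shape[0] != len(self.metabolite_ids):
            raise ValidationError(
                f"stoichiometry has {S.shape[0]} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        if rev.shape != (len(self.reaction_ids),):
            raise ValidationError("reversible flags must align with reaction ids")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)


@dataclass(frozen=True)
class EMSet:
    """A candidate matrix of elementary flux modes, reactions x modes.

    Each column is one mode ``e_i``; columns are defined only up to a
    positive scale.  When a :class:`NetworkSpec` is supplied, columns are
    checked for sign consistency: an irreversible reaction's entry may
    not be negative.
    """

    modes: np.ndarray
    reaction_ids: tuple[str, ...]
    mode_ids: tuple[str, ...]

    def __post_init__(self):
        E = np.asarray(self.modes, dtype=float)
        object.__setattr__(self, "modes", E)
        object.__setattr__(self, "reaction_ids", _check_unique(self.reaction_ids, "reaction"))
        object.__setattr__(self, "mode_ids", _check_unique(self.mode_ids, "mode"))
        if E.ndim != 2:
            raise ValidationError("mode matrix must be 2-D")
        if E.shape != (len(self.reaction_ids), len(self.mode_ids)):
            raise ValidationError(
                f"mode matrix shape {E.shape} does not match "
                f"({len(self.reaction_ids)} reactions, {len(self.mode_ids)} modes)"
            )
        if not np.all(np.isfinite(E)):
            raise ValidationError("mode matrix contains non-finite values")
        zero = np.flatnonzero(np.all(E == 0.0, axis=0))
        if zero.size:
            bad = ", ".join(self.mode_ids[i] for i in zero)
            raise ValidationError(f"all-zero mode column(s): {bad}")

    @property
    def m(self) -> int:
        """Number of candidate modes."""
        return self.modes.shape[1]

    @property
    def n_reactions(self) -> int:
        return self.modes.shape[0]

    def check_against_network(self, network: NetworkSpec, tol: float = 1e-9) -> None:
        """Verify sign consistency of irreversible reactions against *network*."""
        idx = {r: i for i, r in enumerate(network.reaction_ids)}
        for j, rid in enumerate(self.reaction_ids):
            if rid not in idx:
                raise ValidationError(f"reaction id {rid!r} not in network")
            if not network.reversible[idx[rid]] and np.any(self.modes[j] < -tol):
                bad = self.mode_ids[int(np.argmin(self.modes[j]))]
                raise ValidationError(
                    f"mode {bad!r} carries negative flux through irreversible reaction {rid!r}"
                )

    def restrict(self, flux_ids: Sequence[str]) -> np.ndarray:
        """Rows of the mode matrix for the given flux ids, in that order."""
        idx = {r: i for i, r in enumerate(self.reaction_ids)}
        missing = [f for f in flux_ids if f not in idx]
        if missing:
            raise ValidationError(f"measured flux id(s) not in mode matrix: {', '.join(missing)}")
        return self.modes[[idx[f] for f in flux_ids], :]


@dataclass(frozen=True)
class FluxData:
    """Measured reaction fluxes: rows = fluxes, columns = experiments.

    Values are rates (e.g. mmol/gDW/h); each column is one experimental
    condition.
    """

    values: np.ndarray
    flux_ids: tuple[str, ...]
    experiment_ids: tuple[str, ...]

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "flux_ids", _check_unique(self.flux_ids, "flux"))
        object.__setattr__(self, "experiment_ids", _check_unique(self.experiment_ids, "experiment"))
        if V.ndim != 2:
            raise ValidationError("flux matrix must be 2-D")
        if V.shape != (len(self.flux_ids), len(self.experiment_ids)):
            raise ValidationError(
                f"flux matrix shape {V.shape} does not match "
                f"({len(self.flux_ids)} fluxes, {len(self.experiment_ids)} experiments)"
            )
        if V.shape[1] < 1:
            raise ValidationError("need at least one experiment")
        if not np.all(np.isfinite(V)):
            raise ValidationError("flux matrix contains NaN/Inf")
        if np.all(V == 0.0):
            raise ValidationError("flux matrix is identically zero")

    @property
    def n_d(self) -> int:
        """Number of experiments."""
        return self.values.shape[1]

    @property
    def n_mes(self) -> int:
        """Number of measured fluxes."""
        return self.values.shape[0]


@dataclass
class PEMAConfig:
    """Run configuration for the decomposition.

    Parameters
    ----------
    n_fac : int
        Number of modes (factors) to combine; analogous to the number of
        latent variables in PCA.
    tie_tol : float
        Variance-gain ties within this absolute tolerance are broken by
        lowest mode id.
    ambiguity_tol : float
        Two measured-flux restrictions are treated as indistinguishable
        when their cosine similarity is at least ``1 - ambiguity_tol``.
    direction_tol : float
        Relative magnitude below which entries are treated as zero by
        the direction filter.
    prune_tol : float
        Branch-and-bound subtrees are cut when their upper bound does not
        exceed the incumbent by more than this.
    direction_filter_mode : {"global", "off"}
    scaling_mode : {"abs_mean", "signed_mean", "none"}
    seed : int
    max_evals : int or None
        Optional cap on the number of complete combinations scored per
        factor count; when hit, the search returns the incumbent flagged
        as not proven optimal.
    """

    n_fac: int = 1
    tie_tol: float = 1e-12
    ambiguity_tol: float = 1e-9
    direction_tol: float = 1e-9
    prune_tol: float = 1e-12
    direction_filter_mode: str = "global"
    scaling_mode: str = "abs_mean"
    seed: int = 0
    max_evals: int | None = None

    def __post_init__(self):
        if int(self.n_fac) < 1:
            raise ValidationError("n_fac must be >= 1")
        self.n_fac = int(self.n_fac)
        for name in ("tie_tol", "ambiguity_tol", "direction_tol", "prune_tol"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.direction_filter_mode not in ("global", "off"):
            raise ValidationError("direction_filter_mode must be 'global' or 'off'")
        if self.scaling_mode not in ("abs_mean", "signed_mean", "none"):
            raise ValidationError("scaling_mode must be 'abs_mean', 'signed_mean' or 'none'")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SEPS = {"csv": ",", "tsv": "\t"}


def _read_matrix(path, dialect: str) -> pd.DataFrame:
    if dialect not in _SEPS:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ValidationError(
                f"non-numeric value at row {row!r}, column {col!r} in {path}"
            )
        df[col] = converted
    if df.isna().any().any():
        raise ValidationError(f"missing value(s) in {path}")
    return df


def read_flux_table(path, dialect: str = "csv") -> FluxData:
    """Read a measured-flux table (rows = flux ids, columns = experiment ids)."""
    df = _read_matrix(path, dialect)
    return FluxData(df.to_numpy(float), tuple(df.index), tuple(df.columns))


def write_flux_table(flux: FluxData, path, dialect: str = "csv") -> None:
    pd.DataFrame(flux.values, index=list(flux.flux_ids), columns=list(flux.experiment_ids)).to_csv(
        path, sep=_SEPS[dialect]
    )


def read_em_matrix(path, dialect: str = "csv") -> EMSet:
    """Read an elementary-mode matrix (rows = reaction ids, columns = mode ids)."""
    df = _read_matrix(path, dialect)
    return EMSet(df.to_numpy(float), tuple(df.index), tuple(df.columns))


def write_em_matrix(ems: EMSet, path, dialect: str = "csv") -> None:
    pd.DataFrame(ems.modes, index=list(ems.reaction_ids), columns=list(ems.mode_ids)).to_csv(
        path, sep=_SEPS[dialect]
    )


def write_result(result, stats, path, config: PEMAConfig | None = None, manifest: dict | None = None) -> None:
    """Serialize a decomposition result and its search statistics to JSON.

    Writes ``<path>`` (JSON) and ``<path>.txt`` (plain-text factor table:
    rows = factor count, columns = selected mode ids and explained
    variance).
    """
    path = Path(path)
    payload = result.to_dict()
    payload["stats"] = stats.to_dict() if stats is not None else None
    payload["config"] = config.to_dict() if config is not None else None
    payload["manifest"] = manifest or {}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
    path.with_suffix(path.suffix + ".txt").write_text(result.to_table(), encoding="utf-8")


def read_result(path) -> dict:
    """Read back a JSON result written by :func:`write_result`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
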