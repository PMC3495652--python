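"""Per-time-point linear flux systems: assembly, solving, partner fluxes.

Substituting slope estimates for the derivatives decouples the ODE system
into, at each measured time point, the linear system

    diag(V) * s(t_j) = N * v(t_j),

with V the compartment volumes, s the slope vector, N the stoichiometric
matrix and v the flux vector.  If enough fluxes are known independently
(from constraints, or inferred flux-vs-metabolite curves) the remaining
system is square or over-determined and solved exactly or by least squares.

Known fluxes enter as functions of concentration, not of time: an inferred
curve v_k = F_k(X) is evaluated at the measured metabolite values at t_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .pathway import PathwayTopology
from .timeseries import SlopeTable, TimeSeriesSet

__all__ = [
    "FluxProfiles",
    "FluxSystems",
    "DfeError",
    "assemble_flux_equations",
    "solve_flux_system",
    "compute_partner_flux",
    "integrate_flux",
]


class DfeError(ValueError):
    pass


@dataclass
class FluxProfiles:
    """Flux value per time point per flux, with provenance per flux.

    Provenance tags: ``solved`` (linear solve), ``inferred-curve`` (from a
    flux-metabolite look-up), ``derived-partner`` (back-calculated from one
    equation), ``constraint`` (fixed multiple of another flux), ``truth``
    (synthetic generator).
    """

    profiles: dict[str, pd.DataFrame]  # dataset -> (K x fluxes), time index
    residuals: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, dataset_id: str) -> pd.DataFrame:
        return self.profiles[dataset_id]

    def to_frame(self, dataset_id: str) -> pd.DataFrame:
        """Profile table with the residual norm as an extra column."""
        frame = self.profiles[dataset_id].copy()
        frame["residual"] = self.residuals[dataset_id]
        return frame


@dataclass
class FluxSystems:
    """Per-time-point systems A_j x = b_j for the unknown fluxes."""

    unknown_fluxes: list[str]
    equations_used: list[str]  # metabolites whose rows enter the solve
    A: dict[str, np.ndarray]   # dataset -> (K, n_eq, n_unknown)
    b: dict[str, np.ndarray]   # dataset -> (K, n_eq)
    time: dict[str, np.ndarray]
    known_values: dict[str, dict[str, np.ndarray]]  # dataset -> flux -> series

    @property
    def underdetermined(self) -> bool:
        n_eq = len(self.equations_used)
        return n_eq < len(self.unknown_fluxes)


def _evaluate_known(
    flux: str,
    known_value,
    topology: PathwayTopology,
    values: pd.DataFrame,
    allow_extrapolation: bool,
) -> np.ndarray:
    """Evaluate a known flux along a dataset.

    Accepts a FluxCurve-like object (callable on concentration, with an
    optional domain), a plain callable of the dependency values, or an
    explicit series.
    """
    K = len(values)
    if isinstance(known_value, (np.ndarray, list, tuple, pd.Series)):
        arr = np.asarray(known_value, dtype=float)
        if arr.shape != (K,):
            raise DfeError(
                f"explicit series for known flux {flux!r} has shape "
                f"{arr.shape}, expected ({K},)"
            )
        return arr
    deps = topology.dependencies.get(flux, ())
    missing = [d for d in deps if d not in values.columns]
    if missing:
        raise DfeError(f"known flux {flux!r} needs unmeasured metabolites {missing}")
    args = [values[d].to_numpy(dtype=float) for d in deps]
    domain = getattr(known_value, "domain", None)
    if domain is not None and len(deps) == 1:
        x = args[0]
        lo, hi = domain
        outside = (x < lo) | (x > hi)
        if outside.any() and not allow_extrapolation:
            j = int(np.argmax(outside))
            raise DfeError(
                f"known flux {flux!r} queried outside its domain "
                f"[{lo:.4g}, {hi:.4g}] at time index {j} (x={x[j]:.4g}); "
                "pass allow_extrapolation=True to extrapolate linearly"
            )
        return np.asarray(
            known_value(x, extrapolate=True) if outside.any() else known_value(x),
            dtype=float,
        )
    return np.asarray(known_value(*args), dtype=float)


def assemble_flux_equations(
    topology: PathwayTopology,
    ts: TimeSeriesSet,
    slopes: SlopeTable,
    known: Mapping[str, object] | None = None,
    allow_extrapolation: bool = False,
) -> FluxSystems:
    """Build the per-time-point linear systems in the unknown fluxes.

    Constraints are eliminated first.  Rows for unmeasured metabolites are
    dropped from the solve (they can be reconstructed afterwards by
    integrating the solved fluxes).  Contributions of known fluxes move to
    the right-hand side: b_j = diag(V)*s(t_j) - N_known * v_known(t_j).
    """
    known = dict(known or {})
    red = topology.reduce_constraints()
    for f in known:
        if f not in red.flux_names:
            raise DfeError(f"known flux {f!r} not among reduced fluxes")
    unknown = [f for f in red.flux_names if f not in known]
    rows = [i for i, m in enumerate(red.metabolite_names) if m in red.measured]
    used_mets = [red.metabolite_names[i] for i in rows]
    N = red.N
    A_sub = N[np.ix_(rows, [red.flux_index(f) for f in unknown])]
    vol = red.volume_vector[rows]

    A, b, times, known_vals = {}, {}, {}, {}
    for ds in ts:
        S = slopes[ds.dataset_id]
        missing = [m for m in used_mets if m not in S.columns]
        if missing:
            raise DfeError(f"no slopes for measured metabolites {missing}")
        rhs = (S[used_mets].to_numpy(dtype=float) * vol[None, :])
        kv = {}
        for f, obj in known.items():
            series = _evaluate_known(f, obj, red, ds.values, allow_extrapolation)
            kv[f] = series
            coefs = N[rows, red.flux_index(f)]
            rhs = rhs - np.outer(series, coefs)
        K = len(ds.time)
        A[ds.dataset_id] = np.broadcast_to(A_sub, (K, *A_sub.shape)).copy()
        b[ds.dataset_id] = rhs
        times[ds.dataset_id] = ds.time
        known_vals[ds.dataset_id] = kv
    return FluxSystems(
        unknown_fluxes=unknown,
        equations_used=used_mets,
        A=A,
        b=b,
        time=times,
        known_values=known_vals,
    )


def solve_flux_system(systems: FluxSystems, rcond: float = 1e-10) -> FluxProfiles:
    """Solve every per-time-point system.

    Square systems are solved exactly; over-determined ones by unweighted
    least squares (the per-time residual norm is recorded).  A rank-deficient
    system raises, naming the first offending time point - the caller must
    supply more known fluxes.
    """
    n_unknown = len(systems.unknown_fluxes)
    profiles, residuals = {}, {}
    for ds_id, A in systems.A.items():
        b = systems.b[ds_id]
        K, n_eq, _ = A.shape
        if n_eq < n_unknown:
            raise DfeError(
                f"dataset {ds_id!r}: {n_eq} equations cannot determine "
                f"{n_unknown} fluxes (deficiency {n_unknown - n_eq}); "
                "supply more known fluxes"
            )
        V = np.empty((K, n_unknown))
        res = np.empty(K)
        for j in range(K):
            rank = np.linalg.matrix_rank(A[j], tol=None)
            if rank < n_unknown:
                raise DfeError(
                    f"dataset {ds_id!r}: rank-deficient system at time index "
                    f"{j} (t={systems.time[ds_id][j]:.4g}), rank {rank} < "
                    f"{n_unknown}"
                )
            sol, _, _, _ = np.linalg.lstsq(A[j], b[j], rcond=rcond)
            V[j] = sol
            res[j] = float(np.linalg.norm(A[j] @ sol - b[j], ord=np.inf))
        frame = pd.DataFrame(
            V,
            columns=systems.unknown_fluxes,
            index=pd.Index(systems.time[ds_id], name="time"),
        )
        for f, series in systems.known_values[ds_id].items():
            frame[f] = series
        profiles[ds_id] = frame
        residuals[ds_id] = res
    provenance = {f: "solved" for f in systems.unknown_fluxes}
    for ds_vals in systems.known_values.values():
        for f in ds_vals:
            provenance.setdefault(f, "inferred-curve")
    return FluxProfiles(profiles=profiles, residuals=residuals, provenance=provenance)


def compute_partner_flux(
    topology: PathwayTopology,
    metabolite: str,
    ts: TimeSeriesSet,
    slopes: SlopeTable,
    known: Mapping[str, object],
    allow_extrapolation: bool = False,
) -> dict[str, np.ndarray]:
    """Back-calculate the single unknown flux in one mass-balance equation.

    With all but one flux of the chosen equation known at each time point,

        v_f(t_j) = (V_i * S_i(t_j) - sum of known signed contributions)
                   / c_f,

    where c_f is the stoichiometric coefficient of the remaining flux.
    Returns one series per dataset.
    """
    red = topology.reduce_constraints()
    i = red.metabolite_index(metabolite)
    terms = red.equation_fluxes(metabolite)
    unknown_terms = [(f, c) for f, c in terms if f not in known]
    if len(unknown_terms) != 1:
        raise DfeError(
            f"equation of {metabolite!r} has {len(unknown_terms)} unknown "
            f"fluxes ({[f for f, _ in unknown_terms]}); need exactly one"
        )
    target, coef = unknown_terms[0]
    vol = red.volume_of(metabolite)
    out = {}
    for ds in ts:
        S = slopes[ds.dataset_id][metabolite].to_numpy(dtype=float)
        rhs = vol * S
        for f, c in terms:
            if f == target:
                continue
            series = _evaluate_known(f, known[f], red, ds.values, allow_extrapolation)
            rhs = rhs - float(c) * series
        out[ds.dataset_id] = rhs / float(coef)
    return out


def integrate_flux(
    time: np.ndarray, series: np.ndarray, initial: float = 0.0, volume: float = 1.0
) -> np.ndarray:
    """Point-by-point (trapezoid) integration of a flux into a pool.

    Reconstructs an unmeasured metabolite from its net production flux:
    X(t_j) = X(t_0) + (1/V) * cumulative integral of the flux.  Uses the
    trapezoid rule on the measurement grid - no model assumption beyond the
    data resolution.
    """
    from scipy.integrate import cumulative_trapezoid

    series = np.asarray(series, dtype=float)
    cum = cumulative_trapezoid(series, np.asarray(time, dtype=float), initial=0.0)
    return initial + cum / volume
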