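"""Pathway topology: stoichiometry, flux dependencies, volumes, constraints.

A metabolic pathway is described by a system of mass-balance ODEs

    V_i * dX_i/dt = sum_j  c_ij * v_j,

where ``X_i`` are metabolite concentrations, ``v_j`` reaction fluxes,
``c_ij`` signed stoichiometric coefficients and ``V_i`` an optional
compartment volume attached to metabolite ``i`` (so that extracellular and
intracellular pools can be mixed in one system).  The coefficients are kept
as exact :class:`fractions.Fraction` values because they are small integers
or simple ratios in practice; volumes are floats.

Linear flux constraints of the form ``target = coefficient * source`` (for
example a fixed 5 % diversion into a side pathway) are handled by variable
elimination: the target column is folded into the source column, which keeps
the per-time-point linear systems square or over-determined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "FluxConstraint",
    "PathwayTopology",
    "RankReport",
    "TopologyError",
    "load_topology",
    "check_flux_rank",
]

TOPOLOGY_FORMAT = "dfe-topology/1"


class TopologyError(ValueError):
    """Raised when a topology specification fails validation."""


@dataclass(frozen=True)
class FluxConstraint:
    """Linear constraint ``target = coefficient * source``."""

    target: str
    source: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.target == self.source:
            raise TopologyError(
                f"constraint target and source coincide: {self.target!r}"
            )
        if not np.isfinite(self.coefficient) or self.coefficient == 0:
            raise TopologyError(
                f"constraint coefficient for {self.target!r} must be finite "
                f"and nonzero, got {self.coefficient!r}"
            )


@dataclass(frozen=True)
class RankReport:
    """Result of a solvability check on the decoupled flux system."""

    n_equations: int
    n_unknown_fluxes: int
    rank: int
    deficiency: int
    underdetermined: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        state = "underdetermined" if self.underdetermined else "solvable"
        return (
            f"{self.n_equations} equations, {self.n_unknown_fluxes} unknown "
            f"fluxes, rank {self.rank}, deficiency {self.deficiency} "
            f"({state})"
        )


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**6)
    raise TopologyError(f"cannot interpret stoichiometric coefficient {value!r}")


@dataclass
class PathwayTopology:
    """Validated pathway topology.

    Parameters mirror the ``dfe-topology/1`` config schema; see
    :func:`load_topology`.  ``stoichiometry[i][j]`` is the exact coefficient
    of flux ``j`` in the mass balance of metabolite ``i``.
    """

    metabolite_names: list[str]
    flux_names: list[str]
    stoichiometry: list[list[Fraction]]
    dependencies: dict[str, tuple[str, ...]]
    volumes: dict[str, float] = field(default_factory=dict)
    constraints: list[FluxConstraint] = field(default_factory=list)
    measured: frozenset[str] = frozenset()
    constant_inputs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not self.flux_names:
            raise TopologyError("topology declares no fluxes")
        if not self.metabolite_names:
            raise TopologyError("topology declares no metabolites")
        if len(set(self.metabolite_names)) != len(self.metabolite_names):
            raise TopologyError("duplicate metabolite names")
        if len(set(self.flux_names)) != len(self.flux_names):
            raise TopologyError("duplicate flux names")
        n, m = len(self.metabolite_names), len(self.flux_names)
        if len(self.stoichiometry) != n or any(
            len(row) != m for row in self.stoichiometry
        ):
            raise TopologyError(
                f"stoichiometry must be {n} x {m}; got "
                f"{len(self.stoichiometry)} rows"
            )
        self.stoichiometry = [
            [_as_fraction(c) for c in row] for row in self.stoichiometry
        ]
        mets = set(self.metabolite_names)
        for flux in self.flux_names:
            deps = self.dependencies.get(flux, ())
            if not deps and flux not in self.constant_inputs:
                raise TopologyError(
                    f"flux {flux!r} has no dependencies and is not flagged "
                    "as a constant input"
                )
            for d in deps:
                if d not in mets:
                    raise TopologyError(
                        f"flux {flux!r} depends on undeclared metabolite {d!r}"
                    )
        for met, vol in self.volumes.items():
            if met not in mets:
                raise TopologyError(f"volume given for undeclared metabolite {met!r}")
            if not (vol > 0):
                raise TopologyError(f"volume of {met!r} must be positive, got {vol}")
        for met in self.measured:
            if met not in mets:
                raise TopologyError(f"measured flag on undeclared metabolite {met!r}")
        fluxes = set(self.flux_names)
        targets = set()
        for con in self.constraints:
            if con.target not in fluxes or con.source not in fluxes:
                raise TopologyError(
                    f"constraint references undeclared flux: {con.target!r} "
                    f"= {con.coefficient} * {con.source!r}"
                )
            if con.target in targets:
                raise TopologyError(f"flux {con.target!r} constrained twice")
            targets.add(con.target)
        for con in self.constraints:
            if con.source in targets:
                raise TopologyError(
                    "chained constraints are not supported "
                    f"({con.target!r} -> {con.source!r})"
                )

    # -- convenience ----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_names)

    @property
    def n_fluxes(self) -> int:
        return len(self.flux_names)

    @property
    def N(self) -> np.ndarray:
        """Stoichiometric matrix as floats (n metabolites x m fluxes)."""
        return np.array(
            [[float(c) for c in row] for row in self.stoichiometry], dtype=float
        )

    def volume_of(self, metabolite: str) -> float:
        return float(self.volumes.get(metabolite, 1.0))

    @property
    def volume_vector(self) -> np.ndarray:
        return np.array([self.volume_of(m) for m in self.metabolite_names])

    def metabolite_index(self, name: str) -> int:
        try:
            return self.metabolite_names.index(name)
        except ValueError:
            raise TopologyError(f"unknown metabolite {name!r}") from None

    def flux_index(self, name: str) -> int:
        try:
            return self.flux_names.index(name)
        except ValueError:
            raise TopologyError(f"unknown flux {name!r}") from None

    def equation_fluxes(self, metabolite: str) -> list[tuple[str, Fraction]]:
        """Fluxes appearing in a metabolite's mass balance with coefficients."""
        i = self.metabolite_index(metabolite)
        return [
            (flux, c)
            for flux, c in zip(self.flux_names, self.stoichiometry[i])
            if c != 0
        ]

    def constrained_fluxes(self) -> dict[str, FluxConstraint]:
        return {c.target: c for c in self.constraints}

    def reduce_constraints(self) -> "PathwayTopology":
        """Eliminate constrained fluxes by folding their columns.

        For each constraint ``target = coef * source`` the target column is
        added ``coef`` times to the source column and removed, reducing the
        number of unknowns by one per constraint.
        """
        if not self.constraints:
            return self
        drop = self.constrained_fluxes()
        keep = [f for f in self.flux_names if f not in drop]
        cols = {f: j for j, f in enumerate(self.flux_names)}
        new_rows: list[list[Fraction]] = []
        for row in self.stoichiometry:
            new_row = []
            for f in keep:
                c = row[cols[f]]
                for con in self.constraints:
                    if con.source == f:
                        c = c + _as_fraction(con.coefficient) * row[cols[con.target]]
                new_row.append(c)
            new_rows.append(new_row)
        deps = {f: self.dependencies.get(f, ()) for f in keep}
        return PathwayTopology(
            metabolite_names=list(self.metabolite_names),
            flux_names=keep,
            stoichiometry=new_rows,
            dependencies=deps,
            volumes=dict(self.volumes),
            constraints=[],
            measured=self.measured,
            constant_inputs=frozenset(f for f in self.constant_inputs if f in deps),
        )


def load_topology(source) -> PathwayTopology:
    """Load and validate a ``dfe-topology/1`` specification.

    ``source`` may be a mapping, a YAML string, or a path to a YAML file.
    """
    if isinstance(source, Mapping):
        spec = dict(source)
    else:
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            raise TopologyError(f"cannot load topology from {source!r}")
        spec = yaml.safe_load(text)
        if not isinstance(spec, Mapping):
            raise TopologyError("topology document must be a mapping")

    fmt = spec.get("format", TOPOLOGY_FORMAT)
    if fmt != TOPOLOGY_FORMAT:
        raise TopologyError(f"unsupported topology format {fmt!r}")

    met_entries = spec.get("metabolites") or []
    flux_entries = spec.get("fluxes") or []
    if not flux_entries:
        raise TopologyError("topology declares no fluxes")

    metabolite_names, volumes, measured = [], {}, set()
    for entry in met_entries:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry["name"]
        metabolite_names.append(name)
        if "volume" in entry:
            volumes[name] = float(entry["volume"])
        if entry.get("measured", True):
            measured.add(name)

    flux_names, dependencies, constant_inputs = [], {}, set()
    for entry in flux_entries:
        if isinstance(entry, str):
            entry = {"name": entry}
        name = entry["name"]
        flux_names.append(name)
        deps = tuple(entry.get("depends_on", ()) or ())
        dependencies[name] = deps
        if entry.get("constant_input", False) or not deps:
            constant_inputs.add(name)

    equations = spec.get("equations") or {}
    col = {f: j for j, f in enumerate(flux_names)}
    stoich = [[Fraction(0)] * len(flux_names) for _ in metabolite_names]
    for i, met in enumerate(metabolite_names):
        for term in equations.get(met, ()) or ():
            flux = term["flux"]
            if flux not in col:
                raise TopologyError(
                    f"equation for {met!r} references undeclared flux {flux!r}"
                )
            stoich[i][col[flux]] += _as_fraction(term.get("coeff", 1))

    constraints = [
        FluxConstraint(
            target=c["target"], source=c["source"], coefficient=float(c["coefficient"])
        )
        for c in spec.get("constraints") or ()
    ]

    return PathwayTopology(
        metabolite_names=metabolite_names,
        flux_names=flux_names,
        stoichiometry=stoich,
        dependencies=dependencies,
        volumes=volumes,
        constraints=constraints,
        measured=frozenset(measured),
        constant_inputs=frozenset(constant_inputs),
    )


def check_flux_rank(
    topology: PathwayTopology,
    measured_only: bool = True,
    known: Iterable[str] = (),
) -> RankReport:
    """Check whether the decoupled per-time-point flux system is solvable.

    Constraints are substituted first (each removes one unknown).  Fluxes in
    ``known`` (already determined independently) are removed from the
    unknowns.  When ``measured_only`` is set, only mass-balance rows of
    measured metabolites count as usable equations.

    The deficiency is ``n_unknowns - rank``; a positive deficiency means the
    per-time-point solution space is infinite and more fluxes must be
    supplied before solving.
    """
    red = topology.reduce_constraints()
    known = set(known)
    unknown = [f for f in red.flux_names if f not in known]
    if measured_only:
        rows = [
            i for i, met in enumerate(red.metabolite_names) if met in red.measured
        ]
    else:
        rows = list(range(red.n_metabolites))
    N = red.N
    if unknown:
        sub = N[np.ix_(rows, [red.flux_index(f) for f in unknown])]
    else:
        sub = np.zeros((len(rows), 0))
    rank = int(np.linalg.matrix_rank(sub)) if sub.size else 0
    deficiency = len(unknown) - rank
    return RankReport(
        n_equations=len(rows),
        n_unknown_fluxes=len(unknown),
        rank=rank,
        deficiency=deficiency,
        underdetermined=deficiency > 0,
    )
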