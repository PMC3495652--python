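"""Synthetic benchmark systems with known kinetics and exact flux truth.

Three pathway systems of increasing complexity, each exposing both the
simulated concentration data and the underlying true fluxes so every stage
of the flux-estimation pipeline can be validated without external data:

* a three-metabolite linear chain with end-product feedback inhibition
  (mixed power-law and Hill kinetics) whose oscillating trajectories provide
  many repeated concentration values;
* a four-metabolite branched pathway with feedforward activation and
  feedback inhibition (Michaelis-Menten, Hill, hyperbolic-modifier and
  Hill-with-modifier kinetics, plus a constant external input), sampled from
  several initial conditions because single trajectories rarely revisit a
  concentration;
* a trehalose-cycle-like two-compartment system (glycolysis feeding
  trehalose synthesis/degradation, a fixed 5 % diversion into the pentose
  phosphate pathway, leakage to other pathways) that mimics the missing-data
  pattern of in vivo NMR studies: intracellular glucose is merged into the
  extracellular pool and two sink variables are withheld from the reported
  data.  Its rate laws are synthetic stand-ins (no published values exist);
  parameters were chosen once for qualitatively realistic behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dfe import FluxProfiles
from .pathway import FluxConstraint, PathwayTopology, load_topology
from .timeseries import TimeSeries, TimeSeriesSet

__all__ = [
    "SyntheticSystem",
    "linear_feedback_system",
    "branched_system",
    "trehalose_like_system",
    "simulate_system",
    "simulate_linear_feedback",
    "simulate_branched",
    "simulate_trehalose_like",
    "add_noise",
    "DEFAULT_BRANCHED_ICS",
    "CARBON_WEIGHTS",
]

_RTOL = 1e-9
_ATOL = 1e-11


@dataclass
class SyntheticSystem:
    """A pathway topology plus true rate laws and default study conditions."""

    name: str
    topology: PathwayTopology
    rate_laws: dict[str, Callable[[Mapping[str, float]], float]]
    default_ics: tuple[float, ...]
    default_grid: np.ndarray
    guards: dict[str, float] = field(default_factory=dict)  # met -> lower bound

    def flux_function(self, flux: str) -> Callable:
        """True rate law of one flux as a function of a state mapping."""
        return self.rate_laws[flux]

    def true_fluxes(self, state: Mapping[str, float]) -> np.ndarray:
        return np.array([self.rate_laws[f](state) for f in self.topology.flux_names])

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        state = dict(zip(self.topology.metabolite_names, x))
        v = self.true_fluxes(state)
        vol = self.topology.volume_vector
        return (self.topology.N @ v) / vol


def simulate_system(
    system: SyntheticSystem,
    ics: Sequence[float] | None = None,
    grid: np.ndarray | None = None,
    dataset_id: str = "dataset-1",
) -> tuple[TimeSeriesSet, FluxProfiles]:
    """Integrate a system and return concentrations plus true flux profiles.

    Uses a stiff-capable integrator (LSODA) at tight tolerance so the
    generated trajectories satisfy the flux balance essentially exactly.
    A zero-length grid returns the initial conditions only.
    """
    x0 = np.asarray(ics if ics is not None else system.default_ics, dtype=float)
    t = np.asarray(grid if grid is not None else system.default_grid, dtype=float)
    names = system.topology.metabolite_names
    if t.size <= 1:
        t = np.atleast_1d(t) if t.size else np.array([0.0])
        X = x0[None, :].repeat(len(t), axis=0)
    else:
        t0 = min(0.0, t[0])
        sol = solve_ivp(
            system.rhs,
            (t0, t[-1]),
            x0,
            t_eval=t,
            method="LSODA",
            rtol=_RTOL,
            atol=_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"integration of {system.name!r} failed: {sol.message}")
        X = sol.y.T
    for met, lo in system.guards.items():
        j = names.index(met)
        if np.any(X[:, j] <= lo):
            raise RuntimeError(
                f"{system.name!r}: {met} fell to {X[:, j].min():.3g} "
                f"(<= guard {lo}); rate laws diverge there"
            )
    ts = TimeSeriesSet(
        [TimeSeries(dataset_id, t.copy(), pd.DataFrame(X, columns=names))]
    )
    V = np.array(
        [system.true_fluxes(dict(zip(names, row))) for row in X]
    )
    profiles = FluxProfiles(
        profiles={
            dataset_id: pd.DataFrame(
                V, columns=system.topology.flux_names, index=pd.Index(t, name="time")
            )
        },
        residuals={dataset_id: np.zeros(len(t))},
        provenance={f: "truth" for f in system.topology.flux_names},
    )
    return ts, profiles


# ---------------------------------------------------------------------------
# linear chain with feedback inhibition
# ---------------------------------------------------------------------------

_LINEAR_SPEC = {
    "format": "dfe-topology/1",
    "metabolites": ["X1", "X2", "X3"],
    "fluxes": [
        {"name": "v1", "depends_on": ["X3"]},
        {"name": "v2", "depends_on": ["X1"]},
        {"name": "v3", "depends_on": ["X2"]},
        {"name": "v4", "depends_on": ["X3"]},
    ],
    "equations": {
        "X1": [{"flux": "v1", "coeff": 1}, {"flux": "v2", "coeff": -1}],
        "X2": [{"flux": "v2", "coeff": 1}, {"flux": "v3", "coeff": -1}],
        "X3": [{"flux": "v3", "coeff": 1}, {"flux": "v4", "coeff": -1}],
    },
}

#: Hill parameters of the true v3 in the linear-feedback system.
LINEAR_V3_PARAMS = {"v_max": 5.0, "k_m": 2.0, "h": 3.0}


def linear_feedback_system() -> SyntheticSystem:
    """X1 -> X2 -> X3 with the input flux inhibited by X3.

    True kinetics: v1 = 1.5*X3^-6 (power-law feedback inhibition),
    v2 = 2.4*X1^0.8, v3 = 5*X2^3/(2^3 + X2^3) (Hill, V_max=5, K_M=2, h=3),
    v4 = 2*X3^0.75.  The strong feedback makes the trajectories oscillate,
    so single runs revisit concentration values many times.
    """
    laws = {
        "v1": lambda s: 1.5 * s["X3"] ** -6.0,
        "v2": lambda s: 2.4 * s["X1"] ** 0.8,
        "v3": lambda s: 5.0 * s["X2"] ** 3 / (8.0 + s["X2"] ** 3),
        "v4": lambda s: 2.0 * s["X3"] ** 0.75,
    }
    return SyntheticSystem(
        name="linear-feedback",
        topology=load_topology(_LINEAR_SPEC),
        rate_laws=laws,
        default_ics=(5.0, 0.1, 8.0),
        default_grid=0.2 + 0.2 * np.arange(50),
        guards={"X3": 0.0},
    )


def simulate_linear_feedback(
    ics: Sequence[float] = (5.0, 0.1, 8.0),
    n_points: int = 50,
    spacing: float = 0.2,
    t_start: float = 0.2,
) -> tuple[TimeSeriesSet, FluxProfiles]:
    """Default study conditions: 50 samples at spacing 0.2 from t = 0.2.

    Whether the sampling grid includes t = 0 is ambiguous for this kind of
    design; starting at ``t_start = 0.2`` covers every cited interior time
    point and is the package default, with ``t_start = 0`` available.
    """
    grid = t_start + spacing * np.arange(n_points)
    return simulate_system(linear_feedback_system(), ics=ics, grid=grid)


# ---------------------------------------------------------------------------
# branched pathway with feedforward activation and feedback inhibition
# ---------------------------------------------------------------------------

_BRANCHED_SPEC = {
    "format": "dfe-topology/1",
    "metabolites": [
        "X1",
        "X2",
        "X3",
        "X4",
        # X5 is the external input driving v1: constant, not a mass balance
        # of the modelled system, hence unmeasured with an empty equation.
        {"name": "X5", "measured": False},
    ],
    "fluxes": [
        {"name": "v1", "depends_on": ["X5"]},
        {"name": "v2", "depends_on": ["X1", "X3"]},
        {"name": "v3", "depends_on": ["X2"]},
        {"name": "v4", "depends_on": ["X3"]},
        {"name": "v5", "depends_on": ["X1", "X2"]},
        {"name": "v6", "depends_on": ["X4"]},
    ],
    "equations": {
        "X1": [{"flux": "v1", "coeff": 1}, {"flux": "v2", "coeff": -1}],
        "X2": [
            {"flux": "v2", "coeff": 1},
            {"flux": "v3", "coeff": -1},
            {"flux": "v5", "coeff": -1},
        ],
        "X3": [{"flux": "v3", "coeff": 1}, {"flux": "v4", "coeff": -1}],
        "X4": [{"flux": "v5", "coeff": 1}, {"flux": "v6", "coeff": -1}],
    },
}

#: Surrogate initial-condition sets (X1, X2, X3, X4) spanning X2 ~ 0.25-2.3.
#: Synthetic values chosen by this package, not taken from any publication.
DEFAULT_BRANCHED_ICS: tuple[tuple[float, float, float, float], ...] = (
    (0.5, 2.0, 1.0, 0.5),
    (2.0, 0.3, 0.2, 1.5),
    (1.0, 1.0, 1.0, 1.0),
    (0.2, 1.5, 2.0, 0.3),
    (1.5, 0.25, 0.5, 2.0),
    (0.8, 2.3, 1.5, 0.8),
)


def branched_system(input_level: float = 1.0) -> SyntheticSystem:
    """Branched pathway X1 -> X2 -> {X3, X4} with regulation.

    True kinetics (X5 is a declared constant external input feeding v1):

    * v1 = 16*X5/(1+X5) - Michaelis-Menten in the input;
    * v2 = 65*(X1/0.3)*(1+(0.04/2.5)*(X3/0.12)) /
      (1 + X3/0.12 + (X1/0.3)*(1 + X3/(2.5*0.12))) - irreversible general
      hyperbolic modifier kinetics, X3 acting as a (mostly inhibitory)
      modifier;
    * v3 = 5*X2^4/(5+X2^4) - Hill;
    * v4 = 8*X3/(1+X3) and v6 = 8*X4/(1+X4) - Michaelis-Menten;
    * v5 = 5.8*X2^1.13 / (X2^1.13 + (1+X1^1.3)/(1+6.3*X1^1.3)) -
      irreversible Hill function with X1 as activating modifier
      (the feedforward activation).
    """
    x5 = float(input_level)

    def v2(s):
        a = s["X1"] / 0.3
        b = s["X3"] / 0.12
        return 65.0 * a * (1 + (0.04 / 2.5) * b) / (1 + b + a * (1 + b / 2.5))

    def v5(s):
        num = s["X2"] ** 1.13
        mod = (1 + s["X1"] ** 1.3) / (1 + 6.3 * s["X1"] ** 1.3)
        return 5.8 * num / (num + mod)

    laws = {
        "v1": lambda s: 16.0 * s["X5"] / (1.0 + s["X5"]),
        "v2": v2,
        "v3": lambda s: 5.0 * s["X2"] ** 4 / (5.0 + s["X2"] ** 4),
        "v4": lambda s: 8.0 * s["X3"] / (1.0 + s["X3"]),
        "v5": v5,
        "v6": lambda s: 8.0 * s["X4"] / (1.0 + s["X4"]),
    }
    return SyntheticSystem(
        name="branched",
        topology=load_topology(_BRANCHED_SPEC),
        rate_laws=laws,
        default_ics=(*DEFAULT_BRANCHED_ICS[0], x5),
        # the pathway contracts to its steady state within ~3 time units and
        # the first conversion step is nearly instantaneous, so sampling is
        # dense over the initial burst and regular afterwards
        default_grid=np.concatenate(
            [np.arange(0.0, 0.1, 0.005), np.arange(0.1, 3.05, 0.05)]
        ),
    )


def simulate_branched(
    ics_list: Sequence[Sequence[float]] | None = None,
    grid: np.ndarray | None = None,
    input_level: float = 1.0,
) -> tuple[TimeSeriesSet, FluxProfiles]:
    """Simulate one dataset per initial-condition set.

    Single branched-pathway trajectories rarely revisit a concentration, so
    flux inference requires several datasets with different dynamics; the
    default design uses six surrogate initial-condition sets.
    """
    system = branched_system(input_level)
    if ics_list is None:
        ics_list = DEFAULT_BRANCHED_ICS
    datasets, profs, resid = [], {}, {}
    for i, ics in enumerate(ics_list, start=1):
        ics = tuple(ics)
        if len(ics) == 4:  # the external input level completes the state
            ics = (*ics, float(input_level))
        ts, fl = simulate_system(system, ics=ics, grid=grid, dataset_id=f"dataset-{i}")
        datasets.append(ts.datasets[0])
        profs.update(fl.profiles)
        resid.update(fl.residuals)
    return (
        TimeSeriesSet(datasets),
        FluxProfiles(
            profiles=profs,
            residuals=resid,
            provenance={f: "truth" for f in system.topology.flux_names},
        ),
    )


# ---------------------------------------------------------------------------
# trehalose-cycle-like two-compartment system
# ---------------------------------------------------------------------------

V_EXT = 0.05  # L, extracellular (bioreactor) volume
V_INT = 0.00717  # L, intracellular (cell population) volume

_TREHALOSE_SPEC = {
    "format": "dfe-topology/1",
    "metabolites": [
        {"name": "X1", "volume": V_EXT, "measured": True},   # extracellular glucose
        {"name": "X2", "volume": V_INT, "measured": True},   # intracellular glucose
        {"name": "X3", "volume": V_INT, "measured": True},   # glucose 6-phosphate
        {"name": "X4", "volume": V_INT, "measured": True},   # trehalose
        {"name": "X5", "volume": V_INT, "measured": True},   # fructose 1,6-bisphosphate
        {"name": "X6", "volume": V_EXT, "measured": True},   # end products
        {"name": "X7", "volume": V_INT, "measured": False},  # pentose phosphate sink
        {"name": "X8", "volume": V_INT, "measured": False},  # other-pathway sink
    ],
    "fluxes": [
        {"name": "v1", "depends_on": ["X1", "X3"]},  # glucose transport
        {"name": "v2", "depends_on": ["X2"]},        # hexokinase/glucokinase
        {"name": "v3", "depends_on": ["X3"]},        # G6P -> trehalose (aggregated)
        {"name": "v4", "depends_on": ["X4"]},        # trehalase
        {"name": "v5", "depends_on": ["X3"]},        # PGI + PFK
        {"name": "v6", "depends_on": ["X5"]},        # FBP -> end products (aggregated)
        {"name": "v7", "depends_on": ["X3"]},        # pentose phosphate diversion
        {"name": "v8", "depends_on": ["X5"]},        # leakage to other pathways
    ],
    "equations": {
        "X1": [{"flux": "v1", "coeff": -1}],
        "X2": [
            {"flux": "v1", "coeff": 1},
            {"flux": "v4", "coeff": 2},
            {"flux": "v2", "coeff": -1},
        ],
        "X3": [
            {"flux": "v2", "coeff": 1},
            {"flux": "v3", "coeff": -2},
            {"flux": "v5", "coeff": -1},
            {"flux": "v7", "coeff": -1},
        ],
        "X4": [{"flux": "v3", "coeff": 1}, {"flux": "v4", "coeff": -1}],
        "X5": [
            {"flux": "v5", "coeff": 1},
            {"flux": "v6", "coeff": -1},
            {"flux": "v8", "coeff": -1},
        ],
        "X6": [{"flux": "v6", "coeff": 2}],
        "X7": [{"flux": "v7", "coeff": 1}],
        "X8": [{"flux": "v8", "coeff": 1}],
    },
    "constraints": [{"target": "v7", "source": "v5", "coefficient": 0.05}],
}

#: Mass weights in 3-carbon units (hexoses = 2, trehalose = 4, triose
#: products = 1).  With these weights the stoichiometry conserves total
#: mass exactly.
CARBON_WEIGHTS = {
    "X1": 2.0,
    "X2": 2.0,
    "X3": 2.0,
    "X4": 4.0,
    "X5": 2.0,
    "X6": 1.0,
    "X7": 2.0,
    "X8": 2.0,
}

REPORTED_TREHALOSE_COLUMNS = ["X1", "X2", "X3", "X4", "X5", "X6"]


def trehalose_like_system() -> SyntheticSystem:
    """Glycolysis + trehalose cycle stand-in with two compartments.

    The rate laws below are synthetic stand-ins (Michaelis-Menten forms with
    product inhibition on transport); no published parameter set exists for
    this aggregated model.  They were chosen once so that, after a glucose
    pulse, G6P and FBP rise quickly, trehalose rises with a delay, and end
    products accumulate steadily.  The pentose phosphate flux is constrained
    to 5 % of the glycolytic flux (v7 = 0.05*v5).
    """
    laws = {
        "v1": lambda s: 0.40 * s["X1"] / (20.0 + s["X1"]) / (1.0 + (s["X3"] / 25.0) ** 2),
        "v2": lambda s: 0.55 * s["X2"] / (1.0 + s["X2"]),
        "v3": lambda s: 0.012 * s["X3"] ** 2 / (60.0 + s["X3"] ** 2),
        "v4": lambda s: 0.009 * s["X4"] / (4.0 + s["X4"]),
        "v5": lambda s: 0.28 * s["X3"] / (8.0 + s["X3"]),
        "v6": lambda s: 0.26 * s["X5"] / (6.0 + s["X5"]),
        "v8": lambda s: 0.018 * s["X5"] / (6.0 + s["X5"]),
    }
    laws["v7"] = lambda s: 0.05 * laws["v5"](s)
    return SyntheticSystem(
        name="trehalose-like",
        topology=load_topology(_TREHALOSE_SPEC),
        rate_laws=laws,
        default_ics=(65.0, 0.05, 1.0, 0.05, 0.5, 0.0, 0.0, 0.0),
        # 29 samples, minute-scale: dense half-minute sampling right after
        # the glucose pulse (fast transient), minutely afterwards
        default_grid=np.concatenate(
            [np.arange(0.0, 4.5, 0.5), np.arange(5.0, 25.0, 1.0)]
        ),
    )


def simulate_trehalose_like(
    grid: np.ndarray | None = None,
    pool_glucose: bool = False,
) -> tuple[TimeSeriesSet, TimeSeriesSet, FluxProfiles]:
    """Emit (reported data, full truth, true fluxes).

    The reported dataset mimics the missing-data pattern of in vivo NMR
    studies: the sink variables X7 (pentose phosphate) and X8 (other
    pathways) are withheld; their time courses must be reconstructed by
    point-by-point integration of the solved v7 and v8.  With
    ``pool_glucose`` the intracellular glucose column is additionally
    merged into the extracellular one (reported "X1" = X1 + X2), as when
    only total glucose is measurable.  The truth set carries all eight
    state variables.
    """
    system = trehalose_like_system()
    truth_ts, fluxes = simulate_system(system, grid=grid, dataset_id="yeast-like")
    full = truth_ts.datasets[0]
    reported = full.values[REPORTED_TREHALOSE_COLUMNS].copy()
    if pool_glucose:
        reported["X1"] = full.values["X1"] + full.values["X2"]
        reported = reported.drop(columns=["X2"])
    reported_ts = TimeSeriesSet(
        [TimeSeries("yeast-like", full.time.copy(), reported)]
    )
    return reported_ts, truth_ts, fluxes


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(ts: TimeSeriesSet, cv: float, seed: int) -> TimeSeriesSet:
    """Multiplicative Gaussian noise: x -> x*(1+e), e ~ N(0, cv^2), clipped at 0."""
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    if cv == 0:
        return ts
    rng = np.random.default_rng(seed)
    out = []
    for ds in ts:
        arr = ds.values.to_numpy(dtype=float)
        noisy = np.clip(arr * (1.0 + cv * rng.standard_normal(arr.shape)), 0.0, None)
        out.append(
            TimeSeries(
                ds.dataset_id,
                ds.time.copy(),
                pd.DataFrame(noisy, columns=ds.metabolites),
            )
        )
    return TimeSeriesSet(out)
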