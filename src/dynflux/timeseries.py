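"""Metabolite time series: I/O, smoothing, slope estimation, mass balance.

Concentration time courses are the raw material of dynamic flux estimation:
substituting numerically estimated slopes S_i(t_j) for the derivatives
decouples the ODE system into per-time-point linear equations in the fluxes.
Everything downstream therefore depends on the quality of the slopes, which
is why smoothing and differentiation live together in this module.

The default slope estimator is the analytic derivative of a cubic spline
fitted per metabolite: an interpolating spline for noise-free data, or a
penalised smoothing spline (GCV-selected penalty, noise-proportional
weights) when a relative noise level is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_interp_spline, make_smoothing_spline

from .pathway import PathwayTopology

__all__ = [
    "TimeSeries",
    "TimeSeriesSet",
    "SlopeTable",
    "BalanceReport",
    "TimeSeriesError",
    "read_timeseries",
    "smooth_series",
    "estimate_slopes",
    "check_mass_balance",
]


class TimeSeriesError(ValueError):
    pass


@dataclass
class TimeSeries:
    """One dataset: a strictly increasing time grid and a K x n table."""

    dataset_id: str
    time: np.ndarray
    values: pd.DataFrame  # K rows, one column per metabolite

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise TimeSeriesError("time grid must be one-dimensional")
        if len(self.values) != len(self.time):
            raise TimeSeriesError(
                f"dataset {self.dataset_id!r}: {len(self.time)} times but "
                f"{len(self.values)} rows"
            )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise TimeSeriesError(
                f"dataset {self.dataset_id!r}: time not strictly increasing "
                f"at row {row} (t={self.time[row]})"
            )
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise TimeSeriesError(
                f"dataset {self.dataset_id!r}: non-finite concentration values"
            )

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_points(self) -> int:
        return len(self.time)


@dataclass
class TimeSeriesSet:
    """A collection of datasets with independent time grids."""

    datasets: list[TimeSeries]
    interpolants: dict[tuple[str, str], BSpline] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    def __getitem__(self, key) -> TimeSeries:
        if isinstance(key, int):
            return self.datasets[key]
        for ds in self.datasets:
            if ds.dataset_id == key:
                return ds
        raise KeyError(key)

    @property
    def metabolites(self) -> list[str]:
        return self.datasets[0].metabolites if self.datasets else []


@dataclass
class SlopeTable:
    """Estimated derivatives S_i(t_j), one table per dataset."""

    tables: dict[str, pd.DataFrame]
    method: str
    smoothing_level: float | None = None

    def __getitem__(self, dataset_id: str) -> pd.DataFrame:
        return self.tables[dataset_id]


@dataclass
class BalanceReport:
    """Weighted total mass per time point and its relative drift."""

    totals: dict[str, np.ndarray]
    max_relative_deviation: float
    tolerance: float

    @property
    def balanced(self) -> bool:
        return self.max_relative_deviation <= self.tolerance


def read_timeseries(
    paths: Sequence, on_negative: str = "error", sep: str | None = None
) -> TimeSeriesSet:
    """Read delimited text files (first column time, named metabolite columns).

    ``on_negative`` is ``"error"`` (default) or ``"clamp"`` (clip to zero
    with a warning).
    """
    import warnings

    datasets = []
    for path in paths:
        path = Path(path)
        frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        if frame.shape[1] < 2:
            raise TimeSeriesError(f"{path}: need a time column and >=1 metabolite")
        time = frame.iloc[:, 0].to_numpy(dtype=float)
        values = frame.iloc[:, 1:].astype(float)
        neg = values.to_numpy() < 0
        if neg.any():
            if on_negative == "clamp":
                warnings.warn(
                    f"{path}: {int(neg.sum())} negative concentrations clamped to 0",
                    stacklevel=2,
                )
                values = values.clip(lower=0.0)
            else:
                r, c = np.argwhere(neg)[0]
                raise TimeSeriesError(
                    f"{path}: negative concentration {values.iloc[r, c]} in "
                    f"column {values.columns[c]!r} at row {r}"
                )
        datasets.append(TimeSeries(dataset_id=path.stem, time=time, values=values))
    return TimeSeriesSet(datasets)


def _fit_spline(t: np.ndarray, y: np.ndarray, level: float | None) -> BSpline:
    """Cubic spline through (t, y): interpolating, or GCV-smoothing if a
    relative noise level is given (weights ~ 1/sigma^2, sigma = level*|y|)."""
    if level is None or level == 0:
        return make_interp_spline(t, y, k=min(3, len(t) - 1))
    scale = np.abs(y)
    floor = 1e-3 * (scale.max() if scale.max() > 0 else 1.0)
    sigma = level * np.maximum(scale, floor)
    return make_smoothing_spline(t, y, w=1.0 / sigma**2)


def smooth_series(
    ts: TimeSeriesSet,
    method: str = "spline",
    smoothing_level: float | None = None,
) -> TimeSeriesSet:
    """Smooth every series with a cubic (smoothing) spline.

    ``smoothing_level`` is interpreted as the relative (coefficient-of-
    variation) noise amplitude of the data; ``None`` or 0 fits an
    interpolating spline, which leaves noise-free data unchanged at the grid
    points.  ``method="none"`` returns the input unchanged.

    The fitted splines are kept on the returned set (``interpolants``) so
    the smoothed curves can be evaluated at arbitrary times within each grid.
    """
    if method == "none":
        return ts
    if method != "spline":
        raise TimeSeriesError(f"unknown smoothing method {method!r}")
    out, interps = [], {}
    for ds in ts:
        if ds.n_points < 4:
            raise TimeSeriesError(
                f"dataset {ds.dataset_id!r}: need >=4 points for spline smoothing"
            )
        cols = {}
        for met in ds.metabolites:
            spl = _fit_spline(ds.time, ds.values[met].to_numpy(), smoothing_level)
            interps[(ds.dataset_id, met)] = spl
            cols[met] = spl(ds.time)
        out.append(
            TimeSeries(ds.dataset_id, ds.time.copy(), pd.DataFrame(cols))
        )
    return TimeSeriesSet(out, interpolants=interps)


def estimate_slopes(
    ts: TimeSeriesSet,
    method: str = "spline",
    smoothing_level: float | None = None,
) -> SlopeTable:
    """Estimate dX_i/dt at every grid point.

    Uses splines already attached to ``ts`` (from :func:`smooth_series`)
    when present, otherwise fits them here with the same conventions.
    Endpoint slopes are retained; they are the least reliable estimates and
    downstream binning can exclude the first/last time point.
    """
    if method != "spline":
        raise TimeSeriesError(f"unknown slope method {method!r}")
    tables = {}
    for ds in ts:
        cols = {}
        for met in ds.metabolites:
            spl = ts.interpolants.get((ds.dataset_id, met))
            if spl is None:
                spl = _fit_spline(ds.time, ds.values[met].to_numpy(), smoothing_level)
            cols[met] = spl.derivative()(ds.time)
        tables[ds.dataset_id] = pd.DataFrame(cols)
    return SlopeTable(tables=tables, method="spline", smoothing_level=smoothing_level)


def check_mass_balance(
    ts: TimeSeriesSet,
    weights: Mapping[str, float],
    topology: PathwayTopology | None = None,
    tolerance: float = 0.05,
) -> BalanceReport:
    """Check conservation of a weighted total mass over time.

    The total at time ``t_j`` is ``sum_i w_i * V_i * X_i(t_j)`` (volumes
    default to 1 without a topology).  The report flags an imbalance when
    the maximum relative deviation from the initial total exceeds
    ``tolerance`` (default 5 %), which indicates unmodelled influxes or
    leaks.
    """
    totals = {}
    max_dev = 0.0
    for ds in ts:
        missing = [m for m in ds.metabolites if m not in weights]
        if missing:
            raise TimeSeriesError(f"missing mass weights for {missing}")
        w = np.array(
            [
                weights[m] * (topology.volume_of(m) if topology else 1.0)
                for m in ds.metabolites
            ]
        )
        tot = ds.values.to_numpy(dtype=float) @ w
        totals[ds.dataset_id] = tot
        ref = tot[0]
        if ref == 0:
            dev = float(np.max(np.abs(tot)))
        else:
            dev = float(np.max(np.abs(tot - ref) / abs(ref)))
        max_dev = max(max_dev, dev)
    return BalanceReport(
        totals=totals, max_relative_deviation=max_dev, tolerance=tolerance
    )
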