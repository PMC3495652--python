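"""Model-free inference of a flux's concentration dependence.

This is the heart of the package.  For an equation with one influx and one
efflux,

    V_i * S_i(t_j) = v_in(X_in(t_j)) - v_out(X_out(t_j)),

time points where the influx's argument X_in takes (nearly) the same value
share the same (unknown) influx value.  Binning the data on X_in therefore
yields, within each bin, points (X_out, -V_i*S_i) that trace the efflux
curve up to one unknown vertical offset per bin.  Adjacent points within a
bin form pairs; pairs whose X_out separation is below a threshold are
discarded (short segments amplify slope error); the surviving pairs are
merged into one continuous relative curve by choosing a vertical shift per
pair; and a single anchoring step fixes the remaining global constant.

Merging runs in two deterministic stages:

1. an agglomerative pass - every pair is a node and its own subgraph;
   repeatedly the two closest subgraphs (x-interval gap, centroid distance
   as tie-break) are connected, shifting the smaller one so its connecting
   point lands on the piecewise-linear interpolant of the host's points;
2. a fixed-point refinement - each pair's offset is updated by the mean
   residual to a low-order polynomial backbone fitted through all points,
   iterated to convergence.  On offset-consistent data the residuals vanish
   and the refinement is a no-op, so exact instances are reproduced
   unchanged; on real data it distributes the alignment error over all
   pairs instead of letting it accumulate along the merge order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .pathway import PathwayTopology
from .timeseries import SlopeTable, TimeSeriesSet

__all__ = [
    "EquationChoice",
    "BinMember",
    "Bin",
    "BinDatabase",
    "Pair",
    "PairSet",
    "RelativeFluxCurve",
    "FluxCurve",
    "InferenceError",
    "select_target_equation",
    "bin_fixed_variable",
    "bin_fixed_combination",
    "extract_pairs",
    "filter_pairs",
    "merge_pairs",
    "anchor_curve",
    "curve_accuracy",
]


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# equation selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquationChoice:
    metabolite: str
    fluxes: tuple[str, ...]
    dependency_variables: tuple[str, ...]
    all_dependencies_measured: bool
    eligible: bool  # two fluxes, all dependencies measured


def select_target_equation(topology: PathwayTopology) -> list[EquationChoice]:
    """Rank mass-balance equations for flux inference.

    Preference order: fewest fluxes, fewest distinct dependency variables,
    fully measured dependencies first; ties broken by equation order.  Only
    two-flux equations whose dependencies are all measured are eligible for
    automatic inference; if none is, an error asks for a manual choice.
    """
    red = topology.reduce_constraints()
    choices = []
    for met in red.metabolite_names:
        terms = red.equation_fluxes(met)
        fluxes = tuple(f for f, _ in terms)
        if not fluxes:  # external inputs / conserved pools have no equation
            continue
        deps: list[str] = []
        for f in fluxes:
            for d in red.dependencies.get(f, ()):
                if d not in deps:
                    deps.append(d)
        measured = all(d in red.measured for d in deps) and met in red.measured
        choices.append(
            EquationChoice(
                metabolite=met,
                fluxes=fluxes,
                dependency_variables=tuple(deps),
                all_dependencies_measured=measured,
                eligible=len(fluxes) == 2 and measured,
            )
        )
    order = {m: i for i, m in enumerate(red.metabolite_names)}
    ranked = sorted(
        choices,
        key=lambda c: (
            len(c.fluxes),
            len(c.dependency_variables),
            not c.all_dependencies_measured,
            order[c.metabolite],
        ),
    )
    if not any(c.eligible for c in ranked):
        raise InferenceError(
            "no equation with exactly two fluxes and fully measured "
            "dependencies; choose an equation manually"
        )
    return ranked


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinMember:
    dataset_id: str
    time_index: int
    fixed_values: tuple[float, ...]
    x_out: float
    y: float  # signed, volume-scaled slope contribution


@dataclass
class Bin:
    bin_id: tuple[int, ...]
    lower: tuple[float, ...]
    members: list[BinMember] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return len(self.members) >= 2


@dataclass
class BinDatabase:
    fixed_variables: tuple[str, ...]
    widths: tuple[float, ...]
    out_variable: str
    target_metabolite: str
    sign: int
    bins: list[Bin]
    n_points: int

    @property
    def occupied(self) -> int:
        return len(self.bins)

    @property
    def retained_bins(self) -> list[Bin]:
        return [b for b in self.bins if b.retained]

    @property
    def n_retained(self) -> int:
        return len(self.retained_bins)


def bin_fixed_variable(
    ts: TimeSeriesSet,
    slopes: SlopeTable,
    fixed_var: str | Sequence[str],
    out_var: str,
    target_metabolite: str,
    width: float | Sequence[float],
    volume: float = 1.0,
    exclude_endpoints: bool = False,
    sign: int = -1,
) -> BinDatabase:
    """Bin time points on the fixed variable(s) of one flux.

    Bins are half-open intervals ``[lo + k*w, lo + (k+1)*w)`` anchored at
    the observed minimum of each fixed variable; every time point of every
    dataset falls into exactly one bin.  Bins with fewer than two members
    are kept in the database but flagged not-retained.

    Sign convention: fixing the influx's variable(s) to trace the efflux
    uses ``sign=-1`` (the default): each member carries ``y = -V_i*S_i``.
    Fixing the efflux's variable(s) to trace the influx instead uses
    ``sign=+1`` (``y = +V_i*S_i``), since then
    ``V_i*S_i = v_in(X_out) - v_out_const``.
    """
    fixed_vars = (fixed_var,) if isinstance(fixed_var, str) else tuple(fixed_var)
    widths = (
        (float(width),) * len(fixed_vars)
        if np.isscalar(width)
        else tuple(float(w) for w in width)
    )
    if len(widths) != len(fixed_vars):
        raise InferenceError("need one width per fixed variable")
    if any(w <= 0 for w in widths):
        raise InferenceError(f"bin widths must be positive, got {widths}")
    if sign not in (-1, 1):
        raise InferenceError(f"sign must be -1 (trace efflux) or +1, got {sign}")

    # global minima anchor the grid across datasets
    mins = []
    for k, var in enumerate(fixed_vars):
        lo = min(float(ds.values[var].min()) for ds in ts)
        mins.append(lo)

    bins: dict[tuple[int, ...], Bin] = {}
    n_points = 0
    for ds in ts:
        S = slopes[ds.dataset_id][target_metabolite].to_numpy(dtype=float)
        fixed = [ds.values[v].to_numpy(dtype=float) for v in fixed_vars]
        xout = ds.values[out_var].to_numpy(dtype=float)
        K = len(ds.time)
        lo_idx = 1 if exclude_endpoints else 0
        hi_idx = K - 1 if exclude_endpoints else K
        for j in range(lo_idx, hi_idx):
            key = tuple(
                int(math.floor((fixed[k][j] - mins[k]) / widths[k]))
                for k in range(len(fixed_vars))
            )
            member = BinMember(
                dataset_id=ds.dataset_id,
                time_index=j,
                fixed_values=tuple(f[j] for f in fixed),
                x_out=float(xout[j]),
                y=float(sign * volume * S[j]),
            )
            if key not in bins:
                bins[key] = Bin(
                    bin_id=key,
                    lower=tuple(
                        mins[k] + key[k] * widths[k] for k in range(len(fixed_vars))
                    ),
                )
            bins[key].members.append(member)
            n_points += 1
    ordered = [bins[k] for k in sorted(bins)]
    return BinDatabase(
        fixed_variables=fixed_vars,
        widths=widths,
        out_variable=out_var,
        target_metabolite=target_metabolite,
        sign=sign,
        bins=ordered,
        n_points=n_points,
    )


def bin_fixed_combination(
    ts: TimeSeriesSet,
    slopes: SlopeTable,
    fixed_vars: Sequence[str],
    out_var: str,
    target_metabolite: str,
    widths: float | Sequence[float],
    volume: float = 1.0,
    exclude_endpoints: bool = False,
    sign: int = -1,
) -> BinDatabase:
    """Multivariate binning: members match when every fixed variable falls
    into the same per-variable bin.  Semantics otherwise identical to the
    univariate case (to which this reduces for a single variable)."""
    if len(fixed_vars) < 1:
        raise InferenceError("need at least one fixed variable")
    return bin_fixed_variable(
        ts,
        slopes,
        tuple(fixed_vars),
        out_var,
        target_metabolite,
        widths,
        volume=volume,
        exclude_endpoints=exclude_endpoints,
        sign=sign,
    )


# ---------------------------------------------------------------------------
# pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pair:
    bin_id: tuple[int, ...]
    point1: tuple[float, float]  # (x_out, y), x1 < x2
    point2: tuple[float, float]
    members: tuple[BinMember, BinMember] | None = None

    @property
    def separation(self) -> float:
        return self.point2[0] - self.point1[0]


@dataclass
class PairSet:
    pairs: list[Pair]
    threshold: float | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def coverage(self) -> dict:
        """x-axis coverage of the pairs: range and uncovered gaps."""
        if not self.pairs:
            return {"x_min": None, "x_max": None, "gaps": []}
        intervals = sorted((p.point1[0], p.point2[0]) for p in self.pairs)
        gaps = []
        _, cur_hi = intervals[0]
        for lo, hi in intervals[1:]:
            if lo > cur_hi:
                gaps.append((cur_hi, lo))
            cur_hi = max(cur_hi, hi)
        return {
            "x_min": intervals[0][0],
            "x_max": max(hi for _, hi in intervals),
            "gaps": gaps,
        }


def extract_pairs(bins: BinDatabase) -> PairSet:
    """Form adjacent pairs within every retained bin.

    Members are sorted by X_out ascending (ties broken by dataset id and
    time index for reproducibility); q members yield q-1 pairs.
    """
    pairs = []
    for b in bins.retained_bins:
        members = sorted(
            b.members, key=lambda m: (m.x_out, m.dataset_id, m.time_index)
        )
        for m1, m2 in zip(members[:-1], members[1:]):
            pairs.append(
                Pair(
                    bin_id=b.bin_id,
                    point1=(m1.x_out, m1.y),
                    point2=(m2.x_out, m2.y),
                    members=(m1, m2),
                )
            )
    return PairSet(pairs=pairs, threshold=None)


def filter_pairs(pairs: PairSet, threshold: float = 0.2) -> PairSet:
    """Drop pairs whose X_out separation is below the threshold.

    Short segments amplify slope-estimation error; the default separation
    threshold is 0.2 concentration units, but the appropriate value depends
    on the accuracy and quantity of the data - raising it is preferable as
    long as the survivors still cover most of the X_out range (check
    :meth:`PairSet.coverage`).
    """
    if threshold < 0:
        raise InferenceError(f"threshold must be >= 0, got {threshold}")
    kept = [p for p in pairs if p.separation >= threshold]
    return PairSet(pairs=kept, threshold=threshold)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclass
class RelativeFluxCurve:
    """Merged flux-vs-metabolite points, defined up to one global constant."""

    x: np.ndarray  # sorted ascending
    y: np.ndarray
    pair_index: np.ndarray  # which input pair each point came from
    offsets: np.ndarray     # applied per-pair vertical shifts (audit trail)
    merge_log: list[dict] = field(default_factory=list)
    residual_scale: float = 0.0  # robust scale of backbone residuals

    @property
    def n_pairs(self) -> int:
        return len(self.offsets)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, host: int, join: int) -> None:
        self.parent[join] = host


def _pair_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(x-interval gap, centroid distance).  y is excluded because offsets
    across subgraphs are not yet comparable."""
    gap = max(0.0, max(a[0, 0], b[0, 0]) - min(a[1, 0], b[1, 0]))
    cen = abs((a[0, 0] + a[1, 0]) - (b[0, 0] + b[1, 0])) / 2.0
    return (gap, cen)


def _interp_with_extension(xq: float, x: np.ndarray, y: np.ndarray) -> float:
    """Piecewise-linear interpolation, extended by the end segments."""
    if len(x) == 1:
        return float(y[0])
    if xq <= x[0]:
        return float(y[0] + (y[1] - y[0]) * (xq - x[0]) / (x[1] - x[0]))
    if xq >= x[-1]:
        return float(y[-1] + (y[-1] - y[-2]) * (xq - x[-1]) / (x[-1] - x[-2]))
    return float(np.interp(xq, x, y))


def _agglomerate(pts: np.ndarray, log: list[dict]) -> np.ndarray:
    """Closest-first agglomerative merge; returns per-pair offsets."""
    P = len(pts)
    offsets = np.zeros(P)
    work = pts.copy()
    uf = _UnionFind(P)
    n_components = P
    while n_components > 1:
        best = None
        for i in range(P):
            for j in range(i + 1, P):
                if uf.find(i) == uf.find(j):
                    continue
                d = _pair_distance(work[i], work[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        ci, cj = uf.find(i), uf.find(j)
        size = {c: sum(1 for k in range(P) if uf.find(k) == c) for c in (ci, cj)}
        # the larger component hosts; ties broken by component id
        if (size[cj], cj) < (size[ci], ci):
            host_c, join_c, host_n, join_n = ci, cj, i, j
        else:
            host_c, join_c, host_n, join_n = cj, ci, j, i
        host_members = [k for k in range(P) if uf.find(k) == host_c]
        hx = np.concatenate([work[k][:, 0] for k in host_members])
        hy = np.concatenate([work[k][:, 1] for k in host_members])
        order = np.argsort(hx, kind="stable")
        hx, hy = hx[order], hy[order]
        # connecting point: the joining node's point closest to the host node
        hn = work[host_n]
        dists = [
            min(abs(q[0] - hn[0, 0]), abs(q[0] - hn[1, 0])) for q in work[join_n]
        ]
        q = work[join_n][int(np.argmin(dists))]
        shift = _interp_with_extension(q[0], hx, hy) - q[1]
        for k in range(P):
            if uf.find(k) == join_c:
                work[k][:, 1] += shift
                offsets[k] += shift
        log.append(
            {
                "stage": "connect",
                "host_node": int(host_n),
                "joining_node": int(join_n),
                "shift": float(shift),
            }
        )
        uf.union(host_c, join_c)
        n_components -= 1
    return offsets


def _jitter_scale(x: np.ndarray, resid: np.ndarray) -> float:
    """Robust scale of the non-smooth part of residuals along x.

    First differences of residuals sorted by x cancel any smooth trend, so
    lack-of-fit of the backbone does not inflate the estimate - only
    genuine point-to-point scatter does."""
    order = np.argsort(x, kind="stable")
    d = np.diff(resid[order])
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _backbone(px: np.ndarray, y: np.ndarray, s_total: float):
    """Smooth backbone through the (possibly duplicated-x) merged points.

    A cubic smoothing spline whose penalty matches the data's jitter scale:
    on offset-consistent data the penalty is ~0 and the spline interpolates,
    making the subsequent offset update a no-op."""
    ux, inv = np.unique(np.round(px, 9), return_inverse=True)
    counts = np.bincount(inv).astype(float)
    uy = np.bincount(inv, weights=y) / counts
    if len(ux) >= 5:
        import warnings

        from scipy.interpolate import UnivariateSpline

        with warnings.catch_warnings():
            # near-zero penalties trip FITPACK's iteration-limit warning on
            # exactly consistent data; the interpolating fit it returns is
            # precisely what is wanted there
            warnings.simplefilter("ignore", UserWarning)
            spl = UnivariateSpline(ux, uy, w=np.sqrt(counts), k=3, s=s_total)
        return spl(px)
    deg = len(ux) - 1
    coef = np.polynomial.polynomial.polyfit(px, y, deg)
    return np.polynomial.polynomial.polyval(px, coef)


def _refine(
    px: np.ndarray,
    py: np.ndarray,
    pair_of: np.ndarray,
    offsets: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point refinement of per-pair offsets against the backbone."""
    P = len(offsets)
    off = offsets.copy()
    counts = np.bincount(pair_of, minlength=P).astype(float)
    # pin the backbone stiffness once, from the initial alignment
    fit0 = _backbone(px, py + off[pair_of], 0.0)
    sigma0 = _jitter_scale(px, fit0 - (py + off[pair_of]))
    # an interpolating first pass has zero residuals by construction; probe
    # the jitter with a stiff reference instead
    deg = min(3, len(np.unique(px)) - 1)
    coef = np.polynomial.polynomial.polyfit(px, py + off[pair_of], deg)
    sigma0 = max(
        sigma0,
        _jitter_scale(
            px, np.polynomial.polynomial.polyval(px, coef) - (py + off[pair_of])
        ),
    )
    n_unique = len(np.unique(np.round(px, 9)))
    s_total = n_unique * sigma0**2
    resid = np.zeros_like(py)
    for _ in range(max_iter):
        y = py + off[pair_of]
        resid = _backbone(px, y, s_total) - y
        update = np.bincount(pair_of, weights=resid, minlength=P) / counts
        new = off + update
        new -= new.mean()
        if np.abs(new - off).max() < tol:
            off = new
            break
        off = new
    y = py + off[pair_of]
    resid = _backbone(px, y, s_total) - y
    return off, resid


def merge_pairs(pairs: PairSet, refine: bool = True) -> RelativeFluxCurve:
    """Merge shiftable pairs into one continuous relative curve.

    See the module docstring for the two-stage algorithm.  The output is
    every pair's points with its vertical offset applied, sorted by x; a
    global additive constant remains undetermined until anchoring.
    """
    if len(pairs) == 0:
        raise InferenceError("cannot merge an empty pair set")
    pts = np.array(
        [[[p.point1[0], p.point1[1]], [p.point2[0], p.point2[1]]] for p in pairs],
        dtype=float,
    )
    P = len(pts)
    log: list[dict] = []
    offsets = np.zeros(P) if P == 1 else _agglomerate(pts, log)

    pair_of = np.repeat(np.arange(P), 2)
    px = pts[:, :, 0].ravel()
    py = pts[:, :, 1].ravel()
    sigma = 0.0
    if refine and P > 1:
        offsets, resid = _refine(px, py, pair_of, offsets - offsets.mean())
        # scatter scale from point-to-point jitter of the residuals along x:
        # noise shows up as jitter between neighbouring points, while smooth
        # lack-of-fit of the polynomial backbone does not inflate it
        order = np.argsort(px, kind="stable")
        d = np.diff(resid[order])
        if d.size:
            sigma = float(
                1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
            )
        log.append({"stage": "refine", "residual_scale": sigma})

    y = py + offsets[pair_of]
    order = np.argsort(px, kind="stable")
    return RelativeFluxCurve(
        x=px[order],
        y=y[order],
        pair_index=pair_of[order],
        offsets=offsets,
        merge_log=log,
        residual_scale=sigma,
    )


# ---------------------------------------------------------------------------
# anchoring and the final curve
# ---------------------------------------------------------------------------

@dataclass
class FluxCurve:
    """Anchored flux-vs-metabolite look-up relation.

    ``x``/``v`` are the support points (unique x, averaged and - when the
    trend is monotone within tolerance - isotonically projected y); the
    monotone piecewise-cubic (PCHIP) interpolant passes through them
    exactly.  ``raw_x``/``raw_v`` keep every anchored point before
    aggregation for audit.
    """

    x: np.ndarray
    v: np.ndarray
    anchor_method: str
    anchor_value: float
    raw_x: np.ndarray | None = None
    raw_v: np.ndarray | None = None
    residual_scale: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not np.all(np.isfinite(self.v)):
            raise InferenceError("anchored flux values must be finite")
        self._interp = (
            PchipInterpolator(self.x, self.v, extrapolate=False)
            if len(self.x) > 1
            else None
        )

    @property
    def domain(self) -> tuple[float, float]:
        return (float(self.x[0]), float(self.x[-1]))

    def __call__(self, xq, extrapolate: bool = False):
        xq_arr = np.asarray(xq, dtype=float)
        if self._interp is None:
            out = np.full_like(xq_arr, self.v[0], dtype=float)
        else:
            out = self._interp(xq_arr)
            if extrapolate:
                lo, hi = self.domain
                below = xq_arr < lo
                above = xq_arr > hi
                if below.any():
                    slope = (self.v[1] - self.v[0]) / (self.x[1] - self.x[0])
                    out = np.where(below, self.v[0] + slope * (xq_arr - lo), out)
                if above.any():
                    slope = (self.v[-1] - self.v[-2]) / (self.x[-1] - self.x[-2])
                    out = np.where(above, self.v[-1] + slope * (xq_arr - hi), out)
        return out if np.ndim(xq) else float(out)


def _pava_increasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: weighted isotonic (non-decreasing) fit."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i, i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i][1] = blocks[i + 1][1]
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for (lo, hi), v in zip(blocks, vals):
        out[lo : hi + 1] = v
    return out


def _aggregate_support(
    x: np.ndarray, y: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unique-x support values: average duplicates, smooth in proportion to
    the merge residual scale, and project onto a monotone sequence when the
    trend is monotone within tolerance."""
    ux, inv = np.unique(np.round(x, 9), return_inverse=True)
    counts = np.bincount(inv).astype(float)
    uy = np.bincount(inv, weights=y) / counts
    if sigma > 1e-8 and len(ux) >= 5:
        from scipy.interpolate import UnivariateSpline

        spl = UnivariateSpline(ux, uy, w=np.sqrt(counts), k=3, s=len(ux) * sigma**2)
        uy = spl(ux)
    yrange = uy.max() - uy.min()
    if yrange > 0:
        down = np.sum(np.maximum(0.0, -np.diff(uy)))
        up = np.sum(np.maximum(0.0, np.diff(uy)))
        if down <= 0.05 * yrange:
            uy = _pava_increasing(uy, counts)
        elif up <= 0.05 * yrange:
            uy = -_pava_increasing(-uy, counts)
    return ux, uy


def _local_linear_value(
    x: np.ndarray, y: np.ndarray, x0: float, sigma: float
) -> float:
    """Evaluate the relative curve at x0 by a kernel-weighted local line.

    The bandwidth adapts to the merge residual scale (wider when the merged
    points are noisy) and to the distance of x0 outside the support (an
    extrapolated anchor must average over enough points to stabilise the
    local slope).  On clean data the bandwidth collapses towards the nearest
    points and the value approaches plain interpolation.
    """
    if len(x) == 1:
        return float(y[0])
    span = x[-1] - x[0]
    if span <= 0:
        return float(y.mean())
    yrange = max(y.max() - y.min(), 1e-12)
    h_frac = float(np.clip(4.0 * sigma / yrange, 0.02, 0.3))
    d_outside = max(0.0, x[0] - x0, x0 - x[-1])
    h = max(h_frac * span, 2.0 * d_outside, 1e-9)
    w = np.exp(-np.abs(x - x0) / h)
    A = np.c_[np.ones_like(x), x - x0]
    beta, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
    return float(beta[0])


def anchor_curve(
    rel: RelativeFluxCurve,
    strategy: str = "zero_at_zero",
    x0: float | None = None,
    v0: float | None = None,
    family: str | None = None,
    flat_tail_fraction: float = 0.2,
) -> FluxCurve:
    """Fix the global additive constant of a merged relative curve.

    Strategies
    ----------
    ``zero_at_zero``
        Metabolic fluxes vanish as the substrate concentration approaches
        zero, so if the smallest covered x is near zero - or the left tail
        of the curve is flat, indicating the flux has levelled off at its
        minimum - the leftmost value is shifted to zero.  Refused with a
        diagnostic otherwise, because anchoring then requires extrapolation
        and is the one bias-prone step of the method.
    ``known_point``
        Shift so the curve passes through a known value (x0, v0).
    ``fit_family``
        Jointly fit a rate-law family plus offset to the relative curve and
        apply the fitted offset (requires :mod:`dynflux.ratelaws`).
    """
    x, y, sigma = rel.x, rel.y, rel.residual_scale

    if strategy == "known_point":
        if x0 is None or v0 is None:
            raise InferenceError("known_point anchoring needs x0 and v0")
        shift = v0 - _local_linear_value(x, y, float(x0), sigma)
        anchor_value = float(v0)
    elif strategy == "zero_at_zero":
        span = x[-1] - x[0]
        near_zero = x[0] <= 0.05 * max(x[-1], 1e-12)
        # flat left tail: the y-variation across the left fraction of the
        # covered x-range is a negligible share of the total y-range (value
        # based rather than slope based - robust to noisy near-duplicate x)
        flat = False
        if len(x) >= 4 and span > 0:
            window = x <= x[0] + flat_tail_fraction * span
            tail_y = y[window]
            y_range = y.max() - y.min()
            flat = (
                window.sum() >= 2
                and y_range > 0
                and (tail_y.max() - tail_y.min()) <= 0.05 * y_range
            )
        if not (near_zero or flat):
            raise InferenceError(
                "zero_at_zero refused: smallest covered x "
                f"({x[0]:.4g}) is far from zero and the left tail is not "
                "flat; anchoring would extrapolate (bias risk) - supply a "
                "known point or a rate-law family instead"
            )
        shift = -float(y[0])
        anchor_value = 0.0
    elif strategy == "fit_family":
        from .ratelaws import fit_rate_law

        if family is None:
            raise InferenceError("fit_family anchoring needs a family name")
        px, py = _aggregate_support(x, y, sigma)
        provisional = FluxCurve(
            x=px, v=py, anchor_method="relative", anchor_value=0.0
        )
        fit = fit_rate_law(provisional, family, fit_offset=True)
        shift = -fit.parameters["offset"]
        anchor_value = float(shift)
    else:
        raise InferenceError(f"unknown anchor strategy {strategy!r}")

    raw_v = y + shift
    ux, uy = _aggregate_support(x, raw_v, sigma)
    return FluxCurve(
        x=ux,
        v=uy,
        anchor_method=strategy,
        anchor_value=anchor_value,
        raw_x=x.copy(),
        raw_v=raw_v,
        residual_scale=sigma,
    )


def curve_accuracy(
    curve: FluxCurve,
    truth: Callable[[np.ndarray], np.ndarray],
    metric: str = "sum_abs",
) -> float:
    """Deviation between a curve's support points and a true flux function.

    ``metric``: ``sum_abs`` (sum of absolute errors, the default),
    ``sum_sq`` (summed squared errors) or ``mean_abs``.  Benchmark use only:
    the truth is never available in applications.
    """
    err = curve.v - np.asarray(truth(curve.x), dtype=float)
    if metric == "sum_abs":
        return float(np.abs(err).sum())
    if metric == "sum_sq":
        return float((err**2).sum())
    if metric == "mean_abs":
        return float(np.abs(err).mean())
    raise InferenceError(f"unknown metric {metric!r}")
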