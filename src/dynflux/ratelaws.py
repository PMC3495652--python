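"""Candidate rate-law families: evaluation, fitting, and ranking.

The second phase of dynamic flux estimation turns a numerical
flux-vs-metabolite relation into an explicit kinetic form.  The candidate
set is deliberately small and canonical - Michaelis-Menten, Hill, and the
power law of Biochemical Systems Theory - plus a spline look-up fallback
for relations that none of them capture.  Fits are nonlinear least squares
with a deterministic multi-start grid (no random seed), optionally with a
free additive offset so un-anchored (relative) curves can be fitted jointly
with their shift.

Ranking uses a small-sample corrected information score (AICc-style):
raw residual error alone favours over-parameterised models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .inference import FluxCurve

__all__ = [
    "RateLawFit",
    "RateLawError",
    "FAMILIES",
    "evaluate_rate_law",
    "fit_rate_law",
    "rank_candidates",
]


class RateLawError(ValueError):
    pass


@dataclass
class RateLawFit:
    """A fitted (or constructed) rate law."""

    family: str
    parameters: dict[str, float]
    sse: float
    n_points: int
    aicc: float = math.nan
    lookup: FluxCurve | None = None

    @property
    def n_parameters(self) -> int:
        if self.family == "lookup_spline":
            return self.n_points
        return len(self.parameters)


def _mm(x, p):
    return p["v_max"] * x / (p["k_m"] + x)


def _hill(x, p):
    xh = x ** p["h"]
    return p["v_max"] * xh / (p["k"] ** p["h"] + xh)


def _power_law(x, p):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    exps = [v for k, v in sorted(p.items()) if k.startswith("f")]
    if x.shape[0] != len(exps) and x.shape[-1] == len(exps):
        x = x.T
    out = p["gamma"] * np.prod(
        [xi**f for xi, f in zip(x, exps)], axis=0
    )
    return out if out.size > 1 else out.reshape(()).item()


#: family name -> (parameter names, evaluator, positivity mask)
FAMILIES: dict[str, tuple[tuple[str, ...], Callable]] = {
    "michaelis_menten": (("v_max", "k_m"), _mm),
    "hill": (("v_max", "k", "h"), _hill),
    "power_law": (("gamma", "f"), _power_law),
}


def evaluate_rate_law(fit: RateLawFit, x) -> float | np.ndarray:
    """Evaluate a fitted rate law at metabolite value(s) x.

    Michaelis-Menten: v_max*x/(k_m+x); Hill: v_max*x^h/(k^h+x^h);
    power law: gamma * prod(x_i^f_i); lookup: spline interpolation within
    the stored domain.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise RateLawError("rate laws are defined for non-negative concentrations")
    offset = fit.parameters.get("offset", 0.0)
    if fit.family == "lookup_spline":
        if fit.lookup is None:
            raise RateLawError("lookup fit carries no curve")
        lo, hi = fit.lookup.domain
        if np.any(xa < lo) or np.any(xa > hi):
            raise RateLawError(
                f"lookup evaluation outside domain [{lo:.4g}, {hi:.4g}]"
            )
        return fit.lookup(x)
    try:
        params, fn = FAMILIES[fit.family]
    except KeyError:
        raise RateLawError(f"unknown family {fit.family!r}") from None
    return fn(xa, fit.parameters) + offset


def _initial_grid(family: str, x: np.ndarray, v: np.ndarray) -> list[list[float]]:
    """Deterministic multi-start initial guesses (no randomness)."""
    vmax0 = max(float(np.max(np.abs(v))), 1e-6)
    ks = [float(np.percentile(x, q)) for q in (25, 50, 75)]
    ks = [k if k > 0 else 1.0 for k in ks]
    starts = []
    if family == "michaelis_menten":
        for v0 in (1.0, vmax0, 2 * vmax0):
            for k0 in ks:
                starts.append([v0, k0])
    elif family == "hill":
        for v0 in (1.0, vmax0, 2 * vmax0):
            for k0 in ks:
                for h0 in (1.0, 2.0, 4.0):
                    starts.append([v0, k0, h0])
    elif family == "power_law":
        for g0 in (0.5, 1.0, vmax0):
            for f0 in (0.5, 1.0, 2.0):
                starts.append([g0, f0])
    return starts


def fit_rate_law(
    curve: FluxCurve,
    family: str,
    fit_offset: bool = False,
) -> RateLawFit:
    """Fit one family to a curve's support points by least squares.

    Multi-start from a fixed grid of initialisations keeps the fit
    deterministic; the best converged start (lowest SSE) wins.  With
    ``fit_offset`` an additive constant is estimated jointly, which lets
    the same routine fit un-anchored relative curves: the shape parameters
    recovered are then identical to an anchored fit up to the offset.
    """
    if family == "lookup_spline":
        fit = RateLawFit(
            family="lookup_spline",
            parameters={},
            sse=0.0,
            n_points=len(curve.x),
            lookup=curve,
        )
        fit.aicc = _aicc(fit)
        return fit
    if family not in FAMILIES:
        raise RateLawError(f"unknown family {family!r}")
    names, fn = FAMILIES[family]
    x = np.asarray(curve.x, dtype=float)
    v = np.asarray(curve.v, dtype=float)
    n_par = len(names) + (1 if fit_offset else 0)
    if len(x) <= n_par:
        raise RateLawError(
            f"{family}: {len(x)} points cannot determine {n_par} parameters"
        )

    def residual(theta):
        p = dict(zip(names, theta))
        off = theta[-1] if fit_offset else 0.0
        return fn(x, p) + off - v

    lower = [1e-9] * len(names)
    upper = [np.inf] * len(names)
    if family == "power_law":
        lower[1] = -10.0  # exponent may be negative (inhibition)
        upper[1] = 10.0
    if fit_offset:
        lower.append(-np.inf)
        upper.append(np.inf)

    best = None
    for start in _initial_grid(family, x, v):
        theta0 = start + ([0.0] if fit_offset else [])
        theta0 = [min(max(t, lo), up if np.isfinite(up) else t) for t, lo, up in
                  zip(theta0, lower, upper)]
        try:
            res = least_squares(
                residual, theta0, bounds=(lower, upper), max_nfev=2000
            )
        except Exception:
            continue
        if res.success or res.status > 0:
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RateLawError(f"{family}: no start converged")
    params = dict(zip(names, best.x))
    if fit_offset:
        params["offset"] = float(best.x[-1])
    params = {k: float(val) for k, val in params.items()}
    sse = float(2 * best.cost)
    fit = RateLawFit(family=family, parameters=params, sse=sse, n_points=len(x))
    fit.aicc = _aicc(fit)
    return fit


def _aicc(fit: RateLawFit) -> float:
    """Small-sample corrected Akaike-style score on the residual error."""
    n, k = fit.n_points, fit.n_parameters
    sse = max(fit.sse, 1e-300)
    aic = n * math.log(sse / n) + 2 * k
    denom = n - k - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * k * (k + 1) / denom


def rank_candidates(
    curve: FluxCurve,
    families: Sequence[str] = ("michaelis_menten", "hill", "power_law"),
    fit_offset: bool = False,
) -> list[RateLawFit]:
    """Fit every candidate family and rank by the corrected score.

    Families with more parameters than the curve has points are skipped.
    The spline look-up is always appended as a fallback (penalised by its
    effective parameter count, so an explicit family that genuinely
    explains the data ranks above it).  If every parametric fit fails, the
    look-up alone is returned with a warning.
    """
    import warnings

    fits = []
    for fam in families:
        if fam == "lookup_spline":
            continue
        n_par = len(FAMILIES[fam][0]) + (1 if fit_offset else 0)
        if len(curve.x) <= n_par:
            continue
        try:
            fits.append(fit_rate_law(curve, fam, fit_offset=fit_offset))
        except RateLawError:
            continue
    if not fits:
        warnings.warn(
            "no parametric rate law could be fitted; returning the spline "
            "look-up only",
            stacklevel=2,
        )
    fits.append(fit_rate_law(curve, "lookup_spline"))
    # ties in the score resolved in favour of fewer parameters
    return sorted(fits, key=lambda f: (round(f.aicc, 6), f.n_parameters))
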