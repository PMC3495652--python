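"""Two-compartment yeast-like system with withheld variables.

The trehalose-cycle stand-in reports six measured concentrations but
withholds the pentose-phosphate and leakage sinks (X7, X8).  The workflow:
check carbon-unit mass balance, interpolate the smoothed 29-point series to
a dense grid, infer trehalase v4(X4) by fixing G6P (X3), back-calculate its
partner v3, solve the remaining fluxes per time point (the 5% diversion
v7 = 0.05*v5 is eliminated by constraint), and reconstruct the withheld X7
by integrating the solved flux.
"""

import numpy as np
import pandas as pd

import dynflux as dx

V_INT = 0.00717  # L, intracellular volume

reported, truth, true_fluxes = dx.simulate_trehalose_like()
system = dx.trehalose_like_system()

balance = dx.check_mass_balance(
    truth, dx.CARBON_WEIGHTS, system.topology, tolerance=0.05
)
print(f"carbon mass drift over the full truth: "
      f"{balance.max_relative_deviation:.2e} (balanced: {balance.balanced})")

print(dx.check_flux_rank(system.topology))

# densify: evaluate the fitted splines at ~300 time points before binning
sm = dx.smooth_series(reported)
tf = np.linspace(reported[0].time[0], reported[0].time[-1], 300)
cols = {m: sm.interpolants[("yeast-like", m)](tf) for m in reported[0].metabolites}
dense = dx.TimeSeriesSet(
    [dx.TimeSeries("yeast-like", tf, pd.DataFrame(cols))],
    interpolants=sm.interpolants,
)
slopes = dx.estimate_slopes(dense)

bins = dx.bin_fixed_variable(
    dense, slopes, "X3", "X4", "X4", width=0.03, volume=V_INT
)
pairs = dx.filter_pairs(dx.extract_pairs(bins), threshold=0.3)
rel = dx.merge_pairs(pairs)
v4_curve = dx.anchor_curve(rel, "zero_at_zero")  # trehalose starts near zero
print(
    f"v4 inference: {bins.occupied} bins ({bins.n_retained} retained), "
    f"{len(pairs)} pairs, curve on X4 in "
    f"[{v4_curve.x[0]:.2f}, {v4_curve.x[-1]:.2f}]"
)

# partner flux v3 from the X4 equation, then the full per-time-point solve
known = {"v4": v4_curve}
v3_series = dx.compute_partner_flux(
    system.topology, "X4", sm, slopes_29 := dx.estimate_slopes(sm), known,
    allow_extrapolation=True,
)["yeast-like"]
known["v3"] = v3_series
profiles = dx.solve_flux_system(
    dx.assemble_flux_equations(
        system.topology, sm, slopes_29, known=known, allow_extrapolation=True
    )
)
print(f"solved fluxes: {sorted(profiles.profiles['yeast-like'].columns)}")

v7 = 0.05 * profiles.profiles["yeast-like"]["v5"].to_numpy()
x7 = dx.integrate_flux(reported[0].time, v7, initial=0.0, volume=V_INT)
x7_true = truth[0].values["X7"].to_numpy()
print(
    f"reconstructed X7 endpoint: {x7[-1]:.2f} mM (truth {x7_true[-1]:.2f}); "
    f"max deviation {np.abs(x7 - x7_true).max():.2f} mM"
)
# The withheld pentose-phosphate pool is recovered by point-by-point
# integration of the 5%-of-glycolysis flux, without ever measuring it.
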