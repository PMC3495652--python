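# dynflux

Model-free estimation of dynamic metabolic flux profiles from concentration
time-series data, for underdetermined stoichiometric systems.

## The problem

Given metabolite time courses `X_i(t_j)` and a known pathway topology, each
mass balance

```
V_i · dX_i/dt = Σ_j c_ij · v_j
```

links the measurable slopes to the unknown reaction fluxes `v_j` (with
`c_ij` the signed stoichiometric coefficients and `V_i` optional compartment
volumes).  Substituting spline-estimated slopes `S_i(t_j)` for the
derivatives decouples the ODE system into one *linear* system per time
point, `diag(V)·s(t_j) = N·v(t_j)`, which is solvable only if the flux
system has full rank.  Most real pathways have more fluxes than metabolites,
so the per-time-point solution space is infinite.

`dynflux` closes that gap without assuming any rate-law forms, using only
information already in the data.  For an equation with one influx and one
efflux, a flux is a *function* of its substrate: whenever the influx's
argument `X_in` revisits (nearly) the same value, the influx takes (nearly)
the same unknown value `v_in_const`.  Binning the time points on `X_in`
therefore yields, within each bin, points

```
(X_out , −V_i·S_i(t_j))  =  (X_out , v_out(X_out) − v_in_const)
```

that trace the efflux curve up to one unknown vertical offset per bin.
Adjacent points in a bin form pairs; pairs narrower than a separation
threshold `d_r` (default 0.2) are discarded; the surviving pairs are merged
into one continuous relative curve by choosing vertical shifts; and a single
anchoring step (zero flux at zero substrate, one known flux value, or a
joint rate-law + offset fit) fixes the remaining constant.  The resulting
flux-vs-metabolite look-up curve re-enters the linear algebra as a known
flux, the partner flux in the same equation follows directly from the
slopes, and once enough fluxes are determined the rest of the system is
solved per time point.  Optionally, canonical rate laws (Michaelis–Menten
`V_max·x/(K_M+x)`, Hill `V_max·x^h/(K^h+x^h)`, power law `γ·Π x_i^{f_i}`)
are fitted to each inferred curve and ranked by a small-sample-corrected
information score.

The package ships three synthetic benchmark systems with exact flux truth —
an oscillating linear chain with feedback inhibition, a branched pathway
with feedforward activation and feedback inhibition, and a two-compartment
yeast-like glycolysis/trehalose system with withheld variables — so the
whole pipeline is testable without external data.

## Worked example

```python
import numpy as np
import dynflux as dx

def v3_true(x):                       # Hill law generating v3 (unknown in practice)
    return 5.0 * x**3 / (8.0 + x**3)

ts, _ = dx.simulate_linear_feedback()      # 50 samples, spacing 0.2
sm = dx.smooth_series(ts)
slopes = dx.estimate_slopes(sm)

bins  = dx.bin_fixed_variable(sm, slopes, "X1", "X2", "X2", width=0.05)
pairs = dx.filter_pairs(dx.extract_pairs(bins), threshold=0.2)
rel   = dx.merge_pairs(pairs)
curve = dx.anchor_curve(rel, "known_point", x0=1.0, v0=v3_true(1.0))
print(dx.curve_accuracy(curve, v3_true, metric="sum_sq"))
print(dx.fit_rate_law(curve, "hill").parameters)
```

Running `python examples/01_infer_flux_curve.py` prints:

```
3 equations, 4 unknown fluxes, rank 3, deficiency 1 (underdetermined)
bins: 29 occupied, 11 retained; pairs: 10 survive the 0.2 separation filter
anchored v3 curve: 17 support points on X2 in [1.03, 3.01]
summed squared deviation from the true Hill law: 0.0424
Hill fit: V_max=5.10 (true 5), K=2.01 (true 2), h=2.98 (true 3)
```

The flux system is underdetermined by one; binning the repeated X1 values
groups time points where the influx v2 is constant; the ten surviving pairs
merge into a sigmoid flux-vs-X2 relation whose squared deviation from the
generating Hill law is 0.042 — and fitting that curve recovers the true
kinetic parameters to within 2 % without the rate law ever being assumed.

Further examples: `examples/02_composite_pipeline.py` (one-call pipeline
with decision log and coverage diagnostic), `examples/03_branched_multivariate.py`
(multi-dataset designs and joint binning on two variables),
`examples/04_yeast_missing_data.py` (two compartments, a fixed 5 % pathway
diversion, and reconstruction of an unmeasured pool by flux integration).

## Command line

Every pipeline stage is also a subcommand of the `dynflux` CLI:

```bash
dynflux generate --system linear-feedback --out data/
dynflux rank --topology examples/linear_chain.yaml
dynflux infer --topology examples/linear_chain.yaml data/dataset-1.csv \
    --equation X2 --fixed-var X1 --out-var X2 \
    --anchor known_point --x0 1.0 --v0 0.5556 --out curve.csv
dynflux run --config run.yaml
```

Topologies are YAML documents (`format: dfe-topology/1`) declaring
metabolites (with volumes and measured flags), fluxes with their
dependencies, per-metabolite signed flux terms, and linear flux constraints;
composite runs use a `dfe-run/1` config.

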