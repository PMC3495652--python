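"""Run the full pipeline in one call and inspect its decision log.

The composite run smooths, differentiates, checks the rank, infers fluxes
until the system is solvable, back-calculates partners, solves the rest per
time point, and fits candidate rate laws - recording every decision.
"""

import numpy as np

import dynflux as dx
from dynflux.pipeline import AnchorSpec, RunConfig, report_coverage, run_pipeline

v3_at_1 = 5.0 / 9.0  # known flux value used to anchor the inferred curve

config = RunConfig(
    topology=dx.linear_feedback_system().topology,
    generate="linear-feedback",
    target_equations=("X2",),  # prefer the equation v2 - v3 (as a modeller would)
    anchors={"v3": AnchorSpec(strategy="known_point", x0=1.0, v0=v3_at_1)},
    fit_families=("michaelis_menten", "hill", "power_law"),
)
result = run_pipeline(config)

for record in result.inferences:
    print(
        f"inferred {record.inferred_flux} from the {record.target_metabolite} "
        f"equation ({len(record.pairs_kept)} pairs, anchor "
        f"{record.curve.anchor_method}); partner flux: {record.partner_flux}"
    )
print("provenance:", result.fluxes.provenance)

frame = result.fluxes.profiles["dataset-1"]
truth = dx.simulate_linear_feedback()[1].profiles["dataset-1"]
for flux in ("v2", "v3", "v4"):
    err = np.abs(frame[flux].to_numpy() - truth[flux].to_numpy())[2:-2].max()
    print(f"{flux}: max interior deviation from truth = {err:.3f}")

best = result.fits["v3"][0]
print(f"best rate-law family for v3: {best.family} {best.parameters}")
print("coverage:", report_coverage(result)["v3"])
# Interior flux profiles track the ground truth to better than ~0.1 model
# units, and the ranking identifies the Hill family that generated v3.
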