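"""Sweep cell eccentricity and watch alignment track cell shape.

Three independent runs per eccentricity (as in the reference protocol);
mean MTSD decreases monotonically as the cell elongates, with the mean
direction locked to the long axis at high eccentricity.
"""

from mtalign import SimParams, sweep_eccentricity

result = sweep_eccentricity(
    widths=[492.0],
    eccentricities=[0.7, 0.8, 0.9, 0.95],
    params=SimParams(rng_seed=7),
    runs_per_point=3,
)

print(result.summary.round(2).to_string(index=False))
print()
print("Per-run detail (MTDEV = angle between array direction and long axis):")
cols = ["eccentricity", "run", "mtsd_deg", "mtdev_deg", "convergence_s"]
print(result.runs[cols].round(1).to_string(index=False))
print()
print("Rounder cells (e=0.7) hold weakly ordered arrays; elongating the cell")
print("tightens the array onto the long axis (MTDEV of a few degrees) and")
print("drives the MTSD down toward the high-alignment regime.")
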