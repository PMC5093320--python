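"""Simulate microtubule self-organization in one elongated cell.

Runs the full angle-dependent collision rules (zip below 30 degrees,
cross/catastrophe above) in a cell of eccentricity 0.9 and prints how
aligned the steady-state array is (MTSD), how close its mean direction lies
to the cell's long axis (MTDEV), and how quickly alignment stabilized.
"""

from mtalign import SimParams, build_cell_domain, collision_angle_summary, run_simulation

domain = build_cell_domain(492.0, 0.9, "area_matched")
params = SimParams(rng_seed=42)
result = run_simulation(domain, params)

print(f"cell: {domain.width:.0f} x {domain.length:.0f} nm, area {domain.area/1e6:.2f} um^2")
print(f"events simulated: {result.n_events}")
print(f"MTSD  (alignment, 90 = unaligned): {result.mtsd:.1f} deg")
print(f"MTDEV (deviation from long axis):  {result.mtdev:.1f} deg")
print(f"time to stable alignment:          {result.convergence_time_s():.0f} s")
print()
print("Collision outcomes by angle category (boundary target):")
summary = collision_angle_summary(result.events)
bd = summary[summary.target == "boundary"]
print(bd.to_string(index=False))
print()
print("Shallow hits zip along the wall, steep hits trigger catastrophe —")
print("this angle selection is what channels the array onto the long axis.")
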