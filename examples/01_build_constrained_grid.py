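"""Enumerate the feasible reaction-condition grid.

The eight iodination parameters (substrate, chloramine and iodide
stoichiometry, solvent, iodine source, catalyst and loading, temperature)
define 253,440 raw combinations; the chemistry constraints — boiling-point
temperature caps, stoichiometric minimums, and the exclusion of reagent
pairings that play no mechanistic role — cut this to the feasible candidate
set every experiment is drawn from.
"""

from rxnopt import build_default_grid, exclude_substrate

grid = build_default_grid()
frame = grid.frame

n_nis = int((frame["iodine_source"] == "NIS").sum())
print(f"feasible grid points:      {len(grid)}")
print(f"  NIS route:               {n_nis}")
print(f"  chloramine route:        {len(grid) - n_nis}")
print(f"  per substrate:           {len(grid) // frame['alkyne'].nunique()}")

contracted = exclude_substrate(grid, "2-ethynyltoluene")
print(f"after excluding one substrate: {len(contracted)} points")

# Every point re-checks against the full rule set.
assert grid.recheck()
print("all points satisfy every constraint rule")
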