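"""Wild-type steady state: the nuclear Dorsal gradient and its two routes.

Integrates the calibrated reaction-diffusion network to steady state and
prints the total nuclear-Dl profile decomposed into Toll-independent direct
flow (nDl0, uniform along the axis) and the Toll-activated route (nDl*,
ventrally peaked).  The ventral peak sits near 1 because concentrations are
expressed in units of the ventral wild-type nuclear-Dl level.
"""

from dorsalgrad import (
    ModelParameters,
    SpatialGrid,
    decompose_nuclear,
    integrate_to_steady_state,
)

params = ModelParameters()
grid = SpatialGrid(50)
result = integrate_to_steady_state(params, grid)
print(f"converged at t = {result.t_final:g} (residual {result.residual:.2e})")

nDl0, nDlstar, total = decompose_nuclear(result.state)
print(f"{'x':>6} {'nDl_total':>10} {'nDl0':>8} {'nDl*':>8}")
for i in range(0, 50, 7):
    print(f"{grid.positions[i]:6.2f} {total[i]:10.4f} {nDl0[i]:8.4f} "
          f"{nDlstar[i]:8.4f}")

print(
    "\nThe Toll route dominates ventrally (x near 0) and vanishes dorsally;"
    "\ndirect flow contributes the same basal level to every nucleus."
)
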