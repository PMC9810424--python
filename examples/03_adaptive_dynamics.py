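"""Analyse the monomorphic trait dynamics: singular strategies and flow.

Treats the colony as one resident strategy and asks where the selection
gradient drives it, then classifies the resting points: an ESS means the
colony settles on one shared strategy; a branching point means disruptive
selection will split it.
"""

import numpy as np

from colonygames import EnvironmentParams, find_singular, streamline_field
from colonygames.adaptive import integrate_flow

env = EnvironmentParams(b1=20, b2=-6, w=0.3, beta=3)

for s in find_singular(env):
    x, y = s.location
    print(f"singular strategy at (x={x:.3f}, y={y:.3f}, z={1-x-y:.3f}): "
          f"{s.classification}  |grad|={s.gradient_norm:.1e}")

end = integrate_flow((1 / 3, 1 / 3), env)
print(f"flow from the simplex centre ends at "
      f"(x={end[0]:.3f}, y={end[1]:.3f}, z={1-end.sum():.3f})")

field = streamline_field(env, grid=11)
print(f"gradient field evaluated at {field.shape[0]} feasible nodes; "
      f"max |gradient| = {np.hypot(field[:, 2], field[:, 3]).max():.2f}")
# export `field` (x, y, dx, dy) to your plotting tool of choice for a
# streamline picture of the trait dynamics.
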