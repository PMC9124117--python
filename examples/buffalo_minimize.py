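"""Minimize benchmark functions with the buffalo-herd optimizer.

Each buffalo moves toward the herd-wide best (weighted by le1) and its own
personal best (le2); stagnation triggers a restart around the incumbent.
Both benchmarks have a known optimum of 0, so the printed best fitness is
the remaining error.
"""

import numpy as np

from graftsurv.abo import ABOConfig, minimize

sphere = lambda x: float(np.sum(np.asarray(x) ** 2))
shifted = lambda x: float(np.sum((np.asarray(x) - 1.3) ** 2))

config = ABOConfig(n_buffalo=20, max_iterations=200, bounds=(-5.0, 5.0), seed=0)

for name, objective in [("sphere", sphere), ("shifted quadratic", shifted)]:
    result = minimize(objective, 5, config)
    print(f"{name:18s} best_f={result.best_f:.2e}  "
          f"best_x={np.round(result.best_x, 3)}  restarts={result.n_restarts}")

result = minimize(sphere, 5, config)
drops = int(np.sum(np.diff(result.history) < 0))
print(f"history is non-increasing ({drops} strict improvements over "
      f"{len(result.history)} iterations)")
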