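"""Minimize benchmark functions with the Marine Predators Algorithm.

Runs the optimizer on the 10-D sphere and Rastrigin functions and
compares against pure random search at the same evaluation budget.  The
best fitness is the lowest objective value found (0 is the global
optimum for both); MPA should land orders of magnitude below random
search on the sphere and well below it on the multimodal Rastrigin.
"""

import numpy as np

from mpadbn import MPAConfig, SearchSpace, benchmark_objective, optimize

for name in ("sphere", "rastrigin"):
    bench = benchmark_objective(name, 10)
    space = SearchSpace(lb=bench.lb, ub=bench.ub)
    res = optimize(bench.fn, space, MPAConfig(n=25, Imax=300, seed=0))
    rng = np.random.default_rng(1)
    draws = space.lb + rng.uniform(size=(res.evals, 10)) * (space.ub - space.lb)
    random_best = min(bench.fn(x) for x in draws)
    print(f"{name:10s}  MPA best {res.best_f:.3e}  "
          f"random search best {random_best:.3e}  ({res.evals} evals each)")
print("history is non-increasing:", bool(np.all(np.diff(res.history) <= 0)))
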