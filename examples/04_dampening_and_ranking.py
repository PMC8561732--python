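"""Compare input disorder models: sampling dampening and R_free ranking.

Adding hierarchy levels to the input disorder model systematically
reduces the fluctuations the simulation needs to sample; the
overestimated pTLS baseline freezes the low-B core and pays for it in
cross-validation R.
"""

import numpy as np

from microer import conditions
from microer.engine import run_ensemble_refinement

fixture = conditions.standard_fixture(seed=1)
model = fixture.mean_model
b = model.b_iso
core = np.argsort(b)[: model.n_atoms // 10]

print(f"{'disorder model':12s} {'r_work':>7s} {'r_free':>7s} "
      f"{'mean rmsf':>10s} {'core rmsf':>10s}")
for label, dm, levels in conditions.standard_variants(fixture):
    cfg = conditions.standard_er_config(rng_seed=0, disorder=dm,
                                        disorder_levels=levels)
    res = run_ensemble_refinement(model, fixture.reflections, cfg)
    print(f"{label:12s} {res.final_r_work:7.3f} {res.final_r_free:7.3f} "
          f"{res.rmsf.mean():10.3f} {res.rmsf[core].mean():10.3f}")

print("\nReading the table: mean rmsf falls monotonically from 'none' to")
print("'L1+2+3' (the model explains more, the simulation samples less).")
print("pTLS shows similarly small fluctuations but a worse r_free: its")
print("core B factors are overestimated rather than well estimated.")
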