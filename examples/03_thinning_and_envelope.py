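"""Occurrence thinning and the surface range envelope.

Thinning caps records per 1-degree cell (here 5) to correct the spatial
bias of opportunistic collections.  The surface range envelope then
takes, per predictor, the [q, 1-q] quantile interval of presence values
(q = 0.025 ~ a 95% tolerance interval); pseudo-absences are sampled from
cells outside it.
"""

import numpy as np

from camsdm.envelope import fit_sre, sample_pseudoabsences, sre_predict
from camsdm.occurrences import extract_predictors, thin_per_cell
from camsdm.pipeline import BIOCLIM_PREDICTORS
from camsdm.synthetic import default_landscape

land = default_landscape(seed=1)
stack = land.stack.subset(BIOCLIM_PREDICTORS)

thinned = thin_per_cell(land.occurrences, cell_size=1.0, max_per_cell=5, seed=0)
print(f"thinning: {len(land.occurrences)} -> {len(thinned)} records "
      "(at most 5 per 1-degree cell)")

pres_rows, n_dropped = extract_predictors(thinned, stack)
sre = fit_sre(pres_rows[list(BIOCLIM_PREDICTORS)], quantile=0.025)
print("\nenvelope bounds (2.5%-97.5% of presence values):")
for name, (lo, hi) in sre.bounds.items():
    print(f"  {name:24s} [{lo:8.2f}, {hi:8.2f}]")

env = sre_predict(stack, sre)
inside = float(np.nanmean(env.values))
print(f"\n{100 * inside:.1f}% of the landscape lies inside the climate envelope")

pas = sample_pseudoabsences(stack, env, thinned, n_per_realization=len(pres_rows),
                            n_realizations=5, seed=0)
print(f"{len(pas)} pseudo-absence realizations of {len(pas[0].points)} points each, "
      "all outside the envelope")
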