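"""Compute rainfall-predictability indices from a 58-year monthly record.

The Hellmann-Eberle quotient Q is the wettest-year / driest-year ratio
of annual precipitation: Q near 1 means rainfall arrives reliably, large
Q means it is erratic.  The Ellenberg map flags the succulent-hostile
combination of scarce (< 500 mm/yr) *and* erratic (Q > 5) rainfall.
"""

import numpy as np

from camsdm.indices import EllenbergParams, annual_totals, ellenberg_index, hellmann_eberle
from camsdm.synthetic import default_landscape

land = default_landscape(seed=1)
series = land.precip_series
print(f"monthly record: {series.n_years} years x 12 months on {series.grid.shape} cells")

annual = annual_totals(series)
print(f"mean annual precipitation: {np.nanmean(annual.mean_annual.values):.0f} mm/yr")

quotient = hellmann_eberle(annual)
print(f"Hellmann-Eberle quotient: median {np.nanmedian(quotient.values):.2f}, "
      f"range {np.nanmin(quotient.values):.2f}-{np.nanmax(quotient.values):.2f}")

ellen = ellenberg_index(annual.mean_annual, quotient, EllenbergParams())
flagged = float(np.nanmean(ellen.values))
print(f"Ellenberg index: {100 * flagged:.1f}% of cells are dry AND erratic "
      "(predicted hostile to stem succulents)")
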