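"""Mean and effective sterilizing doses across treatment ages.

The mean sterilizing dose drops the average (z = 0) reserve straight to
the 1,000-follicle menopause threshold — sterilizing 50% of subjects.
The effective sterilizing dose (ESD) does the same for a subject at
z = +1.96, covering 97.5% of subjects.  Both fall with age because the
reserve to be destroyed shrinks.
"""

import numpy as np

from ovareserve import PoiCalculator, render_esd_chart

calc = PoiCalculator()
curve = calc.sterilizing_dose_curves(np.arange(0.0, 46.0, 5.0))
print(curve.to_frame().round(2).to_string(index=False))

path = render_esd_chart(np.arange(0.0, 46.0, 1.0), "esd_chart.png", calc)
print(f"\nChart written to {path}")
print("At birth ~16.4 Gy is needed to sterilize half of subjects; by age "
      "45 under 3 Gy suffices. The ESD line sits above the mean line "
      "because richer-than-average reserves need more dose.")
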