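"""Fit wedge quantile regressions and derive a biodiversity tipping point.

Simulates fish richness residuals with a wedge-shaped response to
alteration (true tipping point 0.4, up to 5 species lost), fits the 95th
percentile regression, derives the alteration threshold where the fitted
bound crosses zero, and propagates slope error into threshold bounds.
"""

import numpy as np
import pandas as pd

from eflow.ecology import derive_threshold, fit_quantile_models
from eflow.synthetic import simulate_fish_responses
from eflow.uncertainty import threshold_bounds

rng = np.random.default_rng(0)
ha = pd.Series(rng.uniform(0, 1, 500), index=[f"site{i}" for i in range(500)])
obs = simulate_fish_responses(ha, true_threshold=0.4, max_loss=5.0, seed=0)

df = pd.DataFrame(
    {
        "location_id": ha.index, "region": "R1", "huc4": "H1", "metric": "DL1",
        "alteration": ha.to_numpy(),
        "residual": [o.richness_residual for o in obs],
    }
)
fits, _ = fit_quantile_models(df, taus=(0.5, 0.95), min_n=30)
for fit in fits:
    t = derive_threshold(fit)
    line = (f"tau={fit.tau:.2f}: residual = {fit.beta0:+.2f} "
            f"{fit.beta1:+.2f} x HA  (slope SE {fit.slope_se:.2f})")
    if t is not None and fit.beta1 < 0 and fit.beta0 > 0:
        lo, t_, hi = threshold_bounds(fit)
        line += f"  -> tipping point {t_:.3f} in [{lo:.3f}, {hi:.3f}]"
    else:
        line += f"  -> threshold {t}"
    print(line)
# The 95th-percentile bound tracks the wedge's upper envelope, so its zero
# crossing estimates the alteration beyond which the first native species
# is expected to be lost (truth here: 0.40). The median (tau=0.5) line runs
# through the residual scatter and crosses zero much earlier.
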