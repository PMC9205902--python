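"""Recovering an imposed learning-rate / Kalman-gain correlation.

In the correlated surrogate variant the slow learning rate is set to
0.3 x K per run.  After hierarchical fitting, regressing per-run
posterior-mean b_s on posterior-mean K recovers a positive slope; note
that shrinkage and posterior uncertainty in K attenuate it below the
generating 0.3 at small problem sizes (this demo uses 12 epoch-level
runs; the full validation uses 40 trial-level runs).
"""

import numpy as np

from adapt2state import SamplerConfig, fit_hierarchical, generate_correlated_set
from adapt2state.analysis import gain_learning_regression

dataset = generate_correlated_set(12, factor=0.3, seed=9)
truth = dataset.truth_array()
result = fit_hierarchical(dataset.runs, "two",
                          config=SamplerConfig(chains=2, warmup=400,
                                               draws=400, seed=2))

reg = gain_learning_regression(result.subject_means()[:, 2],
                               result.gain_means())
lo, hi = reg.pooled.slope_ci
print(f"generating relation: b_s = 0.300 x K   (truth b_s range "
      f"{truth[:, 2].min():.3f}-{truth[:, 2].max():.3f})")
print(f"fitted slope: {reg.pooled.slope:.3f}  95% CI ({lo:.3f}, {hi:.3f})  "
      f"R^2 {reg.pooled.r_squared:.3f}")
print("\nAt this demo scale the slope is positive but uncertain; the "
      "full-size validation (40 trial-level runs) tightens the CI around "
      "an attenuated-but-clear positive slope, while an uncorrelated "
      "dataset yields a CI containing 0.")
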