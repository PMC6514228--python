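"""Calibrate GRM item parameters from raw responses and check recovery.

Simulates 1,000 respondents on a known 20-item bank, re-estimates the
parameters by marginal-maximum-likelihood EM, and compares estimates with
the generating truth.
"""

import numpy as np

from catia import SyntheticDesign, calibrate_grm, generate_bank, simulate_responses

design = SyntheticDesign(n_persons=1000, n_items=20, seed=3)
truth = generate_bank(design)
rng = np.random.default_rng(3)
responses = simulate_responses(truth, rng.standard_normal(1000), rng)

result = calibrate_grm(responses)
r = np.corrcoef(truth.a_values, result.bank.a_values)[0, 1]
rmse = np.sqrt(((truth.b_values - result.bank.b_values) ** 2).mean())

print(f"EM converged in {result.n_cycles} cycles; -2LL = {result.neg2ll:.1f}")
print(f"AIC = {result.fit['aic']:.1f}, BIC = {result.fit['bic']:.1f}")
print(f"slope recovery  corr(a_true, a_hat) = {r:.3f}")
print(f"threshold recovery  RMSE(b) = {rmse:.3f}")
print(
    "\nCorrelations above 0.9 and threshold RMSE near 0.1 are typical at "
    "n = 1,000: the sample sizes used for real bank construction support "
    "stable GRM calibration."
)
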