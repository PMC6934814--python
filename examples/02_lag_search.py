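"""Exhaustive precedence-period search with a known answer.

On a dataset whose response is an exact linear function of lag-shifted
availabilities, the scan over all (max_lag+1)^5 lag combinations must find
the true lags with a perfect fit (R = 1).
"""

from dietlag import (
    FULL_SPAN,
    NUTRIENTS,
    AnalysisConfig,
    count_lag_combinations,
    global_optimize,
    synth_validation_dataset,
)

series, r, truth = synth_validation_dataset(seed=0, max_lag=5, noise_sd=0.0)
config = AnalysisConfig(max_lag=5, periods=(FULL_SPAN,))
print(f"scanning {count_lag_combinations(config.max_lag, 5)} lag combinations ...")

result = global_optimize(series, r, FULL_SPAN, config)
print("true lags:     ", dict(zip(NUTRIENTS, truth.true_lags)))
print("recovered lags:", dict(zip(NUTRIENTS, result.optimal_lags)))
print(f"R_optimal = {result.r_optimal:.12f}  (1.0 = the fit explains the "
      "response exactly at the true lags)")
fit = result.optimal_fit
print(f"calculator equation: R = {fit.alpha:+.4f} "
      + " ".join(f"{b:+.5f}*{n}" for n, b in zip(NUTRIENTS, fit.betas)))
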