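"""Confidence sequencing ("stars") for estimated precedence periods.

Three criteria each nominate a lag per nutrient: the lag in the globally
optimal vector, the lag maximizing the mean fit statistic over all other
nutrients' lags (Rmean), and the lag minimizing the spread of that
statistic. Tight agreement earns more stars: SD in [0,2) -> ***, [2,5) ->
**, [5,8) -> *, beyond -> none.
"""

from dietlag import (
    FULL_SPAN,
    AnalysisConfig,
    confidence_table,
    global_optimize,
    synth_validation_dataset,
)

series, r, truth = synth_validation_dataset(seed=0, max_lag=5, noise_sd=0.02)
config = AnalysisConfig(max_lag=5, periods=(FULL_SPAN,))
result = global_optimize(series, r, FULL_SPAN, config)

print(f"{'nutrient':<14} {'true':>4} {'optimal':>7} {'maxRmean':>8} "
      f"{'minSD':>5} {'mean':>5} {'sd':>5}  stars")
for summary, true_lag in zip(confidence_table(result), truth.true_lags):
    print(f"{summary.nutrient:<14} {true_lag:>4} {summary.lag_at_r_optimal:>7} "
          f"{summary.lag_at_max_rmean:>8} {summary.lag_at_min_sd:>5} "
          f"{summary.mean_precedence:>5.1f} {summary.sd_precedence:>5.2f}  "
          f"{summary.stars}")
# when the three criterion lags agree, the precedence period is considered
# well determined; disagreement (larger sd) lowers the star level
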