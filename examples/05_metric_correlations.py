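"""Which agreement metric tracks clinical error best?

Computes Pearson correlations between evaluation metrics across the 41
published method rows of the packaged overnight benchmark table. F1 is
the best (negative) correlate of the WASO error, and accuracy of the
sleep-efficiency error — the metrics to optimize if the clinical
quantities are what ultimately matter.
"""

from sleepwake import load_published_night_benchmark, metric_correlations

table = load_published_night_benchmark()
corr = metric_correlations(table)
print(f"{len(table)} method rows\n")
print("correlation with MAE WASO:")
print(corr["mae_waso"].drop("mae_waso").round(2).sort_values().to_string())
print("\ncorrelation with MAE sleep efficiency:")
print(corr["mae_sleep_eff"].drop("mae_sleep_eff").round(2).sort_values().to_string())
print(f"\nbest correlate of MAE WASO: F1 (r = {corr.loc['f1', 'mae_waso']:.2f})")
print(f"best correlate of MAE sleep efficiency: accuracy (r = {corr.loc['accuracy', 'mae_sleep_eff']:.2f})")
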