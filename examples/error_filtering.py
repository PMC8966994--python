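"""Screening fixes by the device's self-reported error estimate.

The device reports a per-fix error estimate (metres, 67% probability).
When that estimate tracks the realised error (high-frequency schedule),
dropping the few percent of fixes with the largest estimates removes
most genuinely inaccurate positions (> 10 m). When it is uninformative
(sparse schedule), the same procedure removes data at random.
"""

from gpscal import (
    INTERVAL_PRESETS,
    SimConfig,
    annotate_errors,
    efficacy_frame,
    simulate_stationary,
)

for name in ("1min", "60min"):
    cfg = SimConfig(n_devices=1, span_hours=72.0, seed=3,
                    **INTERVAL_PRESETS[name])
    fixes, _ = simulate_stationary(cfg)
    records = annotate_errors(fixes, cfg.reference)
    df = efficacy_frame(records, [0.01, 0.03, 0.05, 0.10])
    h = df[df.axis == "horizontal"]
    rho = INTERVAL_PRESETS[name]["gpserror_reliability"]
    print(f"--- {name} schedule (reported-error reliability {rho}) ---")
    print(h[["fraction_removed", "n_after", "n_inaccurate_after",
             "prop_inaccurate_after", "pct_inaccurate_eliminated"]]
          .round(3).to_string(index=False))
    print()

print("pct_inaccurate_eliminated is the share of originally inaccurate")
print("(> 10 m) positions removed. Near 1.0 on the 1-min schedule the")
print("metric is a usable screen; on the 60-min schedule it hovers near")
print("the removal fraction itself, i.e. no better than random deletion.")
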