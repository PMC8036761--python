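"""Yeast proliferation monitoring and doubling-time estimation.

Simulates an 18 h four-channel proliferation experiment (lag 5 h,
doubling time 90 min, 10 g/L glucose), runs the slope pipeline per
channel, segments the growth phases, and recovers the doubling time
with the joint lagged-logistic fit.
"""

from thermopulse import (
    PulseProtocol,
    fit_growth_multichannel,
    multichannel_experiment,
    phase_segmentation,
    proliferation_scenario,
    slope_series,
)

scenario = proliferation_scenario(od_start=0.2, glucose_g_l=10.0)
protocol = PulseProtocol(cooling_time=300.0, total_duration=18 * 3600.0)

channels = multichannel_experiment(scenario, protocol, seed=42)
series = []
for spec, records in channels:
    s = slope_series(records, spec)
    series.append(s)
    print(
        f"channel Rinit={spec.r_ref:4.1f} ohm: {len(s)} pulses, "
        f"final pct change {s.pct_change[-5:].mean():+.2f} %, min R^2 {s.r2.min():.3f}"
    )

seg = phase_segmentation(series[0])
print(f"\nphases (channel 1): lag ends ~{seg.lag_end:.1f} h", end="")
if seg.has_stationary:
    print(f", stationary from ~{seg.stationary_start:.1f} h")
else:
    print(", stationary phase not yet reached")

fit = fit_growth_multichannel(series)
print(f"joint growth fit: rate {fit.rate:.3f} 1/h  ->  doubling time "
      f"{fit.doubling_time_min:.1f} min (ground truth 90 min)")
print(f"fitted lag {fit.lag_estimate:.1f} h (ground truth 5 h), "
      f"amplitude {fit.amplitude:.2f} %")
print("The percent-change curve reproduces the lag / exponential /")
print("stationary shape of the culture; its exponential-limit rate gives")
print("the doubling time, pooled across the four sensor channels.")
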