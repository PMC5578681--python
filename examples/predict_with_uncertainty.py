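"""Posterior rate predictions with credible bands.

After fitting, the rate surface Lambda[t, u] has a full posterior; this
example prints the posterior mean and a Monte-Carlo 95% credible band for one
unit over a stretch of stimulus time, next to the true simulated rate.
"""

import stimtag as st

params = st.benchmark_preset(seed=3, unit_scale=0.3, time_scale=0.15)
table, truth = st.simulate_dataset(params, seed=3)
config = st.ModelConfig(n_features=3, n_restarts=2, seed=0)
result = st.fit(table, covariates=truth.covariates, config=config)

unit = 0
pred = st.predict_rates(
    result.state, slice(100, 120), unit,
    covariates=truth.covariates, n_draws=2000, seed=0,
)
dt = params.dt
print(f"unit {unit}, bins 100-119 (rates in spikes/s):")
print("t     truth   mean   [2.5%, 97.5%]")
covered = 0
for i, t in enumerate(pred["time_bin"]):
    true_hz = truth.rates[t, unit] / dt
    lo, hi = pred["lower"][i] / dt, pred["upper"][i] / dt
    covered += lo <= true_hz <= hi
    print(f"{t:4d}  {true_hz:6.2f}  {pred['mean'][i]/dt:6.2f}  [{lo:6.2f}, {hi:6.2f}]")
print(f"\n{covered}/20 true rates inside the 95% band")
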