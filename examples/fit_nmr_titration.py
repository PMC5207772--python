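"""Global 1:1 fit of a slow-exchange NMR titration.

Simulates a six-sample titration of a 15N-labeled beta subunit (fixed at
0.17 mol%) with an unlabeled alpha subunit at mole ratios 0-4, where complex
formation makes the free-subunit TROSY peaks fade.  Four peak traces are fit
jointly with one shared Kd, then refit with one peak excluded to show the
outlier workflow.
"""

from bicellefit import (
    BindingParameters,
    SimulationDesign,
    fit_slow_exchange_global,
    refit_excluding,
    simulate_titration,
)

TRUE_KD = 0.63  # mol%: a moderate-affinity heterodimer

series = simulate_titration(
    BindingParameters(kd=TRUE_KD),
    SimulationDesign(u0=0.17, noise_sd=0.05, seed=42),
    n_peaks=4,
)
result = fit_slow_exchange_global(series)

print(f"generating Kd : {TRUE_KD} mol%")
print(f"fitted Kd     : {result.kd:.3f} +/- {result.kd_stderr:.3f} mol% "
      f"({result.bound_flag})")
print(f"saturation    : {result.saturation_fraction:.2f} bound at the top point")
for label, est in result.per_peak.items():
    print(f"  {label}: reference intensity I0 = {est.value:.3f}")

refit = refit_excluding(series, [series.labels[0]])
print(f"refit minus {series.labels[0]}: Kd = {refit.kd:.3f} mol%")
print("-> one global Kd describes all peak traces; dropping a clean peak "
      "barely moves it.")
print("-> note the flag: the top point sits just below the 50% saturation "
      "threshold, so the fit is conservatively marked lower_bound even "
      "though the estimate is well determined.")
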