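"""Fit the hierarchical sex-ratio-transition model and summarize it.

Simulates a strong-signal scenario (so the inflation indicators are
identifiable), samples the posterior by MCMC, and prints the quantities a
demographic analysis would report: per-province inflation probabilities,
SRB estimates with 95% credible intervals, and transition start years with
the fertility level at which each transition began.
"""

import warnings

from srbtrans import (
    MCMCConfig,
    ModelConfig,
    NoInflationDrawsError,
    fit_mcmc,
    inflation_probability,
    simulate_dataset,
    start_year_summary,
    strong_signal_scenario,
    summarize_srb,
)

warnings.filterwarnings("ignore")  # keep the narrative output clean

ds = simulate_dataset(strong_signal_scenario(seed=3))
samples = fit_mcmc(ds.observations, ds.tfr, ModelConfig(),
                   MCMCConfig(n_chains=2, n_warmup=400, n_samples=1000, seed=1))
print("convergence:", {k: round(v, 3)
                       for k, v in samples.diagnostics["summary"].items()})

summary = summarize_srb(samples)
print(f"\n{'province':12s} {'P(inflation)':>12s} {'true':>5s} "
      f"{'SRB 2016 (95% CI)':>24s}")
for p, prov in enumerate(samples.provinces):
    prob = inflation_probability(samples, prov)
    med = summary.value(prov, 2016, 0.5)
    lo = summary.value(prov, 2016, 0.025)
    hi = summary.value(prov, 2016, 0.975)
    print(f"{prov:12s} {prob:12.0%} {ds.deltas[p]:>5d} "
          f"{med:.3f} ({lo:.3f}, {hi:.3f})")
print("-> P(inflation) is the share of posterior draws with the province's")
print("   spike-and-slab indicator on. The truly inflated provinces are")
print("   detected with probability ~1; note Province 6, where two surveys")
print("   happened to draw high ratios by chance and the posterior honestly")
print("   reports elevated (not certain) inflation probability.")

print("\ntransition start years (conditional on inflation):")
for p, prov in enumerate(samples.provinces):
    try:
        sy = start_year_summary(samples, prov, tfr=ds.tfr[prov])
    except NoInflationDrawsError:
        continue
    truth = f"true {ds.shapes[p].t0:.0f}" if ds.deltas[p] else "truly absent"
    print(f"  {prov}: {sy.median_year} ({sy.lower_year}, {sy.upper_year}), "
          f"TFR then {sy.tfr_at_median:.1f}  [{truth}]")
print("-> the start-year prior is located where each province's total")
print("   fertility rate first falls to the reference level (the fertility")
print("   squeeze), so the TFR-at-start-year column reads off that linkage.")
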