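"""Probabilistic SRB projection to 2050.

Fits the model on a synthetic study, then forward-simulates every
posterior draw: the log-scale AR(1) fluctuation is extended by simulation
and each draw's trapezoid is evaluated through the horizon, so transitions
that start in the future contribute with their posterior probability.
"""

import warnings

from srbtrans import (
    MCMCConfig,
    ModelConfig,
    fit_mcmc,
    max_inflation_year,
    project_srb,
    simulate_dataset,
    strong_signal_scenario,
    transition_data_coverage,
)

warnings.filterwarnings("ignore")

ds = simulate_dataset(strong_signal_scenario(seed=3))
samples = fit_mcmc(ds.observations, ds.tfr, ModelConfig(),
                   MCMCConfig(n_chains=2, n_warmup=400, n_samples=1000, seed=1))
proj = project_srb(samples, horizon_year=2050, seed=2)

print(f"{'province':12s} {'peak year':>9s} {'peak SRB':>9s} "
      f"{'SRB 2050 (95% CI)':>22s} {'back to baseline':>17s}")
for prov in samples.provinces:
    year, value = max_inflation_year(proj, prov)
    row = proj.for_province(prov)
    last = row[row["year"] == 2050].iloc[0]
    conv = proj.convergence_year(prov)
    print(f"{prov:12s} {year:9d} {value:9.3f} "
          f"{last['quantile_0.5']:.3f} ({last['quantile_0.025']:.3f}, "
          f"{last['quantile_0.975']:.3f}) {str(conv):>17s}")
print("-> every trapezoid has finite support, so all median trajectories")
print("   return to the 1.049 national baseline; provinces whose transition")
print("   is still young peak later and converge later.")

cov = transition_data_coverage(samples, ds.observations)
print(f"\ndata cover {cov.mean_years_covered:.1f} of "
      f"{cov.mean_length:.1f} transition years on average "
      f"({cov.mean_fraction:.0%})")
print("-> the rest of each transition is informed by the hierarchical priors,")
print("   which is why projection uncertainty grows beyond the data window.")
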