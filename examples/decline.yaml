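# End-to-end demo: simulate a collapsed population, report diversity, run the
# simple engine on each site, and the hierarchical engine with epoch dating.
seed: 11
output_dir: decline_out
simulate:
  model: {kind: decline_exponential, N0: 50, N1: 5000, ta: 100}
  n_per_site: {SA: 15, TU: 15}
  n_loci: 12
samples:
  - {name: SA, sites: [SA]}
  - {name: pooled, sites: [SA, TU], n: 20}
stats:
  n_permutations: 1000
model_a:
  n_runs: 2
  mcmc: {n_iterations: 200000, thinning: 100, n_chains: 2}
model_b:
  n_runs: 1
  mcmc: {n_iterations: 300000, thinning: 150, n_chains: 2}
epochs:
  generation_times: [8, 25]
  window: 500
  horizon: 50000
burnin_fraction: 0.25
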