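"""Two-genotype chemostat competition and the Price-equation decomposition.

The genotype with the lower break-even substrate concentration
S* = K D / (u_max - D) excludes the other.  The Price equation splits the
rate of change of mean fitness into a selection (variance) term and an
environmental (mean-change) term; their near-cancellation is why the
population mean growth rate stays pinned near D (quasi steady state) even
while genotype proportions change dramatically.
"""

import numpy as np

import fluxsel as fx

params = fx.ChemostatParams(dilution_rate=0.12, max_growth_rate=0.40)
_, _, x_star, _ = fx.steady_state(params, (400.0, np.inf))
ens = fx.GenotypeEnsemble(
    u_max=np.array([0.40, 0.35]), x0=np.full(2, x_star / 2),
    params=params, half_sat=5.0, genotype_ids=["fast", "slow"],
)
s_star = fx.break_even_substrate(ens.u_max, 5.0, 0.12)
print(f"break-even substrate: fast {s_star[0]:.3f} uM, slow {s_star[1]:.3f} uM")

res = fx.simulate_ensemble(
    ens, fx.FeedSchedule(kind="static", reservoir_as=400.0),
    t_end=1000.0, n_points=2001)
price = fx.price_decomposition(res)
for t in (0, 100, 300, 1000):
    i = np.searchsorted(res.time, t)
    i = min(i, len(res.time) - 1)
    print(f"t = {res.time[i]:6.1f} h  p_fast = {res.proportions[0, i]:.4f}  "
          f"mean growth = {price['mean_fitness'][i]:.5f} /h  "
          f"Var(lambda) = {price['variance'][i]:.2e}")
print(f"max |Price identity residual| = "
      f"{np.max(np.abs(price['residual'][2:-2])):.2e} /h^2")
print("The fast genotype fixes; the mean growth rate never leaves the "
      "neighborhood of D = 0.12/h, and the Price identity closes to "
      "integration accuracy.")
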