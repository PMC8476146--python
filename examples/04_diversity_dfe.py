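"""Diversity erosion and the distribution of fitness effects (DFE).

Static selection lets one extreme genotype sweep: Shannon diversity collapses
and the DFE grows a long beneficial tail.  The switching environment keeps
diversity high and its DFE compact.
"""

import fluxsel as fx
from fluxsel.diversity import diversity_rate, diversity_series
from fluxsel.fitness import dfe, relative_fitness

table, _ = fx.study_scenario(seed=42)
abund = fx.process_counts(table)
series = diversity_series(abund)

print("condition   H(t=0)  H(t=240)  slope (nats/h)      top share(240h)")
for cond in ("clim", "nlim", "switch"):
    sub = series[series["condition"] == cond]
    h0 = sub[sub["time"] == 0]["shannon"].mean()
    h1 = sub[sub["time"] == 240]["shannon"].mean()
    rate = diversity_rate(series, cond)
    top = fx.top_genotype_share(abund, abund.samples_for(cond)[-1])
    print(f"{cond:10s}  {h0:.3f}   {h1:.3f}   {rate['slope']:+.5f} "
          f"[{rate['ci_low']:+.5f}, {rate['ci_high']:+.5f}]   {top:.3f}")

for cond in ("clim", "switch"):
    f = relative_fitness(abund, cond)
    d = dfe(f, bin_width=0.002)
    print(f"{cond}: DFE sd = {d['sd']:.4f} /h, max = {d['max']:+.4f} /h, "
          f"min = {d['min']:+.4f} /h over {d['n']} genotypes")
print("A top-genotype share above 0.5 with a DFE maximum near +0.04/h marks "
      "the static sweep; the switch condition shows neither.")
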