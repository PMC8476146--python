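"""Cluster the short-term fitness profiles of oscillatory genotypes.

Piecewise fitness (Delta log abundance between consecutive samples / 24 h) of
the periodic-class genotypes is z-scored per genotype and clustered with
Ward linkage into four behavioral groups distinguished by phase.
"""

import fluxsel as fx
import fluxsel.trajectory_models as tm
from fluxsel.fitness import (fitness_variance_series, piecewise_fitness,
                             piecewise_from_abundance)

table, _ = fx.study_scenario(seed=42)
abund = fx.process_counts(table)

print("variance of model-predicted piecewise fitness (x 1e4, per interval):")
for cond in ("clim", "switch"):
    cond_fits = tm.fit_genotypes(abund, cond, period=60.0)
    pred = tm.predicted_log_abundance(abund, cond_fits, cond)
    v = fitness_variance_series(piecewise_fitness(pred)) * 1e4
    print(f"{cond:8s} " + " ".join(f"{x:5.2f}" for x in v))
print("Short-term fitness variance in the switch condition is an order of "
      "magnitude above static C-lim: oscillatory genotypes carry large "
      "piecewise fitness that cancels over the full course.")

fits = tm.fit_genotypes(abund, "switch", period=60.0)
periodic_ids = fits.index[fits["klass"] == "periodic"]
pw = piecewise_from_abundance(abund, "switch")

scaled, constant_flags = fx.scale_profiles(pw, subset=periodic_ids)
result = fx.cluster_profiles(scaled, k=4)
print(f"\nclustered {len(scaled)} oscillatory genotypes into k=4 groups "
      f"(silhouette {result.silhouette:.3f}):")
print(result.labels.value_counts().sort_index().to_string())
print("Clusters are numbered by the interval at which their centroid profile "
      "peaks, i.e. by oscillation phase.")
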