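"""Cell-free nutrient dynamics under a switching feed.

Integrates the chemostat ODE with cell density fixed at zero and a feed that
alternates between nitrogen-limited and carbon-limited media every 30 hours.
Even though the feed switches instantaneously, the vessel concentrations relax
exponentially (first-order kinetics at rate D), producing smooth oscillations.
"""

import numpy as np

import fluxsel as fx

params = fx.ChemostatParams(dilution_rate=0.12)
schedule = fx.FeedSchedule(
    kind="switch",
    reservoir_as=fx.NLIM_MEDIA["ammonium_sulfate_um"],    # N-lim phase first
    reservoir_g=fx.NLIM_MEDIA["glucose_um"],
    alt_reservoir_as=fx.CLIM_MEDIA["ammonium_sulfate_um"],
    alt_reservoir_g=fx.CLIM_MEDIA["glucose_um_recipe"],   # 0.08% w/v reading
    switch_half_period=30.0,
)
initial = fx.ChemostatState(s_as=400.0, s_g=fx.NLIM_MEDIA["glucose_um"], x=0.0)
res = fx.simulate(params, schedule, initial, t_end=240.0, n_points=961)

half_life = np.log(2) / params.dilution_rate
print(f"dilution rate D = {params.dilution_rate} /h "
      f"(relaxation half-life {half_life:.2f} h)")
for t in (29.9, 35.0, 45.0, 59.9):
    s_as = np.interp(t, res.time, res.s_as)
    print(f"t = {t:5.1f} h   ammonium sulfate = {s_as:10.1f} uM")
print("After the switch at t = 30 h the vessel drifts from the N-lim level "
      "(400 uM) toward the C-lim reservoir (37 mM) with ~5.8 h half-life; "
      "it never jumps, which is why cells experience gradual fluctuation.")
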