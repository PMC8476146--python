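"""Experiment-design summary utilities: media recipes and back-of-envelope checks.

Small closed-form quantities used when planning or auditing a chemostat
selection experiment on the pooled yeast deletion collection: the expected de
novo mutation load over the experiment, the elemental nitrogen delivered by a
pulse bolus, and weight/volume-to-molar media conversions.
"""

from __future__ import annotations

__all__ = [
    "expected_mutation_load",
    "nitrogen_equivalent",
    "percent_wv_to_millimolar",
    "CLIM_MEDIA",
    "NLIM_MEDIA",
]

#: Nitrogen atoms per molecule for the nitrogen sources used in pulse feeds.
_N_ATOMS = {
    "ammonium_sulfate": 2,  # (NH4)2SO4
    "glutamine": 2,         # C5H10N2O3 (amide + amine nitrogen)
    "ammonium": 1,
}

#: Nominal molar mass of glucose (g/mol) for media conversions.
GLUCOSE_MOLAR_MASS = 180.0

def expected_mutation_load(rate_per_cycle: float = 2.7e-3, generations: float = 40) -> float:
    """Expected de novo mutations per genome over a selection experiment.

    With a per-replication-cycle genomic mutation rate ``rate_per_cycle`` and
    ``generations`` rounds of replication, the expected load is simply their
    product (2.7e-3 * 40 = 0.108 for the default 240-hour design at D = 0.12/h).
    A load well below 1 justifies treating the pool as standing variation only.
    """
    if rate_per_cycle < 0 or generations < 0:
        raise ValueError("rate and generations must be non-negative")
    return rate_per_cycle * generations


def nitrogen_equivalent(compound: str, concentration_um: float) -> float:
    """Elemental nitrogen (uM) delivered by a bolus of a nitrogen source.

    A 40 uM ammonium-sulfate (or glutamine) bolus delivers 80 uM nitrogen,
    since both molecules carry two nitrogen atoms.
    """
    key = compound.lower().replace(" ", "_").replace("-", "_").replace("l_", "")
    if key not in _N_ATOMS:
        raise KeyError(f"unknown nitrogen source {compound!r}; known: {sorted(_N_ATOMS)}")
    if concentration_um < 0:
        raise ValueError("concentration must be non-negative")
    return _N_ATOMS[key] * concentration_um


def percent_wv_to_millimolar(percent: float, molar_mass: float = GLUCOSE_MOLAR_MASS) -> float:
    """Convert a % w/v recipe to millimolar: ``percent`` g per 100 ml.

    2% w/v glucose at 180 g/mol is 20 g/l / 180 g/mol = 111.1 mM.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    grams_per_liter = percent * 10.0
    return grams_per_liter / molar_mass * 1000.0


#: Study media, in uM of each nutrient.  The carbon-limited glucose
#: concentration has two mutually inconsistent readings at the recipe level
#: (a quoted 444.4 uM vs the 0.08% w/v recipe, which works out to 4444 uM);
#: both are provided and no default is endorsed — feed-schedule builders must
#: pick one explicitly.
CLIM_MEDIA = {
    "glucose_um_low": 444.4,
    "glucose_um_recipe": percent_wv_to_millimolar(0.08) * 1000.0,
    "ammonium_sulfate_um": 3.7e4,
}
NLIM_MEDIA = {
    "glucose_um": percent_wv_to_millimolar(2.0) * 1000.0,  # 2% w/v = 111.1 mM
    "ammonium_sulfate_um": 400.0,
}
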