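"""Synthetic barcode-sequencing data with the study's experimental structure.

The emulated experiment: a pooled library of ~4,000 uniquely barcoded
genotypes grown in chemostats under three selective regimes — static
carbon limitation, static nitrogen limitation, and a switching feed with a
60-hour period — in biological triplicate, sampled every 24 hours for
240 hours and quantified by sequencing barcode read counts at depths of
1e5–1e7 reads per library.

Genotype dynamics are specified on the log-abundance scale as one of five
trajectory classes (flat, linear, quadratic, cubic, periodic); proportions at
each sampling time are the renormalized exponentials of those curves, and
sequencing is modeled as multinomial sampling at the library depth, optionally
overdispersed by a Dirichlet (gamma-normalized) perturbation of the
proportions.  The generator returns its ground truth so downstream estimators
can be audited by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySpec",
    "CountTable",
    "make_design",
    "trajectories_to_proportions",
    "sample_counts",
    "study_scenario",
]

CLASSES = ("flat", "linear", "quadratic", "cubic", "periodic")


@dataclass(frozen=True)
class TrajectorySpec:
    """Log-abundance trajectory of one genotype.

    log n(t) = intercept + slope*t + quad*t^2 + cubic*t^3
               + sin_amp*sin(2*pi*t/period) + cos_amp*cos(2*pi*t/period)

    Only the coefficients implied by ``klass`` may be nonzero; ``period`` is
    in hours and must exceed twice the sampling interval for identifiability.
    """

    genotype_id: str
    klass: str = "flat"
    intercept: float = 0.0
    slope: float = 0.0
    quad: float = 0.0
    cubic: float = 0.0
    sin_amp: float = 0.0
    cos_amp: float = 0.0
    period: float = 60.0

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown trajectory class {self.klass!r}")
        allowed = {
            "flat": (),
            "linear": ("slope",),
            "quadratic": ("slope", "quad"),
            "cubic": ("slope", "quad", "cubic"),
            "periodic": ("slope", "sin_amp", "cos_amp"),
        }[self.klass]
        for name in ("slope", "quad", "cubic", "sin_amp", "cos_amp"):
            if name not in allowed and getattr(self, name) != 0.0:
                raise ValueError(f"{self.klass} spec must have zero {name}")
        if self.klass == "periodic" and self.period <= 0:
            raise ValueError("period must be positive")

    def log_abundance(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        y = self.intercept + self.slope * t + self.quad * t**2 + self.cubic * t**3
        if self.klass == "periodic":
            w = 2.0 * np.pi / self.period
            y = y + self.sin_amp * np.sin(w * t) + self.cos_amp * np.cos(w * t)
        return y


@dataclass
class CountTable:
    """Barcode read counts (genotypes x samples) with their sample design.

    ``counts`` is indexed by genotype_id — or by a (genotype_id, tag)
    MultiIndex when uptag/downtag resolution is kept — with one column per
    sample_id.  ``design`` is indexed by sample_id with columns
    ``condition``, ``replicate``, ``time`` and ``depth``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            missing = set(self.counts.columns) ^ set(self.design.index)
            raise ValueError(f"counts columns and design rows disagree: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def has_tags(self) -> bool:
        return isinstance(self.counts.index, pd.MultiIndex)

    @property
    def genotype_ids(self) -> pd.Index:
        if self.has_tags:
            return self.counts.index.get_level_values(0).unique()
        return self.counts.index

    def samples_for(self, condition=None, replicate=None) -> pd.Index:
        d = self.design
        mask = pd.Series(True, index=d.index)
        if condition is not None:
            mask &= d["condition"] == condition
        if replicate is not None:
            mask &= d["replicate"] == replicate
        idx = d.index[mask]
        return idx[np.argsort(d.loc[idx, "time"].to_numpy(), kind="stable")]

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.design.copy(), dict(self.meta))


def make_design(
    conditions=("clim", "nlim", "switch"),
    n_replicates: int = 3,
    times=tuple(range(0, 241, 24)),
    depth=1_000_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build the sample design table: conditions x replicates x times.

    ``depth`` may be a scalar target library depth (reads) or a callable
    ``depth(rng)`` drawn per sample (e.g. to emulate variable sequencing
    yield).  Deterministic given ``seed``.
    """
    times = list(times)
    if not times or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be nonempty and strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    seen = set()
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for t in times:
                key = (cond, rep, t)
                if key in seen:
                    raise ValueError(f"duplicate sample {key}")
                seen.add(key)
                d = depth(rng) if callable(depth) else depth
                rows.append(
                    {"sample_id": f"{cond}_r{rep}_t{int(t):03d}",
                     "condition": cond, "replicate": rep, "time": float(t),
                     "depth": int(d)}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def trajectories_to_proportions(specs, times) -> pd.DataFrame:
    """Genotype proportion matrix from log-abundance trajectories.

    Evaluates each spec's log-abundance at ``times``, exponentiates and
    renormalizes columnwise (a shared shift per time point leaves proportions
    unchanged, so the exponential is computed stably against overflow).
    """
    if len(specs) < 2:
        raise ValueError("need at least two genotypes")
    t = np.asarray(times, dtype=float)
    log_a = np.vstack([s.log_abundance(t) for s in specs])
    if not np.all(np.isfinite(log_a)):
        raise ValueError(
            "non-finite log abundance; rescale trajectory coefficients"
        )
    log_a = log_a - log_a.max(axis=0, keepdims=True)
    a = np.exp(log_a)
    props = a / a.sum(axis=0, keepdims=True)
    return pd.DataFrame(props, index=[s.genotype_id for s in specs], columns=t)


def sample_counts(
    proportions: pd.DataFrame,
    design: pd.DataFrame,
    overdispersion: float = 0.0,
    tags: bool = False,
    tag_split: float = 0.5,
    seed: int | None = None,
) -> CountTable:
    """Draw a read-count table from per-time genotype proportions.

    For each sample the counts are multinomial at the design depth.  With
    ``overdispersion`` phi > 0 each genotype's proportion is first multiplied
    by an independent Gamma(1/phi, phi) factor (mean 1, variance phi) and the
    vector renormalized — the gamma-multinomial analogue of negative-binomial
    counts with dispersion phi, so the per-count variance is roughly
    mu + phi mu^2.  The realized column sum always equals the depth.  With
    ``tags=True`` each genotype's count is split binomially into an uptag and
    a downtag row.

    ``proportions`` columns are times; each sample picks the column matching
    its design time.
    """
    if (design["depth"] <= 0).any():
        raise ValueError("library depths must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    p_by_time = {float(c): proportions[c].to_numpy() for c in proportions.columns}
    for sample_id, row in design.iterrows():
        p = p_by_time[float(row["time"])]
        if overdispersion > 0:
            w = rng.gamma(1.0 / overdispersion, overdispersion, size=len(p))
            p = p * w
        cols[sample_id] = rng.multinomial(int(row["depth"]), p / p.sum())
    counts = pd.DataFrame(cols, index=proportions.index, columns=design.index)
    if tags:
        up = rng.binomial(counts.to_numpy(), tag_split)
        down = counts.to_numpy() - up
        idx = pd.MultiIndex.from_product(
            [proportions.index, ["up", "down"]], names=["genotype_id", "tag"]
        )
        stacked = np.empty((2 * len(proportions), len(design)), dtype=int)
        stacked[0::2] = up
        stacked[1::2] = down
        counts = pd.DataFrame(stacked, index=idx, columns=design.index)
    counts.index.name = counts.index.name or "genotype_id"
    return CountTable(counts, design.copy(), meta={"overdispersion": overdispersion})


def _spec_classes(rng, n, condition, extreme_advantage, n_periodic, period):
    """Draw per-genotype trajectory specs for one condition."""
    specs: list[TrajectorySpec] = []
    ids = [f"g{i:04d}" for i in range(n)]
    intercepts = rng.normal(0.0, 0.1, size=n)
    # class proportions: static regimes are dominated by flat/linear dynamics
    # with curvature from the sweep; the switching regime is enriched for flat
    # genotypes and carries the oscillatory cohort
    if condition == "switch":
        n_per = n_periodic
        weights = {"flat": 0.45, "linear": 0.25, "quadratic": 0.15, "cubic": 0.15}
    else:
        n_per = 0
        weights = {"flat": 0.40, "linear": 0.30, "quadratic": 0.15, "cubic": 0.15}
    n_rest = n - n_per - (1 if condition != "switch" else 0)
    klasses = rng.choice(list(weights), size=n_rest, p=list(weights.values()))
    i = 0
    if condition != "switch":
        # one rare extreme-fitness genotype that sweeps the static population
        specs.append(TrajectorySpec(ids[i], "linear", intercept=intercepts[i],
                                    slope=extreme_advantage))
        i += 1
    for j in range(n_per):
        amp = rng.uniform(0.3, 0.8)
        phase = rng.uniform(0, 2 * np.pi)
        specs.append(TrajectorySpec(
            ids[i], "periodic", intercept=intercepts[i],
            slope=rng.normal(0.0, 5e-4),
            sin_amp=amp * np.cos(phase), cos_amp=amp * np.sin(phase),
            period=period,
        ))
        i += 1
    for klass in klasses:
        icpt = intercepts[i]
        if klass == "flat":
            specs.append(TrajectorySpec(ids[i], "flat", intercept=icpt))
        elif klass == "linear":
            # a small strongly-deleterious tail underflows the sequencing
            # depth before 240 h, which is how extinction manifests in barseq
            if rng.random() < 0.02:
                slope = rng.uniform(-0.035, -0.015)
            else:
                slope = rng.normal(0.0, 3e-3)
            specs.append(TrajectorySpec(ids[i], "linear", intercept=icpt,
                                        slope=slope))
        elif klass == "quadratic":
            specs.append(TrajectorySpec(
                ids[i], "quadratic", intercept=icpt,
                slope=rng.normal(0.0, 1.5e-3),
                quad=rng.choice([-1, 1]) * rng.uniform(1.0, 2.0) / 240.0**2,
            ))
        else:  # cubic: two sign reversals of the per-cell growth rate
            a3 = rng.choice([-1, 1]) * rng.uniform(1.5, 3.0) / 240.0**3
            specs.append(TrajectorySpec(
                ids[i], "cubic", intercept=icpt,
                slope=rng.normal(0.0, 1.5e-3),
                quad=-1.5 * a3 * 240.0, cubic=a3,
            ))
        i += 1
    return specs


def study_scenario(
    seed: int | None = None,
    n_genotypes: int = 4000,
    n_replicates: int = 3,
    times=tuple(range(0, 241, 24)),
    depth: int = 1_000_000,
    overdispersion: float = 0.005,
    extreme_advantage: float = 0.04,
    n_periodic: int | None = None,
    period: float = 60.0,
) -> tuple[CountTable, dict[str, list[TrajectorySpec]]]:
    """Full synthetic study: 3 conditions x replicates x time course.

    Static conditions (``clim``, ``nlim``) each contain one extreme-fitness
    genotype (log-slope ``extreme_advantage`` per hour, enough to sweep past
    50% of the population by 240 h) in a background of flat/linear/quadratic/
    cubic trajectories.  The ``switch`` condition has no extreme genotype, an
    enriched flat class and a cohort of ``n_periodic`` genotypes (default:
    17.5% of the library, 700 of 4,000) oscillating at the environmental
    period.  Returns the count table and the per-condition ground-truth specs.
    """
    if n_periodic is None:
        n_periodic = round(0.175 * n_genotypes)
    if n_periodic >= n_genotypes:
        raise ValueError("n_periodic must be smaller than n_genotypes")
    rng = np.random.default_rng(seed)
    design = make_design(("clim", "nlim", "switch"), n_replicates, times, depth,
                         seed=int(rng.integers(2**31)))
    truth: dict[str, list[TrajectorySpec]] = {}
    pieces = []
    for cond in ("clim", "nlim", "switch"):
        specs = _spec_classes(rng, n_genotypes, cond, extreme_advantage,
                              n_periodic, period)
        truth[cond] = specs
        props = trajectories_to_proportions(specs, times)
        sub_design = design[design["condition"] == cond]
        ct = sample_counts(props, sub_design, overdispersion=overdispersion,
                           seed=int(rng.integers(2**31)))
        pieces.append(ct.counts)
    counts = pd.concat(pieces, axis=1)[design.index]
    return CountTable(counts, design, meta={"period": period}), truth
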