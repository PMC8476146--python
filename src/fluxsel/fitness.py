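"""Relative fitness, the DFE, and piecewise (short-term) fitness statistics.

Fitness here is a *relative* per-cell growth rate estimated from barseq
abundances on a per-hour basis (hours, not generations, so that static and
fluctuating regimes are directly comparable): for genotype i over an interval
(t1, t2),

    f_i = [ln n_i(t2) - ln n_i(t1)] / (t2 - t1) - mean_j(...)

where n_i is size-factor-normalized abundance and the centering subtracts the
unweighted arithmetic mean over genotypes.  The distribution of these values
across genotypes is the distribution of fitness effects (DFE).  Piecewise
fitness applies the same estimator between consecutive sampling times,
revealing short-term selection that cancels over the full course (the
signature of balancing selection in a switching environment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .processing import AbundanceMatrix

__all__ = [
    "relative_fitness",
    "dfe",
    "piecewise_fitness",
    "piecewise_from_abundance",
    "fitness_variance_series",
]


def _replicate_mean_log(abund: AbundanceMatrix, condition: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicate-averaged log abundance (genotypes x times) and the time grid."""
    samples = abund.samples_for(condition)
    times = abund.design.loc[samples, "time"]
    log_by_time = abund.log[samples].T.groupby(times.to_numpy()).mean().T
    return log_by_time, log_by_time.columns.to_numpy(dtype=float)


def _zero_mask(abund: AbundanceMatrix, condition: str) -> pd.DataFrame:
    """True where the genotype has a zero raw count at a time in any replicate."""
    samples = abund.samples_for(condition)
    times = abund.design.loc[samples, "time"]
    zero = (abund.counts[samples] == 0).T.groupby(times.to_numpy()).any().T
    return zero


def relative_fitness(
    abund: AbundanceMatrix,
    condition: str,
    t1: float = 0.0,
    t2: float = 240.0,
    weighted: bool = False,
) -> pd.Series:
    """Temporal mean relative growth rate (1/h) per genotype over (t1, t2).

    Log normalized abundance is averaged over replicates at each end point;
    genotypes with a zero raw count at either end point (in any replicate)
    get NaN — extinction makes their rate undefined.  Centering subtracts the
    unweighted arithmetic mean over genotypes (``weighted=True`` uses the
    terminal-abundance-weighted mean instead), so the centered values average
    exactly zero over the scored genotypes.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    log_by_time, times = _replicate_mean_log(abund, condition)
    for t in (t1, t2):
        if t not in times:
            raise KeyError(f"time {t} not sampled in condition {condition!r}")
    rate = (log_by_time[t2] - log_by_time[t1]) / (t2 - t1)
    zero = _zero_mask(abund, condition)
    rate[zero[t1] | zero[t2]] = np.nan
    if weighted:
        samples = abund.samples_for(condition)
        at_t2 = abund.design.loc[samples, "time"] == t2
        w = abund.normalized[samples[at_t2]].mean(axis=1)
        w = w / w.sum()
        center = float((rate * w).sum() / w[rate.notna()].sum())
    else:
        center = float(rate.mean())
    out = rate - center
    out.name = f"fitness_{condition}"
    return out


def dfe(fitness: pd.Series, bin_width: float = 0.002,
        proportions_t1: pd.Series | None = None,
        proportions_t2: pd.Series | None = None) -> dict:
    """Bin the distribution of fitness effects; optionally track proportion flux.

    Returns bin edges, genotype counts per bin, summary dispersion (SD, IQR)
    and tail extrema.  When start/end population proportions are supplied the
    per-bin summed proportion change (t2 minus t1) is included; those changes
    sum to zero because total proportion is conserved.
    """
    f = fitness.dropna()
    if len(f) == 0:
        raise ValueError("empty fitness vector")
    lo = np.floor(f.min() / bin_width) * bin_width
    hi = np.ceil(f.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(f.to_numpy(), bins=edges)
    out = {
        "bin_edges": edges,
        "counts": counts,
        "sd": float(f.std(ddof=1)) if len(f) > 1 else 0.0,
        "iqr": float(f.quantile(0.75) - f.quantile(0.25)),
        "min": float(f.min()),
        "max": float(f.max()),
        "n": int(len(f)),
    }
    if proportions_t1 is not None and proportions_t2 is not None:
        delta = (proportions_t2 - proportions_t1).reindex(f.index).fillna(0.0)
        which = np.digitize(f.to_numpy(), edges) - 1
        change = np.zeros(len(edges) - 1)
        np.add.at(change, np.clip(which, 0, len(change) - 1), delta.to_numpy())
        out["proportion_change"] = change
    return out


def piecewise_fitness(
    log_abundance: pd.DataFrame,
    times: np.ndarray | None = None,
    zero_mask: pd.DataFrame | None = None,
    center: bool = True,
) -> pd.DataFrame:
    """Per-genotype, per-interval relative growth rates (1/h).

    ``log_abundance`` is genotypes x times (columns are sampling times) — raw
    replicate-averaged log normalized abundance, or model-predicted values
    (preferred when fits are available, since prediction smooths sampling
    noise).  Interval rate = delta(log)/delta(t) between consecutive columns;
    ``center=True`` subtracts the across-genotype mean within each interval
    (so each interval's centered rates average zero).  ``zero_mask``
    (genotypes x times, True = absent) masks intervals touching a zero
    abundance to NaN.

    Column labels are interval midpoints; ``attrs['interval']`` keeps the
    (start, end) pairs.
    """
    t = np.asarray(times if times is not None else log_abundance.columns,
                   dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    vals = log_abundance.to_numpy(dtype=float)
    dt = np.diff(t)
    rates = np.diff(vals, axis=1) / dt[None, :]
    if zero_mask is not None:
        zm = zero_mask.to_numpy(dtype=bool)
        bad = zm[:, :-1] | zm[:, 1:]
        rates = np.where(bad, np.nan, rates)
    if center:
        rates = rates - np.nanmean(rates, axis=0, keepdims=True)
    mid = (t[:-1] + t[1:]) / 2
    out = pd.DataFrame(rates, index=log_abundance.index, columns=mid)
    out.attrs["interval"] = list(zip(t[:-1], t[1:]))
    return out


def piecewise_from_abundance(abund: AbundanceMatrix, condition: str,
                             center: bool = True) -> pd.DataFrame:
    """Piecewise fitness from replicate-averaged raw log abundances."""
    log_by_time, times = _replicate_mean_log(abund, condition)
    return piecewise_fitness(log_by_time, times,
                             zero_mask=_zero_mask(abund, condition),
                             center=center)


def fitness_variance_series(piecewise: pd.DataFrame) -> pd.Series:
    """Unweighted across-genotype variance of piecewise fitness per interval."""
    return piecewise.var(axis=0, ddof=1)
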