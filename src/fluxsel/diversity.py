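"""Population diversity statistics over barseq time courses.

Shannon's index H = -sum_i q_i ln q_i (nats) over genotype abundance
proportions combines richness (genotypes detected) and evenness
(H / ln richness).  The rate of diversity change per condition is the OLS
slope of H against time with replicate-specific intercepts; static selection
drives H down as a sweep proceeds, while fluctuating selection holds it up.
Extinction is scored from raw counts: a genotype absent from one or more
terminal time points of a condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .processing import AbundanceMatrix

__all__ = [
    "shannon",
    "diversity_series",
    "diversity_rate",
    "extinction",
    "top_genotype_share",
]


def shannon(abundances) -> float:
    """Shannon diversity H (nats) of one sample's abundance vector.

    Proportions are taken within the vector; zero entries contribute nothing.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    q = a[a > 0] / total
    return float(-(q * np.log(q)).sum())


def diversity_series(abund: AbundanceMatrix, source: str = "normalized") -> pd.DataFrame:
    """Per-sample Shannon H, richness and evenness.

    ``source`` selects the abundance used for proportions: ``normalized``
    (size-factor-scaled, the default) or ``counts`` (raw reads).  Richness is
    the number of genotypes with a nonzero raw count; evenness = H / ln
    richness (1 for a single-genotype sample by convention).
    """
    mat = abund.normalized if source == "normalized" else abund.counts
    rows = []
    for sample in mat.columns:
        h = shannon(mat[sample].to_numpy())
        rich = int((abund.counts[sample] > 0).sum())
        evenness = h / np.log(rich) if rich > 1 else 1.0
        rows.append({"sample_id": sample, "shannon": h, "richness": rich,
                     "evenness": evenness})
    out = pd.DataFrame(rows).set_index("sample_id")
    return out.join(abund.design[["condition", "replicate", "time"]])


def diversity_rate(series: pd.DataFrame, condition: str, conf: float = 0.95) -> dict:
    """OLS slope of Shannon H vs time for one condition, with a t-based CI.

    Replicates are pooled with replicate-specific intercepts (H ~ time +
    replicate dummies); the slope (nats/hour) and its ``conf`` confidence
    interval come from the usual t distribution on the residual degrees of
    freedom.  Needs at least 3 time points.
    """
    sub = series[series["condition"] == condition]
    if sub["time"].nunique() < 3:
        raise ValueError("need at least 3 distinct time points")
    t = sub["time"].to_numpy(dtype=float)
    reps = pd.get_dummies(sub["replicate"].astype("category"), drop_first=False,
                          dtype=float)
    x = np.column_stack([t, reps.to_numpy()])
    model = sm.OLS(sub["shannon"].to_numpy(), x).fit()
    slope = float(model.params[0])
    se = float(model.bse[0])
    if model.df_resid > 0 and np.isfinite(se):
        half = sps.t.ppf(0.5 + conf / 2, model.df_resid) * se
    else:
        half = 0.0
    return {"condition": condition, "slope": slope, "se": se,
            "ci_low": slope - half, "ci_high": slope + half,
            "n_samples": len(sub)}


def extinction(abund: AbundanceMatrix, terminal_window: int = 1) -> pd.DataFrame:
    """Extinction flags per genotype x condition, from raw counts.

    A genotype is extinct in a condition when its replicate-summed count is
    zero in at least one of the last ``terminal_window`` time points.  The
    returned frame has one boolean column per condition; the cross-condition
    intersection is the row-wise AND.
    """
    flags = {}
    for cond in abund.conditions:
        samples = abund.samples_for(cond)
        times = abund.design.loc[samples, "time"]
        pooled = abund.counts[samples].T.groupby(times.to_numpy()).sum().T
        terminal = pooled.iloc[:, -terminal_window:]
        flags[cond] = (terminal == 0).any(axis=1)
    return pd.DataFrame(flags)


def top_genotype_share(abund: AbundanceMatrix, sample_id: str,
                       source: str = "counts") -> float:
    """Maximum genotype proportion in one sample (raw-count proportions)."""
    mat = abund.counts if source == "counts" else abund.normalized
    col = mat[sample_id].to_numpy(dtype=float)
    return float(col.max() / col.sum())
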