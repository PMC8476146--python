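"""Count-table processing: library/genotype filters, tag summing, normalization, QC.

The pipeline order mirrors standard pooled-barcode practice: drop
under-sequenced libraries, collapse uptag/downtag rows per genotype, drop
genotypes with negligible aggregate counts, then compute median-of-ratios
size factors and log-transform.  Replicate quality control flags replicate
time-courses whose log-abundance profiles correlate poorly with their
siblings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import CountTable

__all__ = [
    "AbundanceMatrix",
    "filter_libraries",
    "sum_tags",
    "filter_genotypes",
    "normalize",
    "replicate_qc",
    "process_counts",
]

MIN_LIBRARY_READS = 100_000
MIN_GENOTYPE_AGGREGATE = 1_000
DEFAULT_PSEUDOCOUNT = 0.5
MIN_REPLICATE_COR = 0.8


@dataclass
class AbundanceMatrix:
    """Size-factor-normalized abundances and their natural-log transform.

    ``normalized`` = count / size factor; ``log`` = ln(normalized + pseudocount).
    Zeros are retained (not dropped) so extinction analyses can see them.
    ``provenance`` records filtering decisions applied upstream.
    """

    normalized: pd.DataFrame
    log: pd.DataFrame
    size_factors: pd.Series
    design: pd.DataFrame
    counts: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    def samples_for(self, condition=None, replicate=None) -> pd.Index:
        d = self.design
        mask = pd.Series(True, index=d.index)
        if condition is not None:
            mask &= d["condition"] == condition
        if replicate is not None:
            mask &= d["replicate"] == replicate
        idx = d.index[mask]
        return idx[np.argsort(d.loc[idx, "time"].to_numpy(), kind="stable")]

    @property
    def conditions(self):
        return list(pd.unique(self.design["condition"]))

    def drop_samples(self, sample_ids) -> "AbundanceMatrix":
        keep = [c for c in self.normalized.columns if c not in set(sample_ids)]
        return AbundanceMatrix(
            self.normalized[keep], self.log[keep], self.size_factors[keep],
            self.design.loc[keep], self.counts[keep], self.pseudocount,
            dict(self.provenance),
        )


def filter_libraries(counts: CountTable, min_reads: int = MIN_LIBRARY_READS) -> CountTable:
    """Drop sequencing libraries (samples) with total reads < ``min_reads``.

    The rule is strictly-less-than: a library at exactly the threshold is
    kept.  Dropped sample ids are recorded in ``meta['dropped_libraries']``.
    """
    sums = counts.counts.sum(axis=0)
    keep = sums >= min_reads
    if not keep.any():
        raise ValueError("library filter would drop every sample")
    dropped = list(sums.index[~keep])
    out = CountTable(
        counts.counts.loc[:, keep], counts.design.loc[keep],
        {**counts.meta, "dropped_libraries": dropped, "min_reads": min_reads},
    )
    return out


def sum_tags(counts: CountTable, permissive: bool = False) -> CountTable:
    """Collapse uptag/downtag rows to one row per genotype (up + down).

    Genotype-level input passes through unchanged.  By default a genotype must
    carry both tag rows; with ``permissive=True`` a missing tag contributes 0.
    """
    if not counts.has_tags:
        return counts.copy()
    tag_counts = counts.counts.groupby(level=0, sort=False)
    if not permissive:
        n_tags = tag_counts.size()
        incomplete = n_tags.index[n_tags < 2]
        if len(incomplete):
            raise ValueError(
                f"genotypes missing a tag row: {list(incomplete[:5])}"
                " (pass permissive=True to treat missing tags as zero)"
            )
    summed = tag_counts.sum()
    summed.index.name = "genotype_id"
    return CountTable(summed, counts.design.copy(), {**counts.meta, "tags_summed": True})


def filter_genotypes(counts: CountTable, min_aggregate: int = MIN_GENOTYPE_AGGREGATE) -> CountTable:
    """Drop genotypes whose aggregate count over all retained samples is < ``min_aggregate``."""
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_aggregate
    dropped = list(counts.counts.index[~keep])
    return CountTable(
        counts.counts.loc[keep], counts.design.copy(),
        {**counts.meta, "dropped_genotypes": dropped, "min_aggregate": min_aggregate},
    )


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the standard RNA-seq estimator).

    Reference = per-genotype geometric mean across samples, over genotypes
    with no zero anywhere; factor_j = median_i(count_ij / reference_i),
    rescaled to geometric mean 1.  Falls back to total-count scaling (with a
    warning) when no genotype is positive in every sample.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(x[all_pos])
        ref = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - ref, axis=0))
    else:
        warnings.warn(
            "no genotype with all-positive counts; falling back to total-count scaling",
            RuntimeWarning,
        )
        totals = x.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> AbundanceMatrix:
    """Size-factor-normalize a count table and attach the log transform.

    Normalized abundance is invariant to rescaling any sample's depth; the
    log transform uses ``ln(normalized + pseudocount)`` so zero counts stay
    finite and visible to extinction analysis downstream.
    """
    if counts.has_tags:
        raise ValueError("normalize expects genotype-level counts; run sum_tags first")
    factors = size_factors_median_of_ratios(counts.counts)
    normalized = counts.counts / factors
    log = np.log(normalized + pseudocount)
    return AbundanceMatrix(
        normalized=normalized, log=log, size_factors=factors,
        design=counts.design.copy(), counts=counts.counts.copy(),
        pseudocount=pseudocount, provenance=dict(counts.meta),
    )


def replicate_qc(
    abund: AbundanceMatrix,
    min_correlation: float = MIN_REPLICATE_COR,
    drop: bool = True,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Flag replicate time-courses that correlate poorly with their siblings.

    For each condition, every replicate's log-abundance profile (genotypes x
    matched time points, flattened) is Pearson-correlated with each sibling
    replicate; a replicate whose *best* sibling correlation falls below
    ``min_correlation`` is flagged and, with ``drop=True``, removed.  Using
    the best rather than the mean correlation means one corrupted replicate
    among three is flagged alone instead of dragging its two (mutually
    consistent) siblings below the cut with it.  The QC report (one row per
    condition x replicate, with best and mean correlations) is always
    returned.  A condition losing all its replicates is an error.
    """
    rows = []
    to_drop: list[str] = []
    for cond in abund.conditions:
        reps = sorted(pd.unique(abund.design.loc[abund.design["condition"] == cond,
                                                 "replicate"]))
        if len(reps) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        profiles = {}
        for rep in reps:
            samples = abund.samples_for(cond, rep)
            times = abund.design.loc[samples, "time"].to_numpy()
            profiles[rep] = (times, abund.log[samples])
        best_cor, mean_cor = {}, {}
        for rep in reps:
            cors = []
            for other in reps:
                if other == rep:
                    continue
                t_a, a = profiles[rep]
                t_b, b = profiles[other]
                common = np.intersect1d(t_a, t_b)
                va = a.iloc[:, np.isin(t_a, common)].to_numpy().ravel()
                vb = b.iloc[:, np.isin(t_b, common)].to_numpy().ravel()
                cors.append(sps.pearsonr(va, vb).statistic)
            best_cor[rep] = float(np.max(cors))
            mean_cor[rep] = float(np.mean(cors))
        for rep in reps:
            flagged = best_cor[rep] < min_correlation
            rows.append({"condition": cond, "replicate": rep,
                         "best_correlation": best_cor[rep],
                         "mean_correlation": mean_cor[rep], "flagged": flagged})
        flagged_reps = [r for r in reps if best_cor[r] < min_correlation]
        if len(flagged_reps) == len(reps):
            raise ValueError(f"replicate QC would drop all replicates of {cond!r}")
        if drop:
            for rep in flagged_reps:
                to_drop.extend(abund.samples_for(cond, rep))
    report = pd.DataFrame(rows)
    out = abund.drop_samples(to_drop) if (drop and to_drop) else abund
    out.provenance = {**out.provenance, "replicate_qc_dropped": to_drop,
                      "min_replicate_cor": min_correlation}
    return out, report


def process_counts(
    counts: CountTable,
    min_reads: int = MIN_LIBRARY_READS,
    min_aggregate: int = MIN_GENOTYPE_AGGREGATE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_replicate_cor: float | None = None,
    permissive_tags: bool = False,
) -> AbundanceMatrix:
    """Full pipeline: filter libraries -> sum tags -> filter genotypes -> normalize.

    ``min_replicate_cor`` additionally runs :func:`replicate_qc` (dropping
    flagged replicates) when set.
    """
    ct = filter_libraries(counts, min_reads)
    ct = sum_tags(ct, permissive=permissive_tags)
    ct = filter_genotypes(ct, min_aggregate)
    abund = normalize(ct, pseudocount)
    if min_replicate_cor is not None:
        abund, _ = replicate_qc(abund, min_replicate_cor, drop=True)
    return abund
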