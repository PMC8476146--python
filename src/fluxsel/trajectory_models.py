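"""Per-genotype trajectory model selection on log normalized abundance.

Each genotype's log abundance across all time points and replicates is fit to
a hierarchy of Gaussian fixed-effect models sharing per-replicate intercepts:

* constant      y = a_r
* linear        y = a_r + b t
* quadratic     y = a_r + b t + c t^2
* cubic         y = a_r + b t + c t^2 + d t^3
* periodic      y = a_r + b t + p sin(2 pi t / T) + q cos(2 pi t / T)

Selection starts from the richest model and simplifies iteratively by
likelihood-ratio tests.  An omnibus gate (richest model against the constant
model) decides significance for the genotype as a whole, so the fraction of
pure-noise genotypes called significant equals the nominal level alpha; among
significant genotypes, nested likelihood-ratio comparisons pick the retained
polynomial degree, and the periodic terms are tested against the shared linear
null, winning the class when they are significant and the periodic model's
likelihood beats the retained polynomial's.  The simplification path involves
up to three polynomial upgrade decisions plus the periodic comparison; each is
tested at alpha divided by the number of path tests (a Bonferroni bound on the
per-genotype false-upgrade rate), which keeps the probability of promoting a
truly linear genotype to a higher class near alpha rather than compounding it
across steps.

For nested Gaussian linear models the likelihood-ratio statistic
2 (logL1 - logL0) = n log(RSS0/RSS1) is a monotone function of the classical
F statistic, whose null distribution is exact in finite samples; p-values are
taken from that F distribution by default (``calibration='f'``) because the
chi-square approximation is noticeably anti-conservative at ~30 observations.
``calibration='chisq'`` gives the large-sample chi-square version.

Positive/negative classification: non-periodic fits take the sign of the
fitted change in log abundance between the first and last time point, i.e. of
the average growth-rate difference over (0, 240); periodic fits are signed by
phase — positive when the oscillation is rising at the start of the first feed
phase (sin coefficient > 0), so two trajectories 180 degrees apart always get
opposite signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrajectoryFit",
    "fit_polynomials",
    "fit_periodic",
    "scan_period",
    "select_model",
    "classify_sign",
    "fit_genotypes",
    "class_distribution",
    "predicted_log_abundance",
]

POLY_CLASSES = ("nonsignificant", "linear", "quadratic", "cubic")


@dataclass
class ModelFit:
    """One fitted mean model for one genotype: coefficients and likelihood."""

    name: str
    coef: np.ndarray          # replicate intercepts followed by mean-curve terms
    n_intercepts: int
    rss: float
    loglik: float
    n: int
    terms: tuple[str, ...]    # names of the mean-curve terms after intercepts
    period: float | None = None

    @property
    def n_params(self) -> int:
        return len(self.coef) + 1  # + noise variance

    def curve_coef(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coef[self.n_intercepts:]))

    def predict(self, times) -> np.ndarray:
        """Mean prediction at ``times`` using the average replicate intercept."""
        t = np.asarray(times, dtype=float)
        x = _curve_columns(t, self.terms, self.period)
        icpt = float(np.mean(self.coef[:self.n_intercepts]))
        return icpt + x @ self.coef[self.n_intercepts:]


@dataclass
class TrajectoryFit:
    """Selected trajectory model for one genotype in one condition."""

    genotype_id: str
    condition: str | None
    klass: str                      # nonsignificant | linear | quadratic | cubic | periodic
    sign: str | None                # positive | negative (None when nonsignificant)
    fits: dict[str, ModelFit]
    pvalues: dict[str, float]       # omnibus gate + simplification path
    alpha: float
    period: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def chosen(self) -> ModelFit:
        name = "constant" if self.klass == "nonsignificant" else self.klass
        return self.fits[name]


def _curve_columns(t: np.ndarray, terms: tuple[str, ...], period: float | None):
    cols = []
    for term in terms:
        if term == "t":
            cols.append(t)
        elif term == "t2":
            cols.append(t**2)
        elif term == "t3":
            cols.append(t**3)
        elif term == "sin":
            cols.append(np.sin(2 * np.pi * t / period))
        elif term == "cos":
            cols.append(np.cos(2 * np.pi * t / period))
        else:
            raise ValueError(term)
    return np.column_stack(cols) if cols else np.empty((len(t), 0))


_TERMS = {
    "constant": (),
    "linear": ("t",),
    "quadratic": ("t", "t2"),
    "cubic": ("t", "t2", "t3"),
    "periodic": ("t", "sin", "cos"),
    "full": ("t", "t2", "t3", "sin", "cos"),
}


def _design(times, replicate, model: str, period: float | None):
    t = np.asarray(times, dtype=float)
    reps = pd.Categorical(replicate)
    dummies = np.eye(len(reps.categories))[reps.codes]
    terms = _TERMS[model]
    x = np.hstack([dummies, _curve_columns(t, terms, period)])
    return x, dummies.shape[1], terms


def _fit_many(x: np.ndarray, y: np.ndarray):
    """Least-squares fit of many responses at once; returns (coef, rss).

    ``y`` has shape (n_obs, n_genotypes); coef is (n_params, n_genotypes).
    """
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    return coef, rss


def _loglik(rss, n):
    rss = np.maximum(rss, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def _lrt_pvalue(rss0, rss1, df0, df1, n, calibration="f"):
    """p-value for nested Gaussian linear models (model 1 nests model 0).

    ``df`` are mean-parameter counts.  ``calibration='f'`` uses the exact
    finite-sample F distribution of the likelihood-ratio statistic;
    ``'chisq'`` uses the asymptotic chi-square with df1 - df0 degrees.
    """
    d = df1 - df0
    if d <= 0:
        raise ValueError("model 1 must have more parameters")
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.maximum(np.asarray(rss1, dtype=float), 1e-300)
    if calibration == "chisq":
        stat = n * np.log(np.maximum(rss0 / rss1, 1.0))
        return sps.chi2.sf(stat, d)
    denom_df = n - df1
    if denom_df <= 0:
        raise ValueError("not enough observations for the richer model")
    f = ((rss0 - rss1) / d) / (rss1 / denom_df)
    return sps.f.sf(np.maximum(f, 0.0), d, denom_df)


def _fit_one(times, replicate, y, model, period):
    x, n_icpt, terms = _design(times, replicate, model, period)
    if x.shape[0] < x.shape[1] + 1:
        raise ValueError(
            f"insufficient observations ({x.shape[0]}) for model {model!r}"
        )
    coef, rss = _fit_many(x, y.reshape(-1, 1))
    n = len(y)
    return ModelFit(model, coef[:, 0], n_icpt, float(rss[0]),
                    float(_loglik(rss[0], n)), n, terms,
                    period if "sin" in terms else None)


def fit_polynomials(times, replicate, y, max_degree: int = 3) -> dict[str, ModelFit]:
    """Fit the nested polynomial hierarchy (degrees 0..max_degree) to one genotype.

    ``times``/``replicate``/``y`` are aligned 1-D arrays over all samples of
    one condition.  Degrees that the data cannot support are skipped with a
    warning.  Log-likelihoods are nondecreasing with degree.
    """
    names = ["constant", "linear", "quadratic", "cubic"][: max_degree + 1]
    fits: dict[str, ModelFit] = {}
    for name in names:
        try:
            fits[name] = _fit_one(times, replicate, np.asarray(y, float), name, None)
        except ValueError as err:
            warnings.warn(f"skipping {name}: {err}", RuntimeWarning)
    return fits


def fit_periodic(times, replicate, y, period: float = 60.0) -> ModelFit:
    """Fit the periodic model (linear trend + sin/cos at fixed period T).

    Amplitude and phase of the oscillatory component are stored in the fit's
    terms: amplitude = sqrt(b_sin^2 + b_cos^2), phase = atan2(b_cos, b_sin),
    so the component equals amplitude * sin(2 pi t / T + phase).  Periods at
    or below twice the median sampling interval are not identifiable from the
    grid and trigger a warning.
    """
    t = np.asarray(times, dtype=float)
    dt = float(np.median(np.diff(np.unique(t))))
    if period <= 2 * dt:
        warnings.warn(
            f"period {period} h is at/below twice the sampling interval ({dt} h); "
            "oscillation is not identifiable", RuntimeWarning,
        )
    return _fit_one(times, replicate, np.asarray(y, float), "periodic", period)


def amplitude_phase(fit: ModelFit) -> tuple[float, float]:
    """(amplitude, phase) of a periodic fit's oscillatory component."""
    c = fit.curve_coef()
    b, q = c.get("sin", 0.0), c.get("cos", 0.0)
    return float(np.hypot(b, q)), float(np.arctan2(q, b))


def scan_period(times, replicate, y, grid=(30, 40, 50, 60, 70, 80)) -> tuple[float, pd.Series]:
    """Profile log-likelihood of the periodic model over a period grid.

    Returns the maximizing period and the full profile (log-likelihood per
    period).  Periods at or below twice the sampling interval are beyond the
    Nyquist limit of the grid and alias onto longer periods (on a 24 h grid a
    40 h sinusoid is *exactly* indistinguishable from a 60 h one), so they are
    profiled but excluded from the argmax; if every grid period is aliased the
    argmax falls back to the full grid.  Remaining ties break toward the
    smallest period.
    """
    t = np.asarray(times, dtype=float)
    dt = float(np.median(np.diff(np.unique(t))))
    prof = {}
    for period in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof[float(period)] = fit_periodic(times, replicate, y, float(period)).loglik
    series = pd.Series(prof, name="loglik")
    identifiable = series[series.index > 2 * dt]
    chosen = identifiable if len(identifiable) else series
    return float(chosen.idxmax()), series


def select_model(
    fits: dict[str, ModelFit],
    alpha: float = 0.05,
    calibration: str = "f",
    genotype_id: str = "",
    condition: str | None = None,
) -> TrajectoryFit:
    """Iterative likelihood-ratio simplification over one genotype's fits.

    ``fits`` must contain the polynomial hierarchy, and optionally
    ``periodic`` and ``full`` (cubic + periodic terms) fits when an
    environmental period is defined; the richest available model anchors the
    omnibus significance gate.
    """
    const = fits["constant"]
    n = const.n
    has_periodic = "periodic" in fits
    richest = fits.get("full") or fits.get("cubic") or fits["linear"]
    pvalues: dict[str, float] = {}

    def pval(m0: ModelFit, m1: ModelFit) -> float:
        return float(_lrt_pvalue(m0.rss, m1.rss,
                                 m0.n_intercepts + len(m0.terms),
                                 m1.n_intercepts + len(m1.terms),
                                 n, calibration))

    pvalues["omnibus"] = pval(const, richest)
    if pvalues["omnibus"] >= alpha:
        return TrajectoryFit(genotype_id, condition, "nonsignificant", None,
                             fits, pvalues, alpha,
                             richest.period if has_periodic else None)

    # polynomial simplification: cubic -> quadratic -> linear.  Path tests run
    # at alpha / (number of path tests) so the chance of a spurious upgrade
    # anywhere along the path stays bounded by alpha.
    path = [("cubic", "quadratic"), ("quadratic", "linear"), ("linear", "constant")]
    n_path = sum(r in fits for r, _ in path) + (1 if has_periodic else 0)
    alpha_path = alpha / max(n_path, 1)
    klass = "linear"
    for rich_name, simple_name in path:
        if rich_name not in fits:
            continue
        p = pval(fits[simple_name], fits[rich_name])
        pvalues[rich_name] = p
        if p < alpha_path:
            klass = rich_name
            break

    if has_periodic:
        p_per = pval(fits["linear"], fits["periodic"])
        pvalues["periodic"] = p_per
        if p_per < alpha_path and (
            klass in ("linear",) or fits["periodic"].loglik > fits[klass].loglik
        ):
            klass = "periodic"

    chosen = fits[klass]
    sign = classify_sign(chosen)
    return TrajectoryFit(genotype_id, condition, klass, sign, fits, pvalues,
                         alpha, chosen.period)


def classify_sign(fit: ModelFit, t_start: float = 0.0, t_end: float = 240.0) -> str:
    """Positive/negative classification of a non-constant fit.

    Non-periodic models: sign of the fitted change in log abundance between
    ``t_start`` and ``t_end`` (equivalently of the average growth-rate
    difference over the course).  Periodic models: sign of the sin
    coefficient — positive when the oscillation rises at the start of the
    first feed phase; a 180-degree phase shift flips the classification.
    """
    if fit.name == "constant":
        raise ValueError("sign is undefined for the constant model")
    if "sin" in fit.terms:
        b = fit.curve_coef()["sin"]
        if b == 0.0:
            warnings.warn("zero sin coefficient; tie broken to positive",
                          RuntimeWarning)
        return "positive" if b >= 0 else "negative"
    delta = float(fit.predict([t_end])[0] - fit.predict([t_start])[0])
    if delta == 0.0:
        warnings.warn("exactly zero fitted change; tie broken to positive",
                      RuntimeWarning)
    return "positive" if delta >= 0 else "negative"


def fit_genotypes(
    abund,
    condition: str,
    period: float | None = None,
    alpha: float = 0.05,
    calibration: str = "f",
    bh: bool = False,
) -> pd.DataFrame:
    """Fit and classify every genotype of one condition.

    Vectorized over genotypes (all least-squares solves are batched).  With
    ``bh=True`` the omnibus gate p-values are Benjamini-Hochberg adjusted
    across genotypes before being compared with ``alpha`` (off by default).
    Returns one row per genotype: class, sign, per-model log-likelihoods, the
    gate and path p-values, and the curve coefficients of the chosen model.
    """
    samples = abund.samples_for(condition)
    times = abund.design.loc[samples, "time"].to_numpy(dtype=float)
    reps = abund.design.loc[samples, "replicate"].to_numpy()
    y = abund.log[samples].to_numpy(dtype=float).T  # (n_obs, n_genotypes)
    genotypes = abund.log.index

    models = ["constant", "linear", "quadratic", "cubic"]
    if period is not None:
        models += ["periodic", "full"]
    rss: dict[str, np.ndarray] = {}
    coefs: dict[str, np.ndarray] = {}
    meta: dict[str, tuple] = {}
    n = len(times)
    for name in models:
        x, n_icpt, terms = _design(times, reps, name, period)
        c, r = _fit_many(x, y)
        rss[name], coefs[name], meta[name] = r, c, (n_icpt, terms)

    def make_fit(name, j):
        n_icpt, terms = meta[name]
        return ModelFit(name, coefs[name][:, j], n_icpt, float(rss[name][j]),
                        float(_loglik(rss[name][j], n)), n, terms,
                        period if "sin" in terms else None)

    gate_name = "full" if period is not None else "cubic"
    n_icpt = meta["constant"][0]
    gate_p = _lrt_pvalue(rss["constant"], rss[gate_name], n_icpt,
                         n_icpt + len(meta[gate_name][1]), n, calibration)
    if bh:
        from statsmodels.stats.multitest import multipletests

        gate_sig = multipletests(gate_p, alpha=alpha, method="fdr_bh")[0]
    else:
        gate_sig = gate_p < alpha

    rows = []
    for j, gid in enumerate(genotypes):
        fits = {name: make_fit(name, j) for name in models}
        if not gate_sig[j]:
            tf = TrajectoryFit(str(gid), condition, "nonsignificant", None, fits,
                               {"omnibus": float(gate_p[j])}, alpha, period)
        else:
            tf = select_model(fits, alpha=alpha, calibration=calibration,
                              genotype_id=str(gid), condition=condition)
            tf.pvalues["omnibus"] = float(gate_p[j])
        chosen = tf.chosen
        row = {
            "genotype_id": str(gid), "condition": condition, "klass": tf.klass,
            "sign": tf.sign, "p_omnibus": float(gate_p[j]),
            "p_periodic": tf.pvalues.get("periodic", np.nan),
        }
        for name in models:
            row[f"loglik_{name}"] = fits[name].loglik
        row.update({f"coef_{k}": v for k, v in chosen.curve_coef().items()})
        if tf.klass == "periodic":
            amp, phase = amplitude_phase(chosen)
            row["amplitude"], row["phase"] = amp, phase
        rows.append(row)
    out = pd.DataFrame(rows).set_index("genotype_id")
    out.attrs.update({"alpha": alpha, "bh": bh, "period": period,
                      "calibration": calibration})
    return out


def class_distribution(fits: pd.DataFrame) -> pd.DataFrame:
    """Fractions of genotypes per (class, sign); fractions sum to 1.

    ``fits`` may cover several conditions (a ``condition`` column groups the
    table); nonsignificant genotypes carry a null sign.
    """
    df = fits.reset_index() if "condition" not in fits.columns else fits.copy()
    if "condition" not in df.columns:
        df["condition"] = "all"
    counts = (df.groupby(["condition", "klass", "sign"], dropna=False)
                .size().rename("n").reset_index())
    counts["fraction"] = counts.groupby("condition")["n"].transform(lambda s: s / s.sum())
    return counts.drop(columns="n")


def predicted_log_abundance(abund, fits: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Model-predicted log abundance (genotypes x times) for piecewise fitness.

    Uses each genotype's chosen model (the constant model for nonsignificant
    genotypes) evaluated at the condition's sampling times with the average
    replicate intercept.  This is the preferred input to
    :func:`fluxsel.fitness.piecewise_fitness`.
    """
    samples = abund.samples_for(condition)
    times = np.unique(abund.design.loc[samples, "time"].to_numpy(dtype=float))
    all_times = abund.design.loc[samples, "time"].to_numpy(dtype=float)
    reps = abund.design.loc[samples, "replicate"].to_numpy()
    y = abund.log[samples].to_numpy(dtype=float).T
    period = fits.attrs.get("period")

    preds = np.empty((len(fits), len(times)))
    # refit per class in batch: genotypes sharing a class share the design
    for name, terms in _TERMS.items():
        if name == "full":
            continue
        klass = "nonsignificant" if name == "constant" else name
        idx = np.flatnonzero((fits["klass"] == klass).to_numpy())
        if len(idx) == 0:
            continue
        x, n_icpt, terms = _design(all_times, reps, name, period)
        c, _ = _fit_many(x, y[:, idx])
        icpt = c[:n_icpt].mean(axis=0)
        xc = _curve_columns(times, terms, period)
        preds[idx] = (icpt[None, :] + xc @ c[n_icpt:]).T
    return pd.DataFrame(preds, index=fits.index, columns=times)
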