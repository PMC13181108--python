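"""Four-sample integrated analysis of stimulation-specific phenotypes.

A paired-screen design sorts low/high surface-receptor bins both with and
without ligand stimulation.  Genes affecting basal surface expression shift
guide frequencies in the high-vs-low comparison of *both* conditions, and a
systematic trend relates post-stimulation enrichment to basal enrichment
across the library (most cells internalize most of their receptor, which
compresses or re-maps the sort gates).  To isolate internalization and
recycling phenotypes, the differential score compares the observed
post-stimulation bin split of each guide against a null in which

* the guide's unstimulated bin frequencies are free (set to observed),
* the guide's total abundance in the stimulated condition is free (set to
  the observed pooled stimulated frequency), and
* the stimulated high/low split is fixed by a trend fitted to
  e_stim ~ e_unstim over well-read guides.

The log10 likelihood-ratio sum therefore runs over the two stimulated
samples only — the free null parameters make the unstimulated terms and the
stimulated-abundance term identically one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import effects as eff
from .normalization import FrequencyFrame, normalize
from .pipeline import ScoringOptions, ScreenResult, build_tables, score_two_sample
from .scoring import nb_log10_pmf
from .screen_io import CountMatrix, GuideLibrary, ScreenDesign
from .variance_model import VarianceModel, fit_variance_model, predict_variance

#: mean reads/sample a guide needs to inform the enrichment trend fit
TREND_READ_FLOOR = 10.0
#: pseudocount (reads) for enrichment log-ratios
ENRICH_PSEUDOCOUNT = 0.5


def enrichments(
    counts: CountMatrix,
    design: ScreenDesign,
    effective_totals: pd.Series,
    read_floor: float = TREND_READ_FLOOR,
) -> pd.DataFrame:
    """Per-guide high/low log2 enrichment in each condition.

    e = log2(((n_high + 0.5) / T_high) / ((n_low + 0.5) / T_low)) with the
    0.5-read pseudocount keeping zero-count guides finite.  ``read_floor_ok``
    marks guides whose mean read count across the four samples reaches the
    configured floor.
    """
    if design.mode != "four_sample":
        raise ValueError("enrichments requires a four_sample design")
    c = counts.counts

    def _enrich(high_role: str, low_role: str) -> np.ndarray:
        sh, sl = design.sample_for(high_role), design.sample_for(low_role)
        num = (c[sh].to_numpy() + ENRICH_PSEUDOCOUNT) / effective_totals[sh]
        den = (c[sl].to_numpy() + ENRICH_PSEUDOCOUNT) / effective_totals[sl]
        return np.log2(num / den)

    samples = [design.sample_for(r) for r in
               ("unstim_low", "unstim_high", "stim_low", "stim_high")]
    mean_reads = c[samples].mean(axis=1)
    return pd.DataFrame(
        {
            "e_unstim": _enrich("unstim_high", "unstim_low"),
            "e_stim": _enrich("stim_high", "stim_low"),
            "read_floor_ok": (mean_reads >= read_floor).to_numpy(),
        },
        index=c.index,
    )


@dataclass(frozen=True)
class TrendModel:
    """Predictor of post-stimulation enrichment from basal enrichment."""

    intercept: float
    slope: float
    residual_scale: float
    family: str = "lowess"
    lowess_curve: Optional[np.ndarray] = None  # (x, fitted) columns for lowess

    def predict(self, e_unstim) -> np.ndarray:
        x = np.asarray(e_unstim, dtype=float)
        if self.family == "lowess" and self.lowess_curve is not None:
            return np.interp(
                x, self.lowess_curve[:, 0], self.lowess_curve[:, 1]
            )
        return self.intercept + self.slope * x

    def derivative(self, e_unstim) -> np.ndarray:
        """Local slope dg/de_unstim, used to propagate input noise."""
        x = np.asarray(e_unstim, dtype=float)
        if self.family == "lowess" and self.lowess_curve is not None:
            h = 0.1
            return (self.predict(x + h) - self.predict(x - h)) / (2 * h)
        return np.full_like(x, self.slope)


def fit_trend(
    pairs: pd.DataFrame,
    family: str = "lowess",
) -> TrendModel:
    """Fit the basal → stimulated enrichment trend on well-read guides.

    ``pairs`` is the output of :func:`enrichments`.  The default family is
    a LOWESS curve, which estimates the conditional expectation
    E[e_stim | e_unstim]: it follows the identity-like relation where real
    basal effects dominate while staying flat inside the noise cloud, so
    guides with purely basal phenotypes are not handed spurious
    differential residuals.  A Huber-weighted robust linear fit
    (``huber``) is available; a single global slope is attenuated by
    measurement noise in e_unstim and over-corrects strong basal guides.
    Residual scale is the MAD of residuals.
    """
    use = pairs[pairs["read_floor_ok"]]
    if len(use) < 500:
        warnings.warn(
            f"only {len(use)} guides pass the read floor for the trend fit"
        )
    x = use["e_unstim"].to_numpy()
    y = use["e_stim"].to_numpy()
    if x.size == 0 or np.var(x) == 0:
        warnings.warn("degenerate basal enrichments; falling back to identity trend")
        return TrendModel(intercept=0.0, slope=1.0, residual_scale=0.0, family=family)

    if family == "huber":
        import statsmodels.api as sm

        X = sm.add_constant(x)
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        resid = y - (intercept + slope * x)
        curve = None
    elif family == "lowess":
        import statsmodels.api as sm

        smoothed = sm.nonparametric.lowess(y, x, frac=0.3, return_sorted=True)
        curve = np.asarray(smoothed)
        resid = y - np.interp(x, curve[:, 0], curve[:, 1])
        # report the secant slope for diagnostics
        intercept = float(np.interp(0.0, curve[:, 0], curve[:, 1]))
        span = curve[-1, 0] - curve[0, 0]
        slope = float((curve[-1, 1] - curve[0, 1]) / span) if span > 0 else 1.0
    else:
        raise ValueError(f"unknown trend family {family!r}")

    mad = float(np.median(np.abs(resid - np.median(resid))) * 1.4826)
    return TrendModel(
        intercept=intercept,
        slope=slope,
        residual_scale=mad,
        family=family,
        lowess_curve=curve,
    )


def _trend_null_frequencies(
    freqs: FrequencyFrame,
    design: ScreenDesign,
    predicted_e: np.ndarray,
) -> tuple[pd.Series, pd.Series]:
    """Allocate each guide's stimulated abundance across the stim bins.

    The null fixes the stimulated high/low frequency ratio at 2^ê while
    conserving the guide's observed total stimulated reads.
    """
    sh = design.sample_for("stim_high")
    sl = design.sample_for("stim_low")
    t_h = freqs.effective_totals[sh]
    t_l = freqs.effective_totals[sl]
    n_total = (freqs.observed_reads(sh) + freqs.observed_reads(sl)).to_numpy()
    rho = 2.0**predicted_e
    f_low = n_total / (rho * t_h + t_l)
    f_high = rho * f_low
    idx = freqs.freq_pooled.index
    return pd.Series(f_high, index=idx), pd.Series(f_low, index=idx)


def clo_differential(
    freqs: FrequencyFrame,
    design: ScreenDesign,
    trend: TrendModel,
    model: VarianceModel,
    pairs: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Differential CLO scores for every guide.

    The likelihood-ratio sum runs over the two stimulated samples; the sign
    is that of the observed stimulated enrichment minus its trend
    prediction.  Returns per-guide columns ``clo``, ``sign``, ``residual``
    (observed minus predicted stimulated enrichment) and ``read_floor_ok``.
    """
    if pairs is None:
        raise ValueError("pass the enrichment pairs computed on the same totals")
    idx = freqs.freq_pooled.index
    e_u = pairs["e_unstim"].to_numpy()
    e_hat = trend.predict(e_u)
    f_high_null, f_low_null = _trend_null_frequencies(freqs, design, e_hat)

    sh = design.sample_for("stim_high")
    sl = design.sample_for("stim_low")

    # The trend prediction is made from the *measured* basal enrichment, so
    # the null's bin split is itself uncertain for guides whose unstimulated
    # counts are noisy (e.g. strongly depleted basal hits).  Delta method:
    # an error in ê moves the high-bin share s = ρT_h/(ρT_h + T_l) by
    # s(1−s)·ln2 per log2 unit, scaled by the local trend slope.  Each stim
    # sample's log-LR term is weighted by the reliability
    # v_read / (v_read + v_trend): the fraction of the null-deviation
    # variance attributable to read noise.  Guides in the flat part of the
    # trend (the control cloud) have v_trend ≈ 0 and weight 1.
    uh, ul = design.sample_for("unstim_high"), design.sample_for("unstim_low")
    ln2 = np.log(2.0)
    var_eu = np.zeros(len(idx))
    for s in (uh, ul):
        n_ps = freqs.observed_reads(s).to_numpy() + ENRICH_PSEUDOCOUNT
        var_eu += predict_variance(model, n_ps) / n_ps**2
    var_eu /= ln2**2
    var_ehat = trend.derivative(e_u) ** 2 * var_eu

    t_h = freqs.effective_totals[sh]
    t_l = freqs.effective_totals[sl]
    rho = 2.0**e_hat
    share = rho * t_h / (rho * t_h + t_l)
    n_stim = (freqs.observed_reads(sh) + freqs.observed_reads(sl)).to_numpy()
    var_split = (n_stim * share * (1 - share) * ln2) ** 2 * var_ehat

    terms = np.zeros(len(idx))
    terms_raw = np.zeros(len(idx))
    for s, f_null in ((sh, f_high_null), (sl, f_low_null)):
        n = freqs.observed_reads(s).to_numpy()
        mu_null = f_null.to_numpy() * freqs.effective_totals[s]
        v_read = predict_variance(model, mu_null)
        num = nb_log10_pmf(n, n, predict_variance(model, n))
        den = nb_log10_pmf(n, mu_null, v_read)
        with np.errstate(invalid="ignore"):
            weight = np.where(
                v_read > 0, v_read / (v_read + var_split), 1.0
            )
        terms_raw += num - den
        terms += weight * (num - den)

    residual = pairs["e_stim"].to_numpy() - e_hat
    sign = np.sign(residual)
    return pd.DataFrame(
        {
            "clo": sign * terms,
            "clo_unweighted": sign * terms_raw,
            "sign": sign.astype(int),
            "residual": residual,
            "read_floor_ok": pairs["read_floor_ok"].to_numpy(),
        },
        index=idx,
    )


@dataclass
class DifferentialResult:
    """Basal, post-stimulation and differential score sets for one screen."""

    basal: ScreenResult
    stim: ScreenResult
    differential: ScreenResult
    trend: TrendModel
    enrichment_pairs: pd.DataFrame

    def gene_table(self) -> pd.DataFrame:
        """Wide per-gene table with basal_/stim_/diff_ column blocks."""
        blocks = {
            "basal": self.basal.gene_table,
            "stim": self.stim.gene_table,
            "diff": self.differential.gene_table,
        }
        out = None
        for prefix, tab in blocks.items():
            renamed = tab.add_prefix(f"{prefix}_")
            out = renamed if out is None else out.join(renamed, how="outer")
        return out


def differential_pipeline(
    counts: CountMatrix,
    library: GuideLibrary,
    design: ScreenDesign,
    options: Optional[ScoringOptions] = None,
    trend_family: str = "lowess",
) -> DifferentialResult:
    """Full four-sample analysis.

    Emits the two two-sample analyses (basal pair and stimulated pair) plus
    the trend-conditioned differential analysis, each with CLO scores,
    empirical p-values, effects and pFDR hit calls.
    """
    options = options or ScoringOptions()
    if design.mode != "four_sample":
        raise ValueError("differential_pipeline requires a four_sample design")
    counts = counts.align_to(library)

    basal = score_two_sample(
        counts,
        library,
        high_sample=design.sample_for("unstim_high"),
        low_sample=design.sample_for("unstim_low"),
        options=options,
    )
    stim = score_two_sample(
        counts,
        library,
        high_sample=design.sample_for("stim_high"),
        low_sample=design.sample_for("stim_low"),
        options=options,
    )

    # joint normalization and variance model over all four samples
    freqs = normalize(counts, library, design.samples, rescale=options.rescale_totals)
    model = fit_variance_model(freqs, library)
    pairs = enrichments(counts, design, freqs.effective_totals)
    trend = fit_trend(pairs, family=trend_family)
    diff_scores = clo_differential(freqs, design, trend, model, pairs)

    raw = shrunk = None
    prior = None
    if options.compute_effects:
        raw = pd.Series(
            diff_scores["residual"].to_numpy(),
            index=diff_scores.index,
            name="raw_effect",
        )
        sh = design.sample_for("stim_high")
        sl = design.sample_for("stim_low")
        read_means = counts.counts[design.samples].mean(axis=1)
        prior = eff.fit_prior(
            raw,
            read_means,
            min_reads=options.prior_min_reads,
            bandwidth=options.prior_bandwidth,
        )
        e_hat = trend.predict(pairs["e_unstim"].to_numpy())
        f_high_null, f_low_null = _trend_null_frequencies(freqs, design, e_hat)
        shrunk = eff.shrink_effects(
            freqs,
            model,
            prior,
            high_sample=sh,
            low_sample=sl,
            null_high=f_high_null,
            null_low=f_low_null,
            baseline=pd.Series(e_hat, index=diff_scores.index),
        )

    guide_table, gene_table = build_tables(
        diff_scores["clo"], library, options, raw_effect=raw, shrunk_effect=shrunk
    )
    guide_table["read_floor_ok"] = diff_scores["read_floor_ok"]
    differential = ScreenResult(
        guide_table=guide_table,
        gene_table=gene_table,
        frequencies=freqs,
        variance_model=model,
        prior=prior,
    )
    return DifferentialResult(
        basal=basal,
        stim=stim,
        differential=differential,
        trend=trend,
        enrichment_pairs=pairs,
    )
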