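"""CLO (CRISPR log-odds) scores under a negative-binomial read model.

A guide's score is the sign of its effect (high-bin minus low-bin observed
frequency) times the summed log10 likelihood ratio, over the compared
samples, of an "observed" model in which the guide's true frequency equals
its observed frequency in each sample against a null model in which the
true frequency is the pooled frequency across samples:

    CLO_guide = sign × Σ_samples log10 [ P(n | freq_obs,  var)
                                       / P(n | freq_pool, var) ]

Read-count probabilities come from a negative binomial parametrized by its
mean (frequency × effective total reads) and the variance predicted by the
empirical variance model at that mean.  Gene scores are the sums of their
guides' scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .normalization import FrequencyFrame
from .screen_io import GuideLibrary, TARGETING
from .variance_model import VarianceModel, predict_variance

#: log10 probability assigned to impossible outcomes (positive count under a
#: point mass at zero); a large finite constant keeps score sums finite
LOG10_IMPOSSIBLE = -1.0e6


def nb_log10_pmf(n, mean, variance):
    """log10 of the negative-binomial pmf with given mean and variance.

    Uses the shape/success parametrization r = mean²/(variance − mean),
    p = mean/variance, evaluated through log-gamma for numerical stability.
    ``mean = 0`` is treated as a point mass at zero reads.  Accepts scalars
    or broadcastable arrays.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(mean, dtype=float)
    v = np.asarray(variance, dtype=float)
    n, m, v = np.broadcast_arrays(n, m, v)

    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    pos = m > 0
    if (v[pos] <= m[pos]).any():
        raise ValueError(
            "variance must exceed mean for a negative binomial; "
            "apply the variance-model floor first"
        )

    out = np.empty(n.shape, dtype=float)
    # degenerate point mass at zero
    out[~pos] = np.where(n[~pos] == 0, 0.0, LOG10_IMPOSSIBLE)
    if pos.any():
        mp, vp, np_ = m[pos], v[pos], n[pos]
        r = mp * mp / (vp - mp)
        p = mp / vp  # success fraction; mean = r(1-p)/p
        ln10 = np.log(10.0)
        out[pos] = (
            gammaln(np_ + r)
            - gammaln(r)
            - gammaln(np_ + 1.0)
            + r * np.log(p)
            + np_ * np.log1p(-p)
        ) / ln10
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class GuideScore:
    """Per-guide CLO score with its per-sample log10 LR terms."""

    guide_id: str
    clo: float
    sign: int
    terms: pd.Series  # per-sample log10 likelihood-ratio terms


def _lr_terms(
    frequencies: FrequencyFrame, model: VarianceModel
) -> pd.DataFrame:
    """Per-guide per-sample log10 likelihood-ratio terms (observed vs pooled).

    The variance is evaluated at each model's own mean: a shared variance
    would be undefined when one of the means is zero.
    """
    terms = {}
    for s in frequencies.samples:
        n_obs = frequencies.observed_reads(s).to_numpy()
        mu_obs = n_obs  # observed-frequency model mean equals the count itself
        mu_null = frequencies.expected_reads(s).to_numpy()
        num = nb_log10_pmf(n_obs, mu_obs, predict_variance(model, mu_obs))
        den = nb_log10_pmf(n_obs, mu_null, predict_variance(model, mu_null))
        terms[s] = num - den
    return pd.DataFrame(terms, index=frequencies.freq_pooled.index)


def clo_guides(
    frequencies: FrequencyFrame,
    model: VarianceModel,
    high_sample: str,
    low_sample: str,
) -> pd.DataFrame:
    """CLO scores for every guide in a two-sample (low/high bin) comparison.

    Returns a frame indexed by guide with the per-sample log10 LR terms, the
    effect ``sign`` (+1 when the guide is relatively enriched in the high
    bin, −1 in the low bin, 0 on an exact tie) and the signed ``clo``.
    """
    for s in (high_sample, low_sample):
        if s not in frequencies.samples:
            raise ValueError(f"sample {s!r} not in the compared set")
    terms = _lr_terms(frequencies, model)
    diff = (
        frequencies.freq_observed[high_sample]
        - frequencies.freq_observed[low_sample]
    )
    sign = np.sign(diff.to_numpy())
    total = terms.sum(axis=1).to_numpy()
    out = terms.copy()
    out["sign"] = sign.astype(int)
    out["clo"] = sign * total
    return out


def clo_guide(
    guide_id: str,
    frequencies: FrequencyFrame,
    model: VarianceModel,
    high_sample: str,
    low_sample: str,
) -> GuideScore:
    """CLO score for a single guide (see :func:`clo_guides`)."""
    if guide_id not in frequencies.freq_pooled.index:
        raise KeyError(f"guide {guide_id!r} absent from frequencies")
    row = clo_guides(frequencies, model, high_sample, low_sample).loc[guide_id]
    samples = frequencies.samples
    return GuideScore(
        guide_id=guide_id,
        clo=float(row["clo"]),
        sign=int(row["sign"]),
        terms=row[samples],
    )


def clo_genes(guide_clo: pd.Series, library: GuideLibrary) -> pd.Series:
    """Gene-level CLO scores: the sum of the gene's guide scores.

    Genes none of whose guides were scored are absent from the output.
    """
    tab = library.table
    targeting = tab.index[tab["category"] == TARGETING]
    scored = targeting.intersection(guide_clo.index)
    if scored.empty:
        return pd.Series(dtype=float, name="clo")
    genes = tab.loc[scored, "gene"]
    out = guide_clo.loc[scored].groupby(genes).sum()
    out.name = "clo"
    out.index.name = "gene"
    return out
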