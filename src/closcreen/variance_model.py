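"""Empirical mean→variance model for sequencing read counts.

Measurement variance is estimated from control guides only, to avoid
inflating the variance with real phenotypic effects.  For every control
guide and compared sample we form the deviation between observed reads and
the null expectation (pooled frequency × effective total).  Guides are
binned by expected read number on a fixed logarithmic grid (10^1.2 through
10^3 in steps of 10^0.05, i.e. 36 bins); the per-bin variance of the pooled
deviations, corrected by n_samples/(n_samples−1) for the degree of freedom
spent estimating the expectation, is regressed log-log against the bin
center.  Prediction applies a floor of 1.01 × mean so that the downstream
negative-binomial model is always (just) overdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import FrequencyFrame
from .screen_io import GuideLibrary

#: fixed binning grid for expected read number (log10 of the edges)
BIN_LOG10_START = 1.2
BIN_LOG10_STOP = 3.0
BIN_LOG10_STEP = 0.05

#: minimum variance as a multiple of the mean (keeps the NB strictly overdispersed)
VARIANCE_FLOOR_FACTOR = 1.01


def bin_edges() -> np.ndarray:
    """Edges of the expected-read bins (37 edges → 36 bins)."""
    n = int(round((BIN_LOG10_STOP - BIN_LOG10_START) / BIN_LOG10_STEP))
    return 10.0 ** (BIN_LOG10_START + BIN_LOG10_STEP * np.arange(n + 1))


@dataclass(frozen=True)
class VarianceModel:
    """log10(variance) = intercept + slope × log10(mean reads), floored."""

    intercept: float
    slope: float
    floor_factor: float = VARIANCE_FLOOR_FACTOR
    diagnostics: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["center", "variance", "n"])
    )

    def predict(self, mean: float | np.ndarray) -> float | np.ndarray:
        return predict_variance(self, mean)


def predict_variance(model: VarianceModel, mean) -> float | np.ndarray:
    """Predicted variance at a given expected read number.

    Zero mean is a point mass at zero reads (variance 0); otherwise the
    fitted power law, floored at ``floor_factor × mean``.
    """
    m = np.asarray(mean, dtype=float)
    if (m < 0).any():
        raise ValueError("mean must be non-negative")
    m_safe = np.where(m > 0, m, 1.0)
    trend = 10.0 ** (model.intercept + model.slope * np.log10(m_safe))
    var = np.where(m > 0, np.maximum(trend, model.floor_factor * m), 0.0)
    if np.isscalar(mean) or np.ndim(mean) == 0:
        return float(var)
    return var


def fit_variance_model(
    frequencies: FrequencyFrame,
    library: GuideLibrary,
    floor_factor: float = VARIANCE_FLOOR_FACTOR,
) -> VarianceModel:
    """Fit the log-log variance trend on control-guide deviations.

    Each control guide is binned once, by its expected read number averaged
    over the compared samples, and contributes one deviation per sample to
    its bin.  The log10(variance) ~ log10(mean) line is fitted by least
    squares over the non-empty bins, weighted by bin occupancy; bin centers
    are the geometric means of the edges.
    """
    samples = frequencies.samples
    n_samples = len(samples)
    if n_samples < 2:
        raise ValueError("need at least 2 compared samples to fit a variance model")

    ctrl = library.control_ids.intersection(frequencies.freq_pooled.index)
    if ctrl.empty:
        raise ValueError("no control guides to fit the variance model")

    expected = np.column_stack(
        [frequencies.expected_reads(s).loc[ctrl].to_numpy() for s in samples]
    )
    observed = np.column_stack(
        [frequencies.observed_reads(s).loc[ctrl].to_numpy() for s in samples]
    )
    deviations = observed - expected
    mean_expected = expected.mean(axis=1)

    edges = bin_edges()
    idx = np.digitize(mean_expected, edges) - 1  # -1 = below grid, nbins = above
    nbins = len(edges) - 1

    centers, variances, counts = [], [], []
    for b in range(nbins):
        mask = idx == b
        k = int(mask.sum())
        if k == 0:
            continue
        dev = deviations[mask].ravel()
        # deviations are about the model expectation, so variance is the
        # mean square, with the stated dof correction
        var = float(np.mean(dev**2) * n_samples / (n_samples - 1))
        if var <= 0:
            continue
        centers.append(float(np.sqrt(edges[b] * edges[b + 1])))
        variances.append(var)
        counts.append(k)

    if len(centers) < 3:
        raise ValueError(
            f"only {len(centers)} non-empty variance bins; need ≥ 3 "
            "(simulate or sequence deeper so control guides span the "
            "expected-read grid)"
        )

    x = np.log10(centers)
    y = np.log10(variances)
    # least squares weighted by bin occupancy: the sampling variance of a
    # log bin-variance scales as 1/n, and near-empty edge bins would
    # otherwise dominate the fit
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(counts))
    diagnostics = pd.DataFrame(
        {"center": centers, "variance": variances, "n": counts}
    )
    return VarianceModel(
        intercept=float(intercept),
        slope=float(slope),
        floor_factor=floor_factor,
        diagnostics=diagnostics,
    )
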