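"""Control-guide normalization across sorted samples.

Selection during sorting enriches or depletes guides with real phenotypes,
so raw column totals are a biased measure of sequencing effort.  The scaling
here relies on control guides (non-targeting and safe-targeting), which are
expected to have no phenotype: for each sample the scaling factor is the
median, over control guides, of the guide's observed frequency in that
sample divided by its frequency in the data pooled across the compared
samples.  The *effective* total reads of a sample is its actual total times
this factor.

By default the factors are then rescaled by a single global constant so the
effective totals sum to the actual grand total.  The rescaling cancels out
of every frequency ratio and every downstream read-count expectation; it
only pins the overall frequency scale so that the median control-guide
observed/pooled frequency ratio is exactly 1 in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_io import CountMatrix, GuideLibrary


@dataclass(frozen=True)
class FrequencyFrame:
    """Observed and pooled guide frequencies for a set of compared samples.

    freq_observed[g, s] = count[g, s] / effective_total[s]
    freq_pooled[g]      = sum_s count[g, s] / sum_s effective_total[s]
    """

    samples: list[str]
    effective_totals: pd.Series
    freq_observed: pd.DataFrame
    freq_pooled: pd.Series

    def expected_reads(self, sample: str) -> pd.Series:
        """Null-model mean reads per guide: pooled frequency × effective total."""
        return self.freq_pooled * self.effective_totals[sample]

    def observed_reads(self, sample: str) -> pd.Series:
        return self.freq_observed[sample] * self.effective_totals[sample]


def effective_totals(
    counts: CountMatrix,
    library: GuideLibrary,
    samples: list[str] | None = None,
    rescale: bool = True,
) -> pd.Series:
    """Control-guide effective total reads for each compared sample.

    Control guides with zero pooled count are excluded from the median
    (a 0/0 ratio carries no scaling information).  ``rescale`` applies the
    global constant described in the module docstring.
    """
    samples = list(samples) if samples is not None else counts.samples
    sub = counts.counts[samples]
    actual = sub.sum(axis=0).astype(float)
    if (actual == 0).any():
        zero = actual.index[actual == 0].tolist()
        raise ValueError(f"sample(s) with zero total reads: {zero}")

    ctrl = sub.loc[sub.index.intersection(library.control_ids)]
    if ctrl.empty:
        raise ValueError("no control guides available for normalization")
    pooled = ctrl.sum(axis=1).astype(float) / actual.sum()
    keep = pooled > 0
    if not keep.any():
        raise ValueError("all control guides have zero pooled counts")

    factors = {}
    for s in samples:
        obs = ctrl.loc[keep, s].astype(float) / actual[s]
        factors[s] = float(np.median(obs / pooled[keep]))
    factors = pd.Series(factors)
    if (factors <= 0).any():
        raise ValueError(
            "non-positive scaling factor: too many control guides with zero "
            "counts; sequence deeper or check the library join"
        )
    eff = actual * factors
    if rescale:
        eff = eff * (actual.sum() / eff.sum())
    return eff


def frequencies(counts: CountMatrix, totals: pd.Series) -> FrequencyFrame:
    """Observed and pooled frequencies given per-sample effective totals."""
    samples = list(totals.index)
    sub = counts.counts[samples].astype(float)
    freq_obs = sub / totals
    freq_pooled = sub.sum(axis=1) / totals.sum()
    return FrequencyFrame(
        samples=samples,
        effective_totals=totals.astype(float),
        freq_observed=freq_obs,
        freq_pooled=freq_pooled,
    )


def normalize(
    counts: CountMatrix,
    library: GuideLibrary,
    samples: list[str] | None = None,
    rescale: bool = True,
) -> FrequencyFrame:
    """Convenience wrapper: effective totals then frequencies."""
    totals = effective_totals(counts, library, samples, rescale=rescale)
    return frequencies(counts, totals)
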