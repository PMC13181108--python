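"""Empirical p-values, gene-level combination, signed log P-scores and hits.

Guide p-values are rank-based against the control-guide score distribution:
the negative-direction p is (0.5 + number of controls with a strictly lower
score) / (number of controls); the positive-direction p is its complement.
Gene p-values combine the per-guide directional p-values under a uniform
null (Fisher's method by default, or an empirical pseudo-gene null built by
resampling control guides).  Hits are called per direction at a positive
false discovery rate (Storey pFDR) threshold, 0.05 by default, with
Benjamini–Hochberg available as an alternative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def guide_empirical_p(scores, control_scores) -> pd.DataFrame:
    """Directional empirical p-values for guide scores against a control null.

    ``p_neg = (0.5 + #controls strictly lower) / N`` and ``p_pos = 1 − p_neg``
    exactly.  Ties with a control score count as "not lower".  A score above
    every control is treated as having N − 1 controls lower, so both
    directional p-values stay inside (0, 1) with a floor of 0.5/N — the
    resolution limit of the control set.  Accepts a scalar, array or Series
    of scores; returns a frame with columns ``p_neg`` / ``p_pos``.
    """
    controls = np.sort(np.asarray(control_scores, dtype=float))
    n = controls.size
    if n == 0:
        raise ValueError("empty control score set")
    if n < 100:
        warnings.warn(
            f"only {n} control scores; empirical p-values will be coarse"
        )
    s = np.asarray(scores, dtype=float)
    lower = np.minimum(np.searchsorted(controls, s, side="left"), n - 1)
    p_neg = (0.5 + lower) / n
    p_pos = 1.0 - p_neg
    index = scores.index if isinstance(scores, pd.Series) else None
    return pd.DataFrame({"p_neg": p_neg, "p_pos": p_pos}, index=index)


def combine_gene_p(guide_ps, method: str = "fisher") -> float:
    """Combine one direction's guide p-values into a single gene p-value.

    ``fisher``: −2 Σ ln p ~ χ² with 2k degrees of freedom under the uniform
    null.  At k = 1 this is the identity.
    """
    p = np.asarray(guide_ps, dtype=float)
    if p.size == 0:
        raise ValueError("no guide p-values to combine")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if method != "fisher":
        raise ValueError(f"unknown combination method {method!r}")
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * p.size))


def combine_gene_p_frame(
    guide_p: pd.DataFrame, genes: pd.Series, method: str = "fisher"
) -> pd.DataFrame:
    """Per-gene Fisher combination of guide ``p_neg`` / ``p_pos`` columns."""
    if method != "fisher":
        raise ValueError(f"unknown combination method {method!r}")

    def _fisher(col: pd.Series) -> pd.Series:
        grouped = (-2.0 * np.log(col)).groupby(genes)
        stat = grouped.sum()
        k = grouped.size()
        return pd.Series(
            stats.chi2.sf(stat.to_numpy(), 2 * k.to_numpy()), index=stat.index
        )

    aligned = guide_p.loc[genes.index]
    out = pd.DataFrame(
        {
            "p_neg": _fisher(aligned["p_neg"]),
            "p_pos": _fisher(aligned["p_pos"]),
        }
    )
    out.index.name = "gene"
    return out


def empirical_gene_p(
    gene_clo: pd.Series,
    n_guides: pd.Series,
    control_clo,
    rng: np.random.Generator,
    n_pseudo: int = 10000,
) -> pd.DataFrame:
    """Empirical gene p-values from pseudo-genes of resampled control guides.

    For each distinct guide count k, ``n_pseudo`` pseudo-genes are formed by
    summing k control-guide CLO scores drawn with replacement; gene CLO
    values are then ranked against that null with the same
    (0.5 + #lower)/N convention used at the guide level.
    """
    controls = np.asarray(control_clo, dtype=float)
    if controls.size == 0:
        raise ValueError("empty control score set")
    p_neg = pd.Series(index=gene_clo.index, dtype=float)
    for k in sorted(n_guides.unique()):
        null = controls[
            rng.integers(0, controls.size, size=(n_pseudo, int(k)))
        ].sum(axis=1)
        null.sort()
        members = n_guides.index[n_guides == k]
        lower = np.searchsorted(null, gene_clo.loc[members].to_numpy(), side="left")
        p_neg.loc[members] = (0.5 + lower) / n_pseudo
    return pd.DataFrame({"p_neg": p_neg, "p_pos": 1.0 - p_neg})


def logP_score(p, direction) -> float | np.ndarray:
    """Signed log P-score: sign of the effect × (−log10 p).

    Negative effects (surface-level decreases) get negative scores.  p = 0
    is clamped to the smallest positive float with a warning (empirical
    p-values cannot be 0, so this only guards degenerate inputs).
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(direction, dtype=float)
    if (p == 0).any():
        warnings.warn("p = 0 clamped to the smallest representable value")
        p = np.maximum(p, np.finfo(float).tiny)
    out = d * (-np.log10(p))
    if out.ndim == 0:
        return float(out)
    return out


def storey_qvalues(pvalues, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey positive-FDR q-values with smoother π₀ estimation.

    π₀(λ) = #{p > λ} / (m (1 − λ)) is evaluated on a λ grid, smoothed with a
    cubic spline, and read off at the largest λ; q-values are the usual
    step-up minimum of π₀ · m · p(i) / i.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array(
        [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    )
    if m < 100 or np.all(pi0_lambda == 0):
        pi0 = 1.0
    else:
        try:
            from scipy.interpolate import UnivariateSpline

            spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
            pi0 = float(spline(lambdas[-1]))
        except Exception:
            pi0 = float(pi0_lambda[-1])
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (fallback to Storey pFDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def call_hits(
    gene_p: pd.DataFrame,
    alpha: float = 0.05,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """One-tailed hit calling per direction at a pFDR threshold.

    q-values are computed within each direction separately.  A gene's
    reported direction is the one with the smaller p; it is a hit when the
    q-value in that direction is below ``alpha``.  Returns columns
    ``p``, ``direction``, ``logP``, ``q``, ``is_hit``.
    """
    qfunc = {"storey": storey_qvalues, "bh": bh_qvalues}.get(fdr_method)
    if qfunc is None:
        raise ValueError(f"unknown fdr method {fdr_method!r}")
    q_neg = qfunc(gene_p["p_neg"].to_numpy())
    q_pos = qfunc(gene_p["p_pos"].to_numpy())

    neg_wins = gene_p["p_neg"].to_numpy() <= gene_p["p_pos"].to_numpy()
    direction = np.where(neg_wins, -1, 1)
    # exact 0.5/0.5 tie carries no direction
    direction = np.where(
        gene_p["p_neg"].to_numpy() == gene_p["p_pos"].to_numpy(), 0, direction
    )
    p = np.where(neg_wins, gene_p["p_neg"], gene_p["p_pos"])
    q = np.where(neg_wins, q_neg, q_pos)
    out = pd.DataFrame(
        {
            "p": p,
            "direction": direction,
            "logP": logP_score(p, direction),
            "q": q,
            "is_hit": q < alpha,
        },
        index=gene_p.index,
    )
    return out
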