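"""End-to-end two-sample (low bin vs high bin) screen scoring.

Stages: control-guide normalization → empirical variance model → guide and
gene CLO scores → empirical p-values against the control-guide null →
gene-level p combination → signed log P-scores → effect-size estimation →
pFDR hit calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import effects as eff
from . import inference as inf
from .normalization import FrequencyFrame, normalize
from .scoring import clo_genes, clo_guides
from .screen_io import CountMatrix, GuideLibrary, ScreenDesign, TARGETING
from .variance_model import VarianceModel, fit_variance_model


@dataclass
class ScoringOptions:
    """Tunable knobs for a scoring run (defaults follow the screen design)."""

    alpha: float = 0.05
    fdr_method: str = "storey"  # or "bh"
    gene_p_method: str = "fisher"  # or "empirical"
    compute_effects: bool = True
    effect_aggregation: str = "median"
    prior_min_reads: float = eff.PRIOR_MIN_READS
    prior_bandwidth: Optional[float] = None
    n_pseudo_genes: int = 10000
    seed: int = 0
    rescale_totals: bool = True


@dataclass
class ScreenResult:
    """Scored guide and gene tables plus the fitted models."""

    guide_table: pd.DataFrame
    gene_table: pd.DataFrame
    frequencies: FrequencyFrame
    variance_model: VarianceModel
    prior: Optional[eff.EffectPrior] = None

    def summary(self) -> dict:
        hits = self.gene_table[self.gene_table["is_hit"]]
        return {
            "n_guides": int(len(self.guide_table)),
            "n_genes": int(len(self.gene_table)),
            "n_hits": int(len(hits)),
            "n_hits_positive": int((hits["direction"] > 0).sum()),
            "n_hits_negative": int((hits["direction"] < 0).sum()),
            "variance_intercept": self.variance_model.intercept,
            "variance_slope": self.variance_model.slope,
        }


def build_tables(
    guide_clo: pd.Series,
    library: GuideLibrary,
    options: ScoringOptions,
    raw_effect: Optional[pd.Series] = None,
    shrunk_effect: Optional[pd.Series] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guide and gene score tables from per-guide CLO scores.

    Shared by the two-sample and four-sample differential analyses: both
    produce a per-guide CLO score whose null distribution is read off the
    control guides.
    """
    lib = library.table.loc[guide_clo.index]
    control_clo = guide_clo[lib["category"].isin(["non_targeting", "safe_targeting"])]

    guide_p = inf.guide_empirical_p(guide_clo, control_clo)
    p_min = guide_p.min(axis=1)
    direction = np.where(guide_p["p_neg"] <= guide_p["p_pos"], -1, 1)
    direction = np.where(guide_p["p_neg"] == guide_p["p_pos"], 0, direction)

    qfunc = {"storey": inf.storey_qvalues, "bh": inf.bh_qvalues}[options.fdr_method]
    q_neg = qfunc(guide_p["p_neg"].to_numpy())
    q_pos = qfunc(guide_p["p_pos"].to_numpy())
    guide_q = np.where(guide_p["p_neg"] <= guide_p["p_pos"], q_neg, q_pos)
    guide_table = pd.DataFrame(
        {
            "gene": lib["gene"],
            "category": lib["category"],
            "clo": guide_clo,
            "p_neg": guide_p["p_neg"],
            "p_pos": guide_p["p_pos"],
            "p": p_min,
            "logP": inf.logP_score(p_min, direction),
            "q": guide_q,
            "hit_direction": np.where(guide_q < options.alpha, direction, 0),
        }
    )
    if raw_effect is not None:
        guide_table["raw_effect"] = raw_effect
    if shrunk_effect is not None:
        guide_table["effect"] = shrunk_effect
    guide_table.index.name = "guide_id"

    targeting = lib["category"] == TARGETING
    genes = lib.loc[targeting, "gene"]
    gene_clo = clo_genes(guide_clo, library)
    n_guides = genes.groupby(genes).size()

    if options.gene_p_method == "fisher":
        gene_p = inf.combine_gene_p_frame(guide_p.loc[genes.index], genes)
    elif options.gene_p_method == "empirical":
        rng = rng if rng is not None else np.random.default_rng(options.seed)
        gene_p = inf.empirical_gene_p(
            gene_clo, n_guides, control_clo, rng, options.n_pseudo_genes
        )
    else:
        raise ValueError(f"unknown gene p method {options.gene_p_method!r}")

    hits = inf.call_hits(gene_p, alpha=options.alpha, fdr_method=options.fdr_method)
    gene_table = pd.DataFrame(
        {
            "clo": gene_clo,
            "n_guides": n_guides,
            "p_neg": gene_p["p_neg"],
            "p_pos": gene_p["p_pos"],
        }
    ).join(hits)
    gene_table["hit_direction"] = np.where(
        gene_table["is_hit"], gene_table["direction"], 0
    )
    if raw_effect is not None:
        gene_table["raw_effect"] = eff.gene_effects(
            raw_effect, genes, options.effect_aggregation
        )
    if shrunk_effect is not None:
        gene_table["effect"] = eff.gene_effects(
            shrunk_effect, genes, options.effect_aggregation
        )
    gene_table.index.name = "gene"
    return guide_table, gene_table.sort_index()


def score_two_sample(
    counts: CountMatrix,
    library: GuideLibrary,
    high_sample: str,
    low_sample: str,
    options: Optional[ScoringOptions] = None,
) -> ScreenResult:
    """Score a two-sample FACS-bin comparison (high bin vs low bin)."""
    options = options or ScoringOptions()
    counts = counts.align_to(library)
    freqs = normalize(
        counts, library, [low_sample, high_sample], rescale=options.rescale_totals
    )
    model = fit_variance_model(freqs, library)
    scores = clo_guides(freqs, model, high_sample, low_sample)
    guide_clo = scores["clo"]

    prior = None
    raw = shrunk = None
    if options.compute_effects:
        raw_frame = eff.raw_effects(freqs, high_sample, low_sample)
        raw = raw_frame["raw_effect"]
        read_means = counts.counts[[low_sample, high_sample]].mean(axis=1)
        prior = eff.fit_prior(
            raw,
            read_means,
            min_reads=options.prior_min_reads,
            bandwidth=options.prior_bandwidth,
        )
        shrunk = eff.shrink_effects(freqs, model, prior, high_sample, low_sample)

    guide_table, gene_table = build_tables(
        guide_clo, library, options, raw_effect=raw, shrunk_effect=shrunk
    )
    return ScreenResult(
        guide_table=guide_table,
        gene_table=gene_table,
        frequencies=freqs,
        variance_model=model,
        prior=prior,
    )


def score_design(
    counts: CountMatrix,
    library: GuideLibrary,
    design: ScreenDesign,
    options: Optional[ScoringOptions] = None,
) -> ScreenResult:
    """Score a two-sample design by its declared low/high bin roles."""
    if design.mode != "two_sample":
        raise ValueError("score_design expects a two-sample design")
    return score_two_sample(
        counts,
        library,
        high_sample=design.sample_for("high_bin"),
        low_sample=design.sample_for("low_bin"),
        options=options,
    )
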