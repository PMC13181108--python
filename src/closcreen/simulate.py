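"""Synthetic FACS-binned CRISPR screens with known ground truth.

The generative model mirrors the screen design it is used to test: a
knockout library of 10 guides per gene plus 5644 non-targeting and 6750
safe-targeting control guides, ~1000 cells per guide, top/bottom 30% sort
gates, and overdispersed sequencing counts.

Per guide, each cell draws a latent log surface-receptor level from
Normal(effect × efficacy, 1) — the unit is one standard deviation of the
cell-to-cell spread.  Sort gates are the population quantiles of the pooled
cell mixture, so a guide's chance of landing in the low/high bin follows
from normal tail probabilities; cell tallies per bin are multinomial.  Bin
tallies become sequencing reads through a negative binomial with the
configured mean depth and a variance of overdispersion × mean.  In
four-sample mode the stimulated condition shifts the latent mean by
basal_shift + stim_shift, recomputes the gates on the stimulated
population, and re-bins independently differentiated cells.

Library representation is not uniform: cloning and passaging spread guide
abundances over roughly an order of magnitude, which is what lets the
mean→variance trend be estimated across read depths.  Each guide carries a
fixed lognormal abundance weight (mean 1), shared between conditions, and
its cell count per condition is Poisson around cells_per_guide × weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .screen_io import (
    NON_TARGETING,
    SAFE_TARGETING,
    TARGETING,
    CountMatrix,
    GuideLibrary,
    ScreenDesign,
)

TWO_SAMPLE_SAMPLES = {"low": "low_bin", "high": "high_bin"}
FOUR_SAMPLE_SAMPLES = {
    "unstim_low": "unstim_low",
    "unstim_high": "unstim_high",
    "stim_low": "stim_low",
    "stim_high": "stim_high",
}


@dataclass
class SimulationConfig:
    """Study-design parameters of a simulated screen.

    Defaults follow the screen being emulated: 10 guides/gene, 5644
    non-targeting + 6750 safe-targeting controls, 1000 cells/guide and 30%
    sort gates.  ``reads_per_guide`` is the mean sequencing depth per guide
    in each sorted sample; ``overdispersion`` multiplies the Poisson
    variance.  ``effect_table`` is a per-gene frame with ``basal_shift``
    and ``stim_shift`` columns in latent-SD units (genes absent from it
    have no effect).  ``guide_efficacy`` draws per-guide attenuation in
    [0, 1] from Beta(a, b); the default Beta(5, 1) makes most guides
    effective with a weak tail.
    """

    n_genes: int = 200
    guides_per_gene: int = 10
    n_nontargeting: int = 5644
    n_safetargeting: int = 6750
    cells_per_guide: int = 1000
    sort_fraction: float = 0.30
    reads_per_guide: float = 300.0
    overdispersion: float = 2.0
    abundance_sigma: float = 0.5  # SD of ln(abundance weight)
    effect_table: Optional[pd.DataFrame] = None
    efficacy_beta: tuple[float, float] = (5.0, 1.0)
    mode: str = "two_sample"
    seed: int = 0

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"GENE{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimulatedScreen:
    """Counts plus ground truth for recovery and calibration tests."""

    counts: CountMatrix
    library: GuideLibrary
    design: ScreenDesign
    truth_genes: pd.DataFrame  # basal_shift, stim_shift per gene
    truth_guides: pd.DataFrame  # gene, efficacy per guide


def _build_library(config: SimulationConfig) -> GuideLibrary:
    rows = []
    for gene in config.gene_names():
        for i in range(1, config.guides_per_gene + 1):
            rows.append((f"{gene}_g{i}", TARGETING, gene))
    for i in range(1, config.n_nontargeting + 1):
        rows.append((f"nt_{i:05d}", NON_TARGETING, ""))
    for i in range(1, config.n_safetargeting + 1):
        rows.append((f"st_{i:05d}", SAFE_TARGETING, ""))
    table = pd.DataFrame(rows, columns=["guide_id", "category", "gene"])
    return GuideLibrary(table.set_index("guide_id"))


def _gate_thresholds(
    shifts: np.ndarray, weights: np.ndarray, sort_fraction: float
) -> tuple[float, float]:
    """Population quantiles of the abundance-weighted normal mixture."""
    w = weights / weights.sum()

    def mixture_cdf(t: float) -> float:
        return float(w @ stats.norm.cdf(t - shifts))

    lo = optimize.brentq(lambda t: mixture_cdf(t) - sort_fraction, -20, 20)
    hi = optimize.brentq(lambda t: mixture_cdf(t) - (1 - sort_fraction), -20, 20)
    return lo, hi


def _bin_tallies(
    shifts: np.ndarray,
    cells: np.ndarray,
    weights: np.ndarray,
    sort_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    t_lo, t_hi = _gate_thresholds(shifts, weights, sort_fraction)
    p_low = stats.norm.cdf(t_lo - shifts)
    p_high = stats.norm.sf(t_hi - shifts)
    p_rest = np.clip(1.0 - p_low - p_high, 0.0, 1.0)
    pvals = np.column_stack([p_low, p_high, p_rest])
    pvals /= pvals.sum(axis=1, keepdims=True)
    tallies = rng.multinomial(cells, pvals)
    return tallies[:, 0], tallies[:, 1]


def _sequence_reads(
    tallies: np.ndarray,
    total_reads: float,
    overdispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    total_cells = tallies.sum()
    if total_cells == 0:
        return np.zeros_like(tallies)
    mu = tallies / total_cells * total_reads
    pos = mu > 0
    reads = np.zeros(len(tallies), dtype=np.int64)
    if overdispersion <= 1.0:
        reads[pos] = rng.poisson(mu[pos])
        return reads
    r = mu[pos] / (overdispersion - 1.0)
    p = 1.0 / overdispersion
    reads[pos] = rng.negative_binomial(r, p)
    return reads


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate a reproducible synthetic screen from a config and seed."""
    library = _build_library(config)
    genes = config.gene_names()

    effect = pd.DataFrame(
        0.0, index=genes, columns=["basal_shift", "stim_shift"]
    )
    if config.effect_table is not None:
        unknown = config.effect_table.index.difference(effect.index)
        if len(unknown):
            raise ValueError(
                f"effect_table references unknown genes: {unknown[:5].tolist()}"
            )
        for col in ("basal_shift", "stim_shift"):
            if col in config.effect_table:
                effect.loc[config.effect_table.index, col] = config.effect_table[col]

    # deterministic per-stage child streams from the one root seed
    children = np.random.SeedSequence(config.seed).spawn(8)
    rng_eff = np.random.default_rng(children[0])

    tab = library.table
    is_targeting = (tab["category"] == TARGETING).to_numpy()
    efficacy = np.zeros(len(tab))
    a, b = config.efficacy_beta
    efficacy[is_targeting] = rng_eff.beta(a, b, size=int(is_targeting.sum()))

    # library representation: fixed lognormal abundance weight per guide
    rng_abund = np.random.default_rng(children[6])
    sigma = config.abundance_sigma
    weights = rng_abund.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(tab))
    rng_cells = np.random.default_rng(children[7])

    gene_of_guide = tab["gene"].to_numpy()
    basal = np.zeros(len(tab))
    stim_extra = np.zeros(len(tab))
    basal[is_targeting] = effect["basal_shift"].reindex(
        gene_of_guide[is_targeting]
    ).to_numpy()
    stim_extra[is_targeting] = effect["stim_shift"].reindex(
        gene_of_guide[is_targeting]
    ).to_numpy()

    delta_unstim = basal * efficacy
    delta_stim = (basal + stim_extra) * efficacy

    total_reads = config.reads_per_guide * len(tab)
    columns: dict[str, np.ndarray] = {}

    def _condition(shifts: np.ndarray, rng_bins, rng_lo, rng_hi, low_name, high_name):
        cells = rng_cells.poisson(config.cells_per_guide * weights)
        low, high = _bin_tallies(
            shifts, cells, weights, config.sort_fraction, rng_bins
        )
        columns[low_name] = _sequence_reads(
            low, total_reads, config.overdispersion, rng_lo
        )
        columns[high_name] = _sequence_reads(
            high, total_reads, config.overdispersion, rng_hi
        )

    if config.mode == "two_sample":
        _condition(
            delta_unstim,
            np.random.default_rng(children[1]),
            np.random.default_rng(children[2]),
            np.random.default_rng(children[3]),
            "low",
            "high",
        )
        design = ScreenDesign(
            mode="two_sample",
            roles=TWO_SAMPLE_SAMPLES,
            sort_fraction=config.sort_fraction,
        )
    elif config.mode == "four_sample":
        _condition(
            delta_unstim,
            np.random.default_rng(children[1]),
            np.random.default_rng(children[2]),
            np.random.default_rng(children[3]),
            "unstim_low",
            "unstim_high",
        )
        rng_stim = np.random.default_rng(children[4])
        rng_reads = np.random.default_rng(children[5])
        cells = rng_cells.poisson(config.cells_per_guide * weights)
        low, high = _bin_tallies(
            delta_stim, cells, weights, config.sort_fraction, rng_stim
        )
        columns["stim_low"] = _sequence_reads(
            low, total_reads, config.overdispersion, rng_reads
        )
        columns["stim_high"] = _sequence_reads(
            high, total_reads, config.overdispersion, rng_reads
        )
        design = ScreenDesign(
            mode="four_sample",
            roles=FOUR_SAMPLE_SAMPLES,
            sort_fraction=config.sort_fraction,
        )
    else:
        raise ValueError(f"unknown simulation mode {config.mode!r}")

    counts = CountMatrix(pd.DataFrame(columns, index=tab.index))
    truth_guides = pd.DataFrame(
        {"gene": gene_of_guide, "efficacy": efficacy}, index=tab.index
    )
    return SimulatedScreen(
        counts=counts,
        library=library,
        design=design,
        truth_genes=effect,
        truth_guides=truth_guides,
    )


def truth_evaluation(
    gene_table: pd.DataFrame,
    truth_genes: pd.DataFrame,
    shift_col: str = "basal_shift",
) -> dict:
    """Recovery metrics of a scored gene table against simulation truth.

    Returns the ROC AUC of |logP| for detecting genes with a non-zero
    shift, the realized false-discovery proportion among called hits, and
    the Spearman correlation between estimated gene effects and the true
    latent shifts.  The Spearman is computed over the genes with a non-zero
    true shift: the nulls form one large tied group in the truth, so
    including them only measures rank noise among genes whose true rank is
    undefined.
    """
    from sklearn.metrics import roc_auc_score

    truth = truth_genes.reindex(gene_table.index)
    labels = (truth[shift_col] != 0).to_numpy()
    metrics: dict = {"n_genes": int(len(gene_table)), "n_true": int(labels.sum())}

    if 0 < labels.sum() < len(labels):
        metrics["roc_auc"] = float(
            roc_auc_score(labels, gene_table["logP"].abs().to_numpy())
        )
    else:
        metrics["roc_auc"] = float("nan")

    hits = gene_table["is_hit"].to_numpy()
    n_hits = int(hits.sum())
    metrics["n_hits"] = n_hits
    metrics["realized_fdr"] = (
        float((hits & ~labels).sum() / n_hits) if n_hits else 0.0
    )

    if "effect" in gene_table.columns and labels.sum() >= 3:
        est = gene_table.loc[labels, "effect"].to_numpy()
        true_shift = truth.loc[labels, shift_col].to_numpy()
        rho = stats.spearmanr(est, true_shift).statistic
        metrics["effect_spearman"] = float(rho)
    return metrics
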