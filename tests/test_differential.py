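import numpy as np
import pandas as pd
import pytest

from closcreen import (
    CountMatrix,
    ScreenDesign,
    SimulationConfig,
    TrendModel,
    clo_differential,
    differential_pipeline,
    enrichments,
    fit_trend,
    normalize,
    simulate_screen,
)
from closcreen.normalization import frequencies

FOUR = ScreenDesign(
    "four_sample",
    {
        "unstim_low": "unstim_low",
        "unstim_high": "unstim_high",
        "stim_low": "stim_low",
        "stim_high": "stim_high",
    },
)


def four_sample_counts(rows: dict) -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            rows,
            index=pd.Index(
                ["unstim_low", "unstim_high", "stim_low", "stim_high"]
            ),
        ).T
    )


@pytest.fixture(scope="module")
def four_screen():
    genes = [f"GENE{i:04d}" for i in range(1, 16)]
    effect = pd.DataFrame(
        {
            "basal_shift": [1.5] * 5 + [0.0] * 10,
            "stim_shift": [0.0] * 5 + [1.5] * 5 + [-1.5] * 5,
        },
        index=genes,
    )
    cfg = SimulationConfig(
        n_genes=100,
        n_nontargeting=800,
        n_safetargeting=800,
        reads_per_guide=300,
        effect_table=effect,
        seed=7,
        mode="four_sample",
    )
    return simulate_screen(cfg)


class TestEnrichments:
    def test_pseudocounted_arithmetic(self):
        counts = four_sample_counts({"g": [25, 25, 10, 40]})
        totals = pd.Series(1000.0, index=counts.samples)
        out = enrichments(counts, FOUR, totals)
        assert out["e_unstim"].iloc[0] == 0.0
        assert out["e_stim"].iloc[0] == pytest.approx(np.log2(40.5 / 10.5))

    def test_swapping_bins_negates_enrichment(self):
        counts = four_sample_counts({"g": [10, 40, 10, 40]})
        swapped_design = ScreenDesign(
            "four_sample",
            {
                "unstim_low": "unstim_high",
                "unstim_high": "unstim_low",
                "stim_low": "stim_high",
                "stim_high": "stim_low",
            },
        )
        totals = pd.Series(1000.0, index=counts.samples)
        fwd = enrichments(counts, FOUR, totals)
        rev = enrichments(counts, swapped_design, totals)
        assert fwd["e_unstim"].iloc[0] == pytest.approx(-rev["e_unstim"].iloc[0])

    def test_read_floor_flag(self):
        counts = four_sample_counts({"deep": [100, 100, 100, 100],
                                     "shallow": [2, 2, 2, 2]})
        totals = pd.Series(1000.0, index=counts.samples)
        out = enrichments(counts, FOUR, totals, read_floor=10)
        assert out["read_floor_ok"].tolist() == [True, False]


class TestFitTrend:
    def test_linear_slope_recovery_huber(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=10_000)
        y = 0.6 * x + rng.normal(0, 0.3, size=10_000)
        pairs = pd.DataFrame(
            {"e_unstim": x, "e_stim": y, "read_floor_ok": True}
        )
        trend = fit_trend(pairs, family="huber")
        assert trend.slope == pytest.approx(0.6, abs=0.05)
        assert trend.intercept == pytest.approx(0.0, abs=0.02)

    def test_lowess_tracks_a_linear_relation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=10_000)
        y = 0.6 * x + rng.normal(0, 0.3, size=10_000)
        pairs = pd.DataFrame(
            {"e_unstim": x, "e_stim": y, "read_floor_ok": True}
        )
        trend = fit_trend(pairs, family="lowess")
        grid = np.linspace(-2, 2, 9)
        np.testing.assert_allclose(trend.predict(grid), 0.6 * grid, atol=0.05)

    def test_median_residual_near_zero_on_fitting_set(self, four_screen):
        frame = normalize(four_screen.counts, four_screen.library)
        pairs = enrichments(four_screen.counts, four_screen.design,
                            frame.effective_totals)
        trend = fit_trend(pairs)
        use = pairs[pairs["read_floor_ok"]]
        resid = use["e_stim"] - trend.predict(use["e_unstim"].to_numpy())
        assert abs(np.median(resid)) < 0.02

    def test_degenerate_input_falls_back_to_identity(self):
        pairs = pd.DataFrame(
            {"e_unstim": [1.0] * 10, "e_stim": [2.0] * 10,
             "read_floor_ok": True}
        )
        with pytest.warns(UserWarning, match="identity"):
            trend = fit_trend(pairs)
        assert trend.predict([3.0])[0] == 3.0


class TestCloDifferential:
    def test_zero_when_observation_matches_trend(self):
        # stim split identical to unstim split, identity trend, equal totals
        counts = four_sample_counts({"g": [10, 40, 10, 40],
                                     "pad": [100, 100, 100, 100]})
        totals = pd.Series(1000.0, index=counts.samples)
        freqs = frequencies(counts, totals)
        trend = TrendModel(intercept=0.0, slope=1.0, residual_scale=0.1,
                           family="huber")
        model = _flat_model(2.0)
        out = clo_differential(freqs, FOUR, trend, model, pairs=enrichments(
            counts, FOUR, totals))
        assert out["clo"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert out["residual"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_rescaling_unstim_counts(self):
        # unstim frequencies are free null parameters: scaling both unstim
        # bins of a guide by a common factor must not move the likelihood
        # ratio (the reliability weight deliberately does react to unstim
        # depth, so the invariance is asserted on the unweighted score; the
        # residual 0.5-read pseudocount effect vanishes at these depths)
        base = four_sample_counts({"g": [2000, 6000, 1000, 9000],
                                   "pad": [10000, 10000, 10000, 10000]})
        scaled = four_sample_counts({"g": [4000, 12000, 1000, 9000],
                                     "pad": [10000, 10000, 10000, 10000]})
        totals = pd.Series(100_000.0, index=base.samples)
        trend = TrendModel(intercept=0.05, slope=0.8, residual_scale=0.1,
                           family="huber")
        model = _flat_model(2.0)
        outs = []
        for counts in (base, scaled):
            freqs = frequencies(counts, totals)
            pairs = enrichments(counts, FOUR, totals)
            scores = clo_differential(freqs, FOUR, trend, model, pairs)
            outs.append(scores["clo_unweighted"].iloc[0])
        assert outs[0] == pytest.approx(outs[1], rel=1e-3)

    def test_control_scores_center_near_zero(self, four_screen):
        result = differential_pipeline(
            four_screen.counts, four_screen.library, four_screen.design
        )
        ctrl = result.differential.guide_table.loc[
            four_screen.library.control_ids, "clo"
        ]
        assert abs(ctrl.median()) < 0.05


class TestDifferentialPipeline:
    def test_specificity_and_sensitivity(self, four_screen):
        result = differential_pipeline(
            four_screen.counts, four_screen.library, four_screen.design
        )
        gt = result.gene_table()
        basal_only = [f"GENE{i:04d}" for i in range(1, 6)]
        internalization = [f"GENE{i:04d}" for i in range(6, 11)]
        recycling = [f"GENE{i:04d}" for i in range(11, 16)]

        assert gt.loc[basal_only, "basal_is_hit"].all()
        assert not gt.loc[basal_only, "diff_is_hit"].any()
        assert gt.loc[internalization, "diff_is_hit"].all()
        assert (gt.loc[internalization, "diff_direction"] == 1).all()
        assert gt.loc[recycling, "diff_is_hit"].all()
        assert (gt.loc[recycling, "diff_direction"] == -1).all()

    def test_differential_more_specific_than_stim_pair(self, four_screen):
        result = differential_pipeline(
            four_screen.counts, four_screen.library, four_screen.design
        )
        gt = result.gene_table()
        basal_only = [f"GENE{i:04d}" for i in range(1, 6)]
        stim_hits = gt.loc[basal_only, "stim_is_hit"].sum()
        diff_hits = gt.loc[basal_only, "diff_is_hit"].sum()
        assert diff_hits < stim_hits

    def test_three_score_blocks_for_every_gene(self, four_screen):
        result = differential_pipeline(
            four_screen.counts, four_screen.library, four_screen.design
        )
        gt = result.gene_table()
        assert len(gt) == 100
        for prefix in ("basal", "stim", "diff"):
            for col in ("clo", "p", "logP", "effect", "q"):
                assert f"{prefix}_{col}" in gt.columns
            assert gt[f"{prefix}_p"].notna().all()

    def test_rejects_two_sample_design(self, null_screen):
        with pytest.raises(ValueError, match="four_sample"):
            differential_pipeline(
                null_screen.counts, null_screen.library, null_screen.design
            )


def _flat_model(k: float):
    from closcreen import VarianceModel

    return VarianceModel(intercept=np.log10(k), slope=1.0)
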