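import numpy as np
import pandas as pd
import pytest
from scipy import stats

from closcreen import (
    VarianceModel,
    fit_prior,
    gene_effect,
    gene_effects,
    raw_effects,
    shrink_effects,
)
from closcreen.effects import GRID_POINTS, EffectPrior
from closcreen.normalization import FrequencyFrame
from closcreen.scoring import nb_log10_pmf
from closcreen.variance_model import predict_variance
from test_scoring import flat_variance_model, frame_from_counts


class TestRawEffects:
    def test_equal_frequencies_give_zero(self):
        frame = frame_from_counts(
            {"low": [50], "high": [50]}, {"low": 1000, "high": 1000}
        )
        out = raw_effects(frame, "high", "low")
        assert out["raw_effect"].iloc[0] == 0.0
        assert not out["pseudo"].iloc[0]

    def test_four_to_one_ratio_is_two(self):
        frame = frame_from_counts(
            {"low": [10], "high": [40]}, {"low": 1000, "high": 1000}
        )
        assert raw_effects(frame, "high", "low")["raw_effect"].iloc[0] == (
            pytest.approx(2.0)
        )

    def test_zero_count_uses_pseudocount(self):
        frame = frame_from_counts(
            {"low": [0], "high": [20]}, {"low": 1000, "high": 1000}
        )
        out = raw_effects(frame, "high", "low")
        assert out["pseudo"].iloc[0]
        assert out["raw_effect"].iloc[0] == pytest.approx(np.log2(20.5 / 0.5))

    def test_double_zero_reported_as_zero(self):
        frame = frame_from_counts(
            {"low": [0], "high": [0]}, {"low": 1000, "high": 1000}
        )
        out = raw_effects(frame, "high", "low")
        assert out["raw_effect"].iloc[0] == 0.0
        assert out["pseudo"].iloc[0]


class TestPrior:
    def test_density_normalized_on_grid(self):
        rng = np.random.default_rng(0)
        eff = rng.normal(0, 0.5, size=2000)
        prior = fit_prior(eff, np.full(2000, 500.0))
        area = np.trapezoid(prior.density, prior.support)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_effects_give_symmetric_density(self):
        x = np.concatenate([np.linspace(-2, 2, 1001)])
        prior = fit_prior(x, np.full(x.size, 500.0))
        flipped = np.interp(-prior.support[::-1], prior.support, prior.density)
        np.testing.assert_allclose(
            prior.density[::-1], flipped, rtol=1e-6, atol=1e-9
        )

    def test_low_read_guides_are_excluded(self):
        eff = np.array([0.0] * 300 + [50.0] * 300)
        reads = np.array([500.0] * 300 + [1.0] * 300)
        prior = fit_prior(eff, reads)
        assert prior.n_fit == 300
        assert prior.support.max() < 25  # the outliers never entered

    def test_t_kernel_has_heavier_tails_than_gaussian(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.3, size=2000)
        prior = fit_prior(x, np.full(2000, 500.0))
        h = prior.bandwidth
        # Gaussian KDE at the same bandwidth, same data
        far = x.max() + 5 * h
        t_tail = stats.t.pdf((far - x) / h, 3).mean() / h
        g_tail = stats.norm.pdf((far - x) / h).mean() / h
        assert t_tail > g_tail

    def test_no_qualifying_guides_is_an_error(self):
        with pytest.raises(ValueError, match="100"):
            fit_prior(np.zeros(10), np.full(10, 5.0))


def diffuse_prior() -> EffectPrior:
    support = np.linspace(-20, 20, 801)
    density = np.full_like(support, 1 / 40.0)
    return EffectPrior(support=support, density=density, bandwidth=1.0, n_fit=1)


class TestShrinkEffects:
    def test_observed_equal_pooled_gives_zero(self):
        frame = frame_from_counts(
            {"low": [50], "high": [50]}, {"low": 1000, "high": 1000}
        )
        est = shrink_effects(
            frame, flat_variance_model(2.0), diffuse_prior(), "high", "low"
        )
        assert est.iloc[0] == 0.0

    def test_deep_counts_with_diffuse_prior_stay_near_raw(self):
        # 20000 vs 10000 reads out of 10^6: raw effect = 1.0 exactly
        frame = frame_from_counts(
            {"low": [10_000], "high": [20_000]},
            {"low": 1_000_000, "high": 1_000_000},
        )
        est = shrink_effects(
            frame, flat_variance_model(2.0), diffuse_prior(), "high", "low"
        )
        raw = 1.0
        grid_step = raw / (GRID_POINTS - 1) * 2  # coarse bound: one combined step
        assert abs(est.iloc[0] - raw) <= grid_step

    def test_matches_exhaustive_grid_oracle(self):
        # independent re-evaluation of the full 21 × 21 posterior by loops
        frame = frame_from_counts(
            {"low": [30], "high": [90]}, {"low": 2000, "high": 2500}
        )
        model = flat_variance_model(2.5)
        rng = np.random.default_rng(5)
        prior = fit_prior(rng.normal(0, 0.6, 1000), np.full(1000, 500.0))
        est = shrink_effects(frame, model, prior, "high", "low")

        t_h, t_l = 2500.0, 2000.0
        f_obs_h, f_obs_l = 90 / t_h, 30 / t_l
        f_pool = 120 / 4500.0
        best, best_e = -np.inf, None
        for i in range(21):
            f_h = f_obs_h + (f_pool - f_obs_h) * i / 20
            for j in range(21):
                f_l = f_obs_l + (f_pool - f_obs_l) * j / 20
                e = np.log2(f_h / f_l)
                ll = (
                    float(prior.log10_density(e))
                    + nb_log10_pmf(90, f_h * t_h, predict_variance(model, f_h * t_h))
                    + nb_log10_pmf(30, f_l * t_l, predict_variance(model, f_l * t_l))
                )
                if ll > best + 1e-12 or (
                    abs(ll - best) <= 1e-12 and abs(e) < abs(best_e)
                ):
                    best, best_e = ll, e
        assert est.iloc[0] == pytest.approx(best_e, abs=1e-9)

    def test_bounded_by_raw_with_matching_sign(self, planted_screen):
        from closcreen import fit_variance_model, normalize

        frame = normalize(planted_screen.counts, planted_screen.library)
        model = fit_variance_model(frame, planted_screen.library)
        raw = raw_effects(frame, "high", "low")["raw_effect"]
        reads = planted_screen.counts.counts.mean(axis=1)
        prior = fit_prior(raw, reads)
        est = shrink_effects(frame, model, prior, "high", "low")
        assert (np.abs(est) <= np.abs(raw) + 1e-9).all()
        assert ((est == 0) | (np.sign(est) == np.sign(raw))).all()
        # shrinkage on average, strict for the library as a whole
        assert est.abs().mean() < raw.abs().mean()

    def test_shrunk_approaches_raw_with_depth(self):
        model = flat_variance_model(2.0)
        prior = fit_prior(
            np.random.default_rng(2).normal(0, 0.3, 2000), np.full(2000, 500.0)
        )
        gaps = []
        for depth in (100, 1000, 10_000):
            frame = frame_from_counts(
                {"low": [depth], "high": [2 * depth]},
                {"low": depth * 100, "high": depth * 100},
            )
            est = shrink_effects(frame, model, prior, "high", "low")
            gaps.append(abs(est.iloc[0] - 1.0))
        assert gaps[0] >= gaps[1] >= gaps[2]


class TestGeneEffect:
    def test_aggregations(self):
        assert gene_effect([0.7]) == 0.7
        assert gene_effect([0.0, 0.0, 0.0]) == 0.0
        assert gene_effect([0.1, 0.2, 0.9]) == 0.2
        assert gene_effect([0.1, 0.2, 0.9], method="mean") == pytest.approx(0.4)

    def test_vectorized_matches_scalar(self):
        eff = pd.Series([0.1, 0.2, 0.9, -1.0], index=list("abcd"))
        genes = pd.Series(["G1", "G1", "G1", "G2"], index=list("abcd"))
        out = gene_effects(eff, genes)
        assert out["G1"] == 0.2
        assert out["G2"] == -1.0
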