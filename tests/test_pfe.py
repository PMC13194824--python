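"""Promoter fragmentation entropy: closed forms, oracles, selection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from fragdecipher.pfe import (
    PFEConfig,
    control_entropies,
    gene_pfe,
    length_histogram,
    margin_probability,
    pfe_matrix,
    pfe_scores,
    prior_distribution,
    select_pfe_features,
    shannon_entropy,
)
from fragdecipher.synthetic import SampleProfile, simulate_sample
from tests.conftest import make_fragments


class TestShannonEntropy:
    def test_point_mass_is_zero(self):
        p = np.zeros(121)
        p[67] = 1.0
        assert shannon_entropy(p) == 0.0

    def test_uniform_over_121_cells_is_ln_121(self):
        assert shannon_entropy(np.full(121, 1 / 121)) == pytest.approx(np.log(121))

    def test_uniform_over_4_cells_is_ln_4(self):
        assert shannon_entropy(np.array([0.25] * 4)) == pytest.approx(np.log(4))

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([0.5, -0.5, 1.0]))


class TestPrior:
    def test_point_mass_prior(self, small_model):
        # every flank fragment has length 167
        flanks = small_model.ndr_flank_intervals()
        rows = [(chrom, start + 10, start + 177) for _, chrom, start, end in flanks[:50]]
        fs = make_fragments(rows)
        prior = prior_distribution(fs, small_model)
        assert prior[167 - 100] == pytest.approx(1.0)
        assert prior.sum() == pytest.approx(1.0)

    def test_empty_flanks_raise(self, small_model):
        fs = make_fragments([("chrZZ", 0, 167)])
        with pytest.raises(ValueError, match="NDR flank"):
            prior_distribution(fs, small_model)

    def test_prior_mass_sums_to_one(self, small_model, healthy_sample):
        assert prior_distribution(healthy_sample, small_model).sum() == pytest.approx(1.0)


class TestControls:
    def test_exactly_five_values_and_deterministic(self, small_model, healthy_sample,
                                                   fast_pfe_config):
        a = control_entropies(healthy_sample, small_model, fast_pfe_config)
        b = control_entropies(healthy_sample, small_model, fast_pfe_config)
        assert len(a) == 5
        np.testing.assert_array_equal(a, b)

    def test_identical_background_distributions_give_similar_entropies(self, small_model):
        # synthetic promoter pools with the same length distribution everywhere
        rows = []
        for _, chrom, lo, hi in small_model.promoter_intervals():
            mid = (lo + hi) // 2
            rows += [(chrom, mid - 80 + i, mid + 87 + i) for i in range(-3, 3)]
        fs = make_fragments(rows)
        vals = control_entropies(fs, small_model, PFEConfig(seed=1))
        assert np.ptp(vals) < 0.3


class TestMarginProbability:
    def test_closed_form_matches_monte_carlo_oracle(self):
        """P(all ratios > 1+k), k ~ Gamma(0.5, 1): closed form vs 10^6 draws."""
        config = PFEConfig()
        rng = np.random.default_rng(0)
        k = rng.gamma(shape=0.5, scale=1.0, size=1_000_000)
        controls = np.array([3.2, 3.4, 3.3, 3.5, 3.6])
        for entropy in (3.5, 4.0, 4.6, 5.4):
            q_min = entropy / controls.max()
            mc = (q_min > 1 + k).mean()
            closed = margin_probability(np.array([entropy]), controls, config)[0]
            se = np.sqrt(max(mc * (1 - mc), 1e-9) / len(k))
            assert closed == pytest.approx(mc, abs=max(3 * se, 1e-4))

    def test_ratio_below_one_contributes_zero(self):
        p = margin_probability(np.array([3.0]), np.array([3.5, 3.2, 4.0, 3.8, 3.3]))
        assert p[0] == 0.0

    def test_all_ratios_two_give_erf_one(self):
        # Gamma(0.5,1) CDF at 1 equals erf(1) ~ 0.8427
        p = margin_probability(np.array([2.0]), np.array([1.0] * 5))
        assert p[0] == pytest.approx(special.erf(1.0), abs=1e-12)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            margin_probability(np.array([2.0]), np.array([1.0, 0.0, 1.0, 1.0, 1.0]))

    def test_independent_k_variant_is_product_form(self):
        config = PFEConfig(shared_k=False)
        controls = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
        e = np.array([4.5])
        expected = np.prod(stats.gamma.cdf(e[0] / controls - 1, a=0.5, scale=1.0))
        assert margin_probability(e, controls, config)[0] == pytest.approx(expected)


class TestGenePFE:
    def test_score_bounds_and_low_entropy_zero(self):
        config = PFEConfig(n_dirichlet=500, seed=0)
        prior = np.full(121, 1 / 121)
        controls = np.array([4.0, 4.1, 4.0, 4.2, 4.1])
        # concentrated gene counts -> entropy far below controls -> score ~ 0
        counts = np.zeros(121)
        counts[60] = 200
        rng = np.random.default_rng(1)
        low = gene_pfe(counts, prior, controls, config, rng=rng)
        assert low == pytest.approx(0.0, abs=1e-3)
        # near-uniform counts -> higher score, still within [0, 1]
        high = gene_pfe(np.full(121, 50.0), prior, controls, config,
                        rng=np.random.default_rng(2))
        assert 0.0 <= low <= high <= 1.0

    def test_score_monotone_in_gene_entropy(self):
        """Widening the count distribution never decreases the score."""
        config = PFEConfig(n_dirichlet=2000, seed=0)
        prior = np.full(121, 1 / 121)
        controls = np.array([3.0, 3.1, 3.2, 3.0, 3.1])
        cells = np.arange(121)
        scores = []
        for sigma in (2.0, 5.0, 12.0, 30.0, 80.0):
            pdf = np.exp(-0.5 * ((cells - 60) / sigma) ** 2)
            counts = 300 * pdf / pdf.sum()
            scores.append(gene_pfe(counts, prior, controls, config,
                                   rng=np.random.default_rng(7)))
        assert all(b >= a - 0.01 for a, b in zip(scores, scores[1:]))

    def test_prior_dominance_limit(self):
        """As the prior weight grows, all genes converge to the prior's score."""
        prior = np.full(121, 1 / 121)
        controls = np.array([4.2, 4.3, 4.25, 4.35, 4.3])
        rng_counts = np.random.default_rng(3)
        genes = [rng_counts.multinomial(80, np.random.default_rng(s).dirichlet(np.ones(121)))
                 for s in range(6)]
        spreads = []
        for w in (20.0, 2000.0, 200_000.0):
            config = PFEConfig(prior_weight=w, n_dirichlet=500, seed=0)
            scores = [gene_pfe(g.astype(float), prior, controls, config,
                               rng=np.random.default_rng(11))
                      for g in genes]
            spreads.append(np.var(scores))
        assert spreads[-1] < spreads[0] or spreads[0] == 0.0
        assert spreads[-1] == pytest.approx(0.0, abs=1e-6)

    def test_zero_alpha_rejected(self):
        with pytest.raises(ValueError):
            gene_pfe(np.zeros(121), np.zeros(121), np.ones(5), PFEConfig())


class TestPFEMatrix:
    def test_normalized_scores_have_mean_zero_sd_one(self, small_model,
                                                     healthy_sample, fast_pfe_config):
        res = pfe_scores(healthy_sample, small_model, fast_pfe_config)
        z = res.normalized_scores.dropna().to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)
        assert ((res.gene_scores.dropna() >= 0) & (res.gene_scores.dropna() <= 1)).all()

    def test_sample_order_does_not_change_vectors(self, small_model, healthy_sample,
                                                  cancer_sample, fast_pfe_config):
        ab = pfe_matrix({"a": healthy_sample, "b": cancer_sample},
                        small_model, fast_pfe_config)
        ba = pfe_matrix({"b": cancer_sample, "a": healthy_sample},
                        small_model, fast_pfe_config)
        pd.testing.assert_series_equal(ab.loc["a"], ba.loc["a"])
        pd.testing.assert_series_equal(ab.loc["b"], ba.loc["b"])

    def test_boosted_genes_outrank_background_in_cancer(self, small_model,
                                                        cancer_sample, fast_pfe_config):
        res = pfe_scores(cancer_sample, small_model, fast_pfe_config)
        z = res.normalized_scores
        boosted = z[small_model.active_genes].median()
        background = z[small_model.background_genes].median()
        assert boosted > background


class TestSelection:
    def _matrix(self, n_per_group, gen, n_genes=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        for i in range(n_per_group):
            rows[f"c{i}"] = gen(rng, True)
        for i in range(n_per_group):
            rows[f"h{i}"] = gen(rng, False)
        mat = pd.DataFrame(rows).T
        labels = pd.Series([1] * n_per_group + [0] * n_per_group, index=mat.index)
        return mat, labels

    def test_perfect_cancer_high_separation_selected(self):
        mat, labels = self._matrix(
            20, lambda rng, cancer: pd.Series(
                rng.normal(3.0 if cancer else 0.0, 0.1, 5),
                index=[f"g{j}" for j in range(5)]))
        assert select_pfe_features(mat, labels) == [f"g{j}" for j in range(5)]

    def test_cancer_low_gene_excluded_despite_small_p(self):
        mat, labels = self._matrix(
            20, lambda rng, cancer: pd.Series(
                {"down": rng.normal(-3.0 if cancer else 0.0, 0.1),
                 "up": rng.normal(3.0 if cancer else 0.0, 0.1)}))
        assert select_pfe_features(mat, labels) == ["up"]

    def test_null_genes_selected_at_nominal_rate(self):
        """Under the null the two-sided p<0.01 AND cancer-high rule fires
        with probability ~0.005 per gene."""
        rng = np.random.default_rng(5)
        n_genes, n = 400, 15
        mat = pd.DataFrame(rng.normal(size=(2 * n, n_genes)),
                           index=[f"s{i}" for i in range(2 * n)],
                           columns=[f"g{j}" for j in range(n_genes)])
        labels = pd.Series([1] * n + [0] * n, index=mat.index)
        k = len(select_pfe_features(mat, labels))
        # binomial(400, 0.005): P(k > 8) is negligible
        assert k <= 8

    def test_single_class_rejected(self):
        mat = pd.DataFrame(np.zeros((4, 3)), index=list("abcd"))
        with pytest.raises(ValueError):
            select_pfe_features(mat, pd.Series([1, 1, 1, 1], index=list("abcd")))


def test_depth_downsample_preserves_pfe_ranking(small_model, fast_pfe_config):
    """PFE vectors from a 10% downsample of a high-depth sample correlate
    strongly with the full-depth vectors."""
    from fragdecipher.fragments import downsample

    deep = simulate_sample(small_model, SampleProfile(
        label="healthy", target_fragment_count=300_000, seed=55))
    config = PFEConfig(n_dirichlet=1000, seed=5)
    full = pfe_scores(deep, small_model, config).normalized_scores
    sub = downsample(deep, fraction=0.1, seed=6)
    sub.sample_id = "deep@10pct"
    low = pfe_scores(sub, small_model, config).normalized_scores
    r = stats.pearsonr(full, low).statistic
    assert r > 0.7
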