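import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from hippo.counts import ValidationError
from hippo.zero_model import (
    ModelFit,
    deviance_statistic,
    expected_zero,
    fit_nb,
    fit_poisson,
    fit_zinb,
    gene_zero_stats,
    lrt,
    model_variance,
    select_features,
    zero_stats_frame,
)
from .conftest import make_counts
from .oracles import nb_grid_loglik, zinb_grid_loglik

count_vectors = st.lists(st.integers(0, 30), min_size=2, max_size=40).map(np.array)


class TestGeneZeroStats:
    def test_hand_computed_examples(self, tiny_matrix):
        s = gene_zero_stats(tiny_matrix)
        # (0,0,1,1): mean .5, p_hat .5, expected e^-0.5
        assert s[0].mean == 0.5 and s[0].zero_prop == 0.5
        assert s[0].expected_zero == pytest.approx(0.6065307, abs=1e-6)
        assert s[0].z == pytest.approx((0.5 - math.exp(-0.5)) / 0.25, abs=1e-6)
        # all-zero gene: degenerate convention
        assert (s[1].mean, s[1].zero_prop, s[1].expected_zero, s[1].z) == (0, 1, 1, 0)
        # (0,0,0,10)
        assert s[2].z == pytest.approx(
            (0.75 - math.exp(-2.5)) / math.sqrt(0.75 * 0.25 / 4), abs=1e-6
        )
        # no zeros observed: z = 0 by convention
        assert s[3].z == 0.0

    def test_null_se_mode(self, tiny_matrix):
        s = gene_zero_stats(tiny_matrix, se="null")
        e = math.exp(-0.5)
        assert s[0].z == pytest.approx((0.5 - e) / math.sqrt(e * (1 - e) / 4), abs=1e-6)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            gene_zero_stats(make_counts(np.zeros((0, 4), dtype=int)))

    def test_expected_zero_decreasing_in_mean(self):
        rng = np.random.default_rng(3)
        m = make_counts(rng.poisson(rng.uniform(0.1, 5, size=(30, 1)), size=(30, 50)))
        s = sorted(gene_zero_stats(m), key=lambda g: g.mean)
        ez = [g.expected_zero for g in s]
        assert all(0 < e <= 1 for e in ez)
        assert all(a >= b for a, b in zip(ez, ez[1:]))

    def test_stats_frame_has_bonferroni_column(self, tiny_matrix):
        df = zero_stats_frame(gene_zero_stats(tiny_matrix))
        assert ((0 <= df.p_value) & (df.p_value <= 1)).all()
        assert (df.p_bonferroni >= df.p_value).all() and (df.p_bonferroni <= 1).all()


class TestDeviance:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 2, 2], 0.0), ([0, 0, 0], 0.0), ([0, 4], 2 * ((2) + (4 * math.log(2) - 2)))],
    )
    def test_examples(self, counts, expected):
        assert deviance_statistic(counts) == pytest.approx(expected, abs=1e-9)

    @given(count_vectors)
    def test_equals_twice_saturated_minus_fitted_poisson_gap(self, x):
        fitted = fit_poisson(x).loglik
        saturated = sum(float(sps.poisson.logpmf(v, v)) if v > 0 else 0.0 for v in x)
        assert deviance_statistic(x) == pytest.approx(2 * (saturated - fitted), abs=1e-10)

    @given(count_vectors)
    def test_nonnegative_and_zero_iff_constant(self, x):
        d = deviance_statistic(x)
        assert d >= 0
        if np.all(x == x[0]):
            assert d == pytest.approx(0, abs=1e-12)


class TestSelectFeatures:
    def _stats(self, zs, devs=None):
        devs = devs if devs is not None else [0.0] * len(zs)
        return [
            type("S", (), {"z": z, "deviance": d})() for z, d in zip(zs, devs)
        ]

    def test_strict_inequality_on_z(self):
        idx = select_features(self._stats([3.1, 0.5, 2.0, -4.0]), z_threshold=2)
        assert idx.tolist() == [0]

    def test_empty_selection_valid(self):
        assert select_features(self._stats([-1, 0.3]), z_threshold=2).size == 0

    def test_deviance_method_descending_order(self):
        idx = select_features(
            self._stats([0, 0, 0], devs=[10, 3, 0.1]), method="deviance", deviance_threshold=1
        )
        assert idx.tolist() == [0, 1]


class TestPoissonFit:
    def test_all_zero_limit(self):
        f = fit_poisson([0, 0])
        assert f.lam == 0 and f.loglik == 0

    def test_hand_computed_loglik(self):
        f = fit_poisson([1, 3])
        assert f.lam == 2
        assert f.loglik == pytest.approx(4 * math.log(2) - 4 - math.log(6), abs=1e-9)

    def test_mle_is_mean(self):
        assert fit_poisson([5, 5, 5]).lam == 5


class TestNBFit:
    def test_no_overdispersion_hits_poisson_boundary(self):
        f = fit_nb([2, 2, 2, 2])
        assert f.r == 1e6
        assert f.loglik == pytest.approx(fit_poisson([2, 2, 2, 2]).loglik, abs=1e-12)

    def test_overdispersed_beats_poisson(self):
        x = [0, 0, 0, 8]
        assert fit_nb(x).loglik > fit_poisson(x).loglik

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        for x in [rng.poisson(3, 20), rng.negative_binomial(2, 2 / 7, 40), [0, 0, 0, 8]]:
            assert fit_nb(x).loglik == pytest.approx(nb_grid_loglik(x), abs=1e-3)

    def test_parameter_recovery(self):
        from hippo.simulate import simulate_nb

        x = simulate_nb(20000, lam=5, r=2, seed=123)
        f = fit_nb(x)
        assert abs(f.r - 2) / 2 < 0.10


class TestZINBFit:
    def test_no_zeros_defers_to_nb(self):
        x = [1, 2, 3, 4, 5]
        z, n = fit_zinb(x), fit_nb(x)
        assert z.pi0 == 0.0 and z.loglik == pytest.approx(n.loglik, abs=1e-12)

    def test_nesting_and_grid_oracle(self):
        x = np.array([0, 0, 0, 0, 5, 5, 5, 5])
        z = fit_zinb(x)
        assert z.loglik >= fit_nb(x).loglik - 1e-6
        assert z.loglik == pytest.approx(zinb_grid_loglik(x), abs=1e-3)

    def test_parameter_recovery(self):
        from hippo.simulate import simulate_zinb

        x = simulate_zinb(20000, lam=5, r=2, pi0=0.3, seed=321)
        f = fit_zinb(x)
        assert abs(f.pi0 - 0.3) < 0.05

    def test_loglik_ordering_poisson_nb_zinb(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = rng.poisson(rng.uniform(0.2, 4), size=30)
            lp, ln, lz = fit_poisson(x).loglik, fit_nb(x).loglik, fit_zinb(x).loglik
            assert ln >= lp - 1e-6 and lz >= ln - 1e-6


class TestLRT:
    def test_identical_logliks(self):
        a = ModelFit("poisson", 1.0, -10.0, 1)
        b = ModelFit("nb", 1.0, -10.0, 2, r=5.0)
        res = lrt(a, b)
        assert res.stat == 0 and res.p_value == 1

    def test_chi2_95th_percentile(self):
        a = ModelFit("nb", 1.0, -10.0, 2, r=5.0)
        b = ModelFit("zinb", 1.0, -10.0 + 1.92075, 3, r=5.0, pi0=0.1)
        res = lrt(a, b)
        assert res.stat == pytest.approx(3.8415, abs=1e-3)
        assert res.p_value == pytest.approx(0.05, abs=1e-4)

    def test_single_one_among_zeros_gives_p_near_one(self):
        # a gene with UMI count 1 in one cell and 0 elsewhere
        x = np.zeros(500, dtype=int)
        x[0] = 1
        p_over = lrt(fit_poisson(x), fit_nb(x)).p_value
        p_infl = lrt(fit_nb(x), fit_zinb(x)).p_value
        assert p_over > 0.9 and p_infl > 0.9

    def test_non_nested_rejected(self):
        a = ModelFit("poisson", 1.0, -10.0, 1)
        b = ModelFit("zinb", 1.0, -9.0, 3, r=1.0, pi0=0.1)
        with pytest.raises(ValueError):
            lrt(a, b)


class TestClosedForms:
    def test_poisson_expected_zero_matches_reported_subtype(self):
        assert expected_zero("poisson", lam=0.5625) == pytest.approx(0.5698, abs=1e-4)
        assert expected_zero("poisson", lam=25.89) == pytest.approx(5.69e-12, rel=0.015)

    def test_nb_closed_form(self):
        assert expected_zero("nb", lam=1, r=1) == 0.5

    def test_mixture_exceeds_poisson_at_same_mean(self):
        ez = expected_zero("mixture", weights=[0.5, 0.5], lambdas=[0, 2])
        assert ez == pytest.approx(0.5 * (1 + math.exp(-2)), abs=1e-9)
        assert ez > math.exp(-1)

    def test_zinb_zero_probability(self):
        # pi0 + (1-pi0) * (r/(r+lam))^r
        assert expected_zero("zinb", lam=5, r=2, pi0=0.3) == pytest.approx(
            0.3 + 0.7 * (2 / 7) ** 2, abs=1e-12
        )

    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ValidationError):
            expected_zero("mixture", weights=[0.5, 0.6], lambdas=[1, 2])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.0, 20.0), min_size=6, max_size=6),
    )
    def test_jensen_inequality(self, raw_w, lams):
        w = np.array(raw_w) / np.sum(raw_w)
        lams = np.array(lams[: len(w)])
        mix = expected_zero("mixture", weights=w, lambdas=lams)
        assert mix >= math.exp(-float(np.dot(w, lams))) - 1e-12

    def test_variance_closed_forms(self):
        assert model_variance("mixture", weights=[0.5, 0.5], lambdas=[1, 3]) == pytest.approx(3.0)
        assert model_variance("nb", lam=2.0, r=1e12) == pytest.approx(2.0, rel=1e-9)
        assert model_variance("zinb", lam=2.0, r=3.0, pi0=0.0) == model_variance(
            "nb", lam=2.0, r=3.0
        )


class TestNullCalibration:
    def test_homogeneous_poisson_retains_most_genes(self):
        """On i.i.d. Poisson genes the zero-inflation test rarely fires."""
        from hippo.simulate import simulate_homogeneous_poisson

        m, _ = simulate_homogeneous_poisson(n_genes=500, n_cells=600, seed=2024)
        z = np.array([s.z for s in gene_zero_stats(m)])
        assert np.mean(np.abs(z) < 2) >= 0.95
        assert np.mean(z > 2) <= 0.05
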