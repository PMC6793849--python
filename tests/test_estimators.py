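import numpy as np
import pytest

from gaindyn.estimators import (
    EmbeddingSpec,
    active_information_storage,
    active_memory_rate,
    collective_te_rate,
    conditional_te_rate,
    gaussian_cmi,
    mi_null_mean_bits,
    select_embedding,
    takens_embed,
    te_permutation_pvalue,
    te_rate,
    te_significance,
)
from gaindyn.synthetic import VAROracle, generate_var
from gaindyn.workflows import cmi_standard_error_bits

AR1_AIS = -0.5 * np.log2(1 - 0.25)  # phi = 0.5 closed form, 0.20752 bits


def ar1(n, phi=0.5, seed=0):
    o = VAROracle(Phi=[[phi]], Sigma=[[1.0]])
    return generate_var(o, n, seed=seed)[:, 0]


def coupled_pair(n, seed=0, phi=0.5, coupling=1.0):
    """x_{t} = phi x_{t-1} + coupling y_{t-1} + eps; y white noise."""
    o = VAROracle(Phi=[[phi, coupling], [0.0, 0.0]], Sigma=np.eye(2))
    xy = generate_var(o, n, seed=seed)
    return xy[:, 0], xy[:, 1]


class TestTakensEmbedding:
    def test_k1_is_trimmed_series(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(takens_embed(x, 1, 3, offset=1), x[:-1, None])

    def test_first_state_row(self):
        x = np.arange(1.0, 11.0)
        emb = takens_embed(x, k=3, tau_embed=2, offset=1)
        np.testing.assert_array_equal(emb[0], [1.0, 3.0, 5.0])
        # usable (state, next-value) pairs: N - (k-1) tau - offset
        assert emb.shape[0] == 10 - 4 - 1

    def test_too_short_reports_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            takens_embed(np.arange(5.0), k=4, tau_embed=3)


class TestGaussianCMI:
    def test_independent_near_zero(self, rng):
        x, y = rng.normal(size=20000), rng.normal(size=20000)
        assert gaussian_cmi(x, y) < 0.001

    def test_bivariate_closed_form(self, rng):
        n = 200_000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        assert gaussian_cmi(x, y) == pytest.approx(AR1_AIS, abs=0.005)

    def test_self_conditioning_vanishes(self, rng):
        # I(X; Y | X) = 0; the duplicated block makes the plug-in covariance
        # singular, so the regularized path is exercised
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        assert gaussian_cmi(x, y, Z=x, jitter=1e-10) == pytest.approx(0.0, abs=1e-4)

    def test_singular_raises_without_jitter(self, rng):
        x = rng.normal(size=1000)
        with pytest.raises(np.linalg.LinAlgError):
            gaussian_cmi(x, np.column_stack([x, x]))

    def test_jitter_rescues_singular(self, rng):
        x = rng.normal(size=1000)
        val = gaussian_cmi(x, np.column_stack([x, x]), jitter=1e-9)
        assert np.isfinite(val)


class TestStorage:
    def test_ar1_ais_closed_form(self):
        x = ar1(100_000)
        est = active_information_storage(x, EmbeddingSpec(k=1, tau_embed=1))
        assert est.value == pytest.approx(AR1_AIS, abs=0.01)

    def test_white_noise_ais_at_bias_level(self, rng):
        x = rng.normal(size=50_000)
        est = active_information_storage(x, EmbeddingSpec(k=3, tau_embed=1))
        assert est.value - mi_null_mean_bits(3, 1, est.n_samples) < 3 * \
            cmi_standard_error_bits(0.0, 3, est.n_samples)

    def test_deeper_embedding_matches_markov1_oracle(self):
        # AR(1) is Markov-1: AIS at k=3 equals AIS at k=1 analytically
        o = VAROracle(Phi=[[0.5]], Sigma=[[1.0]])
        s1, s3 = EmbeddingSpec(k=1, tau_embed=1), EmbeddingSpec(k=3, tau_embed=1)
        assert o.ais(0, s3) == pytest.approx(o.ais(0, s1), abs=1e-12)
        x = ar1(100_000)
        est = active_information_storage(x, s3)
        assert est.value == pytest.approx(AR1_AIS, abs=0.01)

    def test_memory_rate_vanishes_for_markov1(self):
        x = ar1(100_000)
        dec = active_memory_rate(x, EmbeddingSpec(k=4, tau_embed=1), dt_ms=0.5)
        n = dec.am_rate.n_samples
        # bits/step at the null-bias level for a 3-lag deeper past
        assert dec.am_rate.bits_per_step < mi_null_mean_bits(3, 1, n) + \
            3 * cmi_standard_error_bits(0.0, 3, n)

    def test_ar2_memory_rate_matches_analytic_covariance(self):
        # AR(2) in companion form: deeper past genuinely adds information
        o = VAROracle(Phi=[[0.4, 0.35], [1.0, 0.0]], Sigma=np.diag([1.0, 1e-12]))
        spec = EmbeddingSpec(k=3, tau_embed=1)
        analytic = o.memory_rate_bits_per_step(0, spec)
        x = generate_var(o, 100_000, seed=3)[:, 0]
        dec = active_memory_rate(x, spec, dt_ms=0.5)
        se = cmi_standard_error_bits(analytic, spec.k - 1, dec.am_rate.n_samples)
        assert abs(dec.am_rate.bits_per_step - analytic) < 3 * se + 1e-4

    def test_chain_rule_identity_exact(self, rng):
        x = rng.normal(size=3000).cumsum()  # arbitrary nonstationary series is fine
        dec = active_memory_rate(x, EmbeddingSpec(k=5, tau_embed=2), dt_ms=0.5)
        assert dec.ais.value == pytest.approx(
            dec.ipc.value + dec.am_rate.bits_per_step, abs=1e-10
        )

    def test_memory_rate_requires_deeper_past(self):
        with pytest.raises(ValueError, match="k >= 2"):
            active_memory_rate(np.arange(100.0), EmbeddingSpec(k=1), 0.5)


class TestEmbeddingSelection:
    def test_markov1_data_selects_k1(self):
        x = ar1(50_000)
        k, tau = select_embedding(x, k_max=5, tau_max=5)
        assert k == 1

    def test_returned_pair_maximizes_scores_up_to_parsimony(self):
        from scipy import stats as ss

        x = ar1(5_000, seed=2)
        (k, tau), scores = select_embedding(x, 4, 4, return_scores=True)
        k_best = int(np.argwhere(scores == scores.max())[0][0] + 1)
        allowance = ss.chi2.isf(0.05, max(k_best - k, 1)) / (2 * (len(x) - 1) * np.log(2))
        # the returned pair scores within the parsimony allowance of the max,
        # and nothing smaller does
        assert scores[k - 1, tau - 1] >= scores.max() - allowance
        for k_small in range(1, k):
            a = ss.chi2.isf(0.05, max(k_best - k_small, 1)) / (2 * (len(x) - 1) * np.log(2))
            assert scores[k_small - 1].max() < scores.max() - a

    def test_short_series_truncates_grid(self, caplog):
        x = ar1(200, seed=3)
        with caplog.at_level("WARNING"):
            k, tau = select_embedding(x, k_max=30, tau_max=10)
        assert "truncated" in caplog.text


class TestTransfer:
    def test_unit_coupling_closed_form(self):
        x, y = coupled_pair(100_000)
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        est = te_rate(y, x, spec, dt_ms=0.5)
        # 1/2 log2(1 + 1) = 0.5 bits/step; rate = bits/step / 0.0005 s
        assert est.bits_per_step == pytest.approx(0.5, abs=0.01)
        assert est.value == pytest.approx(est.bits_per_step / 5e-4)

    def test_independent_and_reverse_not_significant(self, rng):
        x, y = coupled_pair(20_000, seed=4)
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        rev = te_rate(x, y, spec, 0.5)
        p, sig = te_significance(rev)
        assert not sig
        z = rng.normal(size=20_000)
        ind = te_rate(z, x, spec, 0.5)
        assert ind.bits_per_step < 5 * mi_null_mean_bits(1, 1, ind.n_samples)

    def test_empty_conditionals_reduce_to_pairwise(self):
        x, y = coupled_pair(5_000)
        spec = EmbeddingSpec(k=2, tau_embed=1, u=1)
        assert conditional_te_rate(y, x, [], spec, 0.5).value == pytest.approx(
            te_rate(y, x, spec, 0.5).value, abs=1e-12
        )

    def test_conditioning_on_source_copy_removes_everything(self):
        x, y = coupled_pair(20_000)
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        est = conditional_te_rate(y, x, [(y.copy(), 1)], spec, 0.5, jitter=1e-9)
        assert est.bits_per_step == pytest.approx(0.0, abs=1e-4)
        assert est.flagged

    def test_conditioning_on_nondriving_process_is_neutral(self):
        # z never enters x: conditioning on it leaves the TE unchanged
        Phi = np.array([[0.3, 0.8, 0.0], [0, 0, 0], [0, 0, 0.4]])
        o = VAROracle(Phi=Phi, Sigma=np.eye(3))
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        assert o.conditional_te_bits_per_step(1, 0, [(2, 1)], spec) == pytest.approx(
            o.te_bits_per_step(1, 0, spec), abs=1e-12
        )
        xyz = generate_var(o, 50_000, seed=5)
        pair = te_rate(xyz[:, 1], xyz[:, 0], spec, 0.5)
        cond = conditional_te_rate(xyz[:, 1], xyz[:, 0], [(xyz[:, 2], 1)], spec, 0.5)
        assert cond.bits_per_step == pytest.approx(pair.bits_per_step, abs=0.01)

    def test_conditioning_on_second_additive_drive_raises_te(self):
        # with two independent additive drives, conditioning on the other
        # source removes its contribution from the residual noise, so the
        # conditional TE exceeds the pairwise TE: 1/2 log2(1.64/1) vs
        # 1/2 log2(2/1.36) for drives 0.8 and 0.6 with unit noises
        Phi = np.array([[0.3, 0.8, 0.6], [0, 0, 0], [0, 0, 0]])
        o = VAROracle(Phi=Phi, Sigma=np.eye(3))
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        assert o.te_bits_per_step(1, 0, spec) == pytest.approx(
            0.5 * np.log2(2.0 / 1.36), abs=1e-12
        )
        assert o.conditional_te_bits_per_step(1, 0, [(2, 1)], spec) == pytest.approx(
            0.5 * np.log2(1.64), abs=1e-12
        )
        xyz = generate_var(o, 50_000, seed=5)
        cond = conditional_te_rate(xyz[:, 1], xyz[:, 0], [(xyz[:, 2], 1)], spec, 0.5)
        assert cond.bits_per_step == pytest.approx(0.5 * np.log2(1.64), abs=0.01)

    def test_collective_single_source_equals_pairwise(self):
        x, y = coupled_pair(5_000)
        spec = EmbeddingSpec(k=2, tau_embed=1, u=1)
        assert collective_te_rate([(y, 1)], x, spec, 0.5).value == pytest.approx(
            te_rate(y, x, spec, 0.5).value, abs=1e-12
        )

    def test_collective_chain_rule_exact(self):
        o = VAROracle(
            Phi=np.array([[0.3, 0.5, 0.4], [0, 0.2, 0], [0, 0, 0.2]]),
            Sigma=np.eye(3),
        )
        xyz = generate_var(o, 20_000, seed=6)
        x, y1, y2 = xyz[:, 0], xyz[:, 1], xyz[:, 2]
        spec = EmbeddingSpec(k=2, tau_embed=1, u=1)
        coll = collective_te_rate([(y1, 1), (y2, 1)], x, spec, 0.5)
        inc1 = te_rate(y1, x, spec, 0.5)
        inc2 = conditional_te_rate(y2, x, [(y1, 1)], spec, 0.5)
        assert coll.value == pytest.approx(inc1.value + inc2.value, abs=1e-8)
        # ordering invariance of the decomposition
        inc1b = te_rate(y2, x, spec, 0.5)
        inc2b = conditional_te_rate(y1, x, [(y2, 1)], spec, 0.5)
        assert coll.value == pytest.approx(inc1b.value + inc2b.value, abs=1e-8)

    def test_duplicated_source_adds_nothing(self):
        x, y = coupled_pair(20_000)
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        single = collective_te_rate([(y, 1)], x, spec, 0.5)
        double = collective_te_rate([(y, 1), (y.copy(), 1)], x, spec, 0.5, jitter=1e-9)
        assert double.value == pytest.approx(single.value, rel=1e-3)


class TestSignificance:
    def test_strong_coupling_p_zero(self):
        x, y = coupled_pair(10_000)
        est = te_rate(y, x, EmbeddingSpec(k=1, tau_embed=1, u=1), 0.5)
        p, sig = te_significance(est)
        assert p < 1e-10 and sig

    def test_bonferroni_threshold_applied(self):
        x, y = coupled_pair(10_000)
        est = te_rate(y, x, EmbeddingSpec(k=1, tau_embed=1, u=1), 0.5)
        # craft a marginal estimate: p ~ 0.01 from the chi-square inverse
        from scipy import stats as ss

        bits = ss.chi2.isf(0.01, 1) / (2 * est.n_samples * np.log(2))
        marginal = type(est)(
            value=bits / 5e-4, measure_kind="TE_rate", n_samples=est.n_samples,
            units="bits/s", bits_per_step=bits,
        )
        p1, sig1 = te_significance(marginal, alpha=0.05, n_tests=1)
        p2, sig2 = te_significance(marginal, alpha=0.05, n_tests=100)
        assert p1 == pytest.approx(0.01, rel=1e-6)
        assert sig1 and not sig2

    def test_n_tests_must_be_positive(self):
        x, y = coupled_pair(2_000)
        est = te_rate(y, x, EmbeddingSpec(k=1, tau_embed=1, u=1), 0.5)
        with pytest.raises(ValueError):
            te_significance(est, n_tests=0)

    def test_permutation_agrees_with_analytic(self):
        x, y = coupled_pair(3_000, seed=9, coupling=0.05)
        spec = EmbeddingSpec(k=1, tau_embed=1, u=1)
        est = te_rate(y, x, spec, 0.5)
        p_analytic, _ = te_significance(est)
        p_perm = te_permutation_pvalue(y, x, spec, 0.5, n_permutations=400, seed=1)
        # both are uniforms under the null; under this weak coupling they
        # should agree within Monte-Carlo error of the permutation estimate
        mc = 3 * np.sqrt(max(p_analytic, 0.01) / 400) + 0.01
        assert abs(p_perm - p_analytic) < max(0.05, mc)


class TestEstimatorInvariances:
    def test_affine_rescaling_invariance(self):
        x, y = coupled_pair(10_000)
        spec = EmbeddingSpec(k=2, tau_embed=1, u=1)
        base_te = te_rate(y, x, spec, 0.5).value
        base_am = active_memory_rate(x, spec, 0.5).am_rate.value
        scaled_te = te_rate(3.7 * y - 2, 0.1 * x + 5, spec, 0.5).value
        scaled_am = active_memory_rate(-4 * x + 1, spec, 0.5).am_rate.value
        assert scaled_te == pytest.approx(base_te, rel=1e-9)
        assert scaled_am == pytest.approx(base_am, rel=1e-9)

    def test_te_equals_granger_statistic(self):
        """Dual route: TE via covariance determinants vs OLS residual variances."""
        x, y = coupled_pair(20_000, coupling=0.3)
        k = 3
        spec = EmbeddingSpec(k=k, tau_embed=1, u=1)
        te_bits = te_rate(y, x, spec, 0.5).bits_per_step

        # explicit nested regressions of x_{n+1} on target past (+ source lag)
        N = len(x)
        rows = np.arange(k, N - 1)
        past = np.column_stack([x[rows - d] for d in range(k)])
        src = y[rows][:, None]
        target = x[rows + 1]

        def rss(design):
            design = np.column_stack([np.ones(len(design)), design])
            beta, *_ = np.linalg.lstsq(design, target, rcond=None)
            r = target - design @ beta
            return r @ r

        granger = np.log(rss(past) / rss(np.hstack([past, src])))
        assert te_bits == pytest.approx(granger / (2 * np.log(2)), abs=1e-4)

    def test_rates_stable_under_downsampling(self):
        """Halving the sampling rate of the neural process moves the rates < 10%.

        The embedding is kept at a fixed physical span (tau halved in samples
        when dt doubles), as a continuous-time rate comparison requires.
        """
        from gaindyn.connectome import Connectome
        from gaindyn.simulator import SimConfig, simulate

        def two_region(weight, sigma, gamma):
            A = np.array([[0.0, 0.0], [weight, 0.0]])
            tau = np.array([[0.0, 0.0], [10.0, 0.0]])
            c = Connectome(A=A, tau=tau, hemisphere=np.array(["L", "R"]),
                           region_names=np.array(["a", "b"]))
            return simulate(c, SimConfig(sigma=sigma, gamma=gamma,
                                         duration=62_000, transient=2_000, seed=3))

        fine = EmbeddingSpec(k=25, tau_embed=12, u=21)
        coarse = EmbeddingSpec(k=25, tau_embed=6, u=11)

        # weakly driven regime for the storage rate
        x1 = two_region(2.0, 0.5, 0.5).V[1]
        am_fine = active_memory_rate(x1, fine, 0.5).am_rate.value
        am_coarse = active_memory_rate(x1[::2], coarse, 1.0).am_rate.value
        assert am_coarse == pytest.approx(am_fine, rel=0.10)

        # strongly coupled regime for the transfer rate
        run = two_region(20.0, 1.0, 0.8)
        te_fine = te_rate(run.V[0], run.V[1], fine, 0.5).value
        te_coarse = te_rate(run.V[0][::2], run.V[1][::2], coarse, 1.0).value
        assert te_coarse == pytest.approx(te_fine, rel=0.10)
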