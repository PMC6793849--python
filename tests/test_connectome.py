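import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaindyn.connectome import (
    Connectome,
    ConnectomeValidationError,
    connectome_stats,
    delay_steps,
    lengths_to_delays,
    load_connectome,
    local_network_support,
    normalize_coupling,
)
from gaindyn.synthetic import write_connectome

from conftest import random_connectome


def brute_force_psi(C: np.ndarray) -> np.ndarray:
    """Quadruple-loop evaluation of the motif sum, independent of matrix powers."""
    n = C.shape[0]
    psi = np.zeros(n)
    for a in range(n):
        for b in range(n):
            psi[a] += C[b, a] * C[a, b]
            for c in range(n):
                psi[a] += C[b, a] * C[c, b] * C[a, c]
                psi[a] += C[b, c] * C[a, b] * C[a, c]
                for d in range(n):
                    psi[a] += C[c, d] * C[b, c] * C[a, b] * C[a, d]
    return psi


class TestLoading:
    def test_toy_round_trip(self, toy_connectome, tmp_path):
        paths = write_connectome(toy_connectome, tmp_path)
        c = load_connectome(paths["weights"], paths["delays"], paths["hemispheres"])
        np.testing.assert_array_equal(c.A, toy_connectome.A)
        np.testing.assert_array_equal(c.tau, toy_connectome.tau)
        assert list(c.hemisphere) == ["L", "L", "R"]
        # 2 non-self causal edges + 1 self-loop
        assert c.causal_edges.shape[0] == 3
        assert c.orientation == "row=target"

    def test_dimension_mismatch_rejected(self, tmp_path):
        np.savetxt(tmp_path / "w.txt", np.zeros((3, 3)))
        np.savetxt(tmp_path / "d.txt", np.zeros((4, 4)))
        (tmp_path / "h.txt").write_text("a,L\nb,L\nc,R\n")
        with pytest.raises(ConnectomeValidationError, match="mismatch"):
            load_connectome(tmp_path / "w.txt", tmp_path / "d.txt", tmp_path / "h.txt")

    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda A, tau: A.__setitem__((0, 1), -1.0), "negative"),
            (lambda A, tau: tau.__setitem__((0, 1), 0.0), "zero delay"),
        ],
    )
    def test_invalid_entries_named(self, mutate, message):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        tau = np.array([[0.0, 3.0], [3.0, 0.0]])
        mutate(A, tau)
        with pytest.raises(ConnectomeValidationError, match=message):
            Connectome(A=A, tau=tau, hemisphere=np.array(["L", "R"]),
                       region_names=np.array(["a", "b"]))

    def test_one_hemisphere_rejected(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        tau = np.array([[0.0, 3.0], [3.0, 0.0]])
        with pytest.raises(ConnectomeValidationError, match="hemisphere"):
            Connectome(A=A, tau=tau, hemisphere=np.array(["L", "L"]),
                       region_names=np.array(["a", "b"]))


class TestStats:
    def test_disconnected_network_all_zero(self):
        c = Connectome(
            A=np.zeros((5, 5)), tau=np.zeros((5, 5)),
            hemisphere=np.array(["L", "L", "R", "R", "R"]),
            region_names=np.array(list("abcde")),
        )
        s = connectome_stats(c)
        assert s["n_connections"] == s["n_self_links"] == 0
        assert s["n_interhemispheric"] == 0
        assert s["weight_mean"] == 0.0

    def test_self_loops_excluded_from_moments(self, toy_connectome):
        s = connectome_stats(toy_connectome)
        assert s["n_nonself_links"] == 2
        assert s["n_self_links"] == 1
        assert s["weight_mean"] == pytest.approx((2.0 + 1.5) / 2)
        assert s["n_interhemispheric"] == 1  # 2->1 crosses R->L
        np.testing.assert_array_equal(s["in_degree"], [1, 1, 0])

    def test_permutation_invariance(self, rng):
        c = random_connectome(8, rng)
        perm = rng.permutation(8)
        cp = Connectome(
            A=c.A[np.ix_(perm, perm)], tau=c.tau[np.ix_(perm, perm)],
            hemisphere=c.hemisphere[perm], region_names=c.region_names[perm],
        )
        s, sp = connectome_stats(c), connectome_stats(cp)
        for key in ("n_connections", "n_self_links", "n_interhemispheric",
                    "weight_mean", "weight_sd", "delay_mean_ms"):
            assert s[key] == pytest.approx(sp[key])
        np.testing.assert_array_equal(s["in_degree"][perm], sp["in_degree"])


class TestDelaySteps:
    @pytest.mark.parametrize(
        "tau, dt, expected",
        [(19.8, 0.5, 40), (20.0, 0.5, 41), (0.0, 0.5, 1), (0.4, 0.5, 1)],
    )
    def test_strictly_greater_rule(self, tau, dt, expected):
        assert delay_steps(tau, dt) == expected

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            delay_steps(10.0, 0.0)

    @given(
        tau=st.floats(0.0, 100.0, allow_nan=False),
        dt=st.floats(0.05, 5.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_bracketing_property(self, tau, dt):
        u = delay_steps(tau, dt)
        assert u >= 1
        assert u * dt > tau
        if u > 1:
            assert (u - 1) * dt <= tau

    def test_length_speed_conversion(self):
        np.testing.assert_allclose(lengths_to_delays(np.array([60.0]), 3.0), [20.0])


class TestNormalization:
    def test_reciprocal_pair_single_parent(self):
        A = np.array([[0.0, 1.7], [0.4, 0.0]])
        tau = np.full((2, 2), 5.0)
        c = Connectome(A=A, tau=tau, hemisphere=np.array(["L", "R"]),
                       region_names=np.array(["a", "b"]))
        nc = normalize_coupling(c)
        np.testing.assert_allclose(nc.C, [[0, 1], [1, 0]])

    def test_in_weight_shares_and_self_share(self):
        A = np.array([[1.0, 2.0, 6.0], [0.0, 0.0, 3.0], [0.0, 0.0, 0.0]])
        tau = np.where(A > 0, 4.0, 0.0)
        np.fill_diagonal(tau, 0.0)
        c = Connectome(A=A, tau=tau, hemisphere=np.array(["L", "L", "R"]),
                       region_names=np.array(["a", "b", "c"]))
        nc = normalize_coupling(c)
        np.testing.assert_allclose(nc.C[0], [0, 0.25, 0.75])
        assert nc.F_diag[0] == pytest.approx(1.0 / 9.0)
        # region with A_ii=1 and total in-weight 4 -> F = 0.25
        A2 = np.diag([1.0]) + np.array([[0.0]])
        c2 = Connectome(
            A=np.array([[1.0, 3.0], [0.0, 0.0]]),
            tau=np.array([[0.0, 2.0], [0.0, 0.0]]),
            hemisphere=np.array(["L", "R"]), region_names=np.array(["a", "b"]),
        )
        assert normalize_coupling(c2).F_diag[0] == pytest.approx(0.25)

    def test_zero_in_degree_rows_are_zero(self, toy_connectome):
        nc = normalize_coupling(toy_connectome)
        np.testing.assert_array_equal(nc.C[2], 0.0)
        # rows with in-edges sum to one
        assert nc.C[0].sum() == pytest.approx(1.0)
        assert nc.C[1].sum() == pytest.approx(1.0)
        assert np.all(np.diag(nc.C) == 0)


class TestMotifSupport:
    def _psi_of(self, C):
        from gaindyn.connectome import NormalizedCoupling

        return local_network_support(NormalizedCoupling(C=C, F_diag=np.zeros(len(C))))

    def test_feedforward_chain_has_no_motifs(self):
        # c -> b -> a only: no feedback loops, no parallel direct edge
        C = np.zeros((3, 3))
        C[0, 1] = 1.0  # b -> a
        C[1, 2] = 1.0  # c -> b
        np.testing.assert_allclose(self._psi_of(C), 0.0)

    def test_uniform_three_cycle(self):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 2] = C[2, 0] = 1.0
        np.testing.assert_allclose(self._psi_of(C), 1.0)

    def test_reciprocal_pair(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(self._psi_of(C), 2.0)

    def test_matrix_form_equals_brute_force(self, rng):
        for _ in range(10):
            c = random_connectome(6, rng)
            nc = normalize_coupling(c)
            np.testing.assert_allclose(
                local_network_support(nc), brute_force_psi(nc.C), atol=1e-12
            )
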