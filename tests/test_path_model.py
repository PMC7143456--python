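"""Path-model parsing, covariance algebra, ML fitting, effect decomposition."""

import itertools

import numpy as np
import pytest

from streamsem import presets
from streamsem.path_model import (
    Edge,
    ModelSpecError,
    PathModel,
    SampleMoments,
    decompose_effects,
    fit_ml,
    implied_covariance,
    parse_model,
    solve_unit_variance_residuals,
    validate_model,
)

from conftest import random_pd_matrix


class TestParseModel:
    def test_single_free_path(self):
        m = parse_model("U -> Y")
        assert m.variables == ["U", "Y"]
        assert m.endogenous == ["Y"]
        assert [e.label for e in m.edges] == ["U->Y"]
        assert m.edges[0].free

    def test_full_model_counts(self, full_model):
        rep = validate_model(full_model)
        assert full_model.p == 6
        assert rep.n_free == 18
        assert rep.df == 3

    def test_refined_model_counts(self, refined_model):
        # 21 moments - 15 free parameters
        assert validate_model(refined_model).df == 6

    def test_fixed_value_path(self):
        m = parse_model("A -> B = 0.7")
        assert m.edges[0].value == 0.7

    def test_comments_and_blank_lines(self):
        m = parse_model("# header\n\nA -> B  # trailing\n")
        assert [e.label for e in m.edges] == ["A->B"]

    @pytest.mark.parametrize(
        "text,needle",
        [
            ("A => B", "line 1"),
            ("A -> A", "self-loop"),
            ("A -> B\nA -> B", "line 2"),
            ("A ~~ B\nB ~~ A", "duplicate covariance"),
        ],
    )
    def test_parse_errors(self, text, needle):
        with pytest.raises(ModelSpecError, match=needle):
            parse_model(text)

    def test_covariance_between_endogenous_rejected(self):
        with pytest.raises(ModelSpecError, match="exogenous"):
            parse_model("A -> B\nA -> C\nB ~~ C")


class TestValidateModel:
    def test_cycle_reported(self):
        m = PathModel(["A", "B"], [Edge("A", "B"), Edge("B", "A")])
        rep = validate_model(m)
        assert not rep.ok
        assert any("cycle" in msg for msg in rep.messages)

    def test_refined_model_valid(self, refined_model):
        rep = validate_model(refined_model)
        assert rep.ok and rep.df == 6

    def test_saturated_chain_just_identified(self):
        m = parse_model("X -> M\nM -> Y\nX -> Y")
        rep = validate_model(m)
        assert rep.ok and rep.df == 0


class TestImpliedCovariance:
    def test_no_paths_returns_psi(self):
        psi = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert np.allclose(implied_covariance(np.zeros((2, 2)), psi), psi)

    def test_single_path_hand_algebra(self):
        beta, psi_y = 0.6, 0.5
        B = np.array([[0.0, 0.0], [beta, 0.0]])
        Psi = np.diag([1.0, psi_y])
        sigma = implied_covariance(B, Psi)
        assert sigma[1, 0] == pytest.approx(beta)
        assert sigma[1, 1] == pytest.approx(beta**2 + psi_y)

    def test_population_model_has_unit_diagonal(self, population_model):
        sigma = population_model.implied()
        assert np.allclose(np.diag(sigma), 1.0, atol=1e-12)

    def test_asymmetric_psi_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            implied_covariance(np.zeros((2, 2)), np.array([[1.0, 0.2], [0.1, 1.0]]))


class TestUnitVarianceResiduals:
    def test_single_path(self):
        B = np.array([[0.0, 0.0], [0.5, 0.0]])
        psi = solve_unit_variance_residuals(B, [0], np.array([[1.0]]))
        assert psi[1, 1] == pytest.approx(0.75)

    def test_two_correlated_parents(self):
        # explained variance: 0.2^2 + 0.53^2 + 2*0.2*0.53*0.2
        B = np.zeros((3, 3))
        B[2, 0], B[2, 1] = 0.20, 0.53
        corr = np.array([[1.0, 0.2], [0.2, 1.0]])
        psi = solve_unit_variance_residuals(B, [0, 1], corr)
        assert psi[2, 2] == pytest.approx(0.6367, abs=1e-12)

    def test_impossible_standardized_coefficient(self):
        B = np.array([[0.0, 0.0], [1.2, 0.0]])
        with pytest.raises(ValueError, match="inconsistent"):
            solve_unit_variance_residuals(B, [0], np.array([[1.0]]))


class TestSampleMoments:
    def test_not_pd_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            SampleMoments(S=S, n=50, names=["a", "b"])

    def test_n_too_small_rejected(self):
        with pytest.raises(ValueError, match="sample size"):
            SampleMoments(S=np.eye(3), n=3, names=list("abc"))

    def test_reorder(self):
        S = np.array([[1.0, 0.5], [0.5, 2.0]])
        mom = SampleMoments(S=S, n=10, names=["a", "b"]).reordered(["b", "a"])
        assert mom.S[0, 0] == 2.0 and mom.S[0, 1] == 0.5


def saturated_recursive_model(names):
    """Fully recursive just-identified model: every earlier var feeds every later."""
    edges = [Edge(s, t) for i, t in enumerate(names) for s in names[:i]]
    covs = {}  # single exogenous variable: just its free variance
    return PathModel(list(names), edges, covs)


def ols_oracle(S, parents_idx, target_idx):
    """Independent normal-equations solve for one structural equation."""
    Spp = S[np.ix_(parents_idx, parents_idx)]
    spt = S[parents_idx, target_idx]
    return np.linalg.solve(Spp, spt)


class TestFitMl:
    def test_single_edge_just_identified(self):
        m = parse_model("X -> Y")
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        fit = fit_ml(m, SampleMoments(S=S, n=100, names=["X", "Y"]))
        assert fit.estimates["X->Y"] == pytest.approx(0.4, abs=1e-8)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0
        assert fit.converged

    def test_just_identified_matches_ols_oracle(self, rng):
        names = ["v0", "v1", "v2", "v3"]
        for _ in range(10):
            S = random_pd_matrix(rng, 4)
            fit = fit_ml(saturated_recursive_model(names), SampleMoments(S=S, n=60, names=names))
            for t in range(1, 4):
                b = ols_oracle(S, list(range(t)), t)
                for s, coef in zip(range(t), b):
                    assert fit.estimates[f"v{s}->v{t}"] == pytest.approx(coef, abs=1e-6)

    def test_self_consistency_on_implied_matrix(self, refined_model, implied_corr_moments):
        fit = fit_ml(refined_model, implied_corr_moments)
        assert fit.converged
        assert fit.chi_square < 1e-6
        for (s, t), v in presets.REFINED_COEFFICIENTS.items():
            assert fit.estimates[f"{s}->{t}"] == pytest.approx(v, abs=1e-4)

    def test_standardized_invariant_to_rescaling(self, refined_model, implied_corr_moments):
        # fitting the covariance of arbitrarily rescaled variables must give
        # the same standardized solution as fitting the correlation matrix
        scales = np.array([2.0, 0.5, 10.0, 1.0, 0.1, 3.0])
        S_cov = implied_corr_moments.S * np.outer(scales, scales)
        mom_cov = SampleMoments(S=S_cov, n=111, names=implied_corr_moments.names)
        fit_corr = fit_ml(refined_model, implied_corr_moments)
        fit_cov = fit_ml(refined_model, mom_cov)
        for lab, v in fit_corr.standardized_estimates.items():
            assert fit_cov.standardized_estimates[lab] == pytest.approx(v, abs=1e-6)

    def test_overidentified_model_positive_chi_square(self, refined_model, rng):
        # perturb the population matrix so the 6-df model no longer fits exactly
        mom = presets.refined_implied_correlation()
        E = random_pd_matrix(rng, 6, jitter=3.0)
        d = np.sqrt(np.diag(E))
        R_noise = E / np.outer(d, d)
        S = 0.85 * mom.S + 0.15 * R_noise
        fit = fit_ml(refined_model, SampleMoments(S=S, n=111, names=mom.names))
        assert fit.converged
        assert fit.chi_square > 0.1
        assert fit.df == 6

    def test_missing_variable_in_moments(self, refined_model):
        with pytest.raises(ValueError, match="missing"):
            fit_ml(refined_model, SampleMoments(S=np.eye(3), n=50, names=["a", "b", "c"]))

    def test_cyclic_model_rejected(self):
        m = PathModel(["A", "B"], [Edge("A", "B"), Edge("B", "A")])
        from streamsem.path_model import FitError

        with pytest.raises(FitError, match="cycle"):
            fit_ml(m, SampleMoments(S=np.eye(2), n=50, names=["A", "B"]))


def path_tracing_oracle(B, source, target):
    """Total effect by enumerating every directed path and summing products."""
    import networkx as nx

    p = B.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(p))
    g.add_edges_from((s, t) for t in range(p) for s in range(p) if B[t, s] != 0.0)
    total = 0.0
    for path in nx.all_simple_paths(g, source, target):
        prod = 1.0
        for a, b in itertools.pairwise(path):
            prod *= B[b, a]
        total += prod
    return total


class TestDecomposeEffects:
    def test_zero_matrix(self):
        eff = decompose_effects(np.zeros((3, 3)))
        assert np.allclose(eff.direct, 0) and np.allclose(eff.total, 0)

    def test_mediation_chain(self):
        a, b, c = 0.5, 0.7, 0.2
        B = np.zeros((3, 3))
        B[1, 0], B[2, 1], B[2, 0] = a, b, c
        eff = decompose_effects(B, names=["X", "M", "Y"])
        res = eff.of("X", "Y")
        assert res["indirect"] == pytest.approx(a * b)
        assert res["total"] == pytest.approx(c + a * b)

    def test_refined_model_indirect_effect(self, population_model):
        B, _ = population_model.matrices()
        eff = decompose_effects(B, names=population_model.variables)
        res = eff.of("urban_pct", "bmi")
        assert res["indirect"] == pytest.approx(0.20 * -0.33, abs=1e-12)

    def test_total_equals_direct_plus_indirect(self, rng):
        B = np.tril(rng.normal(scale=0.4, size=(5, 5)), k=-1)
        eff = decompose_effects(B)
        assert np.allclose(eff.total, eff.direct + eff.indirect)

    def test_total_matches_path_tracing_and_neumann_sum(self, rng):
        B = np.tril(rng.normal(scale=0.4, size=(5, 5)), k=-1)
        eff = decompose_effects(B)
        neumann = sum(np.linalg.matrix_power(B, k) for k in range(1, 5))
        assert np.allclose(eff.total, neumann, atol=1e-12)
        for s in range(5):
            for t in range(5):
                if s != t:
                    assert eff.total[t, s] == pytest.approx(
                        path_tracing_oracle(B, s, t), abs=1e-10
                    )

    def test_cyclic_rejected(self):
        B = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="acyclic"):
            decompose_effects(B)


def test_simulated_refit_recovers_parameters(population_model, refined_model):
    """Round trip: simulate at large n, refit, recover generating values."""
    from streamsem.synthetic_data import simulate_standardized

    df = simulate_standardized(population_model, n=40000, seed=5)
    mom = SampleMoments.from_dataframe(df.drop(columns="site_id"), kind="covariance")
    fit = fit_ml(refined_model, mom)
    assert fit.converged
    for (s, t), v in presets.REFINED_COEFFICIENTS.items():
        assert fit.estimates[f"{s}->{t}"] == pytest.approx(v, abs=0.02)
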