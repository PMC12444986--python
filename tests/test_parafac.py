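import itertools

import numpy as np
import pytest

from eemquench.core import EEM, EEMDataset
from eemquench.errors import GridError, ValidationError
from eemquench.parafac import (
    ParafacModel,
    compute_fmax,
    fit_parafac_hals,
    match_components,
    project_eem,
    select_n_components,
    split_half_similarity,
    tucker_congruence,
)
from eemquench.quench import CompoundQuenchModel, QuenchScenario
from eemquench.synth import CompoundSpec, generate_pair


def _compound(ex_c, em_c, name="c", k_e=0.2):
    return CompoundSpec(
        name=name, ex_center=ex_c, ex_sigma=12.0, em_center=em_c, em_sigma=20.0,
        quench=CompoundQuenchModel(K_e=k_e),
    )


COMPOUNDS3 = [
    _compound(280.0, 340.0, "c1"),
    _compound(312.0, 395.0, "c2"),
    _compound(350.0, 455.0, "c3"),
]


def _ground_truth_model(compounds, grid, n=1):
    """ParafacModel holding the simulator's unit-max loadings."""
    ex = np.column_stack(
        [np.exp(-0.5 * ((grid.excitation - c.ex_center) / c.ex_sigma) ** 2)
         for c in compounds]
    )
    em = np.column_stack(
        [np.exp(-0.5 * ((grid.emission - c.em_center) / c.em_sigma) ** 2)
         for c in compounds]
    )
    return ParafacModel(
        ex_loadings=ex / ex.max(axis=0),
        em_loadings=em / em.max(axis=0),
        scores=np.ones((n, len(compounds))),
        grid=grid,
        eem_ids=[str(i) for i in range(n)],
    )


def _random_stack(compounds, grid, n_eems, seed):
    rng = np.random.default_rng(seed)
    truth = _ground_truth_model(compounds, grid, n=1)
    eems = []
    for _ in range(n_eems):
        scores = rng.uniform(0.5, 5.0, size=len(compounds))
        z = sum(
            scores[r] * truth.component_matrix(r) for r in range(len(compounds))
        )
        eems.append(EEM(grid, z))
    return eems, truth


def _paired_dataset(compounds, grid, n_pairs, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        concs = rng.uniform(0.5, 3.0, size=len(compounds))
        pairs.append(
            generate_pair(
                compounds, concs, Q_e=2.5, grid=grid,
                sample_id=f"s{i}", noise_sigma=noise, rng=rng,
            )
        )
    return EEMDataset(pairs)


class TestFit:
    def test_rank1_exact(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3[:1], small_grid, 6, seed=0)
        m = fit_parafac_hals(eems, 1, seed=0, n_restarts=2)
        assert m.rel_error < 1e-6

    def test_invalid_R(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3[:1], small_grid, 4, seed=0)
        with pytest.raises(ValidationError):
            fit_parafac_hals(eems, 0)

    def test_three_component_recovery(self, small_grid):
        eems, truth = _random_stack(COMPOUNDS3, small_grid, 40, seed=1)
        m = fit_parafac_hals(eems, 3, seed=1, n_restarts=3)
        perm = match_components(truth, m)
        for r in range(3):
            assert tucker_congruence(
                truth.ex_loadings[:, r], m.ex_loadings[:, perm[r]]
            ) >= 0.99
            assert tucker_congruence(
                truth.em_loadings[:, r], m.em_loadings[:, perm[r]]
            ) >= 0.99

    def test_restart_stability(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 30, seed=2)
        m1 = fit_parafac_hals(eems, 3, seed=10, n_restarts=2)
        m2 = fit_parafac_hals(eems, 3, seed=99, n_restarts=2)
        perm = match_components(m1, m2)
        f1 = m1.scores
        f2 = m2.scores[:, perm]
        np.testing.assert_allclose(f1, f2, rtol=1e-4)

    def test_seed_determinism(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 10, seed=3)
        m1 = fit_parafac_hals(eems, 2, seed=7)
        m2 = fit_parafac_hals(eems, 2, seed=7)
        np.testing.assert_array_equal(m1.scores, m2.scores)

    def test_error_trace_non_increasing(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 15, seed=4)
        m = fit_parafac_hals(eems, 3, seed=4, n_restarts=1)
        diffs = np.diff(m.error_trace)
        assert np.all(diffs <= 1e-10)

    def test_order_invariance(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 12, seed=5)
        m1 = fit_parafac_hals(eems, 3, seed=5)
        rev = fit_parafac_hals(eems[::-1], 3, seed=5)
        perm = match_components(m1, rev)
        np.testing.assert_allclose(
            m1.scores, rev.scores[::-1][:, perm], rtol=1e-3, atol=1e-6
        )


class TestFmax:
    def test_unit_max_identity(self, toy_grid):
        m = ParafacModel(
            ex_loadings=np.array([[1.0], [0.5], [0.2], [0.1]]),
            em_loadings=np.array([[0.3], [1.0], [0.4]]),
            scores=np.array([[2.0]]),
            grid=toy_grid,
            eem_ids=["e0"],
        )
        assert compute_fmax(m, 0)[0] == pytest.approx(2.0)

    def test_normalization_invariance(self, toy_grid):
        # rescaling loadings and compensating in scores leaves Fmax fixed
        ex = np.array([[1.0], [0.5], [0.2], [0.1]])
        em = np.array([[0.3], [1.0], [0.4]])
        m1 = ParafacModel(ex, em, np.array([[2.0]]), toy_grid, ["e"])
        m2 = ParafacModel(ex * 4, em * 0.5, np.array([[1.0]]), toy_grid, ["e"])
        assert compute_fmax(m1, 0)[0] == pytest.approx(compute_fmax(m2, 0)[0])

    def test_zero_eem_zero_fmax(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3[:1], small_grid, 5, seed=6)
        eems.append(EEM(small_grid, np.zeros(small_grid.shape)))
        m = fit_parafac_hals(eems, 1, seed=6)
        assert compute_fmax(m, 5)[0] == pytest.approx(0.0, abs=1e-8)

    def test_single_compound_amplitude(self, small_grid):
        # peak amplitude A at the loading peaks -> Fmax ~ A
        c = COMPOUNDS3[0]
        amp = 37.0
        eems = [
            EEM(small_grid, amp * _ground_truth_model([c], small_grid).component_matrix(0)),
            EEM(small_grid, 2 * amp * _ground_truth_model([c], small_grid).component_matrix(0)),
        ]
        m = fit_parafac_hals(eems, 1, seed=0)
        assert compute_fmax(m, 0)[0] == pytest.approx(amp, rel=0.01)


class TestProjection:
    def test_self_consistency(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 20, seed=7)
        m = fit_parafac_hals(eems, 3, seed=7)
        scores, resid = project_eem(m, eems[0])
        np.testing.assert_allclose(scores, m.scores[0], rtol=1e-5, atol=1e-6)

    def test_zero_eem(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 10, seed=8)
        m = fit_parafac_hals(eems, 3, seed=8)
        scores, resid = project_eem(m, EEM(small_grid, np.zeros(small_grid.shape)))
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_pure_component_pattern(self, small_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 15, seed=9)
        m = fit_parafac_hals(eems, 3, seed=9)
        target = EEM(small_grid, 3.0 * m.component_matrix(1))
        scores, _ = project_eem(m, target)
        expected = np.zeros(3)
        expected[1] = 3.0
        np.testing.assert_allclose(scores, expected, atol=1e-6)

    def test_grid_mismatch(self, small_grid, toy_grid):
        eems, _ = _random_stack(COMPOUNDS3, small_grid, 8, seed=10)
        m = fit_parafac_hals(eems, 2, seed=10)
        with pytest.raises(GridError):
            project_eem(m, EEM(toy_grid, np.zeros(toy_grid.shape)))


class TestCongruence:
    def test_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert tucker_congruence(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert tucker_congruence([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_scale_invariance(self):
        assert tucker_congruence([1, 2, 2], [2, 4, 4]) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            tucker_congruence([0, 0], [1, 1])


class TestMatching:
    def _model(self, grid, ex, em):
        R = ex.shape[1]
        return ParafacModel(ex, em, np.ones((1, R)), grid, ["e"])

    def test_identity_permutation(self, small_grid):
        truth = _ground_truth_model(COMPOUNDS3, small_grid)
        np.testing.assert_array_equal(match_components(truth, truth), [0, 1, 2])

    def test_swap_recovered(self, small_grid):
        a = _ground_truth_model(COMPOUNDS3, small_grid)
        b = self._model(
            small_grid, a.ex_loadings[:, [1, 0, 2]], a.em_loadings[:, [1, 0, 2]]
        )
        np.testing.assert_array_equal(match_components(a, b), [1, 0, 2])

    def test_against_brute_force(self, small_grid):
        rng = np.random.default_rng(11)
        a = _ground_truth_model(COMPOUNDS3, small_grid)
        ex = np.abs(a.ex_loadings[:, [2, 0, 1]] + rng.normal(0, 0.05, a.ex_loadings.shape))
        em = np.abs(a.em_loadings[:, [2, 0, 1]] + rng.normal(0, 0.05, a.em_loadings.shape))
        b = self._model(small_grid, ex, em)
        got = match_components(a, b)

        def total(perm):
            return sum(
                tucker_congruence(a.ex_loadings[:, r], b.ex_loadings[:, perm[r]])
                + tucker_congruence(a.em_loadings[:, r], b.em_loadings[:, perm[r]])
                for r in range(3)
            )

        best = max(itertools.permutations(range(3)), key=total)
        assert tuple(got) == best

    def test_unequal_R_rejected(self, small_grid):
        a = _ground_truth_model(COMPOUNDS3, small_grid)
        b = _ground_truth_model(COMPOUNDS3[:2], small_grid)
        with pytest.raises(ValidationError):
            match_components(a, b)


FAST = dict(max_iter=150, tol=1e-7, n_restarts=1)


class TestSplitHalf:
    def test_noiseless_two_component(self, tiny_grid):
        ds = _paired_dataset(COMPOUNDS3[:2], tiny_grid, 8, seed=12)
        res = split_half_similarity(ds, 2, N=3, seed=0, fit_opts=FAST)
        assert res.mean_similarity > 0.999

    def test_determinism(self, tiny_grid):
        ds = _paired_dataset(COMPOUNDS3[:2], tiny_grid, 8, seed=13)
        r1 = split_half_similarity(ds, 2, N=1, seed=5, fit_opts=FAST)
        r2 = split_half_similarity(ds, 2, N=1, seed=5, fit_opts=FAST)
        assert r1.mean_similarity == r2.mean_similarity

    def test_overfit_penalty(self, tiny_grid):
        ds = _paired_dataset(COMPOUNDS3[:2], tiny_grid, 12, seed=14, noise=0.01)
        at_true = split_half_similarity(ds, 2, N=4, seed=1, fit_opts=FAST)
        above = split_half_similarity(ds, 4, N=4, seed=1, fit_opts=FAST)
        assert at_true.mean_similarity >= above.mean_similarity

    def test_too_small_halves_rejected(self, tiny_grid):
        ds = _paired_dataset(COMPOUNDS3[:2], tiny_grid, 4, seed=15)
        with pytest.raises(ValidationError):
            split_half_similarity(ds, 5, N=1, seed=0)


class TestSelectComponents:
    def test_one_component_data(self, tiny_grid):
        ds = _paired_dataset(COMPOUNDS3[:1], tiny_grid, 8, seed=16, noise=0.01)
        rec, curve = select_n_components(ds, [1, 2], N=4, seed=2, fit_opts=FAST)
        assert rec == 1

    def test_unattainable_threshold_warns(self, tiny_grid):
        ds = _paired_dataset(COMPOUNDS3[:1], tiny_grid, 8, seed=17)
        with pytest.warns(UserWarning, match="argmax"):
            rec, curve = select_n_components(
                ds, [1], N=2, seed=3, threshold=1.01, fit_opts=FAST
            )
        assert rec == 1
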