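"""Participation scores, the Gaussian noise model, and related correlates."""

import numpy as np
import pytest

from spiralscope.embed import Embedding, embed_population
from spiralscope.errors import InsufficientDataError
from spiralscope.participation import (
    fit_noise_model,
    hellinger_distance,
    max_consecutive_change,
    participation_changes,
    participation_correlates,
    participation_scores,
    variability_vs_distance,
)
from spiralscope.spikes import RateMatrix


def _embedding_from_axes(axes, eigvals, d, ids=None):
    n = axes.shape[0]
    return Embedding(
        axes=axes, eigvals=np.asarray(eigvals, float),
        var_explained=np.cumsum(eigvals) / np.sum(eigvals), d=d,
        P=np.zeros((10, d)), t=np.arange(10.0), mean=np.zeros(n),
        fit_range=(0.0, 1.0), neuron_ids=ids or [f"n{i}" for i in range(n)],
    )


def test_two_neuron_toy_analytic():
    """Covariance [[2,1],[1,2]]: eigenpairs known in closed form."""
    rng = np.random.default_rng(0)
    L = rng.standard_normal((20000, 2))
    C = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
    F = L @ C.T
    rm = RateMatrix(t=0.01 * np.arange(20000), F=F, sigma=0.1, dt=0.01,
                    window_range=(0.0, 200.0))
    emb = embed_population(rm, var_threshold=1.0)
    table = participation_scores(emb)
    # exact eigenpairs: lambda = 3, 1 with axes (1,1)/sqrt2 and (1,-1)/sqrt2
    # rho_i = |3 * 1/sqrt2| + |1 * 1/sqrt2| = 4/sqrt2 for both neurons -> ratio 1
    assert table.rho[0] == pytest.approx(table.rho[1], rel=0.05)
    exact = _embedding_from_axes(
        np.array([[1, 1], [1, -1]]) / np.sqrt(2), [3.0, 1.0], d=2
    )
    t2 = participation_scores(exact)
    np.testing.assert_allclose(t2.rho, 4 / np.sqrt(2), atol=1e-12)
    np.testing.assert_allclose(t2.rho_norm, 100.0, atol=1e-12)


def test_zero_variance_neuron_has_zero_participation():
    rng = np.random.default_rng(1)
    F = rng.standard_normal((2000, 4))
    F[:, 2] = 7.0
    rm = RateMatrix(t=0.01 * np.arange(2000), F=F, sigma=0.1, dt=0.01,
                    window_range=(0.0, 20.0))
    emb = embed_population(rm, var_threshold=1.0)
    table = participation_scores(emb)
    assert table.rho[2] < 1e-10


def test_sign_invariance_and_eigenvalue_scaling():
    axes = np.array([[0.8, -0.6], [0.6, 0.8]])
    e1 = _embedding_from_axes(axes, [2.0, 1.0], d=2)
    e2 = _embedding_from_axes(-axes, [2.0, 1.0], d=2)
    np.testing.assert_allclose(
        participation_scores(e1).rho, participation_scores(e2).rho, atol=1e-12
    )
    e3 = _embedding_from_axes(axes, [4.0, 2.0], d=2)
    np.testing.assert_allclose(
        participation_scores(e3).rho, 2 * participation_scores(e1).rho, atol=1e-12
    )


class TestNoiseModel:
    def test_pure_gaussian_within_3sd_no_outliers(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(400)
        x = x[np.abs(x - x.mean()) < 2.9 * x.std()]  # construct a 3SD-clean sample
        model = fit_noise_model(x)
        assert model.outliers.size == 0

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.standard_normal(500), [10, -10, 10.5, -11, 9.5]])
        model = fit_noise_model(x)
        planted = set(range(500, 505))
        assert planted <= set(model.outliers.tolist())
        false_pos = set(model.outliers.tolist()) - planted
        assert len(false_pos) <= 3
        assert model.sd == pytest.approx(1.0, abs=0.15)

    def test_iteration_strictly_decreases_and_terminates(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.standard_normal(100), [8.0, -9.0]])
        model = fit_noise_model(x)
        assert model.n_iterations <= x.size
        assert model.threshold_hi > model.threshold_lo

    def test_too_few_deltas_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_noise_model(np.arange(5.0))


class TestHellinger:
    def test_identical_distributions_zero(self):
        x = np.random.default_rng(5).uniform(0, 100, 300)
        assert hellinger_distance(x, x.copy()) == 0.0

    def test_disjoint_distributions_one(self):
        a = np.full(100, 10.0)
        b = np.full(100, 90.0)
        assert hellinger_distance(a, b) == pytest.approx(1.0)

    def test_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.uniform(0, 100, 50)
            b = rng.uniform(0, 100, 50)
            assert 0.0 <= hellinger_distance(a, b) <= 1.0


def _table(rho_norm, ids):
    from spiralscope.participation import ParticipationTable

    return ParticipationTable(rho=np.asarray(rho_norm, float),
                              rho_norm=np.asarray(rho_norm, float), neuron_ids=ids)


def test_identical_programs_zero_change_zero_distance():
    ids = [f"n{i}" for i in range(20)]
    rng = np.random.default_rng(7)
    vals = rng.uniform(0, 100, 20)
    tables = [_table(vals, ids) for _ in range(3)]
    assert np.all(participation_changes(tables) == 0)
    assert np.all(max_consecutive_change(tables) == 0)
    df, corrs = variability_vs_distance(
        tables, {(0, 1): 0.0, (0, 2): 0.0, (1, 2): 0.0}
    )
    assert df["total_change"].eq(0).all()
    assert df["hellinger"].eq(0).all()


def test_rate_driven_participation_correlates():
    """When loadings scale with rate, participation tracks firing rate."""
    rng = np.random.default_rng(8)
    T, n = 4000, 15
    scales = np.linspace(0.5, 3.0, n)
    latent = np.sin(np.linspace(0, 60, T))
    F = 5 * scales[None, :] * (1 + 0.8 * latent[:, None])
    F += 0.3 * rng.standard_normal((T, n))
    rm = RateMatrix(t=0.01 * np.arange(T), F=F, sigma=0.1, dt=0.01,
                    window_range=(0.0, 40.0), stim_off=0.0)
    emb = embed_population(rm)
    table = participation_scores(emb)
    corrs = participation_correlates(table, rm)
    assert corrs["r_rate"] > 0.9
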