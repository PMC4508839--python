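"""Psi, error metrics, surface smoothing, optimum extraction, slopes, sweeps."""

import numpy as np
import pytest

from hebbseq.hcp import HCPConfig, HCPLearningRecord, train_hcp
from hebbseq.markov import TransitionMatrix, make_gaussian_tm
from hebbseq.quantify import (
    ErrorSurface,
    default_alpha_grid,
    default_beta_grid,
    grid_search,
    l1_error,
    learning_slope,
    optimal_params,
    psi,
    smooth_surface,
)


class TestPsi:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(2.0, 0.0, -1.0), (1.0, 1.0, 1.0), (1.9, 0.18, -0.61), (1.05, 0.34, -0.17)],
    )
    def test_reference_values(self, alpha, beta, expected):
        assert round(psi(alpha, beta), 2) == expected

    @pytest.mark.parametrize("alpha", [1.0, 1.3, 1.7, 2.0])
    def test_vanishes_at_half_beta(self, alpha):
        assert psi(alpha, 0.5) == 0.0

    def test_continuous_at_branch_point(self):
        for a in (1.0, 1.5, 2.0):
            below = psi(a, 0.5 - 1e-9)
            above = psi(a, 0.5 + 1e-9)
            assert abs(below - above) < 1e-8

    def test_range_over_default_grids(self):
        vals = [psi(a, b) for a in default_alpha_grid() for b in default_beta_grid()]
        assert -1.0 <= min(vals) and max(vals) <= 1.0

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            psi(0.9, 0.5)
        with pytest.raises(ValueError):
            psi(1.5, 1.2)


class TestL1Error:
    def test_zero_when_equal(self):
        P = make_gaussian_tm(5, 1.0)
        assert l1_error(P.P, P) == 0.0

    def test_uniform_vs_deterministic_closed_form(self):
        # per row |1/n - 1| + (n-1)/n = 2(n-1)/n; mean over rows / n
        for n in (2, 19):
            P = np.eye(n)
            M = np.full((n, n), 1 / n)
            assert l1_error(M, TransitionMatrix(P)) == pytest.approx(2 * (n - 1) / n**2)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_error(np.ones((2, 2)) / 2, TransitionMatrix(np.eye(3)))


class TestSmoothing:
    def test_constant_surface_unchanged(self):
        s = np.full((5, 7), 3.14)
        assert np.allclose(smooth_surface(s), s)

    def test_impulse_becomes_plateau(self):
        s = np.zeros((5, 5))
        s[2, 2] = 9.0
        sm = smooth_surface(s)
        assert np.allclose(sm[1:4, 1:4], 1.0)
        assert sm[0, 0] == 0.0

    def test_requires_3x3(self):
        with pytest.raises(ValueError):
            smooth_surface(np.ones((2, 5)))


def _surface(err, alphas=None, betas=None):
    alphas = np.arange(err.shape[0], dtype=float) + 1 if alphas is None else alphas
    betas = np.arange(err.shape[1], dtype=float) if betas is None else betas
    return ErrorSurface(alphas=alphas, betas=betas, err=err, entropy=np.zeros_like(err))


class TestOptimum:
    def test_recovers_convex_bowl_minimum(self):
        a = np.linspace(1, 2, 9)
        b = np.linspace(0, 1, 11)
        err = (a[:, None] - 1.5) ** 2 + (b[None, :] - 0.3) ** 2
        surf = _surface(err, a, b)
        a_opt, b_opt = optimal_params(surf)
        assert a_opt == pytest.approx(1.5) and b_opt == pytest.approx(0.3)

    def test_tie_breaks_lexicographically(self):
        # two symmetric dips produce many tied cells on the smoothed surface
        # (every cell whose 3x3 window contains a dip); the first tie in
        # row-major order is (0, 0), i.e. the smallest (alpha, beta)
        err = np.ones((7, 7))
        err[1, 1] = err[4, 4] = -8.0
        surf = _surface(err)
        assert surf._opt_idx() == (0, 0)

    def test_flat_surface_returns_smallest_grid_point(self):
        surf = _surface(np.ones((4, 6)))
        assert optimal_params(surf) == (1.0, 0.0)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            _surface(np.ones((3, 3)), np.array([2.0, 1.0, 3.0]), np.arange(3.0))


class TestLearningSlope:
    def _record(self, err):
        err = np.asarray(err, dtype=float)
        return HCPLearningRecord(
            error_t=err,
            entropy_t=np.zeros_like(err),
            M_runs=np.zeros((1, 2, 2)),
            config=HCPConfig(),
            target=np.zeros((2, 2)),
        )

    def test_constant_trajectory(self):
        assert learning_slope(self._record(np.full(100, 0.3)), (0, 50)) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_trajectory(self):
        rec = self._record(1.0 - 0.01 * np.arange(100))
        assert learning_slope(rec, (10, 60)) == pytest.approx(-0.01)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            learning_slope(self._record(np.zeros(10)), (5, 50))

    def test_additive_learns_faster_initially_than_multiplicative(self):
        tm = make_gaussian_tm(19, 0.0)
        common = dict(n_songs=60, n_runs=1, seed=6)
        add = train_hcp(tm, HCPConfig(alpha=1.0, beta=0.0, **common))
        mult = train_hcp(tm, HCPConfig(alpha=1.0, beta=1.0, **common))
        assert abs(learning_slope(add, (0, 50))) > abs(learning_slope(mult, (0, 50)))


class TestGridSearch:
    def test_shape_and_reproducibility(self):
        tm = make_gaussian_tm(5, 0.7)
        cfg = HCPConfig(n_songs=20, n_runs=1, seed=0)
        grids = dict(alphas=np.array([1.0, 1.5, 2.0]), betas=np.array([0.0, 0.3, 0.6, 0.9]))
        a = grid_search(tm, cfg, **grids)
        b = grid_search(tm, cfg, **grids)
        assert a.err.shape == (3, 4)
        assert np.array_equal(a.err, b.err)
        assert np.all(a.err >= 0)
        assert np.all((a.entropy >= 0) & (a.entropy <= np.log2(5) + 1e-9))

    def test_default_grid_definitions(self):
        assert len(default_alpha_grid()) == 21
        assert len(default_beta_grid()) == 51
        assert default_alpha_grid()[1] - default_alpha_grid()[0] == pytest.approx(0.05)
        assert default_beta_grid()[1] - default_beta_grid()[0] == pytest.approx(0.02)
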