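"""Quantification suite: learning error, the Psi balance index, grid
searches over (alpha, beta) with surface smoothing and optimum extraction,
learning-rate slopes, and the entropy / SNR sweep experiments.

Psi(alpha, beta) is a scalar summary of the net balance between the
competitive force (alpha, the depression-potentiation ratio) and the
homogenizing force (beta, the weight dependence of plasticity):

    Psi = 2 (beta - 0.5) / alpha   for beta >= 0.5
    Psi = alpha (beta - 0.5)       for beta <  0.5

Over the default grids alpha in [1, 2], beta in [0, 1] it spans [-1, 1]:
-1 (alpha = 2, beta = 0) is maximally competitive/binarizing, +1
(alpha = 1, beta = 1) maximally homogenizing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .hcp import HCPConfig, HCPLearningRecord, train_hcp, _spawn_seed
from .markov import TransitionMatrix, make_gaussian_tm, solve_sigma_for_entropy

__all__ = [
    "psi",
    "l1_error",
    "default_alpha_grid",
    "default_beta_grid",
    "ErrorSurface",
    "grid_search",
    "smooth_surface",
    "optimal_params",
    "learning_slope",
    "entropy_sweep",
    "snr_sweep",
]


def psi(alpha: float, beta: float) -> float:
    """Homogenization-competition balance index; continuous at beta = 0.5."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if not 0 <= beta <= 1:
        raise ValueError("beta must be in [0, 1]")
    if beta >= 0.5:
        return 2.0 * (beta - 0.5) / alpha
    return alpha * (beta - 0.5)


def l1_error(M: np.ndarray, P: TransitionMatrix | np.ndarray) -> float:
    """Mean absolute difference (1/N^2) sum |m_ij - P_ij|."""
    P = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.shape != P.shape:
        raise ValueError(f"shape mismatch: {M.shape} vs {P.shape}")
    return float(np.abs(M - P).mean())


def default_alpha_grid() -> np.ndarray:
    """alpha in 1:0.05:2 (21 values)."""
    return np.round(np.arange(1.0, 2.0 + 1e-9, 0.05), 10)


def default_beta_grid() -> np.ndarray:
    """beta in 0:0.02:1 (51 values)."""
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 10)


def coarse_alpha_grid() -> np.ndarray:
    """Reduced alpha grid for scaled-down sweeps (spans [1, 2], includes 1.9)."""
    return np.array([1.05, 1.45, 1.9])


def coarse_beta_grid() -> np.ndarray:
    """Reduced beta grid for scaled-down sweeps (spans [0, 1], includes 0.18/0.34)."""
    return np.array([0.1, 0.18, 0.26, 0.34, 0.42, 0.5, 0.62, 0.74, 0.86, 0.98])


@dataclass(frozen=True)
class ErrorSurface:
    """Final error and weight entropy over an (alpha, beta) grid.

    ``err[a, b]`` and ``entropy[a, b]`` index alpha along rows and beta
    along columns.  The optimum is the argmin of the box-smoothed error
    surface, ties broken toward the smallest (alpha, beta).
    """

    alphas: np.ndarray
    betas: np.ndarray
    err: np.ndarray
    entropy: np.ndarray

    def __post_init__(self) -> None:
        for g in (self.alphas, self.betas):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing")
        if self.err.shape != (len(self.alphas), len(self.betas)):
            raise ValueError("surface shape does not match grids")

    @property
    def err_smooth(self) -> np.ndarray:
        return smooth_surface(self.err)

    @property
    def optimum(self) -> tuple[float, float]:
        return optimal_params(self)

    @property
    def optimum_value(self) -> float:
        """Raw (unsmoothed) error at the smoothed-surface optimum cell."""
        ai, bi = self._opt_idx()
        return float(self.err[ai, bi])

    @property
    def optimum_entropy(self) -> float:
        ai, bi = self._opt_idx()
        return float(self.entropy[ai, bi])

    def _opt_idx(self) -> tuple[int, int]:
        s = self.err_smooth
        flat = int(np.argmin(s))  # row-major argmin = lexicographic tie-break
        return flat // s.shape[1], flat % s.shape[1]


def smooth_surface(surface: np.ndarray) -> np.ndarray:
    """Normalized 3x3 box filter with edge replication."""
    surface = np.asarray(surface, dtype=float)
    if surface.ndim != 2 or min(surface.shape) < 3:
        raise ValueError("surface must be at least 3 x 3")
    return ndimage.uniform_filter(surface, size=3, mode="nearest")


def optimal_params(surface: ErrorSurface) -> tuple[float, float]:
    """(alpha*, beta*) at the argmin of the smoothed error surface."""
    ai, bi = surface._opt_idx()
    return float(surface.alphas[ai]), float(surface.betas[bi])


def grid_search(
    tm: TransitionMatrix,
    base_cfg: HCPConfig,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> ErrorSurface:
    """Train at every (alpha, beta) grid point and collect final error/entropy.

    Each cell runs :func:`train_hcp` with ``base_cfg.n_runs`` averaged
    runs; cell seeds are derived independently from ``base_cfg.seed`` and
    the grid indices, so the surface is reproducible and cells are
    statistically independent.
    """
    alphas = default_alpha_grid() if alphas is None else np.asarray(alphas, dtype=float)
    betas = default_beta_grid() if betas is None else np.asarray(betas, dtype=float)
    err = np.empty((len(alphas), len(betas)))
    ent = np.empty_like(err)
    for ai, a in enumerate(alphas):
        for bi, b in enumerate(betas):
            cfg = replace(
                base_cfg,
                alpha=float(a),
                beta=float(b),
                seed=_spawn_seed(base_cfg.seed, ai, bi),
            )
            rec = train_hcp(tm, cfg)
            err[ai, bi] = rec.final_error
            ent[ai, bi] = rec.final_entropy
    return ErrorSurface(alphas=alphas, betas=betas, err=err, entropy=ent)


def learning_slope(
    record: HCPLearningRecord,
    window: tuple[int, int] = (1, 50),
    which: str = "error",
) -> float:
    """Least-squares slope of error (or entropy) vs song index over a window."""
    t0, t1 = window
    traj = record.error_t if which == "error" else record.entropy_t
    if not 0 <= t0 < t1 <= len(traj):
        raise ValueError(f"window {window} outside record of length {len(traj)}")
    t = np.arange(t0, t1)
    return float(np.polyfit(t, traj[t0:t1], 1)[0])


def _sinh_fit(H: np.ndarray, psi_star: np.ndarray):
    """Unweighted least-squares fit psi* = a sinh(b H) + c; returns params, R^2."""

    def f(h, a, b, c):
        return a * np.sinh(b * h) + c

    try:
        popt, _ = optimize.curve_fit(f, H, psi_star, p0=[0.05, 1.0, -0.5], maxfev=20000)
        resid = psi_star - f(H, *popt)
        ss_tot = float(np.sum((psi_star - psi_star.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        return tuple(float(v) for v in popt), r2
    except RuntimeError:
        return (float("nan"),) * 3, float("nan")


def entropy_sweep(
    entropy_targets: np.ndarray,
    base_cfg: HCPConfig,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
    n_states: int = 19,
    final_n_runs: int | None = None,
):
    """Grid-search the optimal (alpha, beta) for each Gaussian entropy target.

    For every target row entropy, builds the circulant Gaussian matrix at
    that entropy, grid-searches (alpha, beta), re-trains at the optimum
    (with ``final_n_runs`` runs if given), and tabulates the optimum, its
    Psi, and the final error/entropy.  Also fits psi* = a sinh(b H) + c
    across targets.  Returns ``(DataFrame, fit_params, r_squared)``.
    """
    rows = []
    for k, H in enumerate(np.asarray(entropy_targets, dtype=float)):
        sigma = solve_sigma_for_entropy(H, n_states)
        tm = make_gaussian_tm(n_states, sigma)
        cfg_k = replace(base_cfg, seed=_spawn_seed(base_cfg.seed, 0xE27, k))
        surf = grid_search(tm, cfg_k, alphas, betas)
        a_opt, b_opt = surf.optimum
        if final_n_runs is not None and final_n_runs != base_cfg.n_runs:
            rec = train_hcp(
                tm,
                replace(cfg_k, alpha=a_opt, beta=b_opt, n_runs=final_n_runs,
                        seed=_spawn_seed(cfg_k.seed, 0xF)),
            )
            final_err, final_H = rec.final_error, rec.final_entropy
        else:
            final_err, final_H = surf.optimum_value, surf.optimum_entropy
        rows.append(
            dict(
                target_entropy=H,
                sigma=sigma,
                alpha_opt=a_opt,
                beta_opt=b_opt,
                psi_opt=psi(a_opt, b_opt),
                final_err=final_err,
                final_entropy=final_H,
            )
        )
    table = pd.DataFrame(rows)
    params, r2 = _sinh_fit(table["target_entropy"].values, table["psi_opt"].values)
    return table, params, r2


def snr_sweep(
    snr_values,
    tm: TransitionMatrix,
    base_cfg: HCPConfig,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Optimal (alpha, beta) per signal-to-noise ratio (inf = no noise)."""
    rows = []
    for k, snr in enumerate(snr_values):
        cfg_k = replace(base_cfg, snr=float(snr), seed=_spawn_seed(base_cfg.seed, 0x5A2, k))
        surf = grid_search(tm, cfg_k, alphas, betas)
        a_opt, b_opt = surf.optimum
        rows.append(dict(snr=float(snr), alpha_opt=a_opt, beta_opt=b_opt,
                         psi_opt=psi(a_opt, b_opt), final_err=surf.optimum_value))
    return pd.DataFrame(rows)
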