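"""Recurrent rate networks trained with Hebbian covariance plasticity (HCP).

A network of n linear-saturating rate units is driven through a Markov
state sequence by a strong teaching input: on each time step the unit for
the current state receives a large input pulse, every unit receives
Poisson background noise, and rates follow

    y(t) = min(M.T y(t-1) + delta(t) + eta, r_max)

with ``m_ij`` the weight from pre-synaptic unit i to post-synaptic unit j.
Weights change by a covariance rule on the deviations of pre rate (at t-1)
and post rate (at t) from their running means: potentiation A+ * s_i * s_j
* (1-m)^beta when both deviations are positive, depression alpha * A+ *
s_i * s_j * m^beta when the signs differ, nothing when both are negative.
After every update weights are clipped to [0, 1] and divisively normalized
so each competing group sums to 1 — the outgoing weights of each
pre-synaptic unit (``site='pre'``) or the incoming weights of each
post-synaptic unit (``site='post'``).  Pre-synaptic competition drives M
toward the forward conditionals of the training sequence, post-synaptic
competition toward the backward conditionals.

The per-step loop is JIT-compiled with numba; a 1000-song training run on
a 19-state chain takes on the order of a second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .markov import TransitionMatrix, backward_from_forward, mean_entropy

__all__ = ["HCPConfig", "HCPLearningRecord", "train_hcp", "weight_dependence",
           "hcp_update", "normalize_and_clip", "step_dynamics"]


@dataclass(frozen=True)
class HCPConfig:
    """Parameters of a Hebbian-covariance-plasticity training run.

    Attributes
    ----------
    A_plus : potentiation learning rate (depression rate is ``alpha * A_plus``).
        The default 0.001 lets 1000 songs reach asymptote on 19-state
        problems while keeping the stochastic weight-fluctuation floor
        small (final entropy of a learned deterministic target scales
        roughly with sqrt(A_plus)).
    alpha : depression-potentiation ratio, in [1, 2].
    beta : weight-dependence exponent, in [0, 1]; 0 is additive, 1 multiplicative.
    site : 'pre' for pre-synaptic (outgoing-sum) competition, 'post' for
        post-synaptic (incoming-sum) competition.
    snr : teaching-signal-to-noise ratio.  Background activity arrives as
        sparse Poisson pulses of amplitude ``delta_amp / snr``; at the
        default rate of 1/n pulses per unit per step the network sees on
        average one noise pulse per step against one teaching pulse, so
        snr is the amplitude ratio of the two.  ``inf`` disables noise.
        The default of 10 keeps the teaching signal dominant, the regime
        in which the learned weights quantitatively track the target
        conditionals; lowering snr strengthens the homogenizing pressure
        of random co-activations.
    noise_rate : expected noise pulses per unit per step; ``None`` means 1/n.
    g_rec : gain on the recurrent input, in (0, 1).  With competing weight
        sums normalized to 1 the recurrence alone conserves total activity,
        so the per-step teaching input would accumulate until every unit
        saturates at r_max and all covariance deviations vanish; a gain
        below 1 (equivalently, a rate leak) keeps network activity bounded
        and stationary.  The value is not critical provided the network
        stays unsaturated.
    n_songs : training iterations; one song is a sequence of ``song_len_factor * n``
        state presentations starting from a uniformly random state.
    n_runs : independent runs averaged (fresh initial weights and sequences).
    ybar_window : length of the running-mean window for rate deviations.
    error_norm : 'l1' (mean absolute difference) or 'l2'.
    """

    alpha: float = 1.25
    beta: float = 0.38
    site: str = "pre"
    A_plus: float = 0.001
    snr: float = 10.0
    n_songs: int = 1000
    song_len_factor: int = 5
    seed: int = 0
    n_runs: int = 5
    r_max: float = 1.0
    delta_amp: float = 1.0
    ybar_window: int = 5
    error_norm: str = "l1"
    init_jitter: float = 0.05
    noise_rate: float | None = None
    g_rec: float = 0.3

    def __post_init__(self) -> None:
        if not self.alpha >= 1:
            raise ValueError("alpha must be >= 1")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        if self.A_plus < 0:
            raise ValueError("A_plus must be >= 0")
        if self.site not in ("pre", "post"):
            raise ValueError("site must be 'pre' or 'post'")
        if not self.snr > 0:
            raise ValueError("snr must be > 0 (use inf for no noise)")
        if self.error_norm not in ("l1", "l2"):
            raise ValueError("error_norm must be 'l1' or 'l2'")
        if not 0 < self.g_rec < 1:
            raise ValueError("g_rec must be in (0, 1)")

    @property
    def noise_amp(self) -> float:
        return 0.0 if math.isinf(self.snr) else self.delta_amp / self.snr


@dataclass(frozen=True)
class HCPLearningRecord:
    """Per-song error and weight-entropy trajectories plus final weights.

    ``error_t`` and ``entropy_t`` are averaged across the independent runs;
    ``M_runs`` stacks each run's final weight matrix and ``M_final`` is
    their mean.
    """

    error_t: np.ndarray
    entropy_t: np.ndarray
    M_runs: np.ndarray
    config: HCPConfig
    target: np.ndarray

    @property
    def M_final(self) -> np.ndarray:
        return self.M_runs.mean(axis=0)

    @property
    def final_error(self) -> float:
        return float(self.error_t[-1])

    @property
    def final_entropy(self) -> float:
        return float(self.entropy_t[-1])


def weight_dependence(m: float | np.ndarray, beta: float):
    """Power-law weight dependence f+ = (1-m)^beta, f- = m^beta."""
    m = np.asarray(m, dtype=float)
    return (1.0 - m) ** beta, m ** beta


def step_dynamics(
    M: np.ndarray,
    y_prev: np.ndarray,
    active_state: int,
    delta_amp: float = 1.0,
    r_max: float = 1.0,
    eta: np.ndarray | None = None,
    g_rec: float = 1.0,
) -> np.ndarray:
    """One rate update: y = min(g_rec * M.T y_prev + delta + eta, r_max).

    ``delta`` is ``delta_amp`` at the active state and zero elsewhere.
    Pure-python reference for the compiled kernel; rates are also floored
    at 0 (conductances and rates are non-negative).  ``g_rec=1`` is the
    raw saturating-linear recurrence; training uses the leaky gain from
    :class:`HCPConfig`.
    """
    drive = g_rec * (y_prev @ M)
    drive[active_state] += delta_amp
    if eta is not None:
        drive = drive + eta
    return np.clip(drive, 0.0, r_max)


def hcp_update(
    M: np.ndarray,
    sigma_pre: np.ndarray,
    sigma_post: np.ndarray,
    cfg: HCPConfig,
) -> np.ndarray:
    """Weight-change matrix of the covariance rule (no clip/normalize).

    Potentiation where both deviations are positive, depression (scaled by
    alpha) where the signs differ, zero where both are non-positive.
    Reference implementation mirrored by the compiled kernel.
    """
    f_plus, f_minus = weight_dependence(M, cfg.beta)
    outer = np.outer(sigma_pre, sigma_post)
    pot = (sigma_pre[:, None] > 0) & (sigma_post[None, :] > 0)
    dep = (sigma_pre[:, None] > 0) & (sigma_post[None, :] < 0)
    dep |= (sigma_pre[:, None] < 0) & (sigma_post[None, :] > 0)
    dM = np.zeros_like(M)
    dM[pot] = cfg.A_plus * outer[pot] * f_plus[pot]
    dM[dep] = cfg.alpha * cfg.A_plus * outer[dep] * f_minus[dep]
    return dM


def normalize_and_clip(M: np.ndarray, site: str = "pre") -> np.ndarray:
    """Clip weights to [0, 1] then divisively normalize the competing sums.

    ``site='pre'``: each pre-synaptic unit's outgoing weights (row of M)
    sum to 1; ``site='post'``: each post-synaptic unit's incoming weights
    (column) sum to 1.  A group whose sum collapses to 0 is reset uniform.
    """
    M = np.clip(M, 0.0, 1.0)
    axis = 1 if site == "pre" else 0
    sums = M.sum(axis=axis, keepdims=True)
    n = M.shape[0]
    uniform = np.full_like(M, 1.0 / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, M / np.where(sums > 0, sums, 1.0), uniform)
    return out


@njit(cache=True)
def _train_kernel(
    cdf,  # (n, n) row CDFs of the forward matrix
    target,  # (n, n) comparison matrix (P_F for pre, P_B for post)
    M,  # (n, n) initial weights, modified in place
    A_plus,
    alpha,
    beta,
    pre_site,  # bool
    noise_amp,
    noise_rate,
    g_rec,
    delta_amp,
    r_max,
    n_songs,
    song_len,
    window,
    use_l2,
    seed,
):
    np.random.seed(seed)
    n = cdf.shape[0]
    err_t = np.empty(n_songs)
    ent_t = np.empty(n_songs)

    # running-mean buffer, pre-loaded with the background mean
    hist = np.empty((window, n))
    bg = min(noise_amp * noise_rate, r_max)
    for w in range(window):
        for i in range(n):
            hist[w, i] = bg
    hist_len = 1
    hist_pos = 1 % window
    y_prev = np.full(n, bg)
    ybar_prev = np.full(n, bg)
    y_now = np.empty(n)
    drive = np.empty(n)
    ybar_now = np.empty(n)

    for song in range(n_songs):
        state = np.random.randint(0, n)
        for step in range(song_len):
            if step > 0:
                u = np.random.random()
                row = cdf[state]
                s = 0
                while s < n - 1 and u > row[s]:
                    s += 1
                state = s
            # rate dynamics
            for j in range(n):
                acc = 0.0
                for i in range(n):
                    acc += M[i, j] * y_prev[i]
                acc *= g_rec
                if j == state:
                    acc += delta_amp
                if noise_amp > 0.0:
                    acc += noise_amp * np.random.poisson(noise_rate)
                if acc > r_max:
                    acc = r_max
                elif acc < 0.0:
                    acc = 0.0
                y_now[j] = acc
            # running mean over the stored history
            for i in range(n):
                acc = 0.0
                for w in range(hist_len):
                    acc += hist[w, i]
                ybar_now[i] = acc / hist_len
            # covariance update
            for i in range(n):
                si = y_prev[i] - ybar_prev[i]
                if si == 0.0:
                    continue
                for j in range(n):
                    sj = y_now[j] - ybar_now[j]
                    m = M[i, j]
                    if si > 0.0 and sj > 0.0:
                        if beta == 0.0:
                            f = 1.0
                        else:
                            f = (1.0 - m) ** beta
                        M[i, j] = m + A_plus * si * sj * f
                    elif (si > 0.0 and sj < 0.0) or (si < 0.0 and sj > 0.0):
                        if beta == 0.0:
                            f = 1.0
                        else:
                            f = m ** beta
                        M[i, j] = m + alpha * A_plus * si * sj * f
            # clip and divisively normalize the competing sums
            for g in range(n):
                tot = 0.0
                for k in range(n):
                    v = M[g, k] if pre_site else M[k, g]
                    if v < 0.0:
                        v = 0.0
                    elif v > 1.0:
                        v = 1.0
                    if pre_site:
                        M[g, k] = v
                    else:
                        M[k, g] = v
                    tot += v
                if tot > 0.0:
                    for k in range(n):
                        if pre_site:
                            M[g, k] /= tot
                        else:
                            M[k, g] /= tot
                else:
                    for k in range(n):
                        if pre_site:
                            M[g, k] = 1.0 / n
                        else:
                            M[k, g] = 1.0 / n
            # advance history
            for i in range(n):
                hist[hist_pos, i] = y_now[i]
                ybar_prev[i] = ybar_now[i]
                y_prev[i] = y_now[i]
            hist_pos = (hist_pos + 1) % window
            if hist_len < window:
                hist_len += 1
        # per-song error and weight entropy
        e = 0.0
        h = 0.0
        for i in range(n):
            for j in range(n):
                d = M[i, j] - target[i, j]
                if use_l2:
                    e += d * d
                else:
                    e += abs(d)
                m = M[i, j] if pre_site else M[j, i]
                if m > 0.0:
                    h -= m * np.log2(m)
        err_t[song] = math.sqrt(e) / (n * n) if use_l2 else e / (n * n)
        ent_t[song] = h / n
    return err_t, ent_t


def _spawn_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def train_hcp(tm: TransitionMatrix, cfg: HCPConfig) -> HCPLearningRecord:
    """Train the recurrent network on sequences from ``tm``.

    Runs ``cfg.n_runs`` independent simulations (fresh +/-5% jittered
    initial weights, fresh stochastic sequences), each for ``cfg.n_songs``
    songs of length ``cfg.song_len_factor * n``.  The per-song error (mean
    absolute difference between M and the target conditionals) is measured
    against the forward matrix for pre-synaptic competition and against
    the Bayes backward matrix for post-synaptic competition; the per-song
    entropy is the mean Shannon entropy of the competing weight groups.
    """
    if tm.kind != "forward":
        raise ValueError("training sequences are sampled from a forward matrix")
    n = tm.n_states
    target_tm = tm if cfg.site == "pre" else backward_from_forward(tm)
    target = target_tm.P if cfg.site == "pre" else target_tm.P.T
    # target[i, j] compares against m_ij: forward P(j|i) for pre competition,
    # backward P(i at t-1 | j at t) for post competition
    cdf = np.cumsum(tm.P, axis=1)
    cdf[:, -1] = 1.0
    song_len = cfg.song_len_factor * n

    err = np.zeros((cfg.n_runs, cfg.n_songs))
    ent = np.zeros((cfg.n_runs, cfg.n_songs))
    M_runs = np.empty((cfg.n_runs, n, n))
    for r in range(cfg.n_runs):
        rng = np.random.default_rng(_spawn_seed(cfg.seed, r, 0x1C0))
        M0 = (1.0 / n) * (1.0 + cfg.init_jitter * rng.uniform(-1, 1, size=(n, n)))
        M0 = normalize_and_clip(M0, cfg.site)
        kseed = _spawn_seed(cfg.seed, r, 0x7E4)
        err[r], ent[r] = _train_kernel(
            cdf,
            target,
            M0,
            cfg.A_plus,
            cfg.alpha,
            cfg.beta,
            cfg.site == "pre",
            cfg.noise_amp,
            cfg.noise_rate if cfg.noise_rate is not None else 1.0 / n,
            cfg.g_rec,
            cfg.delta_amp,
            cfg.r_max,
            cfg.n_songs,
            song_len,
            cfg.ybar_window,
            cfg.error_norm == "l2",
            kseed,
        )
        M_runs[r] = M0
    return HCPLearningRecord(
        error_t=err.mean(axis=0),
        entropy_t=ent.mean(axis=0),
        M_runs=M_runs,
        config=cfg,
        target=target,
    )
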