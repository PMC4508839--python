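"""First-order Markov chains over discrete states: construction, sampling, entropy.

States are 0-based integers.  A :class:`TransitionMatrix` holds a
row-stochastic matrix ``P`` with ``P[i, j] = P(s_j at t+1 | s_i at t)`` for
the forward kind, or ``P[i, j] = P(s_j at t-1 | s_i at t)`` for the backward
kind.  The two are related by Bayes' rule through the stationary
distribution of the chain.

The generators in this module produce the synthetic target families used
throughout the package: circulant Gaussian matrices whose per-row entropy
is controlled by the Gaussian width, sparse skewed "birdsong-like" matrices
emulating the summary statistics of Bengalese finch song (5-10 syllables,
0.1-2.8 bits of sequence entropy), and mixed matrices alternating
deterministic and entropic rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionMatrix",
    "SequenceTrace",
    "EntropyProfile",
    "row_entropy",
    "mean_entropy",
    "entropy_profile",
    "stationary_distribution",
    "backward_from_forward",
    "sample_sequence",
    "make_gaussian_tm",
    "solve_sigma_for_entropy",
    "make_birdsong_like_tm",
    "make_mixed_tm",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix over discrete states.

    Parameters
    ----------
    P : ndarray of shape (n, n)
        ``P[i, j]`` is the conditional probability of state ``j`` given
        state ``i`` (next state for ``kind='forward'``, previous state for
        ``kind='backward'``).
    kind : {'forward', 'backward'}
    """

    P: np.ndarray
    kind: str = "forward"

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"transition matrix must be square, got shape {P.shape}")
        if self.kind not in ("forward", "backward"):
            raise ValueError(f"kind must be 'forward' or 'backward', got {self.kind!r}")
        if np.any(P < -_ROW_TOL) or np.any(P > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = P.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValueError(f"row {bad} sums to {rowsums[bad]:.12g}, not 1")
        # store an exactly renormalized copy
        object.__setattr__(self, "P", np.clip(P, 0.0, 1.0) / rowsums[:, None])

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    def __eq__(self, other) -> bool:  # dataclass default chokes on arrays
        return (
            isinstance(other, TransitionMatrix)
            and self.kind == other.kind
            and self.P.shape == other.P.shape
            and np.array_equal(self.P, other.P)
        )


@dataclass(frozen=True)
class SequenceTrace:
    """A sampled state sequence together with the seed that produced it."""

    states: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class EntropyProfile:
    """Per-state transition entropies h(s_i) and their arithmetic mean (bits)."""

    per_state: np.ndarray
    mean: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean is None:
            object.__setattr__(self, "mean", float(np.mean(self.per_state)))


def row_entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p log2 p of a probability vector, in bits.

    Zero entries contribute nothing (0 * log 0 = 0 convention).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def mean_entropy(M: np.ndarray, normalize: bool = False) -> float:
    """Mean per-row Shannon entropy of a matrix, in bits.

    With ``normalize=True`` each row is divided by its sum first (rows that
    sum to zero count as zero entropy), so the function can be applied to
    un-normalized weight matrices.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("entries must be non-negative")
    if normalize:
        sums = M.sum(axis=1, keepdims=True)
        M = np.divide(M, sums, out=np.zeros_like(M), where=sums > 0)
    return float(np.mean([row_entropy(row) for row in M]))


def entropy_profile(tm: TransitionMatrix) -> EntropyProfile:
    """Per-state transition entropy of each row of a transition matrix."""
    per_state = np.array([row_entropy(row) for row in tm.P])
    return EntropyProfile(per_state=per_state)


def stationary_distribution(
    tm: TransitionMatrix, max_iter: int = 200_000, tol: float = 1e-13
) -> np.ndarray:
    """Stationary distribution pi with pi @ P = pi, by power iteration.

    Raises
    ------
    ValueError
        If the iteration has not converged after ``max_iter`` sweeps, which
        indicates a reducible or periodic chain without a unique limit.
    """
    P = tm.P
    n = tm.n_states
    pi = np.full(n, 1.0 / n)
    # damping breaks period-2 oscillations of genuinely aperiodic-in-the-limit
    # chains while leaving the fixed point unchanged
    for _ in range(max_iter):
        nxt = 0.5 * (pi + pi @ P)
        if np.abs(nxt - pi).max() < tol:
            pi = nxt
            break
        pi = nxt
    else:
        raise ValueError("stationary distribution did not converge: reducible or periodic chain")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ P - pi).max()
    if resid > 1e-9:
        raise ValueError("stationary distribution did not converge: reducible or periodic chain")
    # uniqueness: a reducible chain has a fixed point from every start, but
    # different corners converge to different limits
    probe = np.full(n, 0.5 / max(n - 1, 1))
    probe[0] = 0.5
    for _ in range(max_iter):
        nxt = 0.5 * (probe + probe @ P)
        if np.abs(nxt - probe).max() < tol:
            break
        probe = nxt
    if np.abs(probe / probe.sum() - pi).max() > 1e-6:
        raise ValueError("stationary distribution is not unique: reducible chain")
    return pi


def backward_from_forward(tm_F: TransitionMatrix) -> TransitionMatrix:
    """Backward conditionals P_B[i, j] = P(s_j at t-1 | s_i at t) via Bayes.

    ``P_B[i, j] = P_F[j, i] * pi_j / pi_i`` where ``pi`` is the stationary
    distribution of the forward chain.
    """
    if tm_F.kind != "forward":
        raise ValueError("input must be a forward transition matrix")
    pi = stationary_distribution(tm_F)
    if np.any(pi <= 1e-12):
        raise ValueError("unreachable state: stationary probability is zero")
    PB = tm_F.P.T * pi[None, :] / pi[:, None]
    return TransitionMatrix(P=PB, kind="backward")


def sample_sequence(
    tm: TransitionMatrix, n_steps: int, seed: int, start: int | None = None
) -> SequenceTrace:
    """Sample a state sequence of length ``n_steps`` from a forward chain.

    The first state is uniform over states unless ``start`` is given; each
    subsequent state is drawn from the current state's row of ``P``.
    """
    if tm.kind != "forward":
        raise ValueError("can only sample from a forward transition matrix")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = tm.n_states
    # inverse-CDF sampling against precomputed row CDFs
    cdf = np.cumsum(tm.P, axis=1)
    cdf[:, -1] = 1.0
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.integers(n) if start is None else int(start)
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t])
    return SequenceTrace(states=states, seed=seed)


def _gaussian_row(n: int, center: int, sigma: float) -> np.ndarray:
    """Discretized Gaussian over columns, centered (circularly) at ``center``."""
    if sigma == 0:
        row = np.zeros(n)
        row[center % n] = 1.0
        return row
    j = np.arange(n)
    d = np.abs(j - center % n)
    d = np.minimum(d, n - d)  # circular distance
    row = np.exp(-0.5 * (d / sigma) ** 2)
    return row / row.sum()


def make_gaussian_tm(n_states: int = 19, sigma: float = 1.0) -> TransitionMatrix:
    """Circulant Gaussian forward matrix: row i peaks at column (i+9) mod n.

    Every state sees the same transition profile shifted by its index, so
    all rows have identical entropy, ranging from 0 bits at ``sigma = 0``
    (a pure permutation) to ``log2(n_states)`` bits as ``sigma`` grows
    (uniform rows).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    P = np.stack([_gaussian_row(n_states, i + 9, sigma) for i in range(n_states)])
    return TransitionMatrix(P=P, kind="forward")


def solve_sigma_for_entropy(
    target_bits: float, n_states: int = 19, tol_bits: float = 1e-3
) -> float:
    """Gaussian width whose circulant matrix has the requested row entropy.

    Bisects the monotone entropy-vs-sigma map.  ``target_bits`` must lie in
    ``[0, log2(n_states)]``; the upper end is only reached asymptotically,
    so targets within ``tol_bits`` of the maximum return a large sigma.
    """
    h_max = np.log2(n_states)
    if not 0 <= target_bits <= h_max:
        raise ValueError(f"infeasible entropy: target must be in [0, {h_max:.4f}] bits")
    if target_bits == 0:
        return 0.0

    def h(sigma: float) -> float:
        return row_entropy(_gaussian_row(n_states, 0, sigma))

    lo, hi = 0.0, 1.0
    while h(hi) < min(target_bits, h_max - tol_bits / 4) and hi < 1e6:
        hi *= 2.0
    if h(hi) < target_bits - tol_bits:
        return hi  # asymptotically uniform
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) < target_bits:
            lo = mid
        else:
            hi = mid
        if abs(h(mid) - target_bits) < tol_bits / 10:
            return mid
    return 0.5 * (lo + hi)


def make_mixed_tm(sigma_high: float, n_states: int = 19) -> TransitionMatrix:
    """Matrix alternating deterministic rows (even index) with Gaussian rows.

    Even-indexed rows are the sigma = 0 deterministic rows; odd-indexed rows
    are Gaussian with width ``sigma_high``.  All rows peak at (i+9) mod n.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    P = np.stack(
        [
            _gaussian_row(n_states, i + 9, 0.0 if i % 2 == 0 else sigma_high)
            for i in range(n_states)
        ]
    )
    return TransitionMatrix(P=P, kind="forward")


def make_birdsong_like_tm(
    n_syllables: int, target_mean_entropy: float, seed: int
) -> TransitionMatrix:
    """Sparse, skewed synthetic transition matrix with a set mean row entropy.

    Emulates the published summary statistics of Bengalese finch song
    transition matrices (the matrices themselves are unpublished): each
    syllable transitions to a small set of successors (1-4 where the
    entropy target allows) with skewed probabilities.  Rows are Dirichlet
    draws on a random sparsity mask, tempered by a common exponent that is
    bisected so the mean per-row entropy lands within 0.1 bits of
    ``target_mean_entropy``.  Fully reproducible from ``seed``.
    """
    n = int(n_syllables)
    if n < 2:
        raise ValueError("need at least 2 syllables")
    h_max = np.log2(n)
    if not 0 <= target_mean_entropy <= h_max:
        raise ValueError(f"infeasible entropy: target must be in [0, {h_max:.4f}] bits")
    rng = np.random.default_rng(seed)

    # successor counts: 1-4 per syllable, bumped up if the target demands more
    k = rng.integers(1, 5, size=n)
    while np.mean(np.log2(k)) < target_mean_entropy and np.any(k < n):
        k[np.argmin(k)] += 1

    succ = [rng.choice(n, size=k[i], replace=False) for i in range(n)]
    base = [rng.dirichlet(np.ones(k[i])) for i in range(n)]

    def build(gamma: float) -> np.ndarray:
        P = np.zeros((n, n))
        for i in range(n):
            w = np.maximum(base[i], 1e-300) ** gamma
            P[i, succ[i]] = w / w.sum()
        return P

    def h(gamma: float) -> float:
        return mean_entropy(build(gamma))

    # entropy decreases monotonically in the tempering exponent gamma:
    # gamma -> 0 gives uniform rows over the mask, gamma -> inf deterministic
    if target_mean_entropy <= 0:
        P = np.zeros((n, n))
        for i in range(n):
            P[i, succ[i][np.argmax(base[i])]] = 1.0
        return TransitionMatrix(P=P, kind="forward")
    lo, hi = 1e-6, 1.0
    while h(hi) > target_mean_entropy and hi < 1e4:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) > target_mean_entropy:
            lo = mid
        else:
            hi = mid
        if abs(h(mid) - target_mean_entropy) < 1e-3:
            break
    return TransitionMatrix(P=build(0.5 * (lo + hi)), kind="forward")
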