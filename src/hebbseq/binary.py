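"""Correlation-based Hebbian learning in binary feed-forward networks.

The analytic backbone of the package.  A single binary output unit y
receives weights m_j from binary inputs x_j (post-synaptic competition
case), or a single input fans out onto outputs y_i (pre-synaptic
competition case).  The update

    dm_j  ~  x_j * y  -  (sum_k x_k * y) * m_j

is Hebbian correlation with a decay whose coefficient is the summed
input-output correlation; the decay induces heterosynaptic competition.
Its steady state is the Bayes conditional: m_j -> P(x_j | y) with
post-synaptic competition, and m_i -> P(y_i | x) with pre-synaptic
competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinaryEnsemble",
    "binary_update",
    "binary_steady_state",
    "simulate_binary_learning",
    "BinaryLearningRecord",
]


@dataclass(frozen=True)
class BinaryEnsemble:
    """Joint activation statistics of a binary feed-forward ensemble.

    ``p_pair[j]`` is the probability that array unit j is co-active with
    the singleton unit in one plasticity window: P(x_j = 1, y = 1) for
    ``site='post'`` (many inputs, one output) or P(y_j = 1, x = 1) for
    ``site='pre'`` (one input, many outputs).  Entries must be
    non-negative and sum to at most 1; the deficit is the probability that
    nothing happens in the window.
    """

    p_pair: np.ndarray
    site: str = "post"

    def __post_init__(self) -> None:
        p = np.asarray(self.p_pair, dtype=float)
        if np.any(p < 0) or p.sum() > 1 + 1e-9:
            raise ValueError("p_pair entries must be >= 0 and sum to <= 1")
        if self.site not in ("pre", "post"):
            raise ValueError("site must be 'pre' or 'post'")
        object.__setattr__(self, "p_pair", p)

    @property
    def n(self) -> int:
        return len(self.p_pair)


def binary_update(m: np.ndarray, x: np.ndarray, y: int, lr: float) -> np.ndarray:
    """One correlation-learning step; returns the new weight vector.

    For the pre-competition variant pass the array-unit activities as ``x``
    and the singleton activity as ``y`` — the rule is symmetric under that
    exchange.  Weights are clipped at 0 (large learning rates can push a
    weight transiently negative).
    """
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    dm = lr * (x * y - (x * y).sum() * m)
    return np.clip(m + dm, 0.0, None)


def binary_steady_state(ensemble: BinaryEnsemble) -> np.ndarray:
    """Closed-form steady state of the correlation rule: Bayes conditionals.

    Returns P(x_j | y) for post-synaptic competition (equivalently
    P(y_j | x) for pre-synaptic competition): the joint pairing
    probabilities normalized by their sum.
    """
    total = ensemble.p_pair.sum()
    if total <= 0:
        raise ValueError("all pairing probabilities are zero")
    return ensemble.p_pair / total


@dataclass(frozen=True)
class BinaryLearningRecord:
    """Weight trajectory and L1 distance to the analytic steady state."""

    weights: np.ndarray  # (n_steps + 1, n)
    error: np.ndarray  # (n_steps + 1,)
    seed: int

    @property
    def final_weights(self) -> np.ndarray:
        return self.weights[-1]

    def steady_weights(self, frac: float = 0.2) -> np.ndarray:
        """Trailing time average of the weight trajectory.

        At equilibrium the weights fluctuate around the Bayes steady state
        on a scale ~sqrt(lr); averaging the last ``frac`` of the recorded
        trajectory shrinks that Monte-Carlo noise by the square root of
        the number of effectively independent samples.
        """
        k = max(1, int(frac * len(self.weights)))
        return self.weights[-k:].mean(axis=0)


def simulate_binary_learning(
    ensemble: BinaryEnsemble,
    n_steps: int,
    lr: float = 0.005,
    seed: int = 0,
    m0: np.ndarray | None = None,
    record_every: int = 1,
) -> BinaryLearningRecord:
    """Monte-Carlo simulation of the binary correlation rule.

    Each step draws at most one co-activation event from ``p_pair`` (with
    probability ``1 - sum(p_pair)`` the window is silent and no update
    occurs) and applies :func:`binary_update`.  Weights start uniform at
    1/n unless ``m0`` is given.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = ensemble.n
    m = np.full(n, 1.0 / n) if m0 is None else np.asarray(m0, dtype=float).copy()
    target = binary_steady_state(ensemble)

    n_rec = n_steps // record_every + 1
    weights = np.empty((n_rec, n))
    error = np.empty(n_rec)
    weights[0], error[0] = m, np.abs(m - target).mean()

    # event index per step: n means "silent window"
    probs = np.append(ensemble.p_pair, 1.0 - ensemble.p_pair.sum())
    events = rng.choice(n + 1, size=n_steps, p=np.clip(probs, 0, None) / probs.sum())
    x = np.zeros(n)
    k = 1
    for t, ev in enumerate(events, start=1):
        if ev < n:
            x[:] = 0.0
            x[ev] = 1.0
            m = binary_update(m, x, 1, lr)
        if t % record_every == 0:
            weights[k], error[k] = m, np.abs(m - target).mean()
            k += 1
    return BinaryLearningRecord(weights=weights[:k], error=error[:k], seed=seed)
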