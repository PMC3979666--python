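"""Two-state hidden Markov machinery.

Both decoding rounds of the pipeline share this engine: the caller supplies a
per-position table of emission log-likelihoods (one column per state), a 2x2
transition matrix and an initial distribution; the engine returns either the
Viterbi path or per-position posterior marginals from the forward-backward
recursion.  Everything is computed in log space so that long sequences and
extreme emissions (including exact zeros, passed as -inf) are handled without
underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["build_transition", "stationary_distribution", "viterbi", "posterior"]


class DecodingError(ValueError):
    """Raised when a position has zero likelihood under every state."""


def _validate(loglik: np.ndarray, transition: np.ndarray, initial: np.ndarray):
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[1] != 2:
        raise ValueError(f"emission table must have shape (T, 2), got {loglik.shape}")
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (2, 2):
        raise ValueError("transition matrix must be 2x2")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1")
    if np.any(transition < 0) or np.any(transition > 1):
        raise ValueError("transition probabilities must lie in [0, 1]")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (2,) or not np.isclose(initial.sum(), 1.0, atol=1e-12):
        raise ValueError("initial distribution must be a length-2 simplex vector")
    bad = np.all(np.isneginf(loglik), axis=1)
    if bad.any():
        raise DecodingError(
            f"all-states-impossible emission at position {int(np.flatnonzero(bad)[0])}"
        )
    return loglik, transition, initial


def build_transition(weight: float, persistence: float = 0.5) -> np.ndarray:
    """Transition matrix whose stationary state-1 mass equals ``weight``.

    ``pi_01 = weight * (1 - persistence)`` and ``pi_10 = (1 - weight) *
    (1 - persistence)``, so the chain's stationary distribution is
    ``(1 - weight, weight)`` for any persistence in [0, 1).  Larger
    persistence makes runs of either state stickier without changing the
    marginal fraction of state-1 positions.
    """
    if not 0.0 < weight < 1.0:
        raise ValueError("weight must lie strictly in (0, 1)")
    if not 0.0 <= persistence < 1.0:
        raise ValueError("persistence must lie in [0, 1)")
    p01 = weight * (1.0 - persistence)
    p10 = (1.0 - weight) * (1.0 - persistence)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 2x2 stochastic matrix."""
    transition = np.asarray(transition, dtype=float)
    p01, p10 = transition[0, 1], transition[1, 0]
    total = p01 + p10
    if total == 0.0:  # reducible chain: fall back to uniform
        return np.array([0.5, 0.5])
    return np.array([p10 / total, p01 / total])


def viterbi(
    loglik: np.ndarray, transition: np.ndarray, initial: np.ndarray | None = None
) -> np.ndarray:
    """Maximum a posteriori state path; ties resolve toward state 0.

    Parameters
    ----------
    loglik
        (T, 2) array of emission log-likelihoods per position and state.
    transition
        2x2 row-stochastic matrix.
    initial
        Initial state distribution; defaults to the stationary distribution
        of ``transition``.
    """
    if initial is None:
        initial = stationary_distribution(transition)
    loglik, transition, initial = _validate(loglik, transition, initial)
    T = loglik.shape[0]
    with np.errstate(divide="ignore"):
        log_trans = np.log(transition)
        log_init = np.log(initial)

    delta = log_init + loglik[0]
    back = np.zeros((T, 2), dtype=np.int8)
    for t in range(1, T):
        # cand[i, j] = score of being in i at t-1 then j at t
        cand = delta[:, None] + log_trans
        # argmax over predecessor i; np.argmax takes the first (state 0) on ties
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + loglik[t]

    path = np.zeros(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))  # first index on ties -> state 0
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def posterior(
    loglik: np.ndarray, transition: np.ndarray, initial: np.ndarray | None = None
) -> np.ndarray:
    """Per-position posterior P(state = 1 | whole observation sequence).

    Log-space forward-backward.  The returned marginals satisfy
    P(S=0) + P(S=1) = 1 at every position to within 1e-10.
    """
    if initial is None:
        initial = stationary_distribution(transition)
    loglik, transition, initial = _validate(loglik, transition, initial)
    T = loglik.shape[0]
    with np.errstate(divide="ignore"):
        log_trans = np.log(transition)
        log_init = np.log(initial)

    fwd = np.empty((T, 2))
    fwd[0] = log_init + loglik[0]
    for t in range(1, T):
        fwd[t] = logsumexp(fwd[t - 1][:, None] + log_trans, axis=0) + loglik[t]

    bwd = np.empty((T, 2))
    bwd[-1] = 0.0
    for t in range(T - 2, -1, -1):
        bwd[t] = logsumexp(log_trans + loglik[t + 1] + bwd[t + 1], axis=1)

    joint = fwd + bwd
    joint -= logsumexp(joint, axis=1, keepdims=True)
    return np.exp(joint[:, 1])
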