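"""Independent reference implementations used only as test oracles.

Deliberately naive: brute-force path enumeration for the two-state HMM,
EM fits for the Poisson mixture and the zero-inflated binomial, and a
direct CIGAR interpreter.  None of these share code with the package
implementations they check.
"""

from itertools import product

import numpy as np
from scipy import stats


def brute_force_paths(loglik, transition, initial):
    """Log-probability of every state path of a two-state chain."""
    T = len(loglik)
    with np.errstate(divide="ignore"):
        lt = np.log(transition)
        li = np.log(initial)
    scores = {}
    for path in product((0, 1), repeat=T):
        s = li[path[0]] + loglik[0][path[0]]
        for t in range(1, T):
            s += lt[path[t - 1]][path[t]] + loglik[t][path[t]]
        scores[path] = s
    return scores


def brute_force_viterbi(loglik, transition, initial):
    scores = brute_force_paths(loglik, transition, initial)
    # ties resolve toward the lexicographically smallest path (state 0 first)
    best = max(sorted(scores), key=lambda p: (scores[p], tuple(-x for x in p)))
    return np.array(best)


def brute_force_posterior(loglik, transition, initial):
    scores = brute_force_paths(loglik, transition, initial)
    T = len(loglik)
    logs = np.array(list(scores.values()))
    total = np.logaddexp.reduce(logs)
    post = np.zeros(T)
    for path, s in scores.items():
        w = np.exp(s - total)
        for t, state in enumerate(path):
            if state == 1:
                post[t] += w
    return post


def poisson_mixture_em(y, n_iter=500, tol=1e-10, init=(0.5, 5.0, 0.2)):
    """Plain EM for a two-component Poisson mixture; returns (l0, l1, w)."""
    y = np.asarray(y, dtype=float)
    l0, l1, w = init
    ll_old = -np.inf
    for _ in range(n_iter):
        log_r1 = np.log(w) + stats.poisson.logpmf(y, l1)
        log_r0 = np.log1p(-w) + stats.poisson.logpmf(y, l0)
        norm = np.logaddexp(log_r0, log_r1)
        r1 = np.exp(log_r1 - norm)
        w = r1.mean()
        l1 = (r1 * y).sum() / r1.sum()
        l0 = ((1 - r1) * y).sum() / (1 - r1).sum()
        ll = norm.sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    if l0 > l1:
        l0, l1, w = l1, l0, 1 - w
    return l0, l1, w


def zib_em(m, x, n_iter=2000, tol=1e-12, init=(0.02, 0.3)):
    """EM for a zero-inflated binomial with heterogeneous sizes.

    Latent indicator: structural zero vs binomial draw; returns (p, phi).
    """
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    p, phi = init
    ll_old = -np.inf
    for _ in range(n_iter):
        binom_zero = (1 - p) ** x
        denom = phi + (1 - phi) * binom_zero
        z = np.where(m == 0, phi / denom, 0.0)  # P(structural zero | data)
        phi = z.mean()
        weight = 1 - z
        p = (weight * m).sum() / (weight * x).sum()
        ll = np.where(
            m == 0,
            np.log(phi + (1 - phi) * binom_zero),
            np.log1p(-phi) + stats.binom.logpmf(m, x, p),
        ).sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return p, phi


def cigar_deletion_positions(start, cigar_ops):
    """Reference positions consumed by D operations, via a direct walk.

    ``cigar_ops`` is a list of (op_char, length) with SAM semantics.
    """
    consume_ref = {"M": True, "=": True, "X": True, "D": True, "N": True,
                   "I": False, "S": False, "H": False, "P": False}
    pos = start
    dels = []
    for op, length in cigar_ops:
        if op == "D":
            dels.extend(range(pos, pos + length))
        if consume_ref[op]:
            pos += length
    return dels


def pileup_depths(intervals):
    """Per-base depth dict from (start, end) intervals — sweep oracle."""
    depth = {}
    for s, e in intervals:
        for b in range(s, e):
            depth[b] = depth.get(b, 0) + 1
    return depth
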