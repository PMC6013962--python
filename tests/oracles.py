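"""Independent brute-force oracles used to check the implementation.

Everything here is computed by enumeration or generic root finding,
deliberately sharing no code with the package's estimation routines.
"""

import itertools

import numpy as np


def esf_enumerate(eps, r):
    """gamma_r by explicit enumeration of all size-r subsets."""
    eps = list(eps)
    return sum(np.prod([eps[i] for i in combo])
               for combo in itertools.combinations(range(len(eps)), r)) if r else 1.0


def conditional_loglik_enum(Y, beta):
    """Conditional log-likelihood via subset-enumeration normalizers."""
    Y = np.asarray(Y)
    eps = np.exp(-np.asarray(beta, float))
    total = 0.0
    for row in Y:
        r = int(row.sum())
        if r == 0 or r == len(row):
            continue
        total += float(-(row @ beta)) - np.log(esf_enumerate(eps, r))
    return total


def pattern_probability_enum(pattern, beta):
    """P(pattern | raw score) by enumerating all patterns with that score."""
    pattern = np.asarray(pattern)
    beta = np.asarray(beta, float)
    I = len(pattern)
    r = int(pattern.sum())
    num = np.exp(-float(pattern @ beta))
    den = sum(
        np.exp(-sum(beta[i] for i in combo))
        for combo in itertools.combinations(range(I), r)
    )
    return num / den


def grid_argmax_cml(Y, n_free, span=4.0, steps=(0.05, 0.005, 0.001)):
    """Anchored CML estimate by refined dense grid search.

    Free parameters are the item values with item 0 fixed at 0; the grid
    is refined around the running argmax down to the final step size.
    Only feasible for n_free <= 2.
    """
    Y = np.asarray(Y)
    I = Y.shape[1]
    assert n_free == I - 1 and n_free in (1, 2)

    def logcl(free):
        beta = np.concatenate(([0.0], free))
        return conditional_loglik_enum(Y, beta)

    center = np.zeros(n_free)
    width = span
    for step in steps:
        axes = [np.arange(c - width, c + width + step / 2, step) for c in center]
        best, best_val = None, -np.inf
        for combo in itertools.product(*axes):
            val = logcl(np.array(combo))
            if val > best_val:
                best, best_val = np.array(combo), val
        center = best
        width = 2.5 * step
    return np.concatenate(([0.0], center))


def grid_argmax_lltm(Y, W, span=4.0, steps=(0.05, 0.005, 0.001)):
    """Attribute-weight estimate by refined dense 2-d grid search."""
    Y = np.asarray(Y)
    W = np.asarray(W, float)
    K = W.shape[1]
    assert K == 2

    def logcl(alpha):
        return conditional_loglik_enum(Y, W @ alpha)

    center = np.zeros(K)
    width = span
    for step in steps:
        axes = [np.arange(c - width, c + width + step / 2, step) for c in center]
        best, best_val = None, -np.inf
        for combo in itertools.product(*axes):
            val = logcl(np.array(combo))
            if val > best_val:
                best, best_val = np.array(combo), val
        center = best
        width = 2.5 * step
    return center


def bisect_person(R, beta, lo=-10.0, hi=10.0, tol=1e-10):
    """Root of R - sum_i expit(theta - beta_i) by plain bisection."""
    beta = np.asarray(beta, float)

    def f(t):
        return R - np.sum(1.0 / (1.0 + np.exp(-(t - beta))))

    a, b = lo, hi
    fa = f(a)
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = f(m)
        if abs(b - a) < tol:
            break
        if (fa < 0) == (fm < 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


def brute_force_well_conditioned(Y):
    """Partition condition by enumerating all ordered bipartitions."""
    Y = np.asarray(Y)
    I = Y.shape[1]
    idx = set(range(I))
    for size in range(1, I):
        for A in itertools.combinations(range(I), size):
            B = tuple(sorted(idx - set(A)))
            # need some person with a 1 in A and a 0 in B
            hit = any(
                (row[list(A)] == 1).any() and (row[list(B)] == 0).any()
                for row in Y
            )
            if not hit:
                return False
    return True
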