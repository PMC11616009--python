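"""Independent brute-force reference implementations used by the tests.

These are deliberately written as plain double loops over the defining
formulas, independent of the package's vectorised code paths.
"""

import math

import numpy as np


def brute_nt_xent_directed(Z, i, j, tau):
    """l(i, j) by direct summation of the defining fraction."""
    def sim(u, v):
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    numer = math.exp(sim(Z[i], Z[j]) / tau)
    denom = 0.0
    for k in range(Z.shape[0]):
        if k == i:
            continue
        denom += math.exp(sim(Z[i], Z[k]) / tau)
    return -math.log(numer / denom)


def brute_nt_xent_batch(Z, pairing, tau):
    """Mean of both directed losses over all positive pairs."""
    terms = []
    for i, j in pairing:
        terms.append(brute_nt_xent_directed(Z, i, j, tau))
        terms.append(brute_nt_xent_directed(Z, j, i, tau))
    return sum(terms) / len(terms)


def brute_alignment(E1, E2, normalize=True):
    """Mean squared pair distance by an explicit loop."""
    a = np.array(E1, dtype=float)
    b = np.array(E2, dtype=float)
    if normalize:
        a = np.array([r / np.linalg.norm(r) for r in a])
        b = np.array([r / np.linalg.norm(r) for r in b])
    total = 0.0
    for r1, r2 in zip(a, b):
        total += float(np.sum((r1 - r2) ** 2))
    return total / a.shape[0]


def brute_uniformity(E, t=2.0, normalize=True):
    """log mean Gaussian potential by an explicit double loop."""
    X = np.array(E, dtype=float)
    if normalize:
        X = np.array([r / np.linalg.norm(r) for r in X])
    n = X.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            vals.append(math.exp(-t * float(np.sum((X[i] - X[j]) ** 2))))
    return math.log(sum(vals) / len(vals))
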