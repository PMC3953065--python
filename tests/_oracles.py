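"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def brute_force_pair_marginal(z: np.ndarray) -> np.ndarray:
    """P(first two ranks are (j,k)) by enumerating all n! permutations.

    Plackett–Luce: a permutation's probability is the product of sequential
    softmax choices; the (j,k) marginal sums over permutations starting j,k.
    """
    e = np.exp(z - z.max())
    n = len(z)
    P = np.zeros((n, n))
    for perm in itertools.permutations(range(n)):
        p = 1.0
        rem = e.sum()
        for idx in perm:
            p *= e[idx] / rem
            rem -= e[idx]
        P[perm[0], perm[1]] += p
    return P
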