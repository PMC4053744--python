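"""Independent oracles used by the test suite.

Everything here is written from first principles (brute force, enumeration,
closed forms) and deliberately does not call the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from coevnet.alphabet import AMINO_ACIDS, N_SYMBOLS

A_IDX = AMINO_ACIDS.index("A")
V_IDX = AMINO_ACIDS.index("V")


def brute_force_mi(x, y, pseudocount: float, n_symbols: int = N_SYMBOLS) -> float:
    """MI in bits by the explicit double sum over the pseudocounted joint."""
    joint = np.full((n_symbols, n_symbols), float(pseudocount))
    for a, b in zip(x, y):
        joint[a, b] += 1.0
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    total = 0.0
    for a in range(n_symbols):
        for b in range(n_symbols):
            if joint[a, b] > 0:
                total += joint[a, b] * math.log2(joint[a, b] / (px[a] * py[b]))
    return total


def all_spanning_trees(n_nodes: int):
    """Yield every spanning tree (as a frozenset of index edges) on n nodes."""
    edges = list(itertools.combinations(range(n_nodes), 2))
    for subset in itertools.combinations(edges, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[rv] = ru
        if ok:
            yield frozenset(subset)


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher exact p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(p for p in (prob(k) for k in range(lo, hi + 1)) if p <= p_obs * (1 + 1e-12))


# ---------------------------------------------------------------------------
# exact 16-state chain enumeration for the two-column toy family
# ---------------------------------------------------------------------------


def toy_states():
    """All (a1, a2, b1, b2) states over the {A, V} sub-alphabet."""
    return list(itertools.product([A_IDX, V_IDX], repeat=4))


def toy_transition_matrix(
    score_a: np.ndarray,
    score_b: np.ndarray,
    cond_ba: np.ndarray,
    cond_ab: np.ndarray,
    sub: np.ndarray,
    temperature: float,
) -> np.ndarray:
    """Exact Metropolis–Hastings transition matrix of the toy sampler.

    The toy family has two columns per protein, one contact (column 1 of A
    with column 1 of B) and one non-contact column per protein; at every step
    the contact is resampled on one coin-chosen side and both non-contact
    columns are resampled from the substitution conditional.
    """
    states = toy_states()
    index = {s: k for k, s in enumerate(states)}
    symbols = [A_IDX, V_IDX]

    def fitness(s):
        a1, a2, b1, b2 = s
        return score_a[0, a1] + score_a[1, a2] + score_b[0, b1] + score_b[1, b2]

    P = np.zeros((16, 16))
    for x in states:
        a1, a2, b1, b2 = x
        fx = fitness(x)
        for fix_a in (True, False):
            for new_c in symbols:  # resampled contact side
                for new_a2 in symbols:
                    for new_b2 in symbols:
                        if fix_a:
                            y = (a1, new_a2, new_c, new_b2)
                            q_c = cond_ba[a1, new_c]
                            log_h_c = math.log(cond_ba[a1, b1]) - math.log(q_c)
                        else:
                            y = (new_c, new_a2, b1, new_b2)
                            q_c = cond_ab[b1, new_c]
                            log_h_c = math.log(cond_ab[b1, a1]) - math.log(q_c)
                        q = 0.5 * q_c * sub[a2, new_a2] * sub[b2, new_b2]
                        log_h = (
                            log_h_c
                            + math.log(sub[new_a2, a2]) - math.log(sub[a2, new_a2])
                            + math.log(sub[new_b2, b2]) - math.log(sub[b2, new_b2])
                        )
                        alpha = min(1.0, math.exp((fitness(y) - fx) / temperature + log_h))
                        P[index[x], index[y]] += q * alpha
        P[index[x], index[x]] += 1.0 - P[index[x]].sum()
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left eigenvector of P for eigenvalue 1, normalized to a distribution."""
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()
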