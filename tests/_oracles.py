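"""Independent brute-force oracles used to validate the package.

These deliberately re-derive results by exhaustive enumeration with plain
loops; they share no code with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def afc(a: float, b: float) -> float:
    return a / b if a >= b else b / a


def brute_force_classify(values, threshold_pairs):
    """Exhaustive search over every ordered pair of distinct observed values
    and every (f, n) threshold pair.

    Score of a candidate (a, b): quadratic data coverage with the two
    representative-centrality penalties dividing one coverage factor, times
    the size-balance term 4|A||B|/(|A|+|B|)^2; zero unless afc(a, b) > f.
    Ties: larger coverage, then smaller (a, b), earlier threshold pair.
    Returns (best_score, chosen_pair, states) with states over {L, M, H}.
    """
    e = np.exp(np.asarray(values, dtype=float))
    m = len(e)
    distinct = np.unique(e)

    best_score = 0.0
    best_cov = -1
    best_ab = None
    best_sets = None
    best_pair = None

    for pair in threshold_pairs:
        f, n = pair
        for ai in range(len(distinct)):
            a = float(distinct[ai])
            for bi in range(ai + 1, len(distinct)):
                b = float(distinct[bi])
                if afc(a, b) <= f:
                    continue
                set_a = [j for j in range(m) if afc(float(e[j]), a) <= n]
                set_b = [j for j in range(m) if afc(float(e[j]), b) <= n]
                na, nb = len(set_a), len(set_b)
                cov = len(set(set_a) | set(set_b))
                pa = afc(a, float(np.asarray([e[j] for j in set_a]).sum()) / na)
                pb = afc(b, float(np.asarray([e[j] for j in set_b]).sum()) / nb)
                balance = 4 * na * nb / (na + nb) ** 2
                score = (cov / m) * (cov / (pa * pb)) * balance
                if score > best_score or (
                    score == best_score
                    and (cov > best_cov or (cov == best_cov and (best_ab is None or (a, b) < best_ab)))
                ):
                    best_score = score
                    best_cov = cov
                    best_ab = (a, b)
                    best_sets = (set_a, set_b)
                    best_pair = pair

    if best_ab is None:
        return 0.0, None, ["M"] * m

    set_a, set_b = best_sets
    b1 = max(float(e[j]) for j in set_a)
    b2 = min(float(e[j]) for j in set_b)
    if b1 > b2:
        b1, b2 = b2, b1
    states = []
    for j in range(m):
        if e[j] <= b1:
            states.append("L")
        elif e[j] >= b2:
            states.append("H")
        else:
            states.append("M")
    return best_score, best_pair, states


def pair_counting_jaccard(partition_p, partition_q):
    """Jaccard agreement by literal enumeration of all unordered pairs."""
    label_p = {}
    for k, block in enumerate(partition_p):
        for i in block:
            label_p[i] = k
    label_q = {}
    for k, block in enumerate(partition_q):
        for i in block:
            label_q[i] = k
    items = sorted(label_p)
    assert sorted(label_q) == items
    n11 = n10 = n01 = 0
    for x in range(len(items)):
        for y in range(x + 1, len(items)):
            i, j = items[x], items[y]
            same_p = label_p[i] == label_p[j]
            same_q = label_q[i] == label_q[j]
            if same_p and same_q:
                n11 += 1
            elif same_p:
                n10 += 1
            elif same_q:
                n01 += 1
    denom = n11 + n10 + n01
    return n11 / denom if denom else 0.0
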