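"""Independent brute-force oracles shared by the acceptance tests."""

import numpy as np


def _cos(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def oracle_info_nce_loop(za, zb, temperature=1.0):
    """Literal-equation InfoNCE by explicit loops: the denominator sums
    over cross-patient pairs only."""
    n = len(za)
    out = []
    for i in range(n):
        num = np.exp(_cos(za[i], zb[i]) / temperature)
        denom = sum(np.exp(_cos(za[i], zb[j]) / temperature)
                    for j in range(n) if j != i)
        out.append(-np.log(num / denom))
    return np.array(out)


def pairwise_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_u(s1, s2):
    return sum(1.0 if x > y else (0.5 if x == y else 0.0)
               for x in s1 for y in s2)
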