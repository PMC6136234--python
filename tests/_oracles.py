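"""Independent brute-force oracles kept free of the implementation paths."""

import numpy as np


def sampen_bruteforce(values, m, r):
    """O(N^2) double-loop count of SampEn template matches.

    Returns the ordered-pair counts (A, B): B matches of length m, A of
    length m+1, template starts 0..N-m-1 for both, self-matches excluded,
    Chebyshev distance.
    """
    x = list(map(float, values))
    n = len(x)
    n_tpl = n - m
    a = 0
    b = 0
    for i in range(n_tpl):
        for j in range(n_tpl):
            if i == j:
                continue
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def fluctuation_naive(y, n):
    """Per-box np.polyfit detrending, the slow reference for DFA F(n)."""
    y = np.asarray(y, dtype=float)
    n_boxes = len(y) // n
    t = np.arange(n, dtype=float)
    sq = 0.0
    for b in range(n_boxes):
        box = y[b * n : (b + 1) * n]
        coef = np.polyfit(t, box, 1)
        resid = box - np.polyval(coef, t)
        sq += float((resid**2).sum())
    return np.sqrt(sq / (n_boxes * n))


def holm_by_hand(p_values):
    """Textbook Holm step-down adjustment."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    k = len(p)
    adj_sorted = np.maximum.accumulate(
        [min(1.0, (k - i) * p[order[i]]) for i in range(k)]
    )
    out = np.empty(k)
    out[order] = adj_sorted
    return out
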