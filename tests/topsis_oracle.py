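"""Naive reference implementation of entropy weighting and TOPSIS.

Written independently of the package's vectorized code path, with explicit
Python loops following the textbook step-by-step recipe. Used only as a
cross-check oracle in tests; intentionally slow and simple.
"""

import math


def oracle_entropy_weights(rows):
    """rows: list of lists (strains x indicators), strictly positive.

    Returns (ej, dj, wj) lists per indicator.
    """
    n = len(rows)
    p = len(rows[0])
    ej = []
    for j in range(p):
        col = [rows[i][j] for i in range(n)]
        total = sum(col)
        h = 0.0
        for v in col:
            pij = v / total
            if pij > 0:
                h += pij * math.log(pij)
        ej.append(-h / math.log(n))
    dj = [1.0 - e for e in ej]
    dtot = sum(dj)
    wj = [d / dtot for d in dj]
    return ej, dj, wj


def oracle_topsis(rows, weights, benefit):
    """Step-by-step TOPSIS.

    rows: strains x indicators; weights: per indicator; benefit: list of
    bools. Returns (d_plus, d_minus, ci) lists per strain.
    """
    n = len(rows)
    p = len(rows[0])
    # vector normalization
    norms = [math.sqrt(sum(rows[i][j] ** 2 for i in range(n))) for j in range(p)]
    v = [[weights[j] * rows[i][j] / norms[j] for j in range(p)] for i in range(n)]
    best, worst = [], []
    for j in range(p):
        col = [v[i][j] for i in range(n)]
        if benefit[j]:
            best.append(max(col))
            worst.append(min(col))
        else:
            best.append(min(col))
            worst.append(max(col))
    d_plus, d_minus, ci = [], [], []
    for i in range(n):
        dp = math.sqrt(sum((v[i][j] - best[j]) ** 2 for j in range(p)))
        dm = math.sqrt(sum((v[i][j] - worst[j]) ** 2 for j in range(p)))
        d_plus.append(dp)
        d_minus.append(dm)
        ci.append(0.5 if dp + dm == 0 else dm / (dp + dm))
    return d_plus, d_minus, ci


def oracle_pipeline(rows, benefit=None):
    """Entropy weights then TOPSIS, end to end."""
    if benefit is None:
        benefit = [True] * len(rows[0])
    _, _, wj = oracle_entropy_weights(rows)
    return oracle_topsis(rows, wj, benefit)
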