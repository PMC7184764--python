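"""Independent brute-force oracles for the entropy estimators and the
channel AUC.  Everything here is a naive O(n^2) pure-Python/NumPy
transliteration of the defining formulas, written separately from (and
before) the package implementations they check."""

import math

import numpy as np


def _dist_cheb(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def ape_oracle(x, d=2, r=None):
    """Approximate entropy via the double-loop definition (self-matches in)."""
    x = list(map(float, x))
    L = len(x)
    if r is None:
        r = 0.2 * float(np.std(x))
    phis = []
    for m in (d, d + 1):
        nt = L - m + 1
        templates = [x[i : i + m] for i in range(nt)]
        logs = []
        for i in range(nt):
            c = sum(1 for j in range(nt) if _dist_cheb(templates[i], templates[j]) <= r)
            logs.append(math.log(c / nt))
        phis.append(sum(logs) / nt)
    return phis[0] - phis[1]


def sampen_oracle(x, d=2, r=None):
    """Sample entropy: -ln(A/B), both sums over the first L-d templates,
    self-matches excluded.  Returns None when A or B is zero."""
    x = list(map(float, x))
    L = len(x)
    if r is None:
        r = 0.2 * float(np.std(x))
    nt = L - d
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if _dist_cheb(x[i : i + d], x[j : j + d]) <= r:
                b += 1
            if _dist_cheb(x[i : i + d + 1], x[j : j + d + 1]) <= r:
                a += 1
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def pe_oracle(x, d=3, tau=1):
    """Permutation entropy by explicit pattern counting (base 2)."""
    x = list(map(float, x))
    n_vec = len(x) - (d - 1) * tau
    counts = {}
    for i in range(n_vec):
        window = [x[i + k * tau] for k in range(d)]
        # stable rank pattern: ties broken by position
        pattern = tuple(sorted(range(d), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_vec
        h -= p * math.log2(p)
    return h


def spectral_probs_oracle(x):
    """One-sided periodogram probabilities, DC excluded, by explicit DFT."""
    x = np.asarray(x, dtype=float)
    L = len(x)
    n_bins = L // 2 + 1
    P = []
    for f in range(1, n_bins):
        re = sum(x[t] * math.cos(2 * math.pi * f * t / L) for t in range(L))
        im = sum(-x[t] * math.sin(2 * math.pi * f * t / L) for t in range(L))
        P.append(re * re + im * im)
    P = np.array(P)
    return P / P.sum()


def shannon_oracle(p):
    return -sum(v * math.log(v) for v in p if v > 0)


def renyi_oracle(p, alpha=2.0):
    return math.log(sum(v**alpha for v in p)) / (1 - alpha)


def tsallis_oracle(p, q=2.0):
    return (1 - sum(v**q for v in p)) / (q - 1)


def mann_whitney_auc_oracle(pos_scores, neg_scores):
    """Pairwise-comparison AUC with half credit for ties."""
    wins = 0.0
    for a in pos_scores:
        for b in neg_scores:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
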