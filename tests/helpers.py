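"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the package's own implementation paths.
"""

import itertools

import numpy as np
from scipy import stats


def rank_sum_exact_oracle(a, b) -> float:
    """Two-sided exact Mann-Whitney p by exhaustive rank assignment."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = n1 * n2 / 2
    extreme = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = sum(r + 1 for r in comb) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
    return extreme / total


def second_order_bruteforce(p: np.ndarray) -> np.ndarray:
    """Triple loop over (i, m, j), excluding m in {i, j}."""
    n = p.shape[0]
    out = p.copy()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = p[i, j]
            for m in range(n):
                if m in (i, j):
                    continue
                prod = p[i, m] * p[m, j]
                if prod > best:
                    best = prod
            out[i, j] = best
    return out


def zip_grid_oracle(counts, distances, iters: int = 12):
    """Self-starting nested grid search maximizing the ZIP likelihood.

    Returns (loglik, (alpha0, alpha1, omega)). Independent of the package
    optimizer: the likelihood is re-evaluated from its definition and the
    search uses only function values.
    """
    from awfc.structural_connectivity import zip_loglik

    s = np.asarray(counts, dtype=float)
    g = np.asarray(distances, dtype=float)
    pos = s > 0
    a0c = float(np.log(s[pos].mean()))
    a1c, wc = 0.0, float(np.mean(~pos)) / 2
    h = np.array([1.5, 0.03, 0.25])
    best = -np.inf
    for _ in range(iters):
        a0s = np.linspace(a0c - h[0], a0c + h[0], 9)
        a1s = np.linspace(a1c - h[1], a1c + h[1], 9)
        ws = np.clip(np.linspace(wc - h[2], wc + h[2], 9), 1e-9, 1 - 1e-9)
        vals = np.array(
            [[[zip_loglik(a0, a1, w, s, g) for w in ws] for a1 in a1s] for a0 in a0s]
        )
        i, j, k = np.unravel_index(np.argmax(vals), vals.shape)
        a0c, a1c, wc = a0s[i], a1s[j], ws[k]
        best = vals[i, j, k]
        h = h / 3
    return best, (a0c, a1c, wc)


def zip_sample(seed, n=1000, alpha0=2.0, alpha1=-0.02, omega=0.25):
    """Draw ZIP pair totals at uniform distances, the generator used in fit tests."""
    rng = np.random.default_rng(seed)
    g = rng.uniform(10, 120, n)
    s = rng.poisson(np.exp(alpha0 + alpha1 * g))
    s[rng.random(n) < omega] = 0
    return s, g
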