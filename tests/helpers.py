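"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the fragment-length
oracles enumerate candidate outcomes analytically or literally, and the
Pearson oracle is the textbook formula.
"""

from __future__ import annotations

import itertools

import numpy as np


def expected_length_hist(probabilities: np.ndarray, n_cuts: int) -> np.ndarray:
    """Exact expected per-template fragment-length histogram under the
    rejection cut model, via inclusion-exclusion over the per-candidate
    outcome categories.

    A candidate picks a site uniformly in 1..L-1 and realizes a cut with
    the site's probability.  Fragment (a, b) exists iff no realized cut
    falls strictly inside, a cut falls at ``a`` (or a == 0), and a cut
    falls at ``b`` (or b == L).  Entry ``hist[l]`` is the expected number
    of fragments of length ``l`` per template.
    """
    p = np.asarray(probabilities, dtype=float)
    L = len(p)
    M = L - 1
    q = np.zeros(L)
    q[1:] = p[1:] / M  # P(one candidate realizes a cut at site k)
    S = np.concatenate([[0.0], np.cumsum(q)])  # S[k] = sum_{j <= k-1} q_j
    n = n_cuts
    hist = np.zeros(L + 1)
    for length in range(1, L + 1):
        a = np.arange(0, L - length + 1)
        b = a + length
        iota = S[b] - S[a + 1]  # interior sites a+1 .. b-1
        alpha = np.where(a > 0, q[a], 0.0)
        beta = np.where(b < L, q[np.minimum(b, L - 1)], 0.0)
        P = (1 - iota) ** n
        P -= np.where(a > 0, (1 - iota - alpha) ** n, 0.0)
        P -= np.where(b < L, (1 - iota - beta) ** n, 0.0)
        P += np.where((a > 0) & (b < L), (1 - iota - alpha - beta) ** n, 0.0)
        hist[length] = P.sum()
    return hist


def brute_force_length_hist(probabilities: np.ndarray, n_cuts: int) -> np.ndarray:
    """Literal enumeration over every (site, accept/reject) outcome of
    every candidate.  Exponential cost; tiny templates and n only."""
    p = np.asarray(probabilities, dtype=float)
    L = len(p)
    M = L - 1
    hist = np.zeros(L + 1)
    for combo in itertools.product(range(1, L), repeat=n_cuts):
        for bits in itertools.product([0, 1], repeat=n_cuts):
            w = 1.0
            cuts = set()
            for site, keep in zip(combo, bits):
                w *= (p[site] if keep else (1.0 - p[site])) / M
                if keep:
                    cuts.add(site)
            bounds = [0] + sorted(cuts) + [L]
            for x, y in zip(bounds[:-1], bounds[1:]):
                hist[y - x] += w
    return hist


def pearson_textbook(x, y) -> float:
    """Pearson r by the raw textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(
        n * (y * y).sum() - y.sum() ** 2
    )
    return num / den


def welch_onetailed(a, b) -> tuple[float, float]:
    """Welch t statistic and one-tailed p (a > b), by the hand formula."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, float(tdist.sf(t, df))


def interval_mask(regions, genome) -> np.ndarray:
    """Boolean per-base mask over the concatenated genome."""
    masks = {name: np.zeros(length, dtype=bool) for name, length in genome}
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        masks[chrom][int(start) : int(end)] = True
    return np.concatenate([masks[n] for n in genome.names])
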