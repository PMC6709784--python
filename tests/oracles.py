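"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: direct pairwise
counting, exhaustive enumeration and dense fixed-point iteration, kept
simple enough to verify by eye.
"""

import math
from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def naive_stats(rows: list[str]) -> dict:
    """O(n^2 L) population-genetics statistics by direct counting."""
    n = len(rows)
    L = len(rows[0])
    keep = [j for j in range(L) if all(r[j] not in "-N?" for r in rows)]
    cols = ["".join(r[j] for r in rows) for j in keep]
    S = sum(1 for c in cols if len(set(c)) > 1)
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(sum(1 for c in cols if c[i] != c[j]))
    pi_count = sum(diffs) / len(diffs)
    haps = Counter("".join(r[j] for j in keep) for r in rows)
    hap_div = (n / (n - 1)) * (1 - sum((c / n) ** 2 for c in haps.values()))
    U = [0] * n
    eta_s = 0
    for c in cols:
        counts = Counter(c)
        for base, k in counts.items():
            if k == 1 and len(counts) > 1:
                eta_s += 1
                U[c.index(base)] += 1
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    D = math.nan
    if S > 0:
        var = (c1 / a1) * S + (c2 / (a1 ** 2 + a2)) * S * (S - 1)
        D = (pi_count - S / a1) / math.sqrt(var) if var > 0 else math.nan
    R2 = math.nan
    if S > 0:
        R2 = math.sqrt(sum((u - pi_count / 2) ** 2 for u in U) / n) / S
    return {"S": S, "L": len(keep), "pi": pi_count / len(keep),
            "hap_div": hap_div if len(haps) > 1 else 0.0,
            "K": len(haps), "tajima_d": D, "r2": R2, "eta_s": eta_s}


def smith_waterman_oracle(a: str, b: str, open_=-11.0, ext=-1.0) -> float:
    """Brute-force Gotoh local alignment score (first gap residue costs
    open_, each further residue ext)."""
    la, lb = len(a), len(b)
    NEG = -1e9
    M = np.zeros((la + 1, lb + 1))
    Ix = np.full((la + 1, lb + 1), NEG)
    Iy = np.full((la + 1, lb + 1), NEG)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _B62[a[i - 1]][b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                       Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext)
            best = max(best, M[i, j])
    return best


def naive_mcl_oracle(nodes, weighted_edges, inflation=1.5, iters=200):
    """Dense Markov clustering iterated to a fixed point."""
    import networkx as nx
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, w in weighted_edges:
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(M, loops)
    M = M / M.sum(axis=0)
    for _ in range(iters):
        M = M @ M
        M = M ** inflation
        M = M / M.sum(axis=0)
        M[M < 1e-8] = 0.0
        M = M / M.sum(axis=0)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if M[i, j] > 0:
                G.add_edge(i, j)
    return sorted(sorted(nodes[i] for i in comp)
                  for comp in nx.connected_components(G))
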