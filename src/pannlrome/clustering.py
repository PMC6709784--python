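"""Orthogroup construction: all-against-all protein similarity, orthology
typing of edges, and Markov clustering (MCL).

The similarity graph comes from exact local alignment (Smith–Waterman via
Biopython's C aligner) with BLOSUM62 and affine gaps; a deterministic
shared-k-mer prefilter skips sequence pairs that cannot reach the score
floor. Edges are typed following the orthAgogue conventions: reciprocal
best hits between accessions are orthologs, within-accession pairs scoring
at least as high as both members' best between-accession hits are
inparalogs, and inparalogs of reciprocal-best partners connect as
co-orthologs. MCL runs at inflation 1.5 on the typed, normalized scores;
clusters with at least two genes become orthogroups, the rest are
singletons.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from Bio.Align import PairwiseAligner, substitution_matrices

from .config import ClusteringConfig
from .models import Orthogroup


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str
    gene_b: str
    score: float
    normalized_score: float


@dataclass(frozen=True)
class TypedEdge:
    gene_a: str
    gene_b: str
    weight: float  # normalized score
    edge_type: str  # ortholog | co-ortholog | inparalog


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmer_sets(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def pairwise_similarity(proteins: dict[str, str],
                        config: ClusteringConfig | None = None
                        ) -> list[SimilarityEdge]:
    """All-against-all local-alignment similarity edges.

    Scores below ``config.score_floor`` are omitted; ``normalized_score``
    divides by the smaller of the two self-scores, so identical sequences
    get 1.0.
    """
    config = config or ClusteringConfig()
    aligner = _make_aligner()
    names = sorted(proteins)
    for n in names:
        if not proteins[n]:
            raise ValueError(f"empty protein sequence for {n}")
    self_score = {n: float(aligner.score(proteins[n], proteins[n]))
                  for n in names}
    k = config.kmer_prefilter
    if k:
        # shared-k-mer counts for all pairs at once via a sparse
        # gene x k-mer incidence product
        kmer_index: dict[str, int] = {}
        rows, cols = [], []
        for i, n in enumerate(names):
            for km in _kmer_sets(proteins[n], k):
                j = kmer_index.setdefault(km, len(kmer_index))
                rows.append(i)
                cols.append(j)
        A = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int32), (rows, cols)),
            shape=(len(names), len(kmer_index)))
        shared = sp.triu(A @ A.T, k=1).tocoo()
        candidates = [
            (int(i), int(j)) for i, j, v in
            zip(shared.row, shared.col, shared.data)
            if v >= config.min_shared_kmers]
    else:
        candidates = [(i, j) for i in range(len(names))
                      for j in range(i + 1, len(names))]

    edges = []
    for i, j in sorted(candidates):
        a, b = names[i], names[j]
        s = float(aligner.score(proteins[a], proteins[b]))
        if s < config.score_floor:
            continue
        norm = s / min(self_score[a], self_score[b])
        edges.append(SimilarityEdge(a, b, s, min(norm, 1.0)))
    return edges


def classify_edges(edges: list[SimilarityEdge],
                   accession_of_gene: dict[str, str]) -> list[TypedEdge]:
    """Type similarity edges as ortholog / co-ortholog / inparalog.

    Equal best scores are retained as co-best (both edges typed).
    """
    score: dict[frozenset, float] = {}
    norm: dict[frozenset, float] = {}
    neighbors: defaultdict[str, list[str]] = defaultdict(list)
    for e in edges:
        if e.gene_a not in accession_of_gene or e.gene_b not in accession_of_gene:
            raise KeyError("every gene needs an accession")
        key = frozenset((e.gene_a, e.gene_b))
        score[key] = e.score
        norm[key] = e.normalized_score
        neighbors[e.gene_a].append(e.gene_b)
        neighbors[e.gene_b].append(e.gene_a)

    acc = accession_of_gene
    # best between-accession score per (gene, target accession), and the
    # overall best between-accession score per gene
    best_to_acc: dict[tuple[str, str], float] = {}
    best_between: defaultdict[str, float] = defaultdict(float)
    for key, s in score.items():
        a, b = tuple(key)
        if acc[a] == acc[b]:
            continue
        for g, other in ((a, b), (b, a)):
            t = acc[other]
            if s > best_to_acc.get((g, t), 0.0):
                best_to_acc[(g, t)] = s
            if s > best_between[g]:
                best_between[g] = s

    typed: dict[frozenset, str] = {}
    orthologs: list[tuple[str, str]] = []
    inparalogs_of: defaultdict[str, set[str]] = defaultdict(set)

    for key, s in score.items():
        a, b = tuple(key)
        if acc[a] == acc[b]:
            if s >= best_between[a] and s >= best_between[b]:
                typed[key] = "inparalog"
                inparalogs_of[a].add(b)
                inparalogs_of[b].add(a)
        else:
            # reciprocal best between the two accessions (co-best ties kept)
            if (s >= best_to_acc[(a, acc[b])]
                    and s >= best_to_acc[(b, acc[a])]):
                typed[key] = "ortholog"
                orthologs.append((a, b))

    # co-orthologs: inparalogs of reciprocal-best partners, where the
    # similarity edge exists
    for a, b in orthologs:
        for a2 in inparalogs_of[a]:
            key = frozenset((a2, b))
            if key in score and key not in typed:
                typed[key] = "co-ortholog"
        for b2 in inparalogs_of[b]:
            key = frozenset((a, b2))
            if key in score and key not in typed:
                typed[key] = "co-ortholog"

    out = []
    for key, etype in typed.items():
        a, b = sorted(key)
        out.append(TypedEdge(a, b, norm[key], etype))
    return sorted(out, key=lambda e: (e.gene_a, e.gene_b))


def mcl_cluster(typed_edges: list[TypedEdge],
                config: ClusteringConfig | None = None,
                genes: list[str] | None = None) -> list[list[str]]:
    """Markov clustering of the typed similarity graph.

    Expansion (matrix squaring) alternates with inflation (entry-wise power
    and column renormalization) until the maximum column change drops below
    the tolerance. Self-loops are set to each node's maximum incident edge
    weight. Clusters are connected components of the converged matrix's
    non-zero structure. Deterministic given the input ordering.
    """
    config = config or ClusteringConfig()
    config.validate()
    nodes = sorted({g for e in typed_edges for g in (e.gene_a, e.gene_b)})
    if genes is not None:
        nodes = sorted(set(nodes) | set(genes))
    if not nodes:
        return []
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)

    rows, cols, vals = [], [], []
    max_w = np.zeros(n)
    for e in typed_edges:
        i, j = index[e.gene_a], index[e.gene_b]
        rows += [i, j]
        cols += [j, i]
        vals += [e.weight, e.weight]
        max_w[i] = max(max_w[i], e.weight)
        max_w[j] = max(max_w[j], e.weight)
    # self-loops: max incident weight (1.0 for isolated nodes)
    loop = np.where(max_w > 0, max_w, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def normalize(A):
        colsum = np.asarray(A.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return A @ sp.diags(1.0 / colsum)

    M = normalize(M)
    converged = False
    for _ in range(config.max_iterations):
        prev = M
        M = M @ M                            # expansion
        M = M.power(config.inflation)        # inflation
        M = normalize(M)
        M.data[M.data < config.prune_threshold] = 0.0
        M.eliminate_zeros()
        M = normalize(M)
        diff = abs(M - prev)
        if diff.nnz == 0 or diff.max() < config.convergence_tolerance:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn("MCL did not converge; interpreting current matrix")

    n_comp, labels = sp.csgraph.connected_components(
        (M + M.T) > 0, directed=False)
    clusters: defaultdict[int, list[str]] = defaultdict(list)
    for g, lab in zip(nodes, labels):
        clusters[lab].append(g)
    return [sorted(c) for c in clusters.values()]


def form_ogs(clusters: list[list[str]], min_og_size: int = 2,
             all_genes: list[str] | None = None
             ) -> tuple[list[Orthogroup], list[str]]:
    """Clusters of >= min_og_size become orthogroups; the rest (and any
    unclustered genes) are singletons. OG ids are stable: sorted by
    decreasing size, then lexically by first member."""
    clustered_genes = {g for c in clusters for g in c}
    singles = [g for c in clusters if len(c) < min_og_size for g in c]
    if all_genes is not None:
        singles += [g for g in all_genes if g not in clustered_genes]
    big = [sorted(c) for c in clusters if len(c) >= min_og_size]
    big.sort(key=lambda c: (-len(c), c[0]))
    ogs = [Orthogroup(og_id=f"OG{i:04d}", members=c)
           for i, c in enumerate(big)]
    return ogs, sorted(singles)
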