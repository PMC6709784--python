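"""Orthogroup refinement: per-OG alignment, outlier screening, distance
trees, paralog detection and the 5% prune-vs-split rule, plus the physical
annotations (200-kb clusters, head-to-head pairs) and OG metadata votes.

Refinement targets over-clustered OGs: a gene tree is built for every OG
with more than four members, within-accession duplications are detected on
the midpoint-rooted tree, and if at most 5% of the occupied accessions show
duplicates the extra paralogs are pruned (keeping the most conserved copy);
otherwise the tree is split at duplication nodes and the resulting leaf sets
become new OGs.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .models import CodonAlignment, GeneModel, Orthogroup, RefinedOG

_B62 = substitution_matrices.load("BLOSUM62")
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_B62_DENSE = np.array([[_B62[a][b] for b in _AA] for a in _AA])

_GAP_OPEN = -11.0
_GAP_EXTEND = -1.0


# ---------------------------------------------------------------------------
# progressive protein alignment
# ---------------------------------------------------------------------------

def _profile(rows: list[str]) -> np.ndarray:
    """Column residue-frequency profile (gaps carry zero weight)."""
    L = len(rows[0])
    prof = np.zeros((L, len(_AA)))
    for r in rows:
        for j, c in enumerate(r):
            if c != "-":
                prof[j, _AA_INDEX.get(c, _AA_INDEX["X"])] += 1.0
    tot = prof.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return prof / tot


def _align_profiles(rows_a: list[str], rows_b: list[str]
                    ) -> tuple[list[str], list[str], float]:
    """Global profile–profile Needleman–Wunsch with affine gaps.

    Returns the two row groups expanded with the merge gaps, and the optimal
    alignment score.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    S = pa @ _B62_DENSE @ pb.T  # (la, lb) column-pair scores

    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    Ix[1:, 0] = _GAP_OPEN + _GAP_EXTEND * np.arange(la)
    Iy[0, 1:] = _GAP_OPEN + _GAP_EXTEND * np.arange(lb)

    for i in range(1, la + 1):
        prev_best = np.maximum.reduce([M[i - 1], Ix[i - 1], Iy[i - 1]])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        Ix[i, :] = np.maximum(M[i - 1] + _GAP_OPEN, Ix[i - 1] + _GAP_EXTEND)
        # Iy same-row scan: Iy[i,j] = max(M[i,j-1]+open, Iy[i,j-1]+ext)
        # = j*ext + running_max(M[i,k] + open - (k+1)*ext)
        shift = M[i, :-1] + _GAP_OPEN - _GAP_EXTEND * np.arange(1, lb + 1)
        Iy[i, 1:] = (np.maximum.accumulate(shift)
                     + _GAP_EXTEND * np.arange(1, lb + 1))

    # traceback
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    score = float([M[i, j], Ix[i, j], Iy[i, j]][state])
    while i > 0 or j > 0:
        if state == 0:  # match
            out_a.append(i - 1)
            out_b.append(j - 1)
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:  # gap in B
            out_a.append(i - 1)
            out_b.append(None)
            if np.isclose(Ix[i, j], M[i - 1, j] + _GAP_OPEN):
                state = 0
            i -= 1
        else:  # gap in A
            out_a.append(None)
            out_b.append(j - 1)
            if np.isclose(Iy[i, j], M[i, j - 1] + _GAP_OPEN):
                state = 0
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    out_a.reverse()
    out_b.reverse()

    new_a = ["".join(r[k] if k is not None else "-" for k in out_a)
             for r in rows_a]
    new_b = ["".join(r[k] if k is not None else "-" for k in out_b)
             for r in rows_b]
    return new_a, new_b, score


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [{s[i:i + k] for i in range(max(1, len(s) - k + 1))} for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - inter / denom
    return D


def align_og(proteins: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment of one OG's member proteins.

    k-mer distances feed a UPGMA guide tree; groups are merged by
    profile–profile global alignment with BLOSUM62 and affine gaps. Row
    order of the input mapping is preserved in the output.
    """
    names = list(proteins)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences to align")
    seqs = [proteins[n] for n in names]
    if len(names) == 2:
        a, b, _ = _align_profiles([seqs[0]], [seqs[1]])
        return {names[0]: a[0], names[1]: b[0]}

    D = _kmer_distance(seqs)
    condensed = D[np.triu_indices(len(names), k=1)]
    linkage = sch.linkage(condensed, method="average")

    groups: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(names))}
    nxt = len(names)
    for (a, b, _dist, _cnt) in linkage:
        ia, rows_a = groups.pop(int(a))
        ib, rows_b = groups.pop(int(b))
        na, nb, _ = _align_profiles(rows_a, rows_b)
        groups[nxt] = (ia + ib, na + nb)
        nxt += 1
    order, rows = groups.popitem()[1]
    aligned = dict(zip([names[i] for i in order], rows))
    return {n: aligned[n] for n in names}


# ---------------------------------------------------------------------------
# codon back-translation
# ---------------------------------------------------------------------------

def protein_to_codon(protein_msa: dict[str, str],
                     cds_of_gene: dict[str, str]) -> CodonAlignment:
    """Expand a protein alignment to the corresponding codon alignment.

    Each residue column becomes its codon; a residue gap becomes ``---``.
    A trailing stop codon on the CDS is excluded. A CDS that does not
    translate to its protein row raises an error naming the gene and the
    first mismatched residue.
    """
    ids, seqs = [], []
    for gene, row in protein_msa.items():
        cds = cds_of_gene[gene].upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"{gene}: CDS length {len(cds)} not divisible by 3")
        aa = str(Seq(cds).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
            cds = cds[:-3]
        ungapped = row.replace("-", "")
        if len(aa) != len(ungapped):
            raise ValueError(
                f"{gene}: CDS translates to {len(aa)} residues but protein "
                f"row has {len(ungapped)}")
        for pos, (x, y) in enumerate(zip(aa, ungapped), start=1):
            if x != y and x != "X" and y != "X":
                raise ValueError(
                    f"{gene}: translation mismatch at residue {pos}: "
                    f"CDS gives {x!r}, protein has {y!r}")
        codons = [cds[3 * i: 3 * i + 3] for i in range(len(aa))]
        out = []
        ci = 0
        for c in row:
            if c == "-":
                out.append("---")
            else:
                out.append(codons[ci])
                ci += 1
        ids.append(gene)
        seqs.append("".join(out))
    return CodonAlignment(ids, seqs)


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------

def detect_outliers(protein_msa: dict[str, str], bootstrap_reps: int = 100,
                    seed: int = 0, z_max: float = 3.0) -> set[str]:
    """Flag rows whose bootstrap mean pairwise distance is aberrant.

    Column sets are resampled with replacement; a row whose mean distance
    z-score against the across-row trimmed mean exceeds ``z_max`` is an
    outlier. OGs with fewer than 5 rows are not screened (empty result).
    """
    names = list(protein_msa)
    if len(names) < 5:
        return set()
    rows = [protein_msa[n] for n in names]
    n = len(names)
    L = len(rows[0])
    rng = np.random.default_rng(seed)

    # per-column pairwise mismatch / comparable indicators, flattened to
    # (L, n*n) so every bootstrap replicate is one matrix product with the
    # multinomial column-count matrix
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    diff = np.zeros((L, n * n), dtype=np.float32)
    valid = np.zeros((L, n * n), dtype=np.float32)
    for c in range(L):
        ok = ~gap[:, c]
        v = np.outer(ok, ok)
        d = (arr[:, c][:, None] != arr[:, c][None, :]) & v
        diff[c] = d.ravel()
        valid[c] = v.ravel()
    W = rng.multinomial(L, np.full(L, 1.0 / L), size=bootstrap_reps
                        ).astype(np.float32)
    dsum = W @ diff     # (reps, n*n)
    vsum = W @ valid
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(vsum > 0, dsum / vsum, 1.0).reshape(
            bootstrap_reps, n, n)
    for i in range(n):
        dist[:, i, i] = 0.0
    boot = dist.sum(axis=2) / (n - 1)
    mean_dist = boot.mean(axis=0)

    from scipy.stats import trim_mean
    center = trim_mean(mean_dist, 0.1)
    lo, hi = np.quantile(mean_dist, [0.1, 0.9])
    trimmed = mean_dist[(mean_dist >= lo) & (mean_dist <= hi)]
    sd = trimmed.std()
    if sd < 1e-9:
        sd = 1e-9
    z = (mean_dist - center) / sd
    return {names[i] for i in np.flatnonzero(z > z_max)}


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """A neighbor-joining gene tree with bootstrap supports."""

    tree: TreeNode
    leaves: list[str]
    duplication_nodes: list = field(default_factory=list)

    @property
    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse()
                   if not n.is_root())


def _nucleotide_pdist(aln: CodonAlignment) -> np.ndarray:
    """p-distance with pairwise deletion of gapped positions."""
    arr = np.array([list(s) for s in aln.seqs])
    n = arr.shape[0]
    gap = (arr == "-") | (arr == "N")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            tot = ok.sum()
            D[i, j] = D[j, i] = (
                (arr[i, ok] != arr[j, ok]).sum() / tot if tot else 0.0)
    return D


def _bipartitions(tree: TreeNode, leaf_set: frozenset[str]) -> set[frozenset[str]]:
    out = set()
    for node in tree.non_tips():
        names = frozenset(t.name for t in node.tips())
        if 2 <= len(names) <= len(leaf_set) - 2:
            side = min(names, frozenset(leaf_set - names),
                       key=lambda s: (len(s), sorted(s)))
            out.add(side)
    return out


def _nj_tree(aln: CodonAlignment) -> TreeNode:
    D = _nucleotide_pdist(aln)
    # skbio requires unique ids and a condensed-valid matrix
    dm = DistanceMatrix(D, ids=aln.ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_tree(aln: CodonAlignment, bootstrap_reps: int = 100,
               seed: int = 0) -> GeneTree:
    """Neighbor joining on pairwise p-distances with column-bootstrap
    supports (0–100) on internal edges. Fewer than 3 rows gives a
    degenerate 2-leaf tree without supports."""
    if aln.n < 3:
        D = _nucleotide_pdist(aln)
        d = float(D[0, 1]) if aln.n == 2 else 0.0
        t = TreeNode.read(
            [f"({aln.ids[0]}:{d / 2},{aln.ids[1]}:{d / 2});"]
            if aln.n == 2 else [f"({aln.ids[0]}:0);"])
        return GeneTree(tree=t, leaves=list(aln.ids))

    tree = _nj_tree(aln)
    leaf_set = frozenset(aln.ids)

    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        counts: Counter[frozenset[str]] = Counter()
        for _ in range(bootstrap_reps):
            cols = rng.integers(aln.n_codons, size=aln.n_codons)
            rep = _nj_tree(aln.subset_codon_columns(cols))
            counts.update(_bipartitions(rep, leaf_set))
        for node in tree.non_tips():
            names = frozenset(t.name for t in node.tips())
            if not 2 <= len(names) <= len(leaf_set) - 2:
                continue
            side = min(names, frozenset(leaf_set - names),
                       key=lambda s: (len(s), sorted(s)))
            node.support = 100.0 * counts[side] / bootstrap_reps
    return GeneTree(tree=tree, leaves=list(aln.ids))


# ---------------------------------------------------------------------------
# paralog detection and the 5% rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationNode:
    node_id: int
    leaf_names: frozenset[str]
    kind: str  # simple | complex


def detect_duplications(gene_tree: GeneTree,
                        accession_of_gene: dict[str, str]
                        ) -> list[DuplicationNode]:
    """Find internal nodes where an accession occurs in more than one child
    clade of the midpoint-rooted tree. A duplication is ``simple`` when the
    two occurrences are sister leaves, ``complex`` otherwise."""
    tree = gene_tree.tree
    if len(gene_tree.leaves) < 2:
        return []
    try:
        rooted = tree.root_at_midpoint()
    except Exception:
        rooted = tree
    out = []
    for nid, node in enumerate(rooted.non_tips(include_self=True)):
        children = node.children
        if len(children) < 2:
            continue
        accs_per_child = [
            Counter(accession_of_gene[t.name] for t in ch.tips(include_self=True))
            for ch in children]
        shared = set()
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                shared |= set(accs_per_child[i]) & set(accs_per_child[j])
        if not shared:
            continue
        is_simple = (len(children) == 2
                     and all(ch.is_tip() for ch in children)
                     and accession_of_gene[children[0].name]
                     == accession_of_gene[children[1].name])
        out.append(DuplicationNode(
            node_id=nid,
            leaf_names=frozenset(t.name for t in node.tips(include_self=True)),
            kind="simple" if is_simple else "complex"))
    return out


def refine_og(og: Orthogroup, gene_tree: GeneTree,
              duplications: list[DuplicationNode],
              accession_of_gene: dict[str, str],
              paralog_accession_fraction: float = 0.05
              ) -> tuple[list[Orthogroup], dict[str, str]]:
    """Apply the 5% prune-vs-split rule.

    Let f be the fraction of occupied accessions carrying within-OG
    duplicates. If f <= the threshold, all but one member per duplicated
    accession are pruned (the member with the smallest root-to-leaf path is
    kept) and a single OG returns. Otherwise the tree is split at
    duplication nodes; every resulting leaf set with >= 2 members becomes a
    new OG and the rest become singletons.

    Returns (orthogroups, status) where status maps each original member to
    ``kept``, ``pruned_paralog``, ``split_to:<suffix>`` or ``singleton``.
    """
    members = list(og.members)
    acc_counts = Counter(accession_of_gene[g] for g in members)
    occupied = len(acc_counts)
    dup_accessions = {a for a, c in acc_counts.items() if c > 1}
    status = {g: "kept" for g in members}

    if not dup_accessions:
        return [og], status

    f = len(dup_accessions) / occupied
    tree = gene_tree.tree
    try:
        rooted = tree.root_at_midpoint()
    except Exception:
        rooted = tree
    depth = {}
    for tip in rooted.tips():
        depth[tip.name] = tip.accumulate_to_ancestor(rooted)

    if f <= paralog_accession_fraction:
        keep = []
        for g in members:
            a = accession_of_gene[g]
            if a not in dup_accessions:
                keep.append(g)
        for a in sorted(dup_accessions):
            copies = [g for g in members if accession_of_gene[g] == a]
            copies.sort(key=lambda g: (depth.get(g, 0.0), g))
            keep.append(copies[0])
            for g in copies[1:]:
                status[g] = "pruned_paralog"
        return [Orthogroup(og_id=og.og_id, members=sorted(keep))], status

    # split at duplication nodes: remove those internal nodes from the tree
    # graph; connected components give the new leaf groups
    import networkx as nx
    G = nx.Graph()
    dup_leafsets = {d.leaf_names for d in duplications}
    node_ids = {}
    for i, node in enumerate(rooted.traverse(include_self=True)):
        node_ids[id(node)] = i
        G.add_node(i)
    cut = set()
    for node in rooted.non_tips(include_self=True):
        names = frozenset(t.name for t in node.tips(include_self=True))
        if names in dup_leafsets:
            cut.add(node_ids[id(node)])
    for node in rooted.traverse(include_self=True):
        for ch in node.children:
            G.add_edge(node_ids[id(node)], node_ids[id(ch)])
    G.remove_nodes_from(cut)
    leaf_of_id = {node_ids[id(t)]: t.name for t in rooted.tips()}

    groups = []
    for comp in nx.connected_components(G):
        leaves = sorted(leaf_of_id[i] for i in comp if i in leaf_of_id)
        if leaves:
            groups.append(leaves)
    # leaves under removed duplication nodes whose own component vanished
    seen = {g for grp in groups for g in grp}
    for g in members:
        if g not in seen:
            groups.append([g])

    groups.sort(key=lambda grp: (-len(grp), grp[0]))
    new_ogs = []
    suffix = 0
    for grp in groups:
        if len(grp) >= 2:
            new_id = f"{og.og_id}.{suffix}"
            suffix += 1
            new_ogs.append(Orthogroup(og_id=new_id, members=grp))
            for g in grp:
                status[g] = f"split_to:{new_id}"
        else:
            status[grp[0]] = "singleton"
    return new_ogs, status


# ---------------------------------------------------------------------------
# OG typing and physical annotation
# ---------------------------------------------------------------------------

def classify_og_type(og_size: int, cloud_max: int = 12,
                     shell_max: int = 51) -> str:
    """Size-based OG category: < 13 members cloud, 13–51 shell, > 51 core."""
    if og_size < 2:
        raise ValueError("orthogroups have at least 2 members")
    if og_size <= cloud_max:
        return "cloud"
    if og_size <= shell_max:
        return "shell"
    return "core"


def detect_physical_clusters(genes: list[GeneModel],
                             window: int = 200_000
                             ) -> tuple[dict[str, bool], list[set[str]]]:
    """Single-linkage chaining of same-contig genes whose start-to-start
    distance is within the window; clusters need >= 2 genes."""
    by_contig: defaultdict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_contig[(g.accession, g.contig)].append(g)

    flag = {g.gene_id: False for g in genes}
    clusters = []
    for key, glist in sorted(by_contig.items()):
        glist.sort(key=lambda g: g.start)
        chain = [glist[0]]
        for g in glist[1:]:
            if g.start - chain[-1].start <= window:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append({x.gene_id for x in chain})
                chain = [g]
        if len(chain) >= 2:
            clusters.append({x.gene_id for x in chain})
    for cl in clusters:
        for g in cl:
            flag[g] = True
    return flag, clusters


def detect_pairs(genes: list[GeneModel],
                 max_separation: int = 10_000) -> list[tuple[str, str]]:
    """Head-to-head (divergently transcribed) adjacent gene pairs.

    The left gene must be on the minus strand and the right gene on the
    plus strand with no gene between them and 5'-end separation at most
    ``max_separation``."""
    by_contig: defaultdict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        if g.strand not in {"+", "-"}:
            warnings.warn(f"{g.gene_id}: missing strand, skipped")
            continue
        by_contig[(g.accession, g.contig)].append(g)

    pairs = []
    for key, glist in sorted(by_contig.items()):
        glist.sort(key=lambda g: g.start)
        for left, right in zip(glist, glist[1:]):
            if (left.strand == "-" and right.strand == "+"
                    and right.start - left.end <= max_separation):
                pairs.append((left.gene_id, right.gene_id))
    return pairs


def annotate_og(og: Orthogroup, class_of_gene: dict[str, str | None],
                clustered: dict[str, bool], paired: dict[str, bool],
                has_id: dict[str, bool],
                gene_tree: GeneTree | None = None,
                cloud_max: int = 12, shell_max: int = 51) -> RefinedOG:
    """Attach majority-vote metadata and the size-normalized branch length."""
    classes = [class_of_gene.get(g) for g in og.members]
    counts = Counter(c for c in classes if c)
    label = None
    if counts:
        top = counts.most_common()
        label = top[0][0]
        ties = [c for c, n in top if n == top[0][1]]
        if len(ties) > 1:
            label = sorted(ties)[0]
            warnings.warn(
                f"{og.og_id}: class vote tie {sorted(ties)}, using {label}")
    n = og.size
    mbl = (gene_tree.total_branch_length / n) if gene_tree is not None else 0.0
    return RefinedOG(
        og_id=og.og_id, members=list(og.members),
        og_type=classify_og_type(n, cloud_max, shell_max),
        class_label=label,
        clustered_flag=sum(clustered.get(g, False) for g in og.members) * 2 > n,
        paired_flag=sum(paired.get(g, False) for g in og.members) * 2 > n,
        id_flag=any(has_id.get(g, False) for g in og.members),
        mean_branch_length=mbl)
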