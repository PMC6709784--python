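"""Ground-truthed synthetic pan-NLRome generation.

Every downstream stage of the pipeline is exercised against data produced
here: a panel of accessions shares a set of orthogroups with a configurable
core/shell/cloud presence spectrum; the members of each orthogroup descend
from a common ancestral CDS along a Kingman coalescent genealogy with
Poisson-distributed Jukes–Cantor mutations on branches; genes carry canonical
NLR domain architectures (a minority with integrated domains), sit on contigs
in physical clusters with head-to-head pairs, and are annotated with curation
flags. The generator records full truth tables so that clustering,
classification, refinement and anchoring can be scored against known answers.

Time in the coalescent is measured in units of 2N generations, so that for a
per-site scaled mutation rate theta the expected pairwise diversity per site
is theta (mutations occur on a branch of length t at rate theta/2 per site).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import SimulationConfig
from .models import CodonAlignment, DomainInterval, GeneModel

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

#: fixed catalogue of integrated-domain labels; the labels are arbitrary,
#: their distribution over genes is what the pipeline reasons about.
ID_CATALOGUE = (
    "WRKY-like", "B3-like", "kinase-like", "PAH-like", "DUF640-like",
    "PP2-like", "PPR-like", "alliinase-like", "LIM-like", "DA1-like",
)

_CLASS_PROBS = {"TNL": 0.55, "NL": 0.20, "CNL": 0.18, "RNL": 0.07}


# ---------------------------------------------------------------------------
# coalescent machinery
# ---------------------------------------------------------------------------

def _coalescent_tree(n: int, rng: np.random.Generator):
    """Simulate a Kingman genealogy for n lineages.

    Returns (children, branch_len, root): ``children[v]`` lists the child
    node ids of internal node v; leaves are 0..n-1; ``branch_len[v]`` is the
    length of the branch above node v in units of 2N generations.
    """
    if n == 1:
        return {}, {0: 0.0}, 0
    node_time = {i: 0.0 for i in range(n)}
    active = list(range(n))
    children: dict[int, list[int]] = {}
    branch_len: dict[int, float] = {}
    nxt = n
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        children[nxt] = [a, b]
        branch_len[a] = t - node_time[a]
        branch_len[b] = t - node_time[b]
        node_time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    branch_len[root] = 0.0
    return children, branch_len, root


def _mutate(seq: np.ndarray, n_mut: int, rng: np.random.Generator,
            avoid_stops: bool) -> np.ndarray:
    """Apply n_mut Jukes–Cantor point mutations to a base array in place.

    A site may be hit more than once. With ``avoid_stops`` a substitution
    that creates an in-frame stop codon is redrawn (keeps the family
    translatable, mimicking purifying selection against truncations).
    """
    L = seq.size
    for _ in range(n_mut):
        for _attempt in range(20):
            pos = int(rng.integers(L))
            old = seq[pos]
            new = _BASES[_BASES != old][int(rng.integers(3))]
            seq[pos] = new
            if not avoid_stops:
                break
            c0 = 3 * (pos // 3)
            if "".join(seq[c0:c0 + 3]) not in _STOPS:
                break
            seq[pos] = old  # redraw
    return seq


def _evolve_family(ancestral: str, n: int, theta: float,
                   rng: np.random.Generator,
                   avoid_stops: bool = True) -> list[str]:
    """Evolve n descendant sequences of ``ancestral`` on a random coalescent
    genealogy with per-site scaled mutation rate theta."""
    anc = np.array(list(ancestral))
    if n == 1:
        return ["".join(anc)]
    children, branch_len, root = _coalescent_tree(n, rng)
    L = anc.size
    seqs: dict[int, np.ndarray] = {}

    stack = [(root, anc)]
    while stack:
        node, seq = stack.pop()
        n_mut = rng.poisson(0.5 * theta * L * branch_len[node])
        seq = _mutate(seq.copy(), n_mut, rng, avoid_stops)
        if node in children:
            for ch in children[node]:
                stack.append((ch, seq))
        else:
            seqs[node] = seq
    return ["".join(seqs[i]) for i in range(n)]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random open reading frame with no internal stop codons."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


_CODON_TABLE = {}


def _translate(cds: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------

def simulate_neutral_alignment(n_sequences: int, length: int, theta: float,
                               seed: int) -> CodonAlignment:
    """Simulate an ungapped neutral codon alignment.

    Sequences are generated on a random Kingman genealogy with Poisson
    mutations on branches (a site may be hit repeatedly). ``theta`` is the
    scaled per-site mutation rate; for n=2 the expected pairwise difference
    per site equals theta.
    """
    if length % 3 != 0:
        raise ValueError(f"length {length} not divisible by 3")
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    anc = "".join(rng.choice(_BASES, size=length))
    seqs = _evolve_family(anc, n_sequences, theta, rng, avoid_stops=False)
    ids = [f"seq{i}" for i in range(n_sequences)]
    return CodonAlignment(ids, seqs)


def inject_gene_conversion(alignment: CodonAlignment, donor_index: int,
                           acceptor_index: int, tract: tuple[int, int],
                           seed: int | None = None) -> CodonAlignment:
    """Copy the donor's tract (half-open nucleotide interval) onto the
    acceptor; every other position is untouched. ``seed`` is accepted for
    interface symmetry with the other simulators but unused (the operation
    is deterministic)."""
    n = alignment.n
    for idx in (donor_index, acceptor_index):
        if not 0 <= idx < n:
            raise IndexError(f"sequence index {idx} out of range 0..{n - 1}")
    lo, hi = tract
    if not (0 <= lo <= hi <= alignment.length):
        raise ValueError(f"tract {tract} outside alignment of length "
                         f"{alignment.length}")
    seqs = list(alignment.seqs)
    donor = seqs[donor_index]
    acc = seqs[acceptor_index]
    seqs[acceptor_index] = acc[:lo] + donor[lo:hi] + acc[hi:]
    return CodonAlignment(list(alignment.ids), seqs, alignment.column_domains)


@dataclass
class TruthTables:
    """Ground truth recorded by the simulator."""

    true_og_of_gene: dict[str, str] = field(default_factory=dict)
    true_architecture: dict[str, tuple[str, ...]] = field(default_factory=dict)
    true_pairs: list[tuple[str, str]] = field(default_factory=list)
    true_clusters: list[frozenset[str]] = field(default_factory=list)


@dataclass
class OGTemplate:
    og_id: str
    class_label: str
    presence_p: float
    architecture: tuple[str, ...]            # ordered N->C canonical labels
    domain_layout: list[tuple[str, int, int]]  # (label, start, end) residues
    ancestral_cds: str
    paralog: bool = False
    pair_partner: str | None = None
    cluster_group: int | None = None


class SimulatedPanNLRome:
    """Bundle of simulated gene models, domain calls, sequences and truth."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.genes: list[GeneModel] = []
        self.domains: list[DomainInterval] = []
        self.truth = TruthTables()
        self.og_templates: dict[str, OGTemplate] = {}
        self.accessions: list[str] = []

    # -- convenience views -------------------------------------------------
    def genes_by_accession(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {a: [] for a in self.accessions}
        for g in self.genes:
            out[g.accession].append(g)
        return out

    def presence_matrix(self):
        """Truth OG x accession member-count matrix as a DataFrame."""
        import pandas as pd
        ogs = sorted(self.og_templates)
        mat = pd.DataFrame(0, index=ogs, columns=self.accessions, dtype=int)
        for g in self.genes:
            og = self.truth.true_og_of_gene[g.gene_id]
            mat.loc[og, g.accession] += 1
        return mat

    # -- output ------------------------------------------------------------
    def write(self, outdir) -> None:
        from . import io as pio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_acc = self.genes_by_accession()
        for acc in self.accessions:
            pio.write_gff3(by_acc[acc], outdir / f"{acc}.gff3")
            pio.write_fasta(
                {g.gene_id: g.protein for g in by_acc[acc]},
                outdir / f"{acc}.faa")
            pio.write_fasta(
                {g.gene_id: g.cds for g in by_acc[acc]},
                outdir / f"{acc}.fna")
        pio.write_domains_tsv(self.domains, outdir / "domains.tsv")
        with open(outdir / "truth_og.tsv", "w") as fh:
            fh.write("gene_id\tog_id\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{self.truth.true_og_of_gene[g.gene_id]}\n")
        with open(outdir / "truth_architecture.tsv", "w") as fh:
            fh.write("gene_id\tarchitecture\n")
            for g in self.genes:
                arch = ",".join(self.truth.true_architecture[g.gene_id])
                fh.write(f"{g.gene_id}\t{arch}\n")
        with open(outdir / "truth_pairs.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in self.truth.true_pairs:
                fh.write(f"{a}\t{b}\n")
        with open(outdir / "truth_clusters.tsv", "w") as fh:
            fh.write("cluster_index\tgene_id\n")
            for i, cl in enumerate(self.truth.true_clusters):
                for g in sorted(cl):
                    fh.write(f"{i}\t{g}\n")
        with open(outdir / "config.yaml", "w") as fh:
            cfg = dict(self.config.__dict__)
            cfg["og_spectrum"] = [list(t) for t in cfg["og_spectrum"]]
            yaml.safe_dump(cfg, fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable digest over the full simulated content (determinism checks)."""
        h = hashlib.sha256()
        for g in sorted(self.genes, key=lambda x: x.gene_id):
            h.update(repr((g.gene_id, g.accession, g.contig, g.start, g.end,
                           g.strand, tuple(g.flags), g.protein, g.cds)
                          ).encode())
        for d in sorted(self.domains,
                        key=lambda x: (x.gene_id, x.start, x.label, x.source)):
            h.update(repr((d.gene_id, d.label, d.start, d.end, d.source)
                          ).encode())
        return h.hexdigest()


def _architecture_for_class(class_label: str, P: int):
    """Domain layout (label, start, end) and ordered architecture for a
    class, on a protein of P residues."""
    nterm = {"TNL": "TIR", "CNL": "CC", "RNL": "RPW8", "NL": None}[class_label]
    layout = []
    ordered = []
    if nterm is not None:
        layout.append((nterm, 1, 50))
        ordered.append(nterm)
    nb_end = int(P * 0.75)
    layout.append(("NB", 55, nb_end))
    ordered.append("NB")
    mid = (nb_end + 3 + P) // 2
    layout.append(("LRR", nb_end + 3, mid))
    layout.append(("LRR", mid + 1, P))
    ordered.extend(["LRR", "LRR"])
    return layout, tuple(ordered)


def simulate_pannlrome(config: SimulationConfig) -> SimulatedPanNLRome:
    """Generate a full synthetic pan-NLRome with truth tables.

    Deterministic given ``config.seed``: re-running with the same
    configuration yields byte-identical output files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sim = SimulatedPanNLRome(config)
    n_acc = config.n_accessions
    sim.accessions = [f"acc{i:03d}" for i in range(n_acc)]
    P = config.protein_length

    # -- orthogroup templates ---------------------------------------------
    classes = list(_CLASS_PROBS)
    class_p = np.array([_CLASS_PROBS[c] for c in classes])
    ogs: list[OGTemplate] = []
    k = 0
    for presence_p, n_ogs in config.og_spectrum:
        for _ in range(n_ogs):
            og_id = f"tOG{k:04d}"
            cls = classes[int(rng.choice(len(classes), p=class_p))]
            layout, ordered = _architecture_for_class(cls, P)
            ogs.append(OGTemplate(
                og_id=og_id, class_label=cls, presence_p=presence_p,
                architecture=ordered, domain_layout=layout,
                ancestral_cds=_random_cds(P, rng)))
            k += 1
    n_total = len(ogs)

    # paralog-seeded OGs
    n_paralog = int(round(config.paralog_og_fraction * n_total))
    for i in rng.choice(n_total, size=n_paralog, replace=False):
        ogs[i].paralog = True

    # head-to-head pairs: consecutive OG couples
    n_pair_ogs = int(round(config.pair_fraction * n_total / 2)) * 2
    pair_idx = rng.choice(n_total, size=n_pair_ogs, replace=False)
    for a, b in zip(pair_idx[0::2], pair_idx[1::2]):
        ogs[a].pair_partner = ogs[b].og_id
        ogs[b].pair_partner = ogs[a].og_id

    # physical cluster groups: ~40% of remaining OGs in groups of 2-4
    unpaired = [i for i in range(n_total) if ogs[i].pair_partner is None]
    rng.shuffle(unpaired)
    n_clustered = int(0.4 * len(unpaired))
    gi = 0
    group = 0
    while gi < n_clustered:
        size = int(rng.integers(2, 5))
        for i in unpaired[gi:gi + size]:
            ogs[i].cluster_group = group
        gi += size
        group += 1

    for og in ogs:
        sim.og_templates[og.og_id] = og

    # -- presence sampling -------------------------------------------------
    presence = {}
    for og in ogs:
        presence[og.og_id] = rng.random(n_acc) < og.presence_p

    # -- per-OG sequence families ------------------------------------------
    # copies[og_id] = list of (accession_index, is_paralog_copy, cds)
    copies: dict[str, list[tuple[int, bool, str]]] = {og.og_id: [] for og in ogs}
    for og in ogs:
        acc_idx = np.flatnonzero(presence[og.og_id])
        if acc_idx.size == 0:
            continue
        dup_acc = -1
        if og.paralog and acc_idx.size >= 1:
            dup_acc = int(acc_idx[int(rng.integers(acc_idx.size))])
        n_copies = acc_idx.size + (1 if dup_acc >= 0 else 0)
        seqs = _evolve_family(og.ancestral_cds, n_copies,
                              config.per_og_theta, rng)
        # gene conversion between family members
        for ci in range(n_copies):
            if rng.random() < config.gene_conversion_rate and n_copies >= 2:
                donor = int(rng.integers(n_copies))
                if donor != ci:
                    L = len(seqs[ci])
                    tract = max(3, int(rng.exponential(
                        config.conversion_tract_mean)))
                    lo = int(rng.integers(max(1, L - tract + 1)))
                    hi = min(L, lo + tract)
                    seqs[ci] = (seqs[ci][:lo] + seqs[donor][lo:hi]
                                + seqs[ci][hi:])
        ci = 0
        for ai in acc_idx:
            copies[og.og_id].append((int(ai), False, seqs[ci]))
            ci += 1
        if dup_acc >= 0:
            # extra within-accession copy, diverged by an additional 2x theta
            parent = seqs[list(acc_idx).index(dup_acc)]
            dup_arr = np.array(list(parent))
            n_mut = rng.poisson(2.0 * config.per_og_theta * dup_arr.size)
            dup = "".join(_mutate(dup_arr, n_mut, rng, True))
            copies[og.og_id].append((dup_acc, True, dup))

    # -- integrated domains -------------------------------------------------
    # choose ID-carrying OGs; a gene in such an OG carries the OG's ID label
    all_copy_count = sum(len(v) for v in copies.values())
    target_id_genes = int(round(config.id_gene_fraction * all_copy_count))

    # -- lay out genes on contigs per accession -----------------------------
    gene_counter = 0
    id_assigned = 0
    og_order = sorted(copies)
    # precompute OG -> its ID label (a subset of OGs carries one)
    og_id_label: dict[str, str | None] = {o: None for o in og_order}
    if target_id_genes > 0:
        id_ogs = rng.permutation(og_order)
        acc_count = {o: len(copies[o]) for o in og_order}
        run = 0
        for o in id_ogs:
            if run >= target_id_genes:
                break
            og_id_label[o] = ID_CATALOGUE[int(rng.integers(len(ID_CATALOGUE)))]
            run += acc_count[o]

    for ai, acc in enumerate(sim.accessions):
        # gather this accession's gene copies grouped by layout unit
        acc_genes: list[tuple[OGTemplate, bool, str]] = []
        for og in ogs:
            for (a, is_par, cds) in copies[og.og_id]:
                if a == ai:
                    acc_genes.append((og, is_par, cds))
        # group into contig units: pair partners together, cluster groups
        # together, the rest on singleton contigs
        units: dict[object, list[tuple[OGTemplate, bool, str]]] = {}
        for item in acc_genes:
            og = item[0]
            if og.pair_partner is not None:
                key = ("pair", tuple(sorted((og.og_id, og.pair_partner))))
            elif og.cluster_group is not None:
                key = ("cluster", og.cluster_group)
            else:
                key = ("single", og.og_id)
            units.setdefault(key, []).append(item)

        ctg = 0
        for key in sorted(units, key=repr):
            members = units[key]
            contig = f"{acc}_ctg{ctg:04d}"
            ctg += 1
            pos = int(rng.integers(2_000, 20_000))
            placed: list[GeneModel] = []
            kind = key[0]
            for mi, (og, is_par, cds) in enumerate(members):
                glen = len(cds)  # gene span == CDS length (intronless model)
                if kind == "pair" and len(members) == 2:
                    strand = "-" if mi == 0 else "+"
                    gap = int(rng.integers(1_000, 4_000))
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                    gap = int(rng.integers(2_000, 50_000))
                if mi > 0:
                    pos = placed[-1].end + gap
                gid = f"{acc}_g{gene_counter:05d}"
                gene_counter += 1
                flags = []
                if rng.random() < 0.02:
                    flags.append("truncated")
                if rng.random() < 0.01:
                    flags.append("pseudogene")
                prot = _translate(cds)
                gene = GeneModel(gene_id=gid, accession=acc, contig=contig,
                                 start=pos, end=pos + glen - 1, strand=strand,
                                 flags=flags, protein=prot, cds=cds)
                placed.append(gene)
                sim.genes.append(gene)
                sim.truth.true_og_of_gene[gid] = og.og_id

                # domain annotation
                arch = list(og.architecture)
                for (label, s, e) in og.domain_layout:
                    if label == "CC":
                        # coiled-coil comes from predictor tracks, 2-of-3
                        sim.domains.append(DomainInterval(gid, "CC", s, e,
                                                          "coils"))
                        sim.domains.append(DomainInterval(gid, "CC", s, e,
                                                          "paircoil"))
                        if rng.random() < 0.5:
                            sim.domains.append(DomainInterval(
                                gid, "CC", s, e, "nlrparser"))
                    else:
                        sim.domains.append(DomainInterval(gid, label, s, e,
                                                          "pfam"))
                if og_id_label[og.og_id] is not None:
                    lbl = og_id_label[og.og_id]
                    sim.domains.append(DomainInterval(
                        gid, lbl, max(1, P - 29), P, "pfam"))
                    arch.append(lbl)
                    id_assigned += 1
                sim.truth.true_architecture[gid] = tuple(arch)

            if kind == "pair" and len(placed) == 2:
                sim.truth.true_pairs.append(
                    (placed[0].gene_id, placed[1].gene_id))
            if len(placed) >= 2:
                sim.truth.true_clusters.append(
                    frozenset(g.gene_id for g in placed))
    return sim
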