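"""Placement of non-reference orthogroups by contig co-occurrence.

Orthogroups that lack an allele in the reference accession can still be
placed approximately: whenever such an OG shares contigs with a
reference-anchored OG (NLR or non-NLR) in enough accessions, the anchored
neighbor's reference interval is borrowed. Edge weight is the number of
accessions in which the two OGs co-occur on a contig — counted once per
accession even when an accession has several such contigs, since the
support threshold is phrased in accessions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .models import GeneModel


@dataclass(frozen=True)
class ReferenceInterval:
    chrom: str
    start: int
    end: int

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def build_cooccurrence(genes: list[GeneModel],
                       og_of_gene: dict[str, str],
                       og_attrs: dict[str, dict] | None = None) -> nx.Graph:
    """OG co-occurrence graph over contigs.

    ``og_of_gene`` maps gene ids to OG ids (singletons may be omitted).
    Node attributes (``size``, ``is_nlr``, ``reference_interval``) are taken
    from ``og_attrs`` when given. Edge weight = number of accessions with
    both OGs on one contig.
    """
    contig_ogs: defaultdict[tuple[str, str], set[str]] = defaultdict(set)
    for g in genes:
        og = og_of_gene.get(g.gene_id)
        if og is not None:
            contig_ogs[(g.accession, g.contig)].add(og)

    pair_accessions: defaultdict[frozenset, set[str]] = defaultdict(set)
    for (acc, _contig), ogs in contig_ogs.items():
        ogs = sorted(ogs)
        for i, a in enumerate(ogs):
            for b in ogs[i + 1:]:
                pair_accessions[frozenset((a, b))].add(acc)

    G = nx.Graph()
    for og in set(og_of_gene.values()):
        attrs = (og_attrs or {}).get(og, {})
        G.add_node(og, **attrs)
    for key, accs in pair_accessions.items():
        a, b = sorted(key)
        G.add_edge(a, b, weight=len(accs))
    return G


def subnetworks(graph: nx.Graph, min_accessions: int = 10) -> list[nx.Graph]:
    """Connected components (>= 2 nodes) of the graph after dropping edges
    supported by fewer than ``min_accessions`` accessions."""
    if min_accessions < 1:
        raise ValueError("threshold must be >= 1")
    H = nx.Graph()
    H.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        if data.get("weight", 0) >= min_accessions:
            H.add_edge(a, b, **data)
    comps = []
    for comp in nx.connected_components(H):
        if len(comp) >= 2:
            comps.append(H.subgraph(comp).copy())
    return comps


def anchor_nonreference(components: list[nx.Graph],
                        min_accessions: int = 10) -> pd.DataFrame:
    """Anchor non-reference OGs to the reference interval of their
    highest-weight anchored neighbor (within the thresholded subnetwork);
    ties resolve to the smallest genomic coordinate. OGs in components
    without any anchored node stay unanchored (absent from the table).
    """
    rows = []
    for comp in components:
        anchored = {n for n, d in comp.nodes(data=True)
                    if d.get("reference_interval") is not None}
        if not anchored:
            continue
        for og in sorted(comp.nodes):
            if og in anchored:
                continue
            cands = []
            for nb in comp.neighbors(og):
                if nb in anchored:
                    ival = comp.nodes[nb]["reference_interval"]
                    w = comp[og][nb].get("weight", 0)
                    cands.append((w, ival, nb))
            if not cands:
                continue
            cands.sort(key=lambda t: (-t[0], t[1].chrom, t[1].start, t[2]))
            w, ival, nb = cands[0]
            if w >= min_accessions:
                rows.append((og, str(ival), nb, w))
    return pd.DataFrame(rows, columns=[
        "og_id", "reference_interval", "supporting_neighbor", "edge_weight"])
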