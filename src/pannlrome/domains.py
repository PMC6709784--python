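"""NLR identification, class assignment and domain-architecture analysis.

An NLR must carry at least one of the NB, TIR or RPW8 domains — LRR or
coiled-coil signals alone are not sufficient. Coiled-coil calls are refined
by a majority vote across three predictor tracks (Coils-, Paircoil2- and
NLR-parser-style), keeping residues supported by at least two distinct
predictors. Classes form a partition by precedence: a TIR domain makes a
TNL; otherwise RPW8 makes an RNL; otherwise CC together with NB makes a CNL;
otherwise NB alone makes an NL.

An architecture is the collapsed protein domain set: repeated or re-ordered
occurrences of a domain do not create new architectures. Non-canonical
domains inside NLRs are integrated domains (IDs); IDs seen in only one gene
model of one accession are flagged as singletons and excluded from
architecture-novelty analyses to limit annotation artifacts.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .models import CANONICAL_DOMAINS, DomainInterval, PFAM_TO_CANONICAL

_CC_SOURCES = ("coils", "paircoil", "nlrparser")


def canonicalize_label(label: str) -> str:
    """Map Pfam accessions onto canonical tokens; pass other labels through."""
    return PFAM_TO_CANONICAL.get(label, label)


def identify_nlr(domains: list[DomainInterval]) -> bool:
    """True iff the gene carries at least one NB, TIR or RPW8 domain."""
    labels = {canonicalize_label(d.label) for d in domains}
    return bool(labels & {"NB", "TIR", "RPW8"})


def vote_cc(cc_calls: dict[str, list[tuple[int, int]]],
            min_votes: int = 2) -> list[tuple[int, int]]:
    """Consensus coiled-coil intervals by residue-wise predictor vote.

    ``cc_calls`` maps predictor name -> list of (start, end) residue
    intervals (1-based inclusive). A residue is accepted when covered by at
    least ``min_votes`` distinct predictors; accepted residues are merged
    into maximal intervals. Adding intervals can only grow the consensus.
    """
    votes: defaultdict[int, set[str]] = defaultdict(set)
    for source, intervals in cc_calls.items():
        for (s, e) in intervals:
            for r in range(s, e + 1):
                votes[r].add(source)
    accepted = sorted(r for r, srcs in votes.items() if len(srcs) >= min_votes)
    out: list[tuple[int, int]] = []
    for r in accepted:
        if out and r == out[-1][1] + 1:
            out[-1] = (out[-1][0], r)
        else:
            out.append((r, r))
    return out


def assign_class(collapsed_set: set[str]) -> str:
    """Class by precedence TIR > RPW8 > CC+NB > NB."""
    s = {canonicalize_label(x) for x in collapsed_set}
    if "TIR" in s:
        return "TNL"
    if "RPW8" in s:
        return "RNL"
    if "CC" in s and "NB" in s:
        return "CNL"
    if "NB" in s:
        return "NL"
    raise ValueError(
        f"domain set {sorted(s)} matches no NLR class (gene should not have "
        "passed identify_nlr)")


def collapse_architecture(ordered_domains: list[str]) -> frozenset[str]:
    """The collapsed architecture key: duplicate- and order-independent."""
    return frozenset(canonicalize_label(d) for d in ordered_domains)


def architecture_key(collapsed: frozenset[str]) -> str:
    """Stable string form of a collapsed architecture (sorted, '+'-joined)."""
    return "+".join(sorted(collapsed))


def gene_architectures(domains: list[DomainInterval],
                       cc_vote_min: int = 2) -> pd.DataFrame:
    """Per-gene NLR call, class and architecture from a domain table.

    Coiled-coil predictor tracks are first reduced to consensus CC intervals
    by :func:`vote_cc`; all other sources contribute their intervals
    directly. Returns a DataFrame indexed by gene_id with columns
    ``is_nlr``, ``class_label``, ``ordered``, ``collapsed``, ``has_id``.
    """
    by_gene: defaultdict[str, list[DomainInterval]] = defaultdict(list)
    for d in domains:
        by_gene[d.gene_id].append(d)

    rows = []
    for gene_id, dlist in by_gene.items():
        cc_calls: dict[str, list[tuple[int, int]]] = {}
        effective: list[DomainInterval] = []
        for d in dlist:
            if d.source in _CC_SOURCES:
                cc_calls.setdefault(d.source, []).append((d.start, d.end))
            else:
                effective.append(DomainInterval(
                    gene_id, canonicalize_label(d.label), d.start, d.end,
                    d.source))
        for (s, e) in vote_cc(cc_calls, min_votes=cc_vote_min):
            effective.append(DomainInterval(gene_id, "CC", s, e, "ccvote"))

        effective.sort(key=lambda d: (d.start, d.end))
        ordered = [d.label for d in effective]
        collapsed = collapse_architecture(ordered)
        is_nlr = identify_nlr(effective)
        cls = assign_class(collapsed) if is_nlr else None
        has_id = bool(collapsed - CANONICAL_DOMAINS)
        rows.append((gene_id, is_nlr, cls, tuple(ordered), collapsed, has_id))

    df = pd.DataFrame(
        rows, columns=["gene_id", "is_nlr", "class_label", "ordered",
                       "collapsed", "has_id"])
    return df.set_index("gene_id")


def find_integrated_domains(architectures: pd.DataFrame,
                            accession_of_gene: dict[str, str]) -> pd.DataFrame:
    """Tabulate integrated domains across all NLR gene models.

    Every non-canonical domain label in an NLR counts as an ID. IDs found in
    exactly one gene model of exactly one accession are flagged
    ``singleton`` and should be excluded from architecture-novelty counts.
    Returns a DataFrame with columns id_label, n_genes, n_accessions,
    singleton.
    """
    genes_of_id: defaultdict[str, set[str]] = defaultdict(set)
    for gene_id, row in architectures.iterrows():
        if not row["is_nlr"]:
            continue
        for label in row["collapsed"] - CANONICAL_DOMAINS:
            genes_of_id[label].add(gene_id)

    rows = []
    for label in sorted(genes_of_id):
        genes = genes_of_id[label]
        accs = {accession_of_gene[g] for g in genes}
        singleton = len(genes) == 1 and len(accs) == 1
        rows.append((label, len(genes), len(accs), singleton))
    return pd.DataFrame(
        rows, columns=["id_label", "n_genes", "n_accessions", "singleton"])


def architecture_intersections(
        sets: dict[str, set[frozenset[str]]]) -> pd.DataFrame:
    """UpSet-style membership of each architecture key across named sets.

    Returns one row per distinct architecture with a boolean column per set;
    intersection-cell counts therefore sum to the number of distinct keys.
    """
    names = list(sets)
    universe = sorted({architecture_key(a) for s in sets.values() for a in s})
    keyed = {name: {architecture_key(a) for a in s}
             for name, s in sets.items()}
    rows = [[key] + [key in keyed[name] for name in names]
            for key in universe]
    return pd.DataFrame(rows, columns=["architecture"] + names)
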