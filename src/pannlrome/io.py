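"""Readers and writers for the standard formats the pipeline exchanges.

GFF3 files are 1-based inclusive with ``gene``/``mRNA``/``CDS`` features and
curation flags carried in the gene's ``note=`` attribute as comma-separated
tokens. FASTA goes through Biopython; trees through scikit-bio Newick.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DomainInterval, GeneModel


class FormatError(ValueError):
    """A malformed record, reported with file/line context."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.contig, x.start, x.gene_id)):
            attrs = f"ID={g.gene_id}"
            if g.flags:
                attrs += f";note={','.join(g.flags)}"
            fh.write(f"{g.contig}\tpannlrome\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            fh.write(f"{g.contig}\tpannlrome\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n")
            fh.write(f"{g.contig}\tpannlrome\tCDS\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t0\tID={g.gene_id}.1.cds;"
                     f"Parent={g.gene_id}.1\n")


def read_gff3(path, accession: str | None = None) -> list[GeneModel]:
    """Read gene models from a GFF3 file (gene features only; sequences are
    attached separately from FASTA)."""
    path = Path(path)
    if accession is None:
        accession = path.stem
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if "ID" not in attr:
                raise FormatError(f"{path}:{lineno}: gene without ID")
            flags = attr.get("note", "")
            genes.append(GeneModel(
                gene_id=attr["ID"], accession=accession, contig=contig,
                start=start_i, end=end_i, strand=strand,
                flags=[f for f in flags.split(",") if f]))
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------

DOMAIN_COLUMNS = ["gene_id", "label", "start", "end", "source"]


def write_domains_tsv(domains: list[DomainInterval], path) -> None:
    df = pd.DataFrame(
        [(d.gene_id, d.label, d.start, d.end, d.source) for d in domains],
        columns=DOMAIN_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_domains_tsv(path) -> list[DomainInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "label": str,
                                            "source": str})
    missing = set(DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [DomainInterval(r.gene_id, r.label, int(r.start), int(r.end),
                           r.source)
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path) -> None:
    """Write a scikit-bio TreeNode with branch lengths and supports."""
    tree.write(str(path), format="newick")


def read_newick(path):
    from skbio import TreeNode
    tree = TreeNode.read(str(path), format="newick")
    tree.assign_supports()
    return tree
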