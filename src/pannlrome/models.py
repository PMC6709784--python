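"""Core data containers shared across the pipeline stages.

Coordinates follow the GFF3 convention at file boundaries (1-based,
inclusive); in-memory intervals on sequences use the same convention so that
round-trips through GFF3/TSV are identity maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CANONICAL_DOMAINS = frozenset({"NB", "TIR", "RPW8", "LRR", "CC"})

#: Pfam accessions mapped onto canonical tokens before any classification
#: logic runs. All LRR-family models collapse onto a single LRR token.
PFAM_TO_CANONICAL = {
    "PF00931": "NB",
    "PF01582": "TIR",
    "PF05659": "RPW8",
    "PF00560": "LRR",
    "PF07725": "LRR",
    "PF13306": "LRR",
    "PF13855": "LRR",
}

NLR_CLASSES = ("TNL", "CNL", "RNL", "NL")


@dataclass
class GeneModel:
    """One annotated gene: location, strand, curation flags and sequences."""

    gene_id: str
    accession: str
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'
    flags: list[str] = field(default_factory=list)
    protein: str = ""
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainInterval:
    """A predicted protein domain on one gene, in residue coordinates."""

    gene_id: str
    label: str
    start: int  # 1-based inclusive residue
    end: int
    source: str = "pfam"  # pfam | coils | paircoil | nlrparser

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"{self.gene_id}: empty domain label")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}:{self.label}: start {self.start} > end {self.end}"
            )


class CodonAlignment:
    """A gap-aware codon alignment.

    Rows are gene ids; every row has the same length, a multiple of 3, and
    removing gaps from a row recovers the gene's CDS. ``column_domains``
    optionally carries one domain label per codon column (majority vote over
    the members' domain annotations).
    """

    def __init__(self, ids, seqs, column_domains=None):
        ids = list(ids)
        seqs = [str(s).upper() for s in seqs]
        if len(ids) != len(seqs):
            raise ValueError("ids and seqs differ in length")
        if len(seqs) == 0:
            raise ValueError("empty alignment")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("alignment rows differ in length")
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} not a multiple of 3")
        if column_domains is not None and len(column_domains) != L // 3:
            raise ValueError("column_domains length must equal codon count")
        self.ids = ids
        self.seqs = seqs
        self.column_domains = (
            list(column_domains) if column_domains is not None else None
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Alignment length in nucleotide columns."""
        return len(self.seqs[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def row(self, gene_id: str) -> str:
        return self.seqs[self.ids.index(gene_id)]

    def subset_rows(self, keep_ids) -> "CodonAlignment":
        keep = [i for i, g in enumerate(self.ids) if g in set(keep_ids)]
        return CodonAlignment(
            [self.ids[i] for i in keep],
            [self.seqs[i] for i in keep],
            self.column_domains,
        )

    def subset_codon_columns(self, codon_indices) -> "CodonAlignment":
        idx = list(codon_indices)
        seqs = [
            "".join(s[3 * c: 3 * c + 3] for c in idx) for s in self.seqs
        ]
        doms = (
            [self.column_domains[c] for c in idx]
            if self.column_domains is not None
            else None
        )
        return CodonAlignment(list(self.ids), seqs, doms)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CodonAlignment)
            and self.ids == other.ids
            and self.seqs == other.seqs
        )

    def __repr__(self) -> str:
        return f"<CodonAlignment n={self.n} L={self.length}>"


@dataclass
class Orthogroup:
    """A cluster of genes across accessions."""

    og_id: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RefinedOG(Orthogroup):
    """An orthogroup after refinement, with its metadata annotations."""

    og_type: str | None = None          # cloud | shell | core
    class_label: str | None = None      # majority vote over members
    clustered_flag: bool = False        # majority of members in 200-kb clusters
    paired_flag: bool = False           # majority of members head-to-head paired
    id_flag: bool = False               # any member carries an integrated domain
    mean_branch_length: float = 0.0     # tree branch-length sum / OG size
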