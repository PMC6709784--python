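"""Configuration objects for the simulator, the clustering stage and the
full pipeline.

Thresholds default to the values used throughout the analysis: orthogroups
need at least two members; Markov-clustering inflation is 1.5; orthogroups
with fewer than 13 members are "cloud", more than 51 "core"; physical NLR
clusters chain genes within 200 kb; head-to-head pairs may be at most 10 kb
apart; co-occurrence edges need support from at least 10 accessions; at most
5% of occupied accessions may carry within-OG duplicates before an OG is
split; flag enrichment reports q < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# (presence probability, number of OGs): a scaled-down core/shell/cloud
# spectrum with roughly the 23% / 31% / 46% core:shell:cloud proportions seen
# in real species-wide NLR panels.
DEFAULT_OG_SPECTRUM: list[tuple[float, int]] = [
    (0.95, 34),   # core-like: present in nearly every accession
    (0.50, 46),   # shell-like
    (0.12, 70),   # cloud-like: private or rare
]


@dataclass
class SimulationConfig:
    """Ground-truthed synthetic pan-NLRome parameters.

    ``og_spectrum`` lists (presence_probability, n_ogs) tuples; each OG is
    present in each accession independently with its probability.
    ``per_og_theta`` is the scaled mutation rate per site used for the
    coalescent sequence families.
    """

    n_accessions: int = 64
    og_spectrum: list[tuple[float, int]] = field(
        default_factory=lambda: list(DEFAULT_OG_SPECTRUM)
    )
    per_og_theta: float = 0.02
    gene_conversion_rate: float = 0.05   # events per gene
    conversion_tract_mean: float = 120.0  # bases
    paralog_og_fraction: float = 0.05
    id_gene_fraction: float = 0.05
    pair_fraction: float = 0.10
    cluster_window: int = 200_000
    protein_length: int = 150  # residues per simulated NLR
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be >= 2")
        if not self.og_spectrum:
            raise ValueError("og_spectrum must be non-empty")
        for p, n in self.og_spectrum:
            if not 0 < p <= 1:
                raise ValueError(
                    f"spectrum presence probability {p} not in (0, 1]"
                )
            if n < 0:
                raise ValueError("spectrum OG count must be >= 0")
        for name in (
            "gene_conversion_rate", "paralog_og_fraction",
            "id_gene_fraction", "pair_fraction",
        ):
            v = getattr(self, name)
            if name != "gene_conversion_rate" and not 0 <= v <= 1:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if self.per_og_theta < 0:
            raise ValueError("per_og_theta must be >= 0")
        if self.protein_length < 30:
            raise ValueError("protein_length must be >= 30 residues")


@dataclass
class ClusteringConfig:
    """Similarity-graph and Markov-clustering parameters."""

    inflation: float = 1.5
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tolerance: float = 1e-6
    min_og_size: int = 2
    score_floor: float = 50.0  # minimal alignment score kept as an edge
    kmer_prefilter: int = 4    # shared k-mer length; 0 disables the prefilter
    min_shared_kmers: int = 3

    def validate(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.min_og_size < 2:
            raise ValueError("min_og_size must be >= 2")


@dataclass
class PipelineConfig:
    """Aggregated thresholds for the end-to-end pipeline."""

    cloud_max: int = 12
    shell_max: int = 51
    paralog_accession_fraction: float = 0.05
    cluster_window: int = 200_000
    pair_max_separation: int = 10_000
    cooccurrence_min_accessions: int = 10
    mcl_inflation: float = 1.5
    og_min_size: int = 2
    rarefaction_reps_og: int = 1000
    rarefaction_reps_div: int = 100
    cc_vote_min: int = 2
    enrichment_q_max: float = 0.1
    tree_bootstrap_reps: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.cloud_max >= self.shell_max:
            raise ValueError("cloud_max must be < shell_max")
        for name in (
            "cluster_window", "pair_max_separation",
            "cooccurrence_min_accessions", "og_min_size",
            "rarefaction_reps_og", "rarefaction_reps_div", "cc_vote_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
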