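"""End-to-end pan-NLRome construction: simulate (or load) -> classify ->
cluster -> refine -> stats -> saturate -> anchor -> report.

Each stage logs its input/output gene and OG counts so the partition
invariants (no gene silently lost) can be audited from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering, domains as dom, refinement as ref
from .anchoring import ReferenceInterval, anchor_nonreference, build_cooccurrence, subnetworks
from .config import ClusteringConfig, PipelineConfig, SimulationConfig
from .models import CodonAlignment, GeneModel, Orthogroup, RefinedOG
from .popgen import neutrality_stats
from .saturation import rarefy_ogs, saturation_point
from .simulate import SimulatedPanNLRome, simulate_pannlrome

log = logging.getLogger("pannlrome")


@dataclass
class PipelineResult:
    genes: list[GeneModel]
    architectures: pd.DataFrame
    ogs: list[RefinedOG]
    singletons: list[str]
    member_status: dict[str, str]
    alignments: dict[str, CodonAlignment]
    stats: pd.DataFrame
    presence: pd.DataFrame
    saturation_curve: pd.DataFrame
    saturation_size: int | None
    anchoring: pd.DataFrame
    truth: object | None = None
    clusters: list[set[str]] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def og_of_gene(self) -> dict[str, str]:
        return {g: og.og_id for og in self.ogs for g in og.members}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        arch = self.architectures.copy()
        arch["ordered"] = arch["ordered"].map(lambda t: ",".join(t))
        arch["collapsed"] = arch["collapsed"].map(
            lambda s: "+".join(sorted(s)))
        arch.to_csv(outdir / "architectures.tsv", sep="\t")
        rows = [(og.og_id, g, self.member_status.get(g, "kept"))
                for og in self.ogs for g in og.members]
        pd.DataFrame(rows, columns=["og_id", "gene_id", "status"]).to_csv(
            outdir / "og_members.tsv", sep="\t", index=False)
        meta = pd.DataFrame(
            [(og.og_id, og.size, og.og_type, og.class_label,
              og.clustered_flag, og.paired_flag, og.id_flag,
              og.mean_branch_length) for og in self.ogs],
            columns=["og_id", "size", "og_type", "class_label", "clustered",
                     "paired", "has_id", "mean_branch_length"])
        meta.to_csv(outdir / "og_metadata.tsv", sep="\t", index=False)
        self.stats.to_csv(outdir / "og_stats.tsv", sep="\t", index=False)
        self.presence.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        self.saturation_curve.to_csv(
            outdir / "saturation.tsv", sep="\t", index=False)
        self.anchoring.to_csv(outdir / "anchoring.tsv", sep="\t", index=False)
        with open(outdir / "singletons.txt", "w") as fh:
            fh.write("\n".join(self.singletons) + "\n")


def presence_matrix(ogs: list[Orthogroup],
                    accession_of_gene: dict[str, str],
                    accessions: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=[og.og_id for og in ogs],
                       columns=accessions, dtype=int)
    for og in ogs:
        for g in og.members:
            mat.loc[og.og_id, accession_of_gene[g]] += 1
    return mat


def run_pipeline(sim_config: SimulationConfig | None = None,
                 config: PipelineConfig | None = None,
                 sim: SimulatedPanNLRome | None = None,
                 outdir=None) -> PipelineResult:
    """Run the full pipeline on a simulated pan-NLRome.

    Either pass a ``SimulationConfig`` (a dataset is generated) or an
    already-simulated ``sim`` bundle. Reports are written to ``outdir``
    when given.
    """
    config = config or PipelineConfig()
    config.validate()

    # -- stage 1: data ------------------------------------------------------
    if sim is None:
        if sim_config is None:
            raise ValueError("need sim_config or sim")
        sim = simulate_pannlrome(sim_config)
    genes = sim.genes
    accession_of_gene = {g.gene_id: g.accession for g in genes}
    log.info("stage=simulate genes=%d accessions=%d",
             len(genes), len(sim.accessions))

    # -- stage 2: classification --------------------------------------------
    arch = dom.gene_architectures(sim.domains, cc_vote_min=config.cc_vote_min)
    nlr_ids = set(arch.index[arch["is_nlr"]])
    log.info("stage=classify nlr=%d non_nlr=%d",
             len(nlr_ids), len(genes) - len(nlr_ids))

    # -- stage 3: clustering ------------------------------------------------
    proteins = {g.gene_id: g.protein for g in genes if g.gene_id in nlr_ids}
    ccfg = ClusteringConfig(inflation=config.mcl_inflation,
                            min_og_size=config.og_min_size)
    edges = clustering.pairwise_similarity(proteins, ccfg)
    typed = clustering.classify_edges(edges, accession_of_gene)
    clusters = clustering.mcl_cluster(typed, ccfg, genes=sorted(proteins))
    ogs0, singletons = clustering.form_ogs(
        clusters, ccfg.min_og_size, all_genes=sorted(proteins))
    log.info("stage=cluster edges=%d typed=%d ogs=%d singletons=%d",
             len(edges), len(typed), len(ogs0), len(singletons))

    # -- stage 4: refinement ------------------------------------------------
    cds_of_gene = {g.gene_id: g.cds for g in genes}
    refined: list[Orthogroup] = []
    status: dict[str, str] = {}
    alignments: dict[str, CodonAlignment] = {}
    for og in ogs0:
        if og.size <= 4:
            refined.append(og)
            status.update({g: "kept" for g in og.members})
            if og.size >= 2:
                msa = ref.align_og({g: proteins[g] for g in og.members})
                alignments[og.og_id] = ref.protein_to_codon(msa, cds_of_gene)
            continue
        msa = ref.align_og({g: proteins[g] for g in og.members})
        outliers = ref.detect_outliers(msa, seed=config.seed)
        for g in outliers:
            status[g] = "outlier"
        kept = {g: msa[g] for g in msa if g not in outliers}
        if len(kept) < 2:
            singletons.extend(kept)
            continue
        if len(kept) < len(msa):
            kept = ref.align_og({g: proteins[g] for g in kept})
        caln = ref.protein_to_codon(kept, cds_of_gene)
        gtree = ref.build_tree(caln, bootstrap_reps=config.tree_bootstrap_reps,
                               seed=config.seed)
        dups = ref.detect_duplications(gtree, accession_of_gene)
        sub_ogs, og_status = ref.refine_og(
            Orthogroup(og.og_id, sorted(kept)), gtree, dups,
            accession_of_gene, config.paralog_accession_fraction)
        for g, st in og_status.items():
            status.setdefault(g, st)
            if st == "singleton":
                singletons.append(g)
        for sog in sub_ogs:
            refined.append(sog)
            alignments[sog.og_id] = caln.subset_rows(sog.members)
    refined = [og for og in refined if og.size >= config.og_min_size]
    log.info("stage=refine ogs=%d singletons=%d", len(refined),
             len(singletons))

    # -- stage 5: physical annotation + OG metadata -------------------------
    clustered_flag, phys_clusters = ref.detect_physical_clusters(
        genes, window=config.cluster_window)
    pairs = ref.detect_pairs(genes, max_separation=config.pair_max_separation)
    paired_flag = {g.gene_id: False for g in genes}
    for a, b in pairs:
        paired_flag[a] = True
        paired_flag[b] = True
    class_of_gene = arch["class_label"].to_dict()
    has_id = arch["has_id"].to_dict()
    annotated = [
        ref.annotate_og(og, class_of_gene, clustered_flag, paired_flag,
                        has_id, cloud_max=config.cloud_max,
                        shell_max=config.shell_max)
        for og in refined]
    log.info("stage=annotate clusters=%d pairs=%d", len(phys_clusters),
             len(pairs))

    # -- stage 6: diversity statistics --------------------------------------
    stat_rows = []
    for og in annotated:
        aln = alignments.get(og.og_id)
        if aln is None or aln.n < 2:
            continue
        st = neutrality_stats(aln)
        stat_rows.append({"og_id": og.og_id, **st.as_dict()})
    stats = pd.DataFrame(stat_rows)
    log.info("stage=stats ogs=%d", len(stats))

    # -- stage 7: saturation ------------------------------------------------
    pres = presence_matrix(annotated, accession_of_gene, sim.accessions)
    curve = rarefy_ogs(pres, reps=config.rarefaction_reps_og,
                       seed=config.seed)
    sat = saturation_point(curve, target=0.95)
    log.info("stage=saturate point95=%s", sat)

    # -- stage 8: anchoring -------------------------------------------------
    # the first accession plays the reference: OGs with a member there are
    # anchored at that member's contig position
    ref_acc = sim.accessions[0]
    og_of_gene = {g: og.og_id for og in annotated for g in og.members}
    og_attrs: dict[str, dict] = {}
    for og in annotated:
        ival = None
        for g in og.members:
            if accession_of_gene[g] == ref_acc:
                gm = next(x for x in genes if x.gene_id == g)
                ival = ReferenceInterval(gm.contig, gm.start, gm.end)
                break
        og_attrs[og.og_id] = {"size": og.size, "is_nlr": True,
                              "reference_interval": ival}
    graph = build_cooccurrence(genes, og_of_gene, og_attrs)
    comps = subnetworks(graph, config.cooccurrence_min_accessions)
    anchors = anchor_nonreference(comps, config.cooccurrence_min_accessions)
    log.info("stage=anchor subnetworks=%d anchored=%d", len(comps),
             len(anchors))

    result = PipelineResult(
        genes=genes, architectures=arch, ogs=annotated,
        singletons=sorted(set(singletons)), member_status=status,
        alignments=alignments, stats=stats, presence=pres,
        saturation_curve=curve, saturation_size=sat, anchoring=anchors,
        truth=sim.truth, clusters=phys_clusters, pairs=pairs)
    if outdir is not None:
        result.write(outdir)
        log.info("stage=report outdir=%s", outdir)
    return result
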