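"""End-to-end orchestration: similarity -> families -> composites -> origins
-> downstream statistics, with a planted-truth evaluation mode.

The pipeline mirrors the detection funnel: archaeal all-vs-all alignment,
similarity-network families, haloarchaeal-exclusivity filtering (including
the full-length bacterial screen), per-gene component detection and
clustering, taxonomic origin assignment (rank rule, optional distance-tree
clan screen), composite classification, and the residency/optimization
statistics (presence/absence clustering, Mantel test, isoelectric points).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import __version__
from .composites import (
    CompositeFamily,
    CompositeGene,
    DomainAnnotation,
    call_composite,
    cluster_components,
    components_table,
    composites_table,
    detect_components,
    group_composite_families,
    merge_component_families,
)
from .families import (
    GeneFamily,
    NetworkConfig,
    build_family_graph,
    connected_components,
    families_table,
    filter_halo_exclusive,
)
from .origins import (
    TIP_ARC,
    TIP_BAC,
    TIP_COMPONENT,
    TIP_HALO,
    TaxonomyIndex,
    assign_component_origin,
    assign_phylum,
    classify_composite,
    origins_table,
    tree_origin_screen,
)
from .simulate import SimConfig, SimulatedCorpus, simulate_proteome_set
from .similarity import AlignmentHit, ScoringScheme, all_vs_all, local_align
from .stats import (
    build_presence_matrix,
    clade_distance_matrix,
    compare_distributions,
    family_identity_summary,
    jaccard_distance_matrix,
    jaccard_linkage,
    linkage_table,
    mantel_test,
    pi_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a run produced, plus the JSON-able report."""

    taxonomy: pd.DataFrame
    genome_of: dict[str, str]
    sequences: dict[str, str]
    families: list[GeneFamily]
    candidates: list[GeneFamily]
    genes: list[CompositeGene]
    composite_families: list[CompositeFamily]
    archaeal_hits: list[AlignmentHit]
    candidate_bacterial_hits: list[AlignmentHit]
    presence_matrix: pd.DataFrame | None
    report: dict

    def write_outputs(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        families_table(self.families, self.genome_of).to_csv(
            outdir / "families.tsv", sep="\t", index=False
        )
        components_table(self.genes).to_csv(
            outdir / "components.tsv", sep="\t", index=False
        )
        composites_table(self.genes).to_csv(
            outdir / "composites.tsv", sep="\t", index=False
        )
        origins_table(self.composite_families).to_csv(
            outdir / "origins.tsv", sep="\t", index=False
        )
        if self.presence_matrix is not None:
            self.presence_matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)


def _linkage_to_newick(Z, labels) -> str:
    """SciPy linkage -> Newick with a fixed support of 100 on internal edges.

    The trees are deterministic distance trees, so every internal edge is
    annotated with full support.
    """
    n = len(labels)
    nodes: dict[int, str] = {i: f"'{labels[i]}'" for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    for k, (left, right, height, _size) in enumerate(Z):
        li, ri = int(left), int(right)
        bl_l = (height - heights[li]) / 2 or 0.01
        bl_r = (height - heights[ri]) / 2 or 0.01
        nodes[n + k] = f"({nodes[li]}:{bl_l:.4f},{nodes[ri]}:{bl_r:.4f})100"
        heights[n + k] = height
    return nodes[n + len(Z) - 1] + ";"


def component_identity_tree(
    component_family,
    sequences: dict[str, str],
    scheme: ScoringScheme,
    taxindex: TaxonomyIndex,
    max_partners: int = 8,
) -> tuple[str, dict[str, str]]:
    """Distance tree over a component fragment and its partner proteins.

    Pairwise distances are 1 - fractional identity of the best local
    alignment (1.0 when no alignment exists); complete-linkage agglomeration
    yields a deterministic tree whose tips are categorised for the clan
    screen.  This is the input-generation path for validating rank-rule
    origins on synthetic corpora, where inferred ML phylogenies are not part
    of the protocol.
    """
    comp = component_family.members[0]
    s, e = component_family.span
    fragment = sequences[comp.composite_protein_id][s - 1 : e]
    partners = component_family.partner_ids()[:max_partners]
    tip_seqs = {"COMPONENT": fragment}
    categories = {"COMPONENT": TIP_COMPONENT}
    for pid in partners:
        tip_seqs[pid] = sequences[pid]
        stratum = taxindex.stratum(pid)
        categories[pid] = {"HALO": TIP_HALO, "ARC": TIP_ARC, "BAC": TIP_BAC}[stratum]
    labels = list(tip_seqs)
    m = len(labels)
    dist = np.ones((m, m))
    np.fill_diagonal(dist, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            hits = local_align(tip_seqs[labels[i]], tip_seqs[labels[j]], scheme)
            if hits:
                dist[i, j] = dist[j, i] = 1.0 - hits[0].pct_identity / 100.0
    Z = hierarchy.linkage(squareform(dist), method="complete")
    return _linkage_to_newick(Z, labels), categories


def calls_consistent(rank_origin: str, tree_origin: str) -> bool:
    """Whether two origin calls are consistent rather than conflicting.

    Exact agreement is consistent; so is a PROK call on either side (a
    resolution difference, not a conflict) and HALO-vs-ARC (the clan screen
    has no haloarchaeal-exclusive outcome).  ARC against BAC is a conflict.
    """
    if rank_origin == tree_origin:
        return True
    if "PROK" in (rank_origin, tree_origin):
        return True
    return {rank_origin, tree_origin} == {"HALO", "ARC"}


def run_pipeline(
    sequences: dict[str, str],
    taxonomy: pd.DataFrame,
    genome_of: dict[str, str],
    config: NetworkConfig | None = None,
    scheme: ScoringScheme | None = None,
    domain_annotations: list[DomainAnnotation] | None = None,
    cog_of: dict[str, str] | None = None,
    tree_screen: bool = True,
    mantel_permutations: int = 999,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on an in-memory corpus and assemble the report."""
    config = config or NetworkConfig()
    lengths = {pid: len(s) for pid, s in sequences.items()}
    if scheme is None:
        scheme = ScoringScheme(db_residues=max(sum(lengths.values()), 1))
    taxindex = TaxonomyIndex(taxonomy, genome_of)
    domains_by_protein: dict[str, list[DomainAnnotation]] = {}
    for dom in domain_annotations or []:
        domains_by_protein.setdefault(dom.protein_id, []).append(dom)

    bact_genomes = set(taxonomy.loc[taxonomy.domain == "Bacteria", "genome_id"])
    arc_seqs = {p: s for p, s in sequences.items() if genome_of[p] not in bact_genomes}
    bact_seqs = {p: s for p, s in sequences.items() if genome_of[p] in bact_genomes}

    # similarity stage: archaeal all-vs-all, bacterial all-vs-all (for
    # partner-family resolution of bacterial hits)
    arc_hits = all_vs_all(arc_seqs, scheme=scheme, evalue_max=config.evalue_max)
    bact_internal = all_vs_all(bact_seqs, scheme=scheme, evalue_max=config.evalue_max) \
        if bact_seqs else []

    # family stage
    logger.info("similarity: %d archaeal hits, %d bacterial-internal hits",
                len(arc_hits), len(bact_internal))
    graph = build_family_graph(arc_hits, {p: lengths[p] for p in arc_seqs}, config)
    families = connected_components(graph, genome_of)
    logger.info("families: %d connected components over %d archaeal proteins",
                len(families), len(arc_seqs))
    bact_graph = build_family_graph(
        bact_internal, {p: lengths[p] for p in bact_seqs}, config
    ) if bact_seqs else None
    bact_families = connected_components(bact_graph, genome_of) if bact_graph else []
    family_of: dict[str, str] = {}
    for fam in families:
        for pid in fam.members:
            family_of[pid] = fam.family_id
    for fam in bact_families:
        for pid in fam.members:
            family_of[pid] = "B" + fam.family_id

    # pre-screen candidates (halo-only, enough genomes) before paying for the
    # bacterial comparison, then apply the full filter including the screen
    halo_genomes = set(taxonomy.loc[taxonomy.halo_flag, "genome_id"])
    prelim = [
        f for f in families
        if {genome_of[m] for m in f.members} <= halo_genomes
        and len({genome_of[m] for m in f.members}) >= config.min_halo_genomes
    ]
    prelim_members = {m for f in prelim for m in f.members}
    cand_bact_hits = all_vs_all(
        {p: sequences[p] for p in prelim_members},
        bact_seqs,
        scheme=scheme,
        evalue_max=config.evalue_max,
    ) if prelim_members and bact_seqs else []
    candidates = filter_halo_exclusive(
        families, taxonomy, cand_bact_hits, lengths, genome_of, config
    )

    n_halo_only = sum(f.halo_only for f in families)
    n_enough_genomes = len(prelim)
    logger.info(
        "exclusivity funnel: %d families -> %d halo-only -> %d with >=%d "
        "genomes -> %d candidates after the bacterial screen",
        len(families), n_halo_only, n_enough_genomes,
        config.min_halo_genomes, len(candidates),
    )

    # composite stage
    hits_by_query: dict[str, list[AlignmentHit]] = {}
    for hit in arc_hits + cand_bact_hits:
        hits_by_query.setdefault(hit.query_id, []).append(hit)
    genes: list[CompositeGene] = []
    for fam in candidates:
        for pid in sorted(fam.members):
            comps = detect_components(
                pid, hits_by_query.get(pid, []), family_of, config
            )
            clustered = cluster_components(comps, config, id_prefix=f"{pid}:")
            merged = merge_component_families(clustered, config)
            genes.append(
                call_composite(pid, merged, domains_by_protein.get(pid, []), config)
            )
    composite_families = group_composite_families(genes, candidates)
    logger.info("composites: %d of %d candidate genes composite, %d families",
                sum(g.is_composite for g in genes), len(genes),
                len(composite_families))

    # origin stage
    n_consistent = n_screened = 0
    for comp_fam in composite_families:
        for gene in comp_fam.genes:
            for cf in gene.component_families:
                call = assign_component_origin(cf, taxindex, config)
                cf.origin = call.value
                if cf.origin == "BAC":
                    cf.phylum = assign_phylum(cf, taxindex, config)
                if tree_screen:
                    newick, categories = component_identity_tree(
                        cf, sequences, scheme, taxindex
                    )
                    cf.tree_origin = tree_origin_screen(newick, categories, config).value
                    n_screened += 1
                    n_consistent += calls_consistent(cf.origin, cf.tree_origin)
        comp_fam.class_label = classify_composite(comp_fam.origin_set())
        for gene in comp_fam.genes:
            if gene.is_composite:
                gene.class_label = comp_fam.class_label
        if cog_of is not None:
            from .stats import assign_family_cog

            comp_fam.cog_category = assign_family_cog(
                comp_fam.family.members, cog_of
            )

    class_counts = {"I": 0, "II": 0, "ChiC": 0}
    for comp_fam in composite_families:
        class_counts[comp_fam.class_label] += 1

    # statistics stage
    statistics: dict = {}
    presence = None
    halo_ids = sorted(halo_genomes)
    clade_of = dict(zip(taxonomy.genome_id, taxonomy.halo_clade))
    if composite_families and len(halo_ids) >= 3:
        presence = build_presence_matrix(composite_families, genome_of, halo_ids)
        if presence.shape[1] >= 2:
            Z, labels = jaccard_linkage(presence, axis="columns")
            statistics["linkage_n_merges"] = int(Z.shape[0])
        if len({clade_of[g] for g in halo_ids if clade_of.get(g)}) >= 2:
            try:
                r, p = mantel_test(
                    jaccard_distance_matrix(presence, axis="rows").values,
                    clade_distance_matrix(halo_ids, clade_of).values,
                    n_permutations=mantel_permutations,
                    seed=seed,
                )
                statistics["mantel_r"] = r
                statistics["mantel_p"] = p
            except ValueError:
                statistics["mantel_r"] = statistics["mantel_p"] = None

    composite_ids = {
        pid for f in composite_families for pid in f.family.members
    }
    pi_groups = {
        "composite": {p: sequences[p] for p in sorted(composite_ids)},
        "halo_other": {
            p: s for p, s in sorted(sequences.items())
            if genome_of[p] in halo_genomes and p not in composite_ids
        },
        "archaea_other": {
            p: s for p, s in sorted(arc_seqs.items())
            if genome_of[p] not in halo_genomes
        },
        "bacteria": dict(sorted(bact_seqs.items())),
    }
    pis = pi_table({g: seqs for g, seqs in pi_groups.items() if seqs})
    statistics["pi_median_by_group"] = (
        pis.groupby("group")["pI"].median().round(4).to_dict()
    )
    comp_pi = pis.loc[pis.group == "composite", "pI"]
    bact_pi = pis.loc[pis.group == "bacteria", "pI"]
    if len(comp_pi) and len(bact_pi):
        _u, p = compare_distributions(comp_pi, bact_pi, alternative="less")
        statistics["pi_composite_vs_bacteria_p"] = p

    identity_medians = []
    for comp_fam in composite_families:
        summary = family_identity_summary(comp_fam.family.members, arc_hits)
        if not np.isnan(summary["mean_identity"]):
            identity_medians.append(summary["mean_identity"])
    if identity_medians:
        statistics["median_family_identity"] = float(np.median(identity_medians))
    if tree_screen and n_screened:
        statistics["origin_concordance"] = n_consistent / n_screened

    report = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in asdict(config).items()},
        "counts": {
            "proteins": len(sequences),
            "archaeal_proteins": len(arc_seqs),
            "bacterial_proteins": len(bact_seqs),
            "families": len(families),
            "halo_only_families": n_halo_only,
            "halo_min_genome_families": n_enough_genomes,
            "halo_exclusive_candidates": len(candidates),
            "composite_genes": sum(g.is_composite for g in genes),
            "composite_families": len(composite_families),
            "class_counts": class_counts,
        },
        "families": [
            {
                "family_id": f.family_id,
                "class": f.class_label,
                "cog": f.cog_category,
                "n_members": len(f.family.members),
                "n_genomes": len({genome_of[m] for m in f.family.members}),
                "origins": sorted(f.origin_set()),
            }
            for f in composite_families
        ],
        "statistics": statistics,
    }
    return PipelineResult(
        taxonomy=taxonomy,
        genome_of=genome_of,
        sequences=sequences,
        families=families,
        candidates=candidates,
        genes=genes,
        composite_families=composite_families,
        archaeal_hits=arc_hits,
        candidate_bacterial_hits=cand_bact_hits,
        presence_matrix=presence,
        report=report,
    )


def run_simulated(
    sim_config: SimConfig,
    config: NetworkConfig | None = None,
    tree_screen: bool = True,
    mantel_permutations: int = 999,
) -> tuple[SimulatedCorpus, PipelineResult]:
    """Simulate a corpus and run the full pipeline on it."""
    corpus = simulate_proteome_set(sim_config)
    genome_of = {pid: rec.genome_id for pid, rec in corpus.proteins.items()}
    result = run_pipeline(
        corpus.sequences,
        corpus.taxonomy,
        genome_of,
        config=config,
        tree_screen=tree_screen,
        mantel_permutations=mantel_permutations,
        seed=sim_config.seed,
    )
    return corpus, result


def evaluate_against_truth(result: PipelineResult, truths) -> dict:
    """Recovery metrics of a simulated run against the planted truth.

    Per-class recall (planted composite recovered as a composite family),
    class-label accuracy on recovered composites, component-origin accuracy
    (interval-matched, unmatched counted as wrong), and the false-composite
    rate over candidate families without planted members.
    """
    truths = sorted(truths, key=lambda t: t.composite_id)
    if not truths:
        return {
            "recall": {}, "class_accuracy": None,
            "origin_accuracy": None, "false_composite_rate": None,
        }
    family_of_protein = {
        pid: fam for fam in result.candidates for pid in fam.members
    }
    comp_by_family = {f.family_id: f for f in result.composite_families}
    gene_by_protein = {g.protein_id: g for g in result.genes}

    planted_ids = {pid for t in truths for pid in t.member_ids}
    missing = planted_ids - set(result.sequences)
    if missing:
        raise KeyError(f"truth references unknown proteins {sorted(missing)[:3]}")

    per_class = {"I": [0, 0], "II": [0, 0], "ChiC": [0, 0]}  # recovered, total
    n_class_correct = n_recovered = 0
    origin_correct = origin_total = 0
    for truth in truths:
        per_class[truth.class_label][1] += 1
        fam = next(
            (family_of_protein[pid] for pid in truth.member_ids
             if pid in family_of_protein), None
        )
        comp_fam = comp_by_family.get(fam.family_id) if fam else None
        if comp_fam is None:
            origin_total += len(truth.components)
            continue
        per_class[truth.class_label][0] += 1
        n_recovered += 1
        n_class_correct += comp_fam.class_label == truth.class_label
        gene = next(
            (gene_by_protein[pid] for pid in truth.member_ids
             if pid in gene_by_protein), None
        )
        for tc in truth.components:
            origin_total += 1
            if gene is None:
                continue
            matched = None
            for cf in gene.component_families:
                s, e = cf.span
                overlap = max(0, min(e, tc.end) - max(s, tc.start) + 1)
                if overlap >= 0.5 * (tc.end - tc.start + 1):
                    matched = cf
                    break
            if matched is not None and matched.origin == tc.donor_origin:
                origin_correct += 1

    planted_families = {
        family_of_protein[pid].family_id
        for pid in planted_ids if pid in family_of_protein
    }
    non_planted = [
        f for f in result.candidates if f.family_id not in planted_families
    ]
    n_false = sum(f.family_id in comp_by_family for f in non_planted)

    return {
        "recall": {
            cls: (rec / tot if tot else None) for cls, (rec, tot) in per_class.items()
        },
        "class_accuracy": n_class_correct / n_recovered if n_recovered else None,
        "origin_accuracy": origin_correct / origin_total if origin_total else None,
        "false_composite_rate": n_false / len(non_planted) if non_planted else None,
        "n_recovered": n_recovered,
        "n_planted": len(truths),
        "n_non_planted_candidates": len(non_planted),
    }
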