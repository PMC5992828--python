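"""Detect components on candidate genes, call composites, assign origins.

Reads the hit tables and family partition written by 02_build_families.py.
For every member of a candidate family, hits to proteins of other families
define components (E < 1e-5, span >= 30 aa); components are clustered by
mutual overlap (> 70 % of each), component families merged by inclusion
(> 70 % of the shorter consensus span), and genes with two component
families (or one plus a clear domain annotation) are composite.  Component
origins follow the top-5-bitscore rank rule; any bacterial-origin component
makes the family a ChiC family.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from halochic.composites import (
    call_composite,
    cluster_components,
    components_table,
    composites_table,
    detect_components,
    group_composite_families,
    merge_component_families,
)
from halochic.families import GeneFamily, NetworkConfig
from halochic.origins import (
    TaxonomyIndex,
    assign_component_origin,
    assign_phylum,
    classify_composite,
    origins_table,
)
from halochic.similarity import parse_hits, read_fasta

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    res = args.results

    taxonomy = pd.read_csv(res / "sim" / "taxonomy.tsv", sep="\t")
    fam_table = pd.read_csv(res / "families.tsv", sep="\t")
    genome_of = dict(zip(fam_table.protein_id, fam_table.genome_id))
    config = NetworkConfig()

    with open(res / "hits" / "archaeal.tsv") as fh:
        arc_hits = parse_hits(fh)
    with open(res / "hits" / "bacterial.tsv") as fh:
        bact_hits = parse_hits(fh)
    with open(res / "hits" / "candidate_vs_bacteria.tsv") as fh:
        screen_hits = parse_hits(fh)

    family_of = dict(zip(fam_table.protein_id, fam_table.family_id))
    # bacterial proteins are absent from families.tsv (archaeal network);
    # group them by their own similarity graph so partners resolve
    from halochic.families import build_family_graph, connected_components

    bact_seqs = read_fasta(str(res / "sim" / "proteins.faa"))
    bact_genomes = set(taxonomy.loc[taxonomy.domain == "Bacteria", "genome_id"])
    bact_only = {
        p: s for p, s in bact_seqs.items()
        if p not in family_of
    }
    for pid in bact_only:
        genome_of.setdefault(
            pid, next(g for g in bact_genomes if f"_{g}" in pid or pid.endswith(g))
        )
    bgraph = build_family_graph(
        bact_hits, {p: len(s) for p, s in bact_only.items()}, config
    )
    for fam in connected_components(bgraph, genome_of):
        for pid in fam.members:
            family_of[pid] = "B" + fam.family_id

    candidates = [
        GeneFamily(fid, frozenset(grp.protein_id), frozenset(grp.genome_id))
        for fid, grp in fam_table[fam_table.halo_exclusive_candidate]
        .groupby("family_id")
    ]
    hits_by_query = {}
    for hit in arc_hits + screen_hits:
        hits_by_query.setdefault(hit.query_id, []).append(hit)

    genes = []
    for fam in candidates:
        for pid in sorted(fam.members):
            comps = detect_components(pid, hits_by_query.get(pid, []),
                                      family_of, config)
            merged = merge_component_families(
                cluster_components(comps, config, id_prefix=f"{pid}:"), config
            )
            genes.append(call_composite(pid, merged, [], config))

    composite_families = group_composite_families(genes, candidates)
    taxindex = TaxonomyIndex(taxonomy, genome_of)
    class_counts = {"I": 0, "II": 0, "ChiC": 0}
    for comp_fam in composite_families:
        for gene in comp_fam.genes:
            for cf in gene.component_families:
                cf.origin = assign_component_origin(cf, taxindex, config).value
                if cf.origin == "BAC":
                    cf.phylum = assign_phylum(cf, taxindex, config)
        comp_fam.class_label = classify_composite(comp_fam.origin_set())
        class_counts[comp_fam.class_label] += 1

    components_table(genes).to_csv(res / "components.tsv", sep="\t", index=False)
    composites_table(genes).to_csv(res / "composites.tsv", sep="\t", index=False)
    origins_table(composite_families).to_csv(
        res / "origins.tsv", sep="\t", index=False
    )
    summary = {
        "candidate_families": len(candidates),
        "composite_genes": sum(g.is_composite for g in genes),
        "composite_families": len(composite_families),
        "class_counts": class_counts,
    }
    with open(res / "composite_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("composite calls:", json.dumps(summary))


if __name__ == "__main__":
    main()
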