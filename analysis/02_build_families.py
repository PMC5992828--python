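"""Build similarity-network gene families and apply the exclusivity funnel.

Reads the corpus written by 01_simulate.py, aligns all archaeal proteins
pairwise with the built-in local aligner, links pairs passing E < 1e-5,
identity > 30 % and mutual coverage > 80 %, and takes connected components
as gene families.  Haloarchaea-only families from >= 3 genomes are then
screened against the bacterial proteomes (full-length match at identity
> 25 %, mutual coverage > 80 % disqualifies).  Writes the hit tables,
families.tsv and the funnel counts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from halochic.families import (
    NetworkConfig,
    build_family_graph,
    connected_components,
    families_table,
    filter_halo_exclusive,
)
from halochic.similarity import ScoringScheme, all_vs_all, read_fasta, write_hits

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    sequences = read_fasta(str(args.sim / "proteins.faa"))
    taxonomy = pd.read_csv(args.sim / "taxonomy.tsv", sep="\t")
    genome_of = {
        pid: next(g for g in sorted(taxonomy.genome_id, key=len, reverse=True)
                  if f"_{g}" in pid or pid.endswith(g))
        for pid in sequences
    }
    lengths = {p: len(s) for p, s in sequences.items()}
    config = NetworkConfig()
    scheme = ScoringScheme(db_residues=sum(lengths.values()))

    bact_genomes = set(taxonomy.loc[taxonomy.domain == "Bacteria", "genome_id"])
    arc_seqs = {p: s for p, s in sequences.items()
                if genome_of[p] not in bact_genomes}
    bact_seqs = {p: s for p, s in sequences.items()
                 if genome_of[p] in bact_genomes}

    arc_hits = all_vs_all(arc_seqs, scheme=scheme, evalue_max=config.evalue_max)
    bact_hits = all_vs_all(bact_seqs, scheme=scheme, evalue_max=config.evalue_max)

    graph = build_family_graph(arc_hits, {p: lengths[p] for p in arc_seqs}, config)
    families = connected_components(graph, genome_of)

    halo = set(taxonomy.loc[taxonomy.halo_flag, "genome_id"])
    prelim = [
        f for f in families
        if {genome_of[m] for m in f.members} <= halo
        and len({genome_of[m] for m in f.members}) >= config.min_halo_genomes
    ]
    prelim_members = {m for f in prelim for m in f.members}
    screen_hits = all_vs_all(
        {p: sequences[p] for p in prelim_members}, bact_seqs,
        scheme=scheme, evalue_max=config.evalue_max,
    )
    candidates = filter_halo_exclusive(
        families, taxonomy, screen_hits, lengths, genome_of, config
    )

    hits_dir = args.out / "hits"
    hits_dir.mkdir(parents=True, exist_ok=True)
    for name, hits in (("archaeal", arc_hits), ("bacterial", bact_hits),
                       ("candidate_vs_bacteria", screen_hits)):
        with open(hits_dir / f"{name}.tsv", "w") as fh:
            write_hits(hits, fh)
    families_table(families, genome_of).to_csv(
        args.out / "families.tsv", sep="\t", index=False
    )
    funnel = {
        "proteins": len(sequences),
        "archaeal_proteins": len(arc_seqs),
        "families": len(families),
        "halo_only_min_genomes": len(prelim),
        "halo_exclusive_candidates": len(candidates),
    }
    with open(args.out / "funnel.json", "w") as fh:
        json.dump(funnel, fh, indent=2)
    print("detection funnel:", json.dumps(funnel))


if __name__ == "__main__":
    main()
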