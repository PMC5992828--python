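"""Residency and optimization statistics of the composite families.

Reads the stage outputs of 02/03: builds the genome x composite-family
presence/absence matrix, clusters it (Jaccard distance, complete linkage),
tests whether composite sharing follows the haloarchaeal clades (Mantel
permutation test against a same-clade design distance), and compares
isoelectric-point distributions (composite and haloarchaeal proteins vs
other archaea and bacteria; one-sided Wilcoxon rank-sum).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from halochic.similarity import read_fasta
from halochic.stats import (
    clade_distance_matrix,
    compare_distributions,
    jaccard_distance_matrix,
    jaccard_linkage,
    linkage_table,
    mantel_test,
    pi_table,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    res = args.results

    taxonomy = pd.read_csv(res / "sim" / "taxonomy.tsv", sep="\t")
    fam_table = pd.read_csv(res / "families.tsv", sep="\t")
    origins = pd.read_csv(res / "origins.tsv", sep="\t")
    sequences = read_fasta(str(res / "sim" / "proteins.faa"))

    halo_ids = sorted(taxonomy.loc[taxonomy.halo_flag, "genome_id"])
    composite_ids = sorted(origins.family_id.unique())
    members = fam_table[fam_table.family_id.isin(composite_ids)]
    presence = pd.DataFrame(0, index=halo_ids, columns=composite_ids, dtype=int)
    for row in members.itertuples(index=False):
        if row.genome_id in presence.index:
            presence.loc[row.genome_id, row.family_id] = 1
    presence.index.name = "genome_id"
    presence.to_csv(res / "presence_matrix.tsv", sep="\t")

    Z, labels = jaccard_linkage(presence, axis="columns")
    linkage_table(Z, labels).to_csv(res / "linkage.tsv", sep="\t", index=False)

    clade_of = dict(zip(taxonomy.genome_id, taxonomy.halo_clade))
    r, p = mantel_test(
        jaccard_distance_matrix(presence, axis="rows").values,
        clade_distance_matrix(halo_ids, clade_of).values,
        n_permutations=999,
        seed=args.seed,
    )
    print(f"Mantel test (presence vs clade structure): r = {r:.3f}, p = {p:.3g}")

    genome_of = dict(zip(fam_table.protein_id, fam_table.genome_id))
    composite_proteins = set(members.protein_id)
    halo_set = set(halo_ids)
    groups = {"composite": {}, "halo_other": {}, "archaea_other": {},
              "bacteria": {}}
    bact_genomes = set(taxonomy.loc[taxonomy.domain == "Bacteria", "genome_id"])
    for pid, seq in sorted(sequences.items()):
        genome = genome_of.get(pid)
        if genome is None:  # bacterial proteins are outside the archaeal network
            groups["bacteria"][pid] = seq
        elif pid in composite_proteins:
            groups["composite"][pid] = seq
        elif genome in halo_set:
            groups["halo_other"][pid] = seq
        else:
            groups["archaea_other"][pid] = seq
    pis = pi_table(groups)
    pis.to_csv(res / "pi_table.tsv", sep="\t", index=False)
    medians = pis.groupby("group")["pI"].median()
    print("median pI by group:", medians.round(3).to_dict())
    _u, p_pi = compare_distributions(
        pis.loc[pis.group == "composite", "pI"],
        pis.loc[pis.group == "bacteria", "pI"],
        alternative="less",
    )
    print(f"composite pI below bacterial pI: one-sided Wilcoxon p = {p_pi:.3g}")

    with open(res / "residency_stats.json", "w") as fh:
        json.dump(
            {
                "mantel_r": r,
                "mantel_p": p,
                "pi_median_by_group": medians.round(4).to_dict(),
                "pi_composite_vs_bacteria_p": p_pi,
            },
            fh, indent=2,
        )


if __name__ == "__main__":
    main()
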