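"""Score the pipeline's calls against the planted truth table.

Compares the composite families reported by 03_detect_composites.py with
the truth written by 01_simulate.py: per-class recall, class-label accuracy
on recovered families, and the false-composite rate among candidate
families without planted members.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    res = args.results

    truth = pd.read_csv(res / "sim" / "truth.tsv", sep="\t")
    fam_table = pd.read_csv(res / "families.tsv", sep="\t")
    origins = pd.read_csv(res / "origins.tsv", sep="\t")

    family_of = dict(zip(fam_table.protein_id, fam_table.family_id))
    class_of_family = dict(
        origins.drop_duplicates("family_id")[["family_id", "class_label"]].values
    )

    per_class = {}
    n_correct = n_recovered = 0
    planted_families = set()
    for comp_id, grp in truth.groupby("composite_id"):
        cls = grp["class"].iloc[0]
        members = grp["members"].iloc[0].split(",")
        fam = next((family_of[m] for m in members if m in family_of), None)
        if fam is not None:
            planted_families.add(fam)
        recovered = fam in class_of_family
        rec, tot = per_class.get(cls, (0, 0))
        per_class[cls] = (rec + recovered, tot + 1)
        if recovered:
            n_recovered += 1
            n_correct += class_of_family[fam] == cls

    candidates = set(
        fam_table.loc[fam_table.halo_exclusive_candidate, "family_id"]
    )
    non_planted = candidates - planted_families
    false_pos = sum(f in class_of_family for f in non_planted)

    out = {
        "recall": {c: rec / tot for c, (rec, tot) in sorted(per_class.items())},
        "class_label_accuracy": n_correct / n_recovered if n_recovered else None,
        "false_composite_rate": false_pos / len(non_planted) if non_planted else None,
        "n_planted": int(truth.composite_id.nunique()),
        "n_recovered": n_recovered,
    }
    with open(res / "evaluation.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
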