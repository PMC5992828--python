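# halochic

Discovery of clade-exclusive **composite genes** and **chimeric composite
(ChiC) genes** in prokaryotic proteomes, via sequence-similarity networks.

Composite genes are genes assembled from dissociable subgenic parts
("components") that independently match distinct gene families — the typical
product of gene fusion or of the recycling of laterally transferred DNA
fragments. In Haloarchaea — aerobic, sugar-metabolizing archaea that thrive
in saturated brines using a salt-in osmotic strategy — such novel genes are
of particular interest: composites built partly from *bacterial* genetic
material (ChiC genes) mark a distinct channel of bacterial contribution to
the haloarchaeal lifestyle, separate from ordinary full-gene lateral
transfer, and their residence in these genomes is legible both from their
taxonomic distribution and from the acidified (low isoelectric point)
amino-acid composition that salt-in halophiles require.

`halochic` implements the full detection protocol for any focal clade, plus
a synthetic-proteome generator with planted fusions so that every stage is
verifiable against a known truth table without downloading genomes.

## The protocol

1. **Gene families.** All archaeal proteins are compared pairwise (built-in
   Smith–Waterman local aligner with affine gaps, BLOSUM62; or ingested
   BLAST `-outfmt 6` tables). Two proteins are linked iff a hit has
   E < 1e-5, identity > 30 % and *mutual* coverage > 80 % (both sequences).
   Connected components of this graph are the gene families.
2. **Clade exclusivity.** Families whose members are all haloarchaeal, span
   ≥ 3 distinct genomes, and show no full-length similarity to any bacterial
   protein (identity > 25 %, mutual coverage > 80 %) are candidate novel
   genes.
3. **Components.** For each candidate gene, alignments to proteins of
   *other* families (E < 1e-5, span ≥ 30 aa) define components; components
   overlapping mutually by > 70 % of each length form component families,
   which are merged while one is included by > 70 % of the shorter consensus
   span in another. A gene with ≥ 2 component families — or one component
   family plus a non-overlapping domain annotation — is composite.
4. **Origins and classes.** Each component family is assigned an origin from
   its five best-scoring partners (all bacterial → BAC; all haloarchaeal →
   HALO; archaeal with a non-haloarchaeon → ARC; fewer than five partners or
   a mixed archaeal/bacterial top-5 → PROK), optionally validated by a tree
   screen (smallest clan with support > 70 enclosing the component).
   Families with a BAC component are **ChiC**; origins within {ARC, HALO}
   give **class I**; anything else gives **class II**.
5. **Residency statistics.** Genome × family presence/absence matrix,
   clustered with Jaccard distance and complete linkage; a Mantel
   permutation test of clade-structured sharing; COG enrichment (one-sided
   Fisher); isoelectric points (Henderson–Hasselbalch bisection, IPC_protein
   or EMBOSS pKa sets) compared across origins with Wilcoxon rank-sum tests.

## Worked example

The numbered drivers under `analysis/` chain the stages on the benchmark
synthetic corpus (20 haloarchaeal + 5 archaeal + 5 bacterial genomes, 60
background families, 30 planted composites at 70 % target identity):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_build_families.py
python analysis/03_detect_composites.py
python analysis/04_residency_stats.py
python analysis/05_evaluate_recovery.py
```

which prints (seed 1):

```
detection funnel: {"proteins": 503, "archaeal_proteins": 388, "families": 80,
                   "halo_only_min_genomes": 43, "halo_exclusive_candidates": 43}
composite calls: {"candidate_families": 43, "composite_genes": 113,
                  "composite_families": 30,
                  "class_counts": {"I": 9, "II": 11, "ChiC": 10}}
Mantel test (presence vs clade structure): r = 0.957, p = 0.001
median pI by group: {'archaea_other': 6.154, 'bacteria': 6.007,
                     'composite': 4.428, 'halo_other': 4.477}
composite pI below bacterial pI: one-sided Wilcoxon p = 8.5e-37
recall I/II/ChiC = 1.0/1.0/1.0, class-label accuracy 0.97,
false-composite rate 0.0
```

Reading: of 80 gene families, 43 are haloarchaea-exclusive candidates; all
30 planted composite families are recovered with the correct class for 29
of 30 (one class-I family draws a PROK call on a borderline component and
lands in class II); no unplanted candidate family is called composite.
Composite sharing follows the simulated haloarchaeal clades (Mantel
p = 0.001 at 999 permutations, the smallest attainable p), and composite
proteins carry the acidified, low-pI composition of their haloarchaeal
hosts rather than the higher pI of their bacterial donors.

The same run is available as a single call:

```bash
halochic run-all --simulate --seed 1 --out results/run
```

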