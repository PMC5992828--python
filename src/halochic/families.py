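"""Gene families as connected components of a filtered similarity graph.

An edge joins two proteins when at least one pairwise hit clears every
threshold simultaneously: E-value below the cutoff, percent identity and
mutual coverage above theirs.  All printed thresholds are strict
inequalities.  Families that contain only haloarchaeal proteins, span at
least three distinct genomes, and show no full-length similarity to any
bacterial sequence are the candidate novel, clade-exclusive genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .similarity import AlignmentHit, mutual_coverage


@dataclass
class NetworkConfig:
    """Every threshold of the detection protocol, as printed."""

    evalue_max: float = 1e-5
    min_identity_family: float = 30.0  # percent, strict >
    min_mutual_cov_family: float = 0.80  # fraction, strict > on both sides
    min_identity_bact_screen: float = 25.0  # percent, strict >
    min_cov_bact_screen: float = 0.80
    min_halo_genomes: int = 3
    component_overlap_frac: float = 0.70  # mutual, strict >
    merge_inclusion_frac: float = 0.70  # of the shorter span, strict >
    top_n_hits: int = 5
    min_support: float = 70.0  # bootstrap percent, strict >
    min_component_length: int = 30
    domain_overlap_frac: float = 0.30  # "non-overlapping" tolerance, strict <

    def __post_init__(self) -> None:
        for name in ("min_mutual_cov_family", "min_cov_bact_screen",
                     "component_overlap_frac", "merge_inclusion_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("min_identity_family", "min_identity_bact_screen", "min_support"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise ValueError(f"{name} must lie in (0, 100]")
        if self.min_halo_genomes < 1:
            raise ValueError("min_halo_genomes must be >= 1")


@dataclass
class GeneFamily:
    family_id: str
    members: frozenset[str]
    genomes: frozenset[str]
    halo_only: bool = False
    n_halo_genomes: int = 0
    halo_exclusive_candidate: bool = False

    def __len__(self) -> int:
        return len(self.members)


def edge_passes(
    hit: AlignmentHit,
    lengths: dict[str, int],
    config: NetworkConfig,
) -> bool:
    """Whether one hit satisfies the family-graph criteria (all strict)."""
    if hit.evalue >= config.evalue_max:
        return False
    if hit.pct_identity <= config.min_identity_family:
        return False
    cov_q, cov_s = mutual_coverage(hit, lengths[hit.query_id], lengths[hit.subject_id])
    return cov_q > config.min_mutual_cov_family and cov_s > config.min_mutual_cov_family


def build_family_graph(
    hits: list[AlignmentHit],
    lengths: dict[str, int],
    config: NetworkConfig | None = None,
) -> nx.Graph:
    """Undirected similarity graph over all proteins in ``lengths``.

    Every protein is a node even when isolated.  An edge exists iff ANY hit
    between the pair passes all thresholds; self-hits are ignored.
    """
    config = config or NetworkConfig()
    graph = nx.Graph()
    graph.add_nodes_from(lengths)
    for hit in hits:
        for pid in (hit.query_id, hit.subject_id):
            if pid not in lengths:
                raise KeyError(f"hit references unknown protein {pid!r}")
        if hit.query_id == hit.subject_id:
            continue
        if edge_passes(hit, lengths, config):
            graph.add_edge(hit.query_id, hit.subject_id)
    return graph


def connected_components(
    graph: nx.Graph, genome_of: dict[str, str] | None = None
) -> list[GeneFamily]:
    """Partition the graph into gene families (one per connected component).

    Families are numbered in order of their lexicographically smallest
    member, so ids are stable across runs.
    """
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: c[0])
    families = []
    for i, members in enumerate(comps):
        genomes = frozenset(
            genome_of[m] for m in members) if genome_of else frozenset()
        families.append(
            GeneFamily(f"F{i:05d}", frozenset(members), genomes)
        )
    return families


def filter_halo_exclusive(
    families: list[GeneFamily],
    taxonomy: pd.DataFrame,
    bacterial_screen_hits: list[AlignmentHit],
    lengths: dict[str, int],
    genome_of: dict[str, str],
    config: NetworkConfig | None = None,
) -> list[GeneFamily]:
    """Retain families that are candidate clade-exclusive novel genes.

    A family survives iff (i) every member is haloarchaeal, (ii) members come
    from >= ``min_halo_genomes`` distinct genomes, and (iii) no member shows a
    full-length bacterial similarity (both coverages > ``min_cov_bact_screen``
    and identity > ``min_identity_bact_screen``).  The bacterial screen is
    E-value-free: one qualifying global match disqualifies the whole family.
    """
    config = config or NetworkConfig()
    halo_genomes = set(taxonomy.loc[taxonomy.halo_flag, "genome_id"])
    known_genomes = set(taxonomy.genome_id)

    screened_out: set[str] = set()  # proteins with a full-length bacterial match
    for hit in bacterial_screen_hits:
        if hit.pct_identity <= config.min_identity_bact_screen:
            continue
        cov_q, cov_s = mutual_coverage(
            hit, lengths[hit.query_id], lengths[hit.subject_id]
        )
        if cov_q > config.min_cov_bact_screen and cov_s > config.min_cov_bact_screen:
            screened_out.add(hit.query_id)
            screened_out.add(hit.subject_id)

    retained = []
    for fam in families:
        genomes = {genome_of[m] for m in fam.members}
        missing = genomes - known_genomes
        if missing:
            raise KeyError(f"no taxonomy for genome(s) {sorted(missing)}")
        halo_only = genomes <= halo_genomes
        n_halo = len(genomes & halo_genomes)
        ok = (
            halo_only
            and n_halo >= config.min_halo_genomes
            and not (fam.members & screened_out)
        )
        fam.halo_only = halo_only
        fam.n_halo_genomes = n_halo
        fam.halo_exclusive_candidate = ok
        if ok:
            retained.append(fam)
    return retained


def families_table(
    families: list[GeneFamily], genome_of: dict[str, str]
) -> pd.DataFrame:
    rows = [
        (f.family_id, m, genome_of[m], f.halo_exclusive_candidate)
        for f in families
        for m in sorted(f.members)
    ]
    return pd.DataFrame(
        rows, columns=["family_id", "protein_id", "genome_id", "halo_exclusive_candidate"]
    )
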