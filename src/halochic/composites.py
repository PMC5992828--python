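"""Subgenic component detection and composite-gene calling.

A component is an interval of a candidate protein that aligns to a protein
from a *different* gene family.  Components on one gene are clustered into
component families by mutual interval overlap (> 70 % of each length), then
nested/overlapping component families are merged until fixpoint (> 70 %
inclusion of the shorter consensus span).  A gene is composite when it
carries at least two component families, or one component family plus a
domain annotation on a region not overlapping it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .families import GeneFamily, NetworkConfig
from .similarity import AlignmentHit


@dataclass(frozen=True)
class Component:
    """One qualifying hit interval on a candidate composite protein."""

    composite_protein_id: str
    start: int  # 1-based inclusive on the composite
    end: int
    partner_id: str
    partner_family: str
    source_hit: AlignmentHit

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("component interval inverted")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ComponentFamily:
    """A cluster of mutually overlapping components on one protein."""

    id: str
    members: list[Component]
    origin: str | None = None  # HALO | ARC | BAC | PROK, set by the origins stage
    tree_origin: str | None = None
    phylum: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        """Consensus interval: (min start, max end) over the members."""
        return (min(c.start for c in self.members), max(c.end for c in self.members))

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s + 1

    def partner_ids(self) -> list[str]:
        return sorted({c.partner_id for c in self.members})


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    accession: str
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("domain interval inverted")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CompositeGene:
    protein_id: str
    component_families: list[ComponentFamily]
    domains: list[DomainAnnotation]
    is_composite: bool
    rule_used: str  # "two_components" | "component_plus_domain" | ""
    class_label: str | None = None


@dataclass
class CompositeFamily:
    family: GeneFamily
    genes: list[CompositeGene]  # every member gene, composite or not
    class_label: str | None = None
    cog_category: str | None = None

    @property
    def family_id(self) -> str:
        return self.family.family_id

    def composite_genes(self) -> list[CompositeGene]:
        return [g for g in self.genes if g.is_composite]

    def component_families(self) -> list[ComponentFamily]:
        return [cf for g in self.genes for cf in g.component_families]

    def origin_set(self) -> set[str]:
        return {cf.origin for cf in self.component_families() if cf.origin}


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two 1-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def detect_components(
    protein_id: str,
    hits: list[AlignmentHit],
    family_of: dict[str, str],
    config: NetworkConfig | None = None,
) -> list[Component]:
    """Components of one candidate protein from its hits to the corpus.

    A hit qualifies when its E-value clears the cutoff, the partner belongs
    to a different gene family, and the aligned span on the candidate is at
    least ``min_component_length`` residues.
    """
    config = config or NetworkConfig()
    own_family = family_of.get(protein_id)
    components = []
    for hit in hits:
        if hit.query_id != protein_id:
            hit = hit.swapped()
            if hit.query_id != protein_id:
                continue
        partner = hit.subject_id
        if partner == protein_id:
            continue
        if hit.evalue >= config.evalue_max:
            continue
        partner_family = family_of.get(partner)
        if partner_family is None:
            raise KeyError(f"partner {partner!r} not in the family map")
        if own_family is not None and partner_family == own_family:
            continue
        if hit.q_span < config.min_component_length:
            continue
        components.append(
            Component(protein_id, hit.q_start, hit.q_end, partner, partner_family, hit)
        )
    return components


def cluster_components(
    components: list[Component],
    config: NetworkConfig | None = None,
    id_prefix: str = "",
) -> list[ComponentFamily]:
    """Cluster components of one protein by mutual interval overlap.

    Two components are directly linked iff their overlap exceeds 70 % of the
    length of EACH; component families are the connected components of that
    link relation (transitive closure), so the result is order-invariant.
    """
    config = config or NetworkConfig()
    if not components:
        return []
    comps = sorted(components, key=lambda c: (c.start, c.end, c.partner_id))
    n = len(comps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ov = _overlap((comps[i].start, comps[i].end), (comps[j].start, comps[j].end))
            if (
                ov > config.component_overlap_frac * comps[i].length
                and ov > config.component_overlap_frac * comps[j].length
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[Component]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(comps[i])
    ordered = sorted(groups.values(), key=lambda g: (g[0].start, g[0].end))
    return [
        ComponentFamily(f"{id_prefix}cf{k}", members)
        for k, members in enumerate(ordered)
    ]


def merge_component_families(
    families: list[ComponentFamily],
    config: NetworkConfig | None = None,
) -> list[ComponentFamily]:
    """Merge nested/overlapping component families until fixpoint.

    Two families qualify for merging when the intersection of their consensus
    spans exceeds 70 % of the shorter span; the merged consensus is the union
    span.  Each pass merges the connected components of the qualifying-pair
    relation (its transitive closure) simultaneously, and passes repeat until
    nothing merges.  Closure passes make the fixpoint a function of the span
    set alone, hence independent of input order; merging one pair at a time
    is not, because a union span also grows the shorter-span denominator.
    """
    config = config or NetworkConfig()
    merged = [ComponentFamily(f.id, list(f.members), f.origin) for f in families]
    changed = True
    while changed:
        changed = False
        merged.sort(key=lambda f: (f.span, sorted(c.partner_id for c in f.members)))
        n = len(merged)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = merged[i], merged[j]
                ov = _overlap(a.span, b.span)
                if ov > config.merge_inclusion_frac * min(a.span_length, b.span_length):
                    parent[find(i)] = find(j)
        groups: dict[int, list[ComponentFamily]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(merged[i])
        if any(len(g) > 1 for g in groups.values()):
            changed = True
            merged = [
                ComponentFamily(g[0].id, [c for f in g for c in f.members],
                                g[0].origin)
                for g in groups.values()
            ]
    merged.sort(key=lambda f: f.span)
    for k, fam in enumerate(merged):
        fam.id = f"{fam.id.split('cf')[0]}cf{k}" if "cf" in fam.id else fam.id
    return merged


def call_composite(
    protein_id: str,
    component_families: list[ComponentFamily],
    domains: list[DomainAnnotation],
    config: NetworkConfig | None = None,
) -> CompositeGene:
    """Apply the composite-gene definition to one protein.

    "Non-overlapping" domain means its overlap with EVERY component-family
    span stays below 30 % of the domain's length (configurable tolerance for
    alignment fuzz at the component borders).
    """
    config = config or NetworkConfig()
    if len(component_families) >= 2:
        return CompositeGene(protein_id, component_families, list(domains), True,
                             "two_components")
    if len(component_families) == 1:
        for dom in domains:
            if all(
                _overlap((dom.start, dom.end), cf.span)
                < config.domain_overlap_frac * dom.length
                for cf in component_families
            ):
                return CompositeGene(protein_id, component_families, list(domains),
                                     True, "component_plus_domain")
    return CompositeGene(protein_id, component_families, list(domains), False, "")


def group_composite_families(
    genes: list[CompositeGene],
    families: list[GeneFamily],
) -> list[CompositeFamily]:
    """Lift composite calls to the family level.

    A candidate gene family becomes a composite family when at least one of
    its member genes is composite.
    """
    by_protein = {g.protein_id: g for g in genes}
    out = []
    for fam in families:
        fam_genes = [by_protein[m] for m in sorted(fam.members) if m in by_protein]
        if any(g.is_composite for g in fam_genes):
            out.append(CompositeFamily(fam, fam_genes))
    return out


def components_table(genes: list[CompositeGene]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for cf in g.component_families:
            for c in cf.members:
                rows.append(
                    (g.protein_id, cf.id, c.start, c.end, c.partner_id,
                     c.partner_family, c.source_hit.evalue)
                )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "component_family", "start", "end", "partner_id",
                 "partner_family", "evalue"],
    )


def composites_table(genes: list[CompositeGene]) -> pd.DataFrame:
    rows = [
        (g.protein_id, len(g.component_families), g.is_composite, g.rule_used)
        for g in genes
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "n_component_families", "is_composite", "rule_used"]
    )


def read_domain_annotations(path) -> list[DomainAnnotation]:
    """Read a CDD-style interval table (protein_id, start, end, accession, evalue)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(r.protein_id, int(r.start), int(r.end), str(r.accession),
                         float(getattr(r, "evalue", 0.0)))
        for r in df.itertuples(index=False)
    ]
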