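"""Taxonomic origin assignment of component families and composite classes.

Two screens are implemented.  The rank rule inspects the five best-scoring
partner sequences of a component family: a unanimous taxon wins (all
bacterial -> BAC, all haloarchaeal -> HALO, all archaeal with at least one
non-haloarchaeon -> ARC); fewer than five partners, or a mixture of archaea
and bacteria, yields the unresolved prokaryotic call (PROK).  The tree rule
searches an input phylogeny for the smallest well-supported clan (bipartition
side, support strictly above 70) enclosing the component: an all-bacterial
clan -> BAC, an archaeal clan containing non-haloarchaea -> ARC, else PROK.

Composite families are classed from their component origins: any bacterial
component makes a chimeric composite (ChiC); origins confined to archaea or
haloarchaea make class I; anything else (unresolved prokaryotic material,
no bacterial) makes class II.
"""

from __future__ import annotations


from dataclasses import dataclass

import dendropy
import pandas as pd

from .composites import ComponentFamily
from .families import NetworkConfig

ORIGINS = ("HALO", "ARC", "BAC", "PROK")

#: tip categories understood by the tree screen
TIP_COMPONENT = "component"
TIP_HALO = "halo"
TIP_ARC = "arc"
TIP_BAC = "bac"


@dataclass(frozen=True)
class OriginCall:
    value: str  # HALO | ARC | BAC | PROK
    method: str  # rank_rule | tree_rule
    evidence: tuple[str, ...]  # top partner ids, or the supporting clan's tips

    def __post_init__(self) -> None:
        if self.value not in ORIGINS:
            raise ValueError(f"unknown origin {self.value!r}")


class TaxonomyIndex:
    """Resolve protein ids to HALO/ARC/BAC strata and bacterial phyla."""

    def __init__(self, taxonomy: pd.DataFrame, genome_of: dict[str, str]):
        self._genome_of = genome_of
        self._domain = dict(zip(taxonomy.genome_id, taxonomy.domain))
        self._halo = dict(zip(taxonomy.genome_id, taxonomy.halo_flag))
        self._phylum = dict(zip(taxonomy.genome_id, taxonomy.phylum))

    def stratum(self, protein_id: str) -> str:
        genome = self._genome_of[protein_id]
        if genome not in self._domain:
            raise KeyError(f"no taxonomy for genome {genome!r}")
        if self._domain[genome] == "Bacteria":
            return "BAC"
        return "HALO" if self._halo[genome] else "ARC"

    def phylum(self, protein_id: str) -> str:
        return self._phylum[self._genome_of[protein_id]]


def _ranked_partners(component_family: ComponentFamily) -> list[tuple[str, float]]:
    """Distinct partners by best bitscore, tie-broken by E-value then id."""
    best: dict[str, tuple[float, float]] = {}
    for comp in component_family.members:
        hit = comp.source_hit
        cur = best.get(comp.partner_id)
        cand = (hit.bitscore, hit.evalue)
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[comp.partner_id] = cand
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
    return [(pid, score) for pid, (score, _e) in ranked]


def assign_component_origin(
    component_family: ComponentFamily,
    taxonomy: TaxonomyIndex,
    config: NetworkConfig | None = None,
) -> OriginCall:
    """Rank rule: origin from the top-N best-scoring distinct partners."""
    config = config or NetworkConfig()
    ranked = _ranked_partners(component_family)
    if not ranked:
        raise ValueError(
            f"component family {component_family.id} has no generating hits"
        )
    top = [pid for pid, _ in ranked[: config.top_n_hits]]
    strata = [taxonomy.stratum(pid) for pid in top]
    if len(top) < config.top_n_hits:
        value = "PROK"
    elif any(s == "BAC" for s in strata):
        value = "BAC" if all(s == "BAC" for s in strata) else "PROK"
    elif all(s == "HALO" for s in strata):
        value = "HALO"
    else:  # all archaeal, at least one from outside the Haloarchaea
        value = "ARC"
    return OriginCall(value, "rank_rule", tuple(top))


def assign_phylum(
    component_family: ComponentFamily,
    taxonomy: TaxonomyIndex,
    config: NetworkConfig | None = None,
) -> str:
    """Phylum-level call for a bacterial-origin component family.

    Returns the phylum shared by all of the top five bacterial partners, or
    "unresolved" when they disagree or fewer than five exist.
    """
    config = config or NetworkConfig()
    if component_family.origin != "BAC":
        raise ValueError("phylum assignment applies only to BAC-origin components")
    ranked = [
        pid for pid, _ in _ranked_partners(component_family)
        if taxonomy.stratum(pid) == "BAC"
    ]
    top = ranked[: config.top_n_hits]
    if len(top) < config.top_n_hits:
        return "unresolved"
    phyla = {taxonomy.phylum(pid) for pid in top}
    return phyla.pop() if len(phyla) == 1 else "unresolved"


def classify_composite(origins) -> str:
    """Map a composite family's component-origin set to {I, II, ChiC}."""
    origins = set(origins)
    if not origins:
        raise ValueError("cannot classify a composite with no origin calls")
    unknown = origins - set(ORIGINS)
    if unknown:
        raise ValueError(f"unknown origins {sorted(unknown)}")
    if "BAC" in origins:
        return "ChiC"
    if origins <= {"ARC", "HALO"}:
        return "I"
    return "II"


# ---------------------------------------------------------------------------
# tree screen


class NewickError(ValueError):
    pass


def _parse_support(node) -> float | None:
    label = node.label
    if label is None and node.taxon is not None:
        label = node.taxon.label
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def tree_origin_screen(
    tree,
    tip_categories: dict[str, str],
    config: NetworkConfig | None = None,
) -> OriginCall:
    """Clan rule on a (rooted or unrooted) tree with branch supports.

    ``tree`` is a Newick string, a readable stream, or a ``dendropy.Tree``.
    ``tip_categories`` maps every tip label to one of ``component``, ``halo``,
    ``arc``, ``bac``.  Clans are bipartition sides of internal edges; a clan
    qualifies when its support exceeds ``min_support`` (strict) and it
    contains every component tip.  The smallest qualifying clan whose other
    tips are exclusively bacterial gives BAC; exclusively archaeal with at
    least one non-haloarchaeal tip gives ARC; with no such clan the component
    is called prokaryotic (PROK).
    """
    config = config or NetworkConfig()
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        if hasattr(tree, "read"):
            tree = tree.read()
        try:
            t = dendropy.Tree.get(data=tree, schema="newick",
                                  suppress_internal_node_taxa=True)
        except Exception as exc:
            raise NewickError(f"unparseable Newick: {exc}") from exc

    tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    comp_tips = {tip for tip, cat in tip_categories.items() if cat == TIP_COMPONENT}
    if not comp_tips or not comp_tips <= tips:
        raise ValueError("component tip(s) absent from the tree")
    unknown = tips - set(tip_categories)
    if unknown:
        raise ValueError(f"tips without a category: {sorted(unknown)}")

    clans: list[frozenset[str]] = []
    for node in t.preorder_internal_node_iter():
        if node.parent_node is None:
            continue  # the root edge is not an internal edge
        support = _parse_support(node)
        if support is None or support <= config.min_support:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        for clan in (side, frozenset(tips) - side):
            if comp_tips <= clan and clan != tips:
                clans.append(clan)

    for clan in sorted(set(clans), key=lambda c: (len(c), sorted(c))):
        others = [tip_categories[tip] for tip in clan - comp_tips]
        if not others:
            continue
        if all(cat == TIP_BAC for cat in others):
            return OriginCall("BAC", "tree_rule", tuple(sorted(clan)))
        if all(cat in (TIP_ARC, TIP_HALO) for cat in others) and any(
            cat == TIP_ARC for cat in others
        ):
            return OriginCall("ARC", "tree_rule", tuple(sorted(clan)))
    return OriginCall("PROK", "tree_rule", ())


def origins_table(families) -> pd.DataFrame:
    """origins.tsv: one row per component family of each composite family."""
    rows = []
    for comp_fam in families:
        for gene in comp_fam.genes:
            for cf in gene.component_families:
                rows.append(
                    (comp_fam.family_id, gene.protein_id, cf.id, cf.origin,
                     cf.tree_origin, cf.phylum, comp_fam.class_label)
                )
    return pd.DataFrame(
        rows,
        columns=["family_id", "protein_id", "component_family", "rank_origin",
                 "tree_origin", "phylum", "class_label"],
    )
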