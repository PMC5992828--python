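"""Synthetic proteome sets with planted composite genes.

The generator emulates the statistical structure the detection pipeline
assumes: background gene families confined to one taxonomic stratum
(haloarchaeal-only, other-archaeal, bacterial, or "prokaryotic" = shared by
archaea and bacteria), plus composite genes planted exclusively in
haloarchaeal genomes.  Each planted composite is a fusion of two subgenic
fragments sliced from donor-family ancestors, separated by short random
linkers, and copied into at least three haloarchaeal genomes of one
haloarchaeal clade.  Haloarchaeal sequences are compositionally acidified
(residues swapped toward D/E) so the proteome-wide isoelectric-point contrast
characteristic of salt-in halophiles is reproducible.

No indels, no explicit phylogeny: divergence is modelled as exact-count point
substitution toward a target percent identity, which is the regime the
30 %-identity network threshold is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import (
    CANONICAL_AA,
    ScoringScheme,
    local_align,
    mutual_coverage,
    write_fasta,
)

HALO_CLADES = ("A", "B", "C", "D")
BACTERIAL_PHYLA = ("Proteobacteria", "Firmicutes", "Actinobacteria")

#: fusion recipes per composite class, cycled over planted composites;
#: each entry is the pair of donor-stratum origins of the two components
CLASS_RECIPES: dict[str, tuple[tuple[str, str], ...]] = {
    "I": (("ARC", "HALO"), ("ARC", "ARC")),
    "II": (("PROK", "HALO"), ("PROK", "ARC"), ("PROK", "PROK")),
    "ChiC": (("BAC", "HALO"), ("BAC", "ARC"), ("BAC", "PROK")),
}


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    sequence: str


@dataclass(frozen=True)
class TruthComponent:
    start: int  # 1-based inclusive, on the composite
    end: int
    donor_family: str
    donor_origin: str  # HALO | ARC | BAC | PROK


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one planted composite gene family."""

    composite_id: str
    class_label: str  # I | II | ChiC
    components: tuple[TruthComponent, ...]
    member_ids: tuple[str, ...]  # one protein copy per carrier genome

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a planted composite carries at least two components")
        if self.class_label == "ChiC" and not any(
            c.donor_origin == "BAC" for c in self.components
        ):
            raise ValueError("a ChiC truth record needs a BAC-origin component")


@dataclass
class SimConfig:
    """Study conditions of the synthetic corpus.

    Defaults describe the planted-fusion recovery benchmark: 20 haloarchaeal,
    5 other-archaeal and 5 bacterial genomes, 60 background families, ten
    planted composites per class, within-family divergence at 70 % identity.
    """

    n_halo_genomes: int = 20
    n_arc_genomes: int = 5
    n_bact_genomes: int = 5
    n_background_families: int = 60
    family_size_range: tuple[int, int] = (5, 8)
    protein_length_range: tuple[int, int] = (150, 250)
    n_planted_per_class: dict[str, int] = field(
        default_factory=lambda: {"I": 10, "II": 10, "ChiC": 10}
    )
    target_identity: float = 0.7
    halo_acidification: float = 0.1
    min_component_length: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = (
            self.n_halo_genomes,
            self.n_arc_genomes,
            self.n_bact_genomes,
            self.n_background_families,
        )
        if any(c < 0 for c in counts):
            raise ValueError("genome and family counts must be >= 0")
        if not 0.25 < self.target_identity <= 1.0:
            raise ValueError("target_identity must lie in (0.25, 1]")
        if not 0.0 <= self.halo_acidification <= 1.0:
            raise ValueError("halo_acidification must lie in [0, 1]")
        n_planted = sum(self.n_planted_per_class.values())
        if any(v < 0 for v in self.n_planted_per_class.values()):
            raise ValueError("planted counts must be >= 0")
        if set(self.n_planted_per_class) - {"I", "II", "ChiC"}:
            raise ValueError("planted classes must be a subset of {I, II, ChiC}")
        if n_planted > 0 and self.n_halo_genomes < 3:
            raise ValueError(
                "planting composites requires >= 3 haloarchaeal genomes "
                "(the exclusivity filter can never pass otherwise)"
            )
        lo, hi = self.protein_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid protein_length_range")
        # 2 components plus three >=3-residue linkers must fit the shortest protein
        if n_planted > 0 and lo < 2 * self.min_component_length + 9:
            raise ValueError(
                "protein_length_range cannot host two components of "
                f"min_component_length={self.min_component_length}"
            )
        if self.seed is None:
            raise ValueError("a seed is required; simulated runs must be reproducible")


# ---------------------------------------------------------------------------
# sequence-level primitives


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_protein(length: int, rng) -> str:
    rng = _as_rng(rng)
    return "".join(np.array(list(CANONICAL_AA))[rng.integers(0, 20, size=length)])


def mutate_to_identity(sequence: str, identity: float, seed) -> str:
    """Substitute residues so exactly ``round(identity * L)`` positions match.

    Substitution-only (no indels); every mutated position receives a residue
    different from the original, so the realised identity is exact.
    """
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must lie in (0, 1]")
    rng = _as_rng(seed)
    length = len(sequence)
    n_keep = round(identity * length)
    n_mut = length - n_keep
    if n_mut == 0:
        return sequence
    positions = rng.choice(length, size=n_mut, replace=False)
    out = list(sequence)
    for pos in positions:
        alternatives = CANONICAL_AA.replace(out[pos], "")
        out[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def acidify(sequence: str, fraction: float, seed) -> str:
    """Swap a fraction of the non-acidic residues to D or E.

    Models the amino-acid acidification of salt-in halophile proteomes; the
    exact substituted count is ``round(fraction * #non-D/E positions)``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    candidates = [i for i, aa in enumerate(sequence) if aa not in "DE"]
    n_swap = round(fraction * len(candidates))
    if n_swap == 0:
        return sequence
    chosen = rng.choice(len(candidates), size=n_swap, replace=False)
    out = list(sequence)
    for idx in chosen:
        out[candidates[idx]] = "DE"[rng.integers(0, 2)]
    return "".join(out)


# ---------------------------------------------------------------------------
# corpus generation


def _make_taxonomy(config: SimConfig) -> pd.DataFrame:
    rows = []
    n_halo = config.n_halo_genomes
    for i in range(n_halo):
        # contiguous clade blocks: first quarter clade A, etc.
        clade = HALO_CLADES[min(i * len(HALO_CLADES) // max(n_halo, 1), 3)]
        rows.append((f"HALO{i + 1:02d}", "Archaea", "Euryarchaeota", True, clade))
    for i in range(config.n_arc_genomes):
        rows.append((f"ARC{i + 1:02d}", "Archaea", "Crenarchaeota", False, ""))
    for i in range(config.n_bact_genomes):
        phylum = BACTERIAL_PHYLA[i % len(BACTERIAL_PHYLA)]
        rows.append((f"BACT{i + 1:02d}", "Bacteria", phylum, False, ""))
    return pd.DataFrame(
        rows, columns=["genome_id", "domain", "phylum", "halo_flag", "halo_clade"]
    )


def _stratum_pools(taxonomy: pd.DataFrame) -> dict[str, list[str]]:
    halo = taxonomy.loc[taxonomy.halo_flag, "genome_id"].tolist()
    arc = taxonomy.loc[
        (taxonomy.domain == "Archaea") & ~taxonomy.halo_flag, "genome_id"
    ].tolist()
    bact = taxonomy.loc[taxonomy.domain == "Bacteria", "genome_id"].tolist()
    return {"HALO": halo, "ARC": arc, "BAC": bact}


def _plan_strata(config: SimConfig) -> list[str]:
    """Stratum of every background family; donor demand is satisfied first."""
    demand: list[str] = []
    for cls in ("I", "II", "ChiC"):
        recipes = CLASS_RECIPES[cls]
        for k in range(config.n_planted_per_class.get(cls, 0)):
            demand.extend(recipes[k % len(recipes)])
    if len(demand) > config.n_background_families:
        raise ValueError(
            f"{len(demand)} donor families needed but only "
            f"{config.n_background_families} background families configured"
        )
    strata = list(demand)
    fill = ("HALO", "ARC", "BAC", "PROK")
    i = 0
    while len(strata) < config.n_background_families:
        strata.append(fill[i % 4])
        i += 1
    return strata


def _pick_genomes(pool: list[str], n: int, rng) -> list[str]:
    """n genome slots from the pool; wraps around (paralogs) when n > |pool|."""
    if not pool:
        raise ValueError("empty genome pool for a configured stratum")
    base = list(rng.permutation(pool))
    out = []
    while len(out) < n:
        out.extend(base)
    return out[:n]


class SimulatedCorpus:
    """Bundle returned by :func:`simulate_proteome_set`."""

    def __init__(self, proteins, taxonomy, truths, family_ancestors, family_members):
        self.proteins: dict[str, ProteinRecord] = proteins
        self.taxonomy: pd.DataFrame = taxonomy
        self.truths: list[SimTruth] = truths
        #: background family id -> (ancestor sequence, stratum)
        self.family_ancestors: dict[str, tuple[str, str]] = family_ancestors
        #: background family id -> member protein ids
        self.family_members: dict[str, list[str]] = family_members

    @property
    def sequences(self) -> dict[str, str]:
        return {pid: rec.sequence for pid, rec in self.proteins.items()}

    def planted_protein_ids(self) -> set[str]:
        return {pid for t in self.truths for pid in t.member_ids}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, str(outdir / "proteins.faa"))
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        rows = []
        for t in self.truths:
            for c in t.components:
                rows.append(
                    (
                        t.composite_id,
                        t.class_label,
                        c.start,
                        c.end,
                        c.donor_family,
                        c.donor_origin,
                        ",".join(t.member_ids),
                    )
                )
        pd.DataFrame(
            rows,
            columns=[
                "composite_id",
                "class",
                "start",
                "end",
                "donor_family",
                "donor_origin",
                "members",
            ],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_proteome_set(config: SimConfig) -> SimulatedCorpus:
    """Generate proteomes, a taxonomy table and the planted-composite truth.

    Background families are confined to one stratum each; planted composites
    exist only in haloarchaeal genomes (>= 3 distinct genomes of one clade).
    Fragment lengths never exceed 60 % of the composite, so no planted
    composite can show full-length (mutual coverage > 80 %) similarity to any
    background protein — the exclusivity screen cannot delete truth cases.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = _make_taxonomy(config)
    pools = _stratum_pools(taxonomy)
    halo_by_clade = {
        clade: taxonomy.loc[
            taxonomy.halo_flag & (taxonomy.halo_clade == clade), "genome_id"
        ].tolist()
        for clade in HALO_CLADES
    }

    proteins: dict[str, ProteinRecord] = {}

    def add_protein(pid: str, genome: str, seq: str) -> None:
        is_halo = genome.startswith("HALO")
        if is_halo and config.halo_acidification > 0:
            seq = acidify(seq, config.halo_acidification, rng)
        proteins[pid] = ProteinRecord(pid, genome, seq)

    # --- background families -------------------------------------------------
    strata = _plan_strata(config)
    family_ancestors: dict[str, tuple[str, str]] = {}
    family_members: dict[str, list[str]] = {}
    lo, hi = config.protein_length_range
    for idx, stratum in enumerate(strata):
        fam_id = f"BG{idx:03d}_{stratum}"
        ancestor = random_protein(int(rng.integers(lo, hi + 1)), rng)
        family_ancestors[fam_id] = (ancestor, stratum)
        size = int(rng.integers(config.family_size_range[0], config.family_size_range[1] + 1))
        if stratum == "PROK":
            n_arc = size // 2
            genomes = _pick_genomes(pools["ARC"], n_arc, rng) + _pick_genomes(
                pools["BAC"], size - n_arc, rng
            )
        else:
            genomes = _pick_genomes(pools[stratum], size, rng)
        members = []
        seen: dict[str, int] = {}
        for genome in genomes:
            seen[genome] = seen.get(genome, 0) + 1
            suffix = "" if seen[genome] == 1 else f".{seen[genome]}"
            pid = f"{fam_id}_{genome}{suffix}"
            add_protein(pid, genome, mutate_to_identity(ancestor, config.target_identity, rng))
            members.append(pid)
        family_members[fam_id] = members

    # --- planted composites ----------------------------------------------------
    donor_cursor = 0  # donor families were laid out first by _plan_strata
    donor_ids = list(family_ancestors)
    truths: list[SimTruth] = []
    clade_cursor = 0
    scheme = ScoringScheme()
    for cls in ("I", "II", "ChiC"):
        recipes = CLASS_RECIPES[cls]
        for k in range(config.n_planted_per_class.get(cls, 0)):
            recipe = recipes[k % len(recipes)]
            donors = []
            for origin in recipe:
                fam_id = donor_ids[donor_cursor]
                assert family_ancestors[fam_id][1] == origin
                donors.append((fam_id, origin))
                donor_cursor += 1

            comp_id = f"CPS_{cls}_{k:02d}"
            clade = HALO_CLADES[clade_cursor % len(HALO_CLADES)]
            clade_cursor += 1
            pool = halo_by_clade[clade]
            if len(pool) < 3:
                pool = pools["HALO"]

            # proteins of the donor families: the only sequences a planted
            # composite is related to, hence the only ones that could anchor
            # a spurious full-length similarity
            related = [
                proteins[pid].sequence
                for fam_id, _origin in donors
                for pid in family_members[fam_id]
            ]

            for _attempt in range(30):
                total_len = int(rng.integers(lo, hi + 1))
                linkers = [int(rng.integers(3, 12)) for _ in range(3)]
                room = total_len - sum(linkers)
                len_a = room // 2
                len_b = room - len_a
                parts = [random_protein(linkers[0], rng)]
                components = []
                cursor = linkers[0]
                for pos, ((fam_id, origin), frag_len) in enumerate(
                    zip(donors, (len_a, len_b))
                ):
                    ancestor = family_ancestors[fam_id][0]
                    start = int(rng.integers(0, len(ancestor) - frag_len + 1))
                    parts.append(ancestor[start : start + frag_len])
                    components.append(
                        TruthComponent(cursor + 1, cursor + frag_len, fam_id, origin)
                    )
                    cursor += frag_len
                    parts.append(random_protein(linkers[pos + 1], rng))
                    cursor += linkers[pos + 1]
                composite_ancestor = "".join(parts)

                n_copies = int(rng.integers(3, min(5, len(pool)) + 1))
                genomes = list(rng.permutation(pool))[:n_copies]
                copies = {}
                for genome in sorted(genomes):
                    seq = mutate_to_identity(
                        composite_ancestor, config.target_identity, rng
                    )
                    if config.halo_acidification > 0:
                        seq = acidify(seq, config.halo_acidification, rng)
                    copies[f"{comp_id}_{genome}"] = (genome, seq)
                if all(
                    _no_fulllength_match(seq, related, scheme)
                    for _genome, seq in copies.values()
                ):
                    break
            else:  # pragma: no cover - would need a pathological configuration
                raise RuntimeError(
                    f"could not place composite {comp_id} without a full-length "
                    "background similarity after 30 attempts"
                )

            for pid, (genome, seq) in copies.items():
                proteins[pid] = ProteinRecord(pid, genome, seq)
            truths.append(
                SimTruth(comp_id, cls, tuple(components), tuple(sorted(copies)))
            )

    return SimulatedCorpus(proteins, taxonomy, truths, family_ancestors, family_members)


#: screen-safety margin: stricter than both the family-edge (30 %) and the
#: bacterial-screen (25 %) identity thresholds
_SCREEN_IDENTITY = 25.0
_SCREEN_COVERAGE = 0.80


def _no_fulllength_match(seq: str, related: list[str], scheme: ScoringScheme) -> bool:
    """True when no related protein aligns near-globally to ``seq``.

    A planted composite may share a component with its donors but must never
    show mutual coverage > 80 % at identity > 25 % against any of them —
    otherwise the exclusivity screen (or the family graph) would swallow it.
    """
    for other in related:
        for hit in local_align(seq, other, scheme):
            if hit.pct_identity <= _SCREEN_IDENTITY:
                continue
            cov_q, cov_s = mutual_coverage(hit, len(seq), len(other))
            if cov_q > _SCREEN_COVERAGE and cov_s > _SCREEN_COVERAGE:
                return False
    return True


def verify_screen_safety(corpus: SimulatedCorpus) -> list[tuple[str, str]]:
    """Post-hoc check of the construction guarantee.

    Returns every (composite copy, background protein) pair showing a
    full-length similarity that would trip the exclusivity screen; an empty
    list certifies the corpus.
    """
    scheme = ScoringScheme()
    planted = corpus.planted_protein_ids()
    background = [
        corpus.proteins[pid].sequence
        for members in corpus.family_members.values()
        for pid in members
    ]
    background_ids = [
        pid for members in corpus.family_members.values() for pid in members
    ]
    offenders = []
    for pid in sorted(planted):
        seq = corpus.proteins[pid].sequence
        for other_id, other in zip(background_ids, background):
            if not _no_fulllength_match(seq, [other], scheme):
                offenders.append((pid, other_id))
    return offenders
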