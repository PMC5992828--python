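"""Downstream statistics: isoelectric points, distribution comparisons,
functional enrichment, presence/absence clustering and the Mantel test.

The pI calculator solves the Henderson-Hasselbalch net-charge equation by
bisection; the pKa set is a named, swappable parameter (default: the
IPC_protein set, with the EMBOSS set also provided).  Rank-sum and Fisher
tests wrap SciPy; the Mantel permutation test and the presence/absence
Jaccard clustering are thin, deterministic layers over SciPy primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .similarity import AlignmentHit


# ---------------------------------------------------------------------------
# isoelectric points


@dataclass(frozen=True)
class PkaSet:
    """pKa values of the nine ionizable groups of a protein.

    Basic groups (positive below their pKa): N-terminus, H, K, R.
    Acidic groups (negative above their pKa): C-terminus, D, E, C, Y.
    """

    name: str
    n_term: float
    c_term: float
    D: float
    E: float
    C: float
    Y: float
    H: float
    K: float
    R: float

    def __post_init__(self) -> None:
        for group in ("n_term", "c_term", "D", "E", "C", "Y", "H", "K", "R"):
            v = getattr(self, group)
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa of {group} must lie in (0, 14)")


IPC_PROTEIN = PkaSet(
    name="IPC_protein",
    n_term=9.094, c_term=2.869,
    D=3.872, E=4.412, C=7.555, Y=10.85, H=5.637, K=9.052, R=11.84,
)

EMBOSS = PkaSet(
    name="EMBOSS",
    n_term=8.6, c_term=3.6,
    D=3.9, E=4.1, C=8.5, Y=10.1, H=6.5, K=10.8, R=12.5,
)

PKA_SETS = {"IPC_protein": IPC_PROTEIN, "EMBOSS": EMBOSS}


def net_charge(sequence: str, ph: float, pka: PkaSet = IPC_PROTEIN) -> float:
    """Net charge Z(pH) of a sequence, counting side chains and both termini."""
    pos = [("n_term", 1), ("H", sequence.count("H")), ("K", sequence.count("K")),
           ("R", sequence.count("R"))]
    neg = [("c_term", 1), ("D", sequence.count("D")), ("E", sequence.count("E")),
           ("C", sequence.count("C")), ("Y", sequence.count("Y"))]
    z = 0.0
    for group, n in pos:
        if n:
            z += n / (1.0 + 10.0 ** (ph - getattr(pka, group)))
    for group, n in neg:
        if n:
            z -= n / (1.0 + 10.0 ** (getattr(pka, group) - ph))
    return z


def isoelectric_point(
    sequence: str, pka: PkaSet = IPC_PROTEIN, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Z is strictly decreasing in pH, positive at pH 0 and negative at pH 14
    (both termini are always present), so the crossing is unique.
    """
    if not sequence:
        raise ValueError("cannot compute the pI of an empty sequence")
    lo, hi = 0.0, 14.0
    # bisect until the bracket collapses: |Z| alone stops too early on the
    # flat stretch between well-separated pKa values
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    assert abs(net_charge(sequence, mid, pka)) < tol
    return mid


def pi_table(groups: dict[str, dict[str, str]], pka: PkaSet = IPC_PROTEIN) -> pd.DataFrame:
    """pI per protein for labelled groups of sequences (group -> id -> seq)."""
    rows = [
        (pid, group, isoelectric_point(seq, pka))
        for group, seqs in groups.items()
        for pid, seq in seqs.items()
    ]
    return pd.DataFrame(rows, columns=["protein_id", "group", "pI"])


# ---------------------------------------------------------------------------
# hypothesis tests


def compare_distributions(values_a, values_b, alternative: str = "two-sided"):
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution for combined n <= 20 without ties; the normal
    approximation with tie correction (no continuity correction) otherwise.
    Returns ``(U statistic of the first sample, p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return (a.size * b.size / 2.0, 1.0)
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=False
    )
    return (float(res.statistic), float(res.pvalue))


def enrichment_test(k_in_class: int, n_class: int, k_total: int, n_total: int) -> float:
    """One-sided Fisher (hypergeometric upper tail) enrichment p-value.

    Probability of observing >= ``k_in_class`` annotated families among the
    ``n_class`` families of one class, when ``k_total`` of all ``n_total``
    families carry the annotation.
    """
    ok = (
        0 <= k_in_class <= n_class <= n_total
        and k_in_class <= k_total <= n_total
        and (k_total - k_in_class) <= (n_total - n_class)
    )
    if not ok:
        raise ValueError("inconsistent contingency margins")
    return float(sps.hypergeom.sf(k_in_class - 1, n_total, k_total, n_class))


# ---------------------------------------------------------------------------
# presence/absence structure


def build_presence_matrix(composite_families, genome_of, genome_ids) -> pd.DataFrame:
    """Genome x composite-family binary matrix (1 = family present)."""
    index = list(genome_ids)
    cols = [fam.family_id for fam in composite_families]
    mat = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    for fam in composite_families:
        for pid in fam.family.members:
            genome = genome_of[pid]
            if genome in mat.index:
                mat.loc[genome, fam.family_id] = 1
    mat.index.name = "genome_id"
    return mat


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration with a lexicographic tie-break.

    ``dist`` is a square distance matrix.  At every step the pair of
    clusters with the smallest maximum inter-profile distance is merged;
    exact ties are broken by the smallest member index of each cluster, so
    the dendrogram is fully deterministic.  Returns a SciPy-style merge
    table (left id, right id, height, size) with cluster ids ``n + k`` for
    the cluster created at step ``k``.

    Hand-rolled (Lance-Williams ``max`` update) because library nearest-
    neighbour-chain implementations leave tie order unspecified.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("need a square distance matrix")
    active = list(range(n))  # positions into d
    cluster_id = list(range(n))
    min_member = list(range(n))
    sizes = [1] * n
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                a, b = sorted((min_member[i], min_member[j]))
                key = (d[i, j], a, b)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        (height, _a, _b), ai, aj = best
        i, j = active[ai], active[aj]
        Z[step] = (cluster_id[i], cluster_id[j], height, sizes[i] + sizes[j])
        d[i, :] = np.maximum(d[i, :], d[j, :])
        d[:, i] = d[i, :]
        d[i, i] = 0.0
        cluster_id[i] = n + step
        min_member[i] = min(min_member[i], min_member[j])
        sizes[i] += sizes[j]
        del active[aj]
    return Z


def jaccard_linkage(
    matrix: pd.DataFrame,
    axis: str = "columns",
    metric: str = "jaccard",
    method: str = "complete",
):
    """Hierarchical clustering of a binary presence/absence matrix.

    Returns ``(linkage matrix, labels)``; rows of the linkage matrix are the
    standard SciPy merge table.  Jaccard distance between two all-zero
    profiles is 0 by convention.  ``metric="euclidean"`` supports clustering
    origin-ratio profiles.  Complete linkage uses the deterministic
    tie-broken agglomeration of :func:`complete_linkage`; other methods fall
    back to SciPy.
    """
    data = matrix.T if axis == "columns" else matrix
    labels = list(data.index)
    if len(labels) < 2:
        raise ValueError("need at least two profiles to cluster")
    dist = pdist(data.values.astype(float), metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)  # two empty profiles: distance 0
    if method == "complete":
        return complete_linkage(squareform(dist)), labels
    return hierarchy.linkage(dist, method=method), labels


def linkage_table(linkage_matrix, labels) -> pd.DataFrame:
    """The merge table in a plain, writable form."""
    return pd.DataFrame(
        linkage_matrix, columns=["left", "right", "height", "size"]
    ).assign(n_leaves=len(labels))


def jaccard_distance_matrix(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    data = matrix if axis == "rows" else matrix.T
    dist = squareform(np.nan_to_num(pdist(data.values.astype(float), metric="jaccard")))
    return pd.DataFrame(dist, index=data.index, columns=data.index)


def clade_distance_matrix(genome_ids, clade_of: dict[str, str]) -> pd.DataFrame:
    """0/1 design distance: 0 within a haloarchaeal clade, 1 across clades."""
    n = len(genome_ids)
    mat = np.ones((n, n))
    for i, g1 in enumerate(genome_ids):
        for j, g2 in enumerate(genome_ids):
            if clade_of.get(g1) and clade_of.get(g1) == clade_of.get(g2):
                mat[i, j] = 0.0
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=list(genome_ids), columns=list(genome_ids))


def mantel_test(dist_a, dist_b, n_permutations: int = 999, seed=None):
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the upper triangles; the one-sided p is
    ``(1 + #{permuted r >= observed r}) / (1 + n_permutations)`` with rows and
    columns of the second matrix permuted jointly.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and of equal order")
    n = a.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs order >= 3")
    for m, name in ((a, "first"), (b, "second")):
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError(f"{name} matrix has a non-zero diagonal")
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("degenerate (constant) distance matrix; r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    vb_c = vb - vb.mean()
    denom_b = np.sqrt((vb_c ** 2).sum())
    va_c = va - va.mean()
    denom_a = np.sqrt((va_c ** 2).sum())
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vp = b[perm[iu[0]], perm[iu[1]]]
        vp_c = vp - vp.mean()
        r_perm = float((va_c * vp_c).sum() / (denom_a * np.sqrt((vp_c ** 2).sum())))
        if r_perm >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# per-family summaries


def family_identity_summary(member_ids, hits: list[AlignmentHit]) -> dict:
    """Mean/median pairwise percent identity within one family.

    The best hit per unordered member pair is used; pairs without any hit are
    skipped and counted in ``n_missing_pairs``.
    """
    members = sorted(set(member_ids))
    best: dict[frozenset, float] = {}
    member_set = set(members)
    for hit in hits:
        if hit.query_id in member_set and hit.subject_id in member_set \
                and hit.query_id != hit.subject_id:
            key = frozenset((hit.query_id, hit.subject_id))
            best[key] = max(best.get(key, 0.0), hit.pct_identity)
    n_pairs = len(members) * (len(members) - 1) // 2
    values = sorted(best.values())
    return {
        "mean_identity": float(np.mean(values)) if values else float("nan"),
        "median_identity": float(np.median(values)) if values else float("nan"),
        "n_pairs_with_hit": len(values),
        "n_missing_pairs": n_pairs - len(values),
    }


def assign_family_cog(member_ids, annotation_of: dict[str, str],
                      share_threshold: float = 0.60) -> str:
    """Family-level COG category: the annotation shared by > 60 % of members.

    Members without an annotation stay in the denominator; no category
    reaching the threshold yields "unknown".
    """
    members = list(member_ids)
    counts: dict[str, int] = {}
    for pid in members:
        cat = annotation_of.get(pid)
        if cat:
            counts[cat] = counts.get(cat, 0) + 1
    for cat, n in sorted(counts.items()):
        if n > share_threshold * len(members):
            return cat
    return "unknown"
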