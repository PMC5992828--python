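"""Component detection, interval clustering/merging, composite calls."""

import random

import pytest

from halochic.composites import (
    Component,
    DomainAnnotation,
    call_composite,
    cluster_components,
    detect_components,
    group_composite_families,
    merge_component_families,
)
from halochic.families import GeneFamily, NetworkConfig

from conftest import make_hit


def comp(start, end, pid="cand", partner="x", family="FX"):
    return Component(
        pid, start, end, partner, family,
        make_hit(q=pid, s=partner, q_start=start, q_end=end,
                 s_start=1, s_end=end - start + 1),
    )


FAMILY_OF = {"cand": "F0", "same": "F0", "other": "F1", "bact": "BF0"}


class TestDetectComponents:
    def test_qualifying_hit_yields_component(self):
        hit = make_hit(q="cand", s="bact", q_start=10, q_end=150, evalue=1e-30)
        out = detect_components("cand", [hit], FAMILY_OF)
        assert [(c.start, c.end) for c in out] == [(10, 150)]
        assert out[0].partner_family == "BF0"

    def test_weak_evalue_excluded(self):
        hit = make_hit(q="cand", s="bact", q_start=10, q_end=150, evalue=1e-3)
        assert detect_components("cand", [hit], FAMILY_OF) == []

    def test_own_family_partner_excluded(self):
        hit = make_hit(q="cand", s="same", q_start=10, q_end=150, evalue=1e-30)
        assert detect_components("cand", [hit], FAMILY_OF) == []

    def test_short_span_excluded(self):
        hit = make_hit(q="cand", s="other", q_start=10, q_end=30, evalue=1e-30)
        assert detect_components("cand", [hit], FAMILY_OF) == []

    def test_subject_side_hits_are_reoriented(self):
        hit = make_hit(q="other", s="cand", q_start=1, q_end=80,
                       s_start=10, s_end=90, evalue=1e-30)
        out = detect_components("cand", [hit], FAMILY_OF)
        assert [(c.start, c.end) for c in out] == [(10, 90)]


def _interval_cluster_oracle(intervals, frac=0.70):
    """Brute-force transitive closure of the mutual-overlap rule."""
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            s1, e1 = intervals[i]
            s2, e2 = intervals[j]
            ov = max(0, min(e1, e2) - max(s1, s2) + 1)
            if ov > frac * (e1 - s1 + 1) and ov > frac * (e2 - s2 + 1):
                adj[i][j] = True
    # transitive closure by repeated squaring of the boolean relation
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if not adj[i][j] and any(adj[i][k] and adj[k][j] for k in range(n)):
                    adj[i][j] = True
                    changed = True
    labels = [-1] * n
    next_label = 0
    for i in range(n):
        if labels[i] == -1:
            labels[i] = next_label
            for j in range(n):
                if adj[i][j]:
                    labels[j] = next_label
            next_label += 1
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(intervals[i])
    return sorted(frozenset(g) for g in groups.values())


class TestClusterComponents:
    def test_strongly_overlapping_pair_clusters(self):
        fams = cluster_components([comp(10, 100), comp(20, 110)])
        assert len(fams) == 1

    def test_weakly_overlapping_pair_stays_separate(self):
        fams = cluster_components([comp(10, 100), comp(80, 200)])
        assert len(fams) == 2

    def test_random_sets_match_brute_force_oracle(self):
        rng = random.Random(31)
        for _ in range(100):
            intervals = set()
            for _ in range(rng.randint(1, 12)):
                s = rng.randint(1, 150)
                intervals.add((s, s + rng.randint(30, 120)))
            intervals = sorted(intervals)
            comps = [comp(s, e, partner=f"x{i}") for i, (s, e) in enumerate(intervals)]
            fams = cluster_components(comps)
            got = sorted(
                frozenset((c.start, c.end) for c in f.members) for f in fams
            )
            assert got == _interval_cluster_oracle(intervals)

    def test_order_invariance(self):
        rng = random.Random(5)
        comps = [comp(s, s + l, partner=f"x{i}")
                 for i, (s, l) in enumerate([(10, 90), (15, 95), (200, 60), (210, 70)])]
        base = cluster_components(comps)
        shuffled = list(comps)
        rng.shuffle(shuffled)
        other = cluster_components(shuffled)
        key = lambda fams: sorted(
            sorted((c.start, c.end) for c in f.members) for f in fams
        )
        assert key(base) == key(other)


class TestMergeComponentFamilies:
    def test_nested_families_merge(self):
        fams = [
            cluster_components([comp(10, 100)])[0],
            cluster_components([comp(5, 150, partner="y")])[0],
        ]
        merged = merge_component_families(fams)
        assert len(merged) == 1
        assert merged[0].span == (5, 150)

    def test_disjoint_families_unchanged(self):
        fams = [
            cluster_components([comp(1, 50)])[0],
            cluster_components([comp(100, 150, partner="y")])[0],
        ]
        assert len(merge_component_families(fams)) == 2

    def test_merge_is_idempotent_and_order_invariant(self):
        rng = random.Random(13)
        spans = [(1, 80), (10, 90), (60, 200), (55, 210), (300, 360)]
        fams = [
            cluster_components([comp(s, e, partner=f"z{i}")])[0]
            for i, (s, e) in enumerate(spans)
        ]
        merged = merge_component_families(fams)
        again = merge_component_families(merged)
        assert [f.span for f in merged] == [f.span for f in again]
        shuffled = list(fams)
        rng.shuffle(shuffled)
        assert [f.span for f in merge_component_families(shuffled)] == \
            [f.span for f in merged]


class TestCallComposite:
    def _cf(self, start, end, partner="x"):
        return cluster_components([comp(start, end, partner=partner)])[0]

    def test_two_component_families_make_a_composite(self):
        gene = call_composite("cand", [self._cf(1, 120), self._cf(150, 300, "y")], [])
        assert gene.is_composite and gene.rule_used == "two_components"

    def test_component_plus_clear_domain_makes_a_composite(self):
        dom = DomainAnnotation("cand", 160, 240, "PF0001")
        gene = call_composite("cand", [self._cf(1, 150)], [dom])
        assert gene.is_composite and gene.rule_used == "component_plus_domain"

    def test_nested_domain_does_not_qualify(self):
        dom = DomainAnnotation("cand", 30, 120, "PF0001")
        gene = call_composite("cand", [self._cf(1, 150)], [dom])
        assert not gene.is_composite

    def test_domain_overlap_tolerance_is_strict(self):
        # domain length 100, overlap exactly 30 -> not "non-overlapping"
        dom = DomainAnnotation("cand", 121, 220, "PF0001")
        gene = call_composite("cand", [self._cf(1, 150)], [dom])
        assert not gene.is_composite
        # overlap 29 of 100 -> qualifies
        dom2 = DomainAnnotation("cand", 122, 221, "PF0001")
        gene2 = call_composite("cand", [self._cf(1, 150)], [dom2])
        assert gene2.is_composite

    def test_no_components_is_not_composite(self):
        gene = call_composite("cand", [], [DomainAnnotation("cand", 1, 50, "PF1")])
        assert not gene.is_composite


class TestGroupCompositeFamilies:
    def test_family_with_composite_member_is_kept(self):
        fam = GeneFamily("F9", frozenset({"a", "b", "c"}), frozenset())
        genes = [
            call_composite("a", [], []),
            call_composite(
                "b",
                [cluster_components([comp(1, 100, pid="b")])[0],
                 cluster_components([comp(150, 250, pid="b", partner="y")])[0]],
                [],
            ),
        ]
        out = group_composite_families(genes, [fam])
        assert len(out) == 1 and out[0].family_id == "F9"

    def test_family_without_composites_is_dropped(self):
        fam = GeneFamily("F9", frozenset({"a"}), frozenset())
        out = group_composite_families([call_composite("a", [], [])], [fam])
        assert out == []
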