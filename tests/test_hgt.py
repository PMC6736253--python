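import dendropy
import numpy as np
import pytest

from lossguard.hgt import (
    LeafMeta,
    annotate_leca_clades,
    assign_unsampled,
    cross_root_bbh,
    toy_similarity_scores,
)


def bbh_oracle(scores, left, right):
    """Mutual-argmax reference implementation."""
    pairs = []
    for l in left:
        cand_r = [r for r in right if (l, r) in scores]
        if not cand_r:
            continue
        best_r = min(cand_r, key=lambda r: (-scores[(l, r)], r))
        cand_l = [x for x in left if (x, best_r) in scores]
        best_l = min(cand_l, key=lambda x: (-scores[(x, best_r)], x))
        if best_l == l:
            pairs.append((l, best_r))
    return sorted(pairs)


class TestCrossRootBBH:
    def test_single_pair_always_selected(self):
        assert cross_root_bbh({("l1", "r1"): 5.0}, ["l1"], ["r1"]) == [("l1", "r1")]

    def test_asymmetric_bests_yield_no_pair(self):
        scores = {
            ("l1", "r1"): 10.0,
            ("l2", "r1"): 20.0,  # r1's best is l2
            ("l2", "r2"): 30.0,  # but l2's best is r2
            ("l1", "r2"): 1.0,
        }
        pairs = cross_root_bbh(scores, ["l1", "l2"], ["r1", "r2"])
        assert ("l1", "r1") not in pairs
        assert pairs == [("l2", "r2")]

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            cross_root_bbh({}, [], ["r1"])

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 16)), int(rng.integers(2, 16))
        left = [f"l{i}" for i in range(n)]
        right = [f"r{j}" for j in range(m)]
        scores = {
            (l, r): float(rng.integers(0, 50))
            for l in left
            for r in right
            if rng.random() > 0.1  # some unscored pairs
        }
        assert cross_root_bbh(scores, left, right) == bbh_oracle(scores, left, right)

    def test_toy_scorer_feeds_bbh(self):
        left = {"l1": "MKWVFAARHEDT", "l2": "GGGGGGGGGGGG"}
        right = {"r1": "MKWVFAARHEDT", "r2": "CCCCCCCCCCCC"}
        scores = toy_similarity_scores(left, right)
        assert ("l1", "r1") in cross_root_bbh(scores, list(left), list(right))


class TestAssignUnsampled:
    def test_single_candidate(self):
        assert assign_unsampled({"s1": {"leafA": 4.0}}) == {"s1": "leafA"}

    def test_best_score_wins(self):
        assert assign_unsampled({"s1": {"a": 50.0, "b": 40.0}}) == {"s1": "a"}

    def test_invariant_under_positive_rescaling(self):
        scores = {"s1": {"a": 5.0, "b": 3.0}, "s2": {"a": 1.0, "b": 9.0}}
        doubled = {s: {k: 2 * v for k, v in d.items()} for s, d in scores.items()}
        assert assign_unsampled(scores) == assign_unsampled(doubled)

    def test_no_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_unsampled({"s1": {}})


SG5 = (
    "Excavata",
    "SAR+Haptista",
    "Archaeplastida+Cryptista",
    "Amoebozoa",
    "Opisthokonta+Apusozoa",
)


def euk(species, side, sg):
    return LeafMeta(kind="eukaryote", species_id=species, root_side=side, supergroup5=sg)


def prok(species):
    return LeafMeta(kind="prokaryote", species_id=species)


def build_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestLecaCladeAnnotation:
    def meta_for(self, spec):
        """spec: leaf -> (side, sg index) for eukaryotes, None for prokaryotes."""
        meta = {}
        for leaf, v in spec.items():
            if v is None:
                meta[leaf] = prok(leaf)
            else:
                side, sg_i = v
                meta[leaf] = euk(leaf, side, SG5[sg_i])
        return meta

    def test_boundary_mean_exactly_15_is_leca(self):
        # 5 supergroups with totals (20,20,20,20,20); clade carries
        # 4,4,2,2,3 species -> percentages (20,20,10,10,15), mean 15.
        leaves = []
        spec = {}
        i = 0
        for sg_i, count in enumerate([4, 4, 2, 2, 3]):
            for j in range(count):
                name = f"e{i}"
                side = "left" if i % 2 == 0 else "right"
                spec[name] = (side, sg_i)
                leaves.append(name)
                i += 1
        spec["p1"] = None
        newick = "(p1,(" + ",(".join(leaves[:-1]) + "," + leaves[-1] + ")" * (len(leaves) - 1) + ");"
        tree = build_tree(newick)
        totals = {sg: 20 for sg in SG5}
        calls, is_leca = annotate_leca_clades(tree, self.meta_for(spec), totals)
        assert len(calls) == 1
        assert calls[0].mean_percentage == pytest.approx(15.0)
        assert calls[0].is_leca_clade
        assert is_leca

    def test_mean_below_threshold_not_leca(self):
        spec = {f"e{i}": ("left" if i % 2 else "right", i) for i in range(5)}
        spec["p1"] = None
        tree = build_tree("(p1,(e0,(e1,(e2,(e3,e4)))));")
        totals = {sg: 10 for sg in SG5}  # each sg at 10% -> mean 10
        calls, is_leca = annotate_leca_clades(tree, self.meta_for(spec), totals)
        assert calls[0].mean_percentage == pytest.approx(10.0)
        assert not is_leca

    def test_single_root_side_never_leca(self):
        spec = {f"e{i}": ("left", i) for i in range(5)}
        spec["p1"] = None
        tree = build_tree("(p1,(e0,(e1,(e2,(e3,e4)))));")
        totals = {sg: 1 for sg in SG5}  # 100% everywhere, mean 100
        calls, is_leca = annotate_leca_clades(tree, self.meta_for(spec), totals)
        assert calls[0].mean_percentage == pytest.approx(100.0)
        assert not calls[0].has_both_root_sides
        assert not is_leca

    def test_maximal_clades_only(self):
        # two eukaryote clades separated by prokaryotes: each maximal
        spec = {
            "e0": ("left", 0), "e1": ("right", 1),
            "e2": ("left", 2), "e3": ("right", 3),
            "p1": None, "p2": None,
        }
        tree = build_tree("((e0,e1),(p1,((e2,e3),p2)));")
        totals = {sg: 1 for sg in SG5}
        calls, is_leca = annotate_leca_clades(tree, self.meta_for(spec), totals)
        assert len(calls) == 2
        assert is_leca

    def test_unsampled_assignment_augments_clade(self):
        # clade alone is below threshold; assigned unsampled sequences lift it
        spec = {"e0": ("left", 0), "e1": ("right", 1), "p1": None}
        tree = build_tree("(p1,(e0,e1));")
        totals = {sg: 2 for sg in SG5}  # base percentages (50,50,0,0,0): mean 20
        meta = self.meta_for(spec)
        unsampled = {
            "u1": euk("x1", "left", SG5[2]),
            "u2": euk("x2", "right", SG5[3]),
        }
        calls_without, _ = annotate_leca_clades(tree, meta, totals)
        calls_with, _ = annotate_leca_clades(
            tree, meta, totals,
            unsampled_meta=unsampled, assignments={"u1": "e0", "u2": "e1"},
        )
        assert calls_with[0].mean_percentage > calls_without[0].mean_percentage

    def test_verdict_invariant_under_rerooting_on_prokaryote_edge(self):
        spec = {
            "e0": ("left", 0), "e1": ("right", 1), "e2": ("left", 2),
            "p1": None, "p2": None,
        }
        totals = {sg: 4 for sg in SG5}
        newick = "((e0,(e1,e2)),(p1,p2));"
        tree = build_tree(newick)
        _, verdict = annotate_leca_clades(tree, self.meta_for(spec), totals)
        rerooted = build_tree(newick)
        p2 = rerooted.find_node_with_taxon_label("p2")
        rerooted.reroot_at_edge(p2.edge)
        _, verdict2 = annotate_leca_clades(rerooted, self.meta_for(spec), totals)
        assert verdict == verdict2

    def test_fully_sampled_domain_is_always_leca(self):
        spec = {}
        leaves = []
        for sg_i in range(5):
            for j in range(2):
                name = f"e{sg_i}_{j}"
                spec[name] = ("left" if j == 0 else "right", sg_i)
                leaves.append(name)
        spec["p1"] = None
        newick = "(p1,(" + ",(".join(leaves[:-1]) + "," + leaves[-1] + ")" * (len(leaves) - 1) + ");"
        tree = build_tree(newick)
        totals = {sg: 2 for sg in SG5}
        _, is_leca = annotate_leca_clades(tree, self.meta_for(spec), totals, threshold=1.0)
        assert is_leca

    def test_zero_total_rejected(self):
        tree = build_tree("(e0,e1);")
        meta = {"e0": euk("a", "left", SG5[0]), "e1": euk("b", "right", SG5[1])}
        with pytest.raises(ValueError):
            annotate_leca_clades(tree, meta, {sg: 0 for sg in SG5})
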