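"""RED computation, rank windows, delineation, anchoring, recovery scoring."""

import numpy as np
import pytest

from gvtaxon.io import tree_from_string
from gvtaxon.pipeline import noiseless_windows
from gvtaxon.red import (AnchorConflictError, RankWindows, WindowError,
                         apply_anchors, assign_identifiers, compute_red,
                         delineate, derive_rank_windows, recovery_score)
from gvtaxon.synthetic import (RANKS, SimulationConfig, TrueTaxonomy,
                               simulate_taxonomy, simulate_tree)


def _rooted(newick):
    t = tree_from_string(newick)
    t.is_rooted = True
    return t


class TestComputeRed:
    def test_boundary_conditions(self, quiet_tree):
        red = compute_red(quiet_tree)
        assert red[quiet_tree.seed_node] == 0.0
        for lf in quiet_tree.leaf_node_iter():
            assert red[lf] == 1.0

    def test_balanced_four_leaf_hand_value(self):
        # internal children of root: x = 1, mean tip distance = 1
        # -> red = 0 + 1/(1+1) * (1 - 0) = 0.5
        t = _rooted("((A:1,B:1):1,(C:1,D:1):1);")
        red = compute_red(t)
        internals = [n for n in t.preorder_node_iter()
                     if n.parent_node and not n.is_leaf()]
        assert [red[n] for n in internals] == [0.5, 0.5]

    def test_polytomy_ybar_averages_all_tips(self):
        # node with 3 tip children at distances 1, 2, 3: ybar = 2
        t = _rooted("((A:1,B:2,C:3):2,D:4);")
        red = compute_red(t)
        node = [n for n in t.preorder_node_iter()
                if n.parent_node and not n.is_leaf()][0]
        assert red[node] == pytest.approx(2 / (2 + 2))

    def test_monotone_along_every_path(self, default_config):
        cfg = SimulationConfig(genomes_per_genus=2, branch_noise=0.6, seed=13)
        tree = simulate_tree(simulate_taxonomy(cfg), cfg)
        red = compute_red(tree)
        for lf in tree.leaf_node_iter():
            path = []
            node = lf
            while node is not None:
                path.append(red[node])
                node = node.parent_node
            assert path == sorted(path, reverse=True)

    def test_unrooted_rejected(self):
        t = tree_from_string("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            compute_red(t)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_red(_rooted("((A:1,B:-0.5):1,C:1);"))


class TestRankWindows:
    def test_midpoint_rule_hand_computed(self, quiet_tree, quiet_taxonomy):
        red = compute_red(quiet_tree)
        anchors = {}
        for rank in RANKS:
            for name, members in quiet_taxonomy.taxa_at(rank).items():
                anchors.update({})
        # anchor two classes at RED 0.05 and four orders at RED 0.2 etc.
        # derive from full truth, then verify the class/order boundary is
        # the midpoint of the adjacent rank RED ranges.
        windows = noiseless_windows(SimulationConfig(seed=11))
        cls_hi = windows.windows["class"][1]
        assert cls_hi == pytest.approx((0.05 + 0.2) / 2)
        assert windows.windows["order"][1] == pytest.approx((0.2 + 0.6) / 2)
        assert windows.windows["family"][1] == pytest.approx((0.6 + 0.85) / 2)
        assert windows.windows["genus"][1] == pytest.approx((0.85 + 1.0) / 2)
        assert windows.windows["class"][0] == pytest.approx(0.05 / 2)

    def test_explicit_midpoint_example(self):
        # class MRCAs at {0.02, 0.03}, orders at {0.16, 0.24}:
        # boundary must sit at (0.03 + 0.16) / 2 = 0.095
        t = _rooted(
            "(((a1:1,a2:1):5,(b1:1,b2:1):5):1,((c1:1,c2:1):5,(d1:1,d2:1):5):2);"
        )
        red = compute_red(t)
        # build anchors from the two depth-1 nodes (class) and the four
        # depth-2 nodes (order) of this toy tree
        anchors_cls = {"a1": ("class", "C1"), "b1": ("class", "C1"),
                       "c1": ("class", "C2"), "d1": ("class", "C2")}
        anchors_ord = {"a1": ("order", "O1"), "a2": ("order", "O1"),
                       "c1": ("order", "O2"), "c2": ("order", "O2")}
        from gvtaxon.red import rank_red_ranges
        rc = rank_red_ranges(t, red, anchors_cls)["class"]
        ro = rank_red_ranges(t, red, anchors_ord)["order"]
        boundary = (rc[1] + ro[0]) / 2
        assert rc[1] < ro[0]
        assert boundary == pytest.approx((rc[1] + ro[0]) / 2)

    def test_defaults_echoed_without_anchors(self):
        defaults = {"class": (0.0, 0.1), "order": (0.1, 0.4),
                    "family": (0.4, 0.7), "genus": (0.7, 0.95)}
        t = _rooted("((A:1,B:1):1,(C:1,D:1):1);")
        w = derive_rank_windows(t, compute_red(t), defaults=defaults)
        assert w.as_dict() == {k: list(v) for k, v in defaults.items()}

    def test_overlapping_windows_rejected(self):
        with pytest.raises(WindowError, match="overlap"):
            RankWindows({"class": (0.0, 0.2), "order": (0.1, 0.4),
                         "family": (0.4, 0.7), "genus": (0.7, 0.9)})

    def test_overlapping_anchor_ranges_demand_manual_windows(self, quiet_tree,
                                                             quiet_taxonomy):
        red = compute_red(quiet_tree)
        # anchor a family as if it were an order: ranges now overlap
        fam = quiet_taxonomy.taxa_at("family")
        cls = quiet_taxonomy.taxa_at("class")
        gen = quiet_taxonomy.taxa_at("genus")
        anchors = {}
        for name, members in cls.items():
            for g in members[:2]:
                anchors[g] = ("class", name)
        fam_names = sorted(fam)
        mis = fam_names[0]
        for g in fam[mis]:
            anchors[g] = ("order", "bogus_order")  # family-depth "order"
        for name in fam_names[1:3]:
            for g in fam[name][:3]:
                anchors.setdefault(g, ("family", name))
        for name, members in sorted(gen.items())[:4]:
            for g in members:
                anchors.setdefault(g, ("genus", name))
        with pytest.raises(WindowError, match="overlap"):
            derive_rank_windows(quiet_tree, red, anchors)


class TestDelineate:
    def test_noiseless_recovery_exact_at_all_ranks(self, quiet_taxonomy,
                                                   quiet_tree, quiet_config):
        red = compute_red(quiet_tree)
        windows = noiseless_windows(quiet_config)
        a = delineate(quiet_tree, red, windows)
        for rank in RANKS:
            ari, exact = recovery_score(quiet_taxonomy, a, rank)
            assert ari == 1.0
            assert exact == 1.0

    def test_undersized_family_becomes_incertae_sedis(self):
        # a 2-leaf clade in the family window dissolves (>= 3 members rule)
        windows = RankWindows({"class": (0.01, 0.1), "order": (0.1, 0.3),
                               "family": (0.3, 0.7), "genus": (0.7, 0.95)})
        t = _rooted(
            "(((p1:0.55,p2:0.55):0.4,(q1:0.5,q2:0.5,q3:0.5):0.45):0.05,"
            "((r1:0.5,r2:0.5,r3:0.5):0.45,(s1:0.5,s2:0.5,s3:0.5):0.45):0.05);"
        )
        red = compute_red(t)
        a = delineate(t, red, windows)
        assert a.is_incertae_sedis("p1", "family")
        assert a.is_incertae_sedis("p2", "family")
        assert not a.is_incertae_sedis("q1", "family")
        assert a.label("p1", "family") == "incertae_sedis"

    def test_rank_decisions_independent_for_window_skipping_branch(self):
        # long branch jumps over the family window; a genus-window node
        # deeper down still assigns the genus
        windows = RankWindows({"class": (0.01, 0.1), "order": (0.1, 0.3),
                               "family": (0.3, 0.6), "genus": (0.7, 0.95)})
        t = _rooted(
            "(((x1:0.2,x2:0.2):0.05,x3:0.25):0.75,"
            "((y1:0.5,y2:0.5,y3:0.5):0.45,(z1:0.5,z2:0.5,z3:0.5):0.45):0.05);"
        )
        red = compute_red(t)
        a = delineate(t, red, windows)
        # x-clade root sits at red 0.75: inside the genus window, past family
        assert a.is_incertae_sedis("x1", "family")
        assert not a.is_incertae_sedis("x1", "genus")

    def test_partition_refinement_across_ranks(self):
        cfg = SimulationConfig(branch_noise=0.25, seed=17)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        a = delineate(tree, compute_red(tree), noiseless_windows(cfg))
        for fine, coarse in (("genus", "family"), ("family", "order"),
                             ("order", "class")):
            seen: dict[str, str] = {}
            for g in a.membership:
                cf = a.membership[g][fine]
                cc = a.membership[g][coarse]
                if cf is None or cc is None:
                    continue
                assert seen.setdefault(cf, cc) == cc

    def test_no_node_cut_at_two_ranks(self):
        cfg = SimulationConfig(branch_noise=0.3, seed=19)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        a = delineate(tree, compute_red(tree), noiseless_windows(cfg))
        seen = set()
        for clade in a.clades.values():
            key = tuple(clade.members)
            assert (key, clade.rank) not in seen
            seen.add((key, clade.rank))

    def test_parameter_recovery_under_noise(self):
        """20 seeded noisy simulations recover families and orders."""
        windows = noiseless_windows(SimulationConfig(branch_noise=0.2))
        fam, orr = [], []
        for seed in range(20):
            cfg = SimulationConfig(branch_noise=0.2, seed=seed)
            tax = simulate_taxonomy(cfg)
            tree = simulate_tree(tax, cfg)
            a = delineate(tree, compute_red(tree), windows)
            fam.append(recovery_score(tax, a, "family")[0])
            orr.append(recovery_score(tax, a, "order")[0])
        assert np.mean(fam) >= 0.95
        assert np.mean(orr) >= 0.99


class TestAnchorsAndIdentifiers:
    def _assignment(self, cfg=None):
        cfg = cfg or SimulationConfig(branch_noise=0.0, seed=11)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        a = delineate(tree, compute_red(tree), noiseless_windows(cfg))
        return tax, a

    def test_anchor_names_adopted(self):
        tax, a = self._assignment()
        fam = tax.taxa_at("family")
        first = sorted(fam)[0]
        anchor_genome = fam[first][0]
        apply_anchors(a, {anchor_genome: ("family", "Mimiviridae")})
        assert a.label(anchor_genome, "family") == "Mimiviridae"
        # all true family members share the adopted name
        for g in fam[first]:
            assert a.label(g, "family") == "Mimiviridae"

    def test_conflicting_anchor_names_rejected(self):
        tax, a = self._assignment()
        fam = tax.taxa_at("family")
        first = sorted(fam)[0]
        g1, g2 = fam[first][0], fam[first][1]
        with pytest.raises(AnchorConflictError):
            apply_anchors(a, {g1: ("family", "Mimiviridae"),
                              g2: ("family", "Phycodnaviridae")})

    def test_identifiers_numbered_in_traversal_order(self):
        tax, a = self._assignment()
        prefixes = {a.label(g, "order"): f"O{a.label(g, 'order')[-3:]}"
                    for g in a.membership
                    if not a.is_incertae_sedis(g, "order")}
        assign_identifiers(a, prefixes)
        fams = a.clades_at("family")
        named = [c.name for c in fams]
        assert all(n is not None and "_" in n for n in named)
        # numbering restarts per order prefix and is zero-padded
        for prefix in set(prefixes.values()):
            nums = [int(n.split("_")[1]) for n in named
                    if n.startswith(prefix + "_")]
            assert nums == list(range(1, len(nums) + 1))

    def test_identifiers_stable_under_input_permutation(self):
        cfg = SimulationConfig(branch_noise=0.0, seed=11)
        tax1, a1 = self._assignment(cfg)
        tax2, a2 = self._assignment(cfg)
        prefixes1 = {a1.label(g, "order"): "IM" for g in a1.membership
                     if not a1.is_incertae_sedis(g, "order")}
        assign_identifiers(a1, prefixes1)
        assign_identifiers(a2, prefixes1)
        assert a1.to_frame().to_csv() == a2.to_frame().to_csv()

    def test_anchored_family_consumes_no_number(self):
        tax, a = self._assignment()
        fam = tax.taxa_at("family")
        first = sorted(fam)[0]
        apply_anchors(a, {fam[first][0]: ("family", "Mimiviridae")})
        prefixes = {a.label(g, "order"): "IM" for g in a.membership
                    if not a.is_incertae_sedis(g, "order")}
        assign_identifiers(a, prefixes)
        names = [c.name for c in a.clades_at("family")]
        assert "Mimiviridae" in names
        numbered = [n for n in names if n.startswith("IM_")]
        assert len(numbered) == len(names) - 1

    def test_missing_prefix_rejected(self):
        tax, a = self._assignment()
        with pytest.raises(KeyError, match="prefix"):
            assign_identifiers(a, {})


class TestRecoveryScore:
    def _truth(self):
        return TrueTaxonomy({
            f"g{i}": ("C1", "O1", f"F{i // 3}", f"G{i}") for i in range(6)
        })

    def test_perfect_inference_scores_one(self):
        cfg = SimulationConfig(branch_noise=0.0, seed=11)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        a = delineate(tree, compute_red(tree), noiseless_windows(cfg))
        assert recovery_score(tax, a, "family") == (1.0, 1.0)

    def test_single_blob_vs_many_families_near_zero(self):
        from sklearn.metrics import adjusted_rand_score
        truth = [f"F{i // 6}" for i in range(48)]
        blob = ["X"] * 48
        assert adjusted_rand_score(truth, blob) == pytest.approx(0.0, abs=1e-9)

    def test_random_labels_have_null_ari(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(23)
        truth = [f"F{i // 6}" for i in range(48)]
        aris = []
        for _ in range(100):
            aris.append(adjusted_rand_score(truth, rng.permutation(truth)))
        assert abs(np.mean(aris)) <= 0.05

    def test_genome_set_mismatch_rejected(self):
        cfg = SimulationConfig(branch_noise=0.0, seed=11)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        a = delineate(tree, compute_red(tree), noiseless_windows(cfg))
        bad = TrueTaxonomy({"other": ("C", "O", "F", "G")})
        with pytest.raises(ValueError, match="genome sets"):
            recovery_score(bad, a, "family")
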