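"""Cutoff calibration, ortholog selection, concatenation, benchmarking."""

import numpy as np
import pandas as pd
import pytest

from gvtaxon.markers import (benchmark_marker_sets, bootstrap_trees,
                             calibrate_cutoff, concatenate, monophyly_check,
                             nj_tree, select_orthologs)
from gvtaxon.io import tree_from_string
from gvtaxon.profiles import build_profile, search_profile
from gvtaxon.synthetic import (SimulationConfig, simulate_marker_alignments,
                               simulate_taxonomy, simulate_tree)
from gvtaxon.tree_support import tree_certainty


class TestCalibrateCutoff:
    def test_nearest_rank_hand_enumerated(self):
        scores = list(range(10, 210, 10))  # 10, 20, ..., 200 (n = 20)
        # rank = ceil(5/100 * 20) = 1 -> first ascending score
        assert calibrate_cutoff(scores, 5) == 10

    def test_single_score(self):
        assert calibrate_cutoff([50], 5) == 50

    def test_zeroth_percentile_is_minimum(self):
        assert calibrate_cutoff([30, 10, 20], 0) == 10

    def test_linear_method_available(self):
        assert calibrate_cutoff([0, 100], 50, method="linear") == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cutoff([], 5)


class TestSelectOrthologs:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["genome_id", "marker",
                                           "protein_id", "bitscore"])

    def test_single_survivor_is_best(self):
        t = select_orthologs(
            self._hits([("g1", "m", "p1", 100.0)]), {"m": 50.0})
        assert t.is_best.tolist() == [True]
        assert t.is_extra_copy.tolist() == [False]

    def test_second_survivor_is_extra_copy(self):
        t = select_orthologs(
            self._hits([("g1", "m", "p1", 120.0), ("g1", "m", "p2", 95.0)]),
            {"m": 50.0})
        best = t[t.is_best]
        extra = t[t.is_extra_copy]
        assert best.protein_id.tolist() == ["p1"]
        assert extra.protein_id.tolist() == ["p2"]

    def test_below_cutoff_hits_dropped(self):
        t = select_orthologs(
            self._hits([("g1", "m", "p1", 40.0)]), {"m": 50.0})
        assert len(t) == 0

    def test_bitscore_tie_broken_by_protein_id(self):
        t = select_orthologs(
            self._hits([("g1", "m", "pB", 100.0), ("g1", "m", "pA", 100.0)]),
            {"m": 0.0})
        assert t[t.is_best].protein_id.tolist() == ["pA"]

    def test_one_best_per_genome_marker_pair(self):
        rng = np.random.default_rng(0)
        rows = [(f"g{i}", f"m{j}", f"p{i}_{j}_{k}", float(rng.integers(60, 200)))
                for i in range(5) for j in range(3) for k in range(3)]
        t = select_orthologs(self._hits(rows), {f"m{j}": 0.0 for j in range(3)})
        per_pair = t[t.is_best].groupby(["genome_id", "marker"]).size()
        assert (per_pair == 1).all()

    def test_planted_paralogs_flagged_against_truth(self):
        """Extra-copy flags should match the generator's paralog records."""
        cfg = SimulationConfig(branch_noise=0.0, marker_loss_prob=0.0,
                               paralog_prob=0.4, seed=9)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        sim = simulate_marker_alignments(tree, ["m"], [250], cfg)
        aln = sim.alignments["m"]
        orthologs = {k: v for k, v in aln.items() if "|" not in k}
        prof = build_profile("m", orthologs, calibrate=False)
        rows = []
        for seq_id, seq in aln.items():
            hit = search_profile(seq_id, seq, prof)
            rows.append({"genome_id": seq_id.split("|")[0], "marker": "m",
                         "protein_id": seq_id, "bitscore": hit.bitscore})
        table = select_orthologs(pd.DataFrame(rows), {"m": 0.0})
        true_paralogs = {p for ids in sim.truth.paralog_ids for p in
                         (ids.split(",") if ids else [])}
        flagged = set(table[table.is_extra_copy].protein_id)
        n_copies = len(table)
        agree = n_copies - len(true_paralogs ^ flagged)
        assert true_paralogs  # planted something to detect
        assert agree / n_copies >= 0.95


class TestConcatenate:
    ALN = {
        "mB": {"g1": "AAAAA" * 10, "g2": "CCCCC" * 10},  # width 50
        "mA": {"g1": "D" * 100, "g2": "E" * 100},  # width 100
    }

    def test_widths_and_partitions_tile(self):
        c = concatenate(self.ALN)
        assert all(len(r) == 150 for r in c.rows.values())
        assert c.partitions == {"mA": (0, 100), "mB": (100, 150)}

    def test_missing_marker_gap_filled_to_partition_width(self):
        aln = {"mA": {"g1": "D" * 100, "g2": "E" * 100},
               "mB": {"g1": "A" * 50}}
        c = concatenate(aln)
        start, end = c.partitions["mB"]
        assert c.rows["g2"][start:end] == "-" * 50
        assert c.missing["g2"] == ["mB"]

    def test_canonical_order_independent_of_input_order(self):
        c1 = concatenate(dict(sorted(self.ALN.items())))
        c2 = concatenate(dict(sorted(self.ALN.items(), reverse=True)))
        assert c1.rows == c2.rows
        assert c1.partitions == c2.partitions

    def test_genome_absent_everywhere_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="absent from all markers"):
            c = concatenate(self.ALN, genome_set=["g1", "g2", "ghost"])
        assert "ghost" not in c.rows

    def test_partition_text_one_based_inclusive(self):
        c = concatenate(self.ALN)
        assert c.partition_text() == \
            "PROT, mA = 1-100\nPROT, mB = 101-150\n"


class TestBenchmark:
    def _system(self, seed, conflict=False):
        cfg = SimulationConfig(n_classes=2, orders_per_class=2,
                               families_per_order=1, genera_per_family=2,
                               genomes_per_genus=2, branch_noise=0.0,
                               marker_loss_prob=0.0, paralog_prob=0.0,
                               seed=seed)
        tax = simulate_taxonomy(cfg)
        tree = simulate_tree(tax, cfg)
        sim = simulate_marker_alignments(tree, ["m1", "m2"], [120, 120], cfg)
        alns = dict(sim.alignments)
        # A third marker evolved on a leaf-shuffled copy of the tree carries
        # a deliberately incongruent signal.
        shuffled = tree.clone(depth=1)
        rng = np.random.default_rng(seed + 1000)
        leaves = [lf for lf in shuffled.leaf_node_iter()]
        taxa = [lf.taxon for lf in leaves]
        for lf, tx in zip(leaves, rng.permutation(taxa)):
            lf.taxon = tx
        sim3 = simulate_marker_alignments(shuffled, ["m3"], [120], cfg)
        alns["m3"] = sim3.alignments["m3"]
        return alns

    def test_run_bookkeeping(self):
        alns = self._system(0)
        (res,) = benchmark_marker_sets({"pair": ["m1", "m2"]}, alns,
                                       n_runs=5, n_boot=10, seed=0)
        assert len(res.tc_values) == 5
        assert res.best_index == int(np.argmax(res.tc_values))
        assert res.backend == "nj_tree"

    def test_conflicting_marker_lowers_tc(self):
        """Excluding an incongruent marker should not hurt TC (10 replicates)."""
        incl, excl = [], []
        for seed in range(10):
            alns = self._system(seed)
            results = {
                r.name: r for r in benchmark_marker_sets(
                    {"with_m3": ["m1", "m2", "m3"], "without_m3": ["m1", "m2"]},
                    alns, n_runs=2, n_boot=15, seed=seed)
            }
            incl.append(results["with_m3"].best_tc)
            excl.append(results["without_m3"].best_tc)
        assert np.mean(excl) >= np.mean(incl)

    def test_failing_backend_recorded_not_raised(self):
        def broken(alignment, seed):
            raise RuntimeError("backend exploded")

        alns = self._system(1)
        (res,) = benchmark_marker_sets({"pair": ["m1", "m2"]}, alns,
                                       tree_backend=broken, n_runs=1,
                                       n_boot=2, seed=0)
        assert res.error is not None
        assert "exploded" in res.error

    def test_benchmark_deterministic(self):
        alns = self._system(2)
        r1 = benchmark_marker_sets({"pair": ["m1", "m2"]}, alns,
                                   n_runs=2, n_boot=5, seed=3)
        r2 = benchmark_marker_sets({"pair": ["m1", "m2"]}, alns,
                                   n_runs=2, n_boot=5, seed=3)
        assert r1[0].tc_values == r2[0].tc_values
        assert r1[0].trees == r2[0].trees


class TestMonophyly:
    def test_clean_groups(self):
        t = tree_from_string("((A1,A2),(B1,B2));")
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        assert monophyly_check(t, labels) == {"A": True, "B": True}

    def test_interleaved_groups(self):
        t = tree_from_string("((A1,B1),(A2,B2));")
        labels = {"A1": "A", "B1": "B", "A2": "A", "B2": "B"}
        assert monophyly_check(t, labels) == {"A": False, "B": False}

    def test_unknown_label_rejected(self):
        t = tree_from_string("((A1,A2),(B1,B2));")
        with pytest.raises(KeyError):
            monophyly_check(t, {"A1": "A", "A2": "A", "B1": "B", "Z": "B"})

    def test_agrees_with_bipartition_oracle_on_random_tree(self):
        """Unrooted monophyly must equal 'some split isolates the group'."""
        import dendropy

        rng = np.random.default_rng(11)
        n = 32
        names = [f"t{i:02d}" for i in range(n)]
        # random topology by sequential joining
        newick = self._random_newick(names, rng)
        t = tree_from_string(newick)
        t.is_rooted = False
        labels = {name: f"G{rng.integers(0, 5)}" for name in names}
        result = monophyly_check(t, labels)

        t2 = tree_from_string(newick)
        t2.is_rooted = False
        t2.encode_bipartitions()
        tn = t2.taxon_namespace
        split_masks = {int(b.leafset_bitmask) for b in t2.bipartition_encoding}
        full = (1 << n) - 1
        for grp, verdict in result.items():
            mask = 0
            for name, g in labels.items():
                if g == grp:
                    mask |= tn.taxon_bitmask(tn.get_taxon(name))
            expected = (mask in split_masks
                        or (full ^ mask) in split_masks
                        or bin(mask).count("1") == 1)
            assert verdict == expected, grp

    @staticmethod
    def _random_newick(names, rng):
        items = list(names)
        while len(items) > 3:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            b = items.pop(j)
            a = items.pop(i)
            items.append(f"({a},{b})")
        return f"({items[0]},{items[1]},{items[2]});"
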