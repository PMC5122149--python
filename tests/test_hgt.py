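"""HGT-evidence tests: G+C window arithmetic against counting oracles,
composition anomaly, incongruence detection on constructed and simulated
trees, neighborhood similarity, co-transfer components, and the
evidence-combination rule."""

import math

import numpy as np
import pytest

from chsphylo.hgt import (CotransferGroup, HgtCall, combine_evidence,
                          detect_cotransfer, detect_incongruent_leaves,
                          gc_anomaly, gc_windows, neighborhood_similarity)
from chsphylo.io import NeighborhoodTable, parse_newick
from chsphylo.phylo import bootstrap_support, root_by_outgroup
from chsphylo.simulate import OUTGROUP_GROUP

import pandas as pd


class TestGcWindows:
    def test_all_gc_sequence_window_count_law(self):
        prof = gc_windows("G" * 2000, window=1000, step=30)
        assert len(prof.starts) == (2000 - 1000) // 30 + 1 == 34
        assert all(v == 1.0 for v in prof.values)

    def test_at_only_sequence(self):
        prof = gc_windows("AT" * 1000, window=1000, step=30)
        assert all(v == 0.0 for v in prof.values)

    def test_mixed_sequence_matches_counting_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), 3000))
        prof = gc_windows(seq, window=500, step=37)
        for s, v in zip(prof.starts, prof.values):
            win = seq[s:s + 500]
            gc = sum(c in "GC" for c in win)
            tot = sum(c in "ACGT" for c in win)
            assert v == pytest.approx(gc / tot)

    def test_count_law_property(self, rng):
        for _ in range(50):
            L = int(rng.integers(1, 5000))
            window = int(rng.integers(1, 2000))
            step = int(rng.integers(1, 200))
            prof = gc_windows("A" * L, window=window, step=step)
            expect = (L - window) // step + 1 if L >= window else 0
            assert len(prof.starts) == expect

    def test_short_sequence_empty_profile(self):
        assert gc_windows("ACGT", window=10).values == []

    def test_case_and_ambiguity_handling(self):
        prof = gc_windows("gcgcnnnnat", window=10, step=1)
        # 4 G/C among 6 unambiguous bases
        assert prof.values[0] == pytest.approx(4 / 6)


class TestGcAnomaly:
    def test_region_at_background_mean(self, rng):
        bg = gc_windows("".join(rng.choice(list("ACGT"), 5000)), 1000, 30)
        mu = float(np.mean(bg.values))
        region = ("GC" * 500 + "AT" * 500)  # gc 0.5 ~ background mean
        z, flag = gc_anomaly(region, bg)
        assert abs(z) < 2 and not flag

    def test_simulated_recent_transfer_flagged(self, std_dataset):
        ds = std_dataset
        for g in ds.genes:
            if g.is_hgt:
                bg = gc_windows(ds.contexts[g.taxon])
                z, flag = gc_anomaly(g.cds, bg)
                assert flag
                # independent statistics oracle
                vals = np.array(bg.values)
                region_gc = sum(c in "GC" for c in g.cds) / len(g.cds)
                z_oracle = (region_gc - vals.mean()) / vals.std()
                assert z == pytest.approx(z_oracle)

    def test_zero_variance_fallback(self):
        bg = gc_windows("G" * 200 + "C" * 200, window=100, step=100)
        assert set(bg.values) == {1.0}
        z, flag = gc_anomaly("GC" * 100, bg)  # region 1.0 -> no anomaly
        assert not flag
        z, flag = gc_anomaly("GCGCGCGCAT" * 50, bg)  # differs by 0.2
        assert flag and math.isinf(z)


class TestIncongruence:
    def test_bacterial_leaf_inside_fungal_clade(self):
        # one bacteria-labeled gene nested in a supported fungal clade
        t = parse_newick(
            "(((f1:1,bac:1)100:1,(f2:1,f3:1)90:1)100:2,(b1:1,b2:1)100:2);",
            rooted=True)
        groups = {"f1": "fungi", "f2": "fungi", "f3": "fungi",
                  "bac": "bacteria", "b1": "bacteria", "b2": "bacteria"}
        calls = detect_incongruent_leaves(t, groups, support_min=60)
        assert [(c[0], c[2]) for c in calls] == [("bac", "fungi")]

    def test_congruent_tree_yields_nothing(self):
        t = parse_newick(
            "(((f1:1,f2:1)100:1,f3:1)100:2,((b1:1,b2:1)95:1,b3:1)100:2);",
            rooted=True)
        groups = {"f1": "fungi", "f2": "fungi", "f3": "fungi",
                  "b1": "bacteria", "b2": "bacteria", "b3": "bacteria"}
        assert detect_incongruent_leaves(t, groups, support_min=60) == []

    def test_unmapped_leaf_rejected(self):
        t = parse_newick("((a:1,b:1)90:1,(c:1,d:1)90:1);", rooted=True)
        with pytest.raises(ValueError):
            detect_incongruent_leaves(t, {"a": "x", "b": "x", "c": "y"})

    def test_simulated_transfers_recovered(self, std_dataset):
        ds = std_dataset
        tree = root_by_outgroup(
            bootstrap_support(ds.alignment, 100, "p", seed=5),
            ds.outgroup_ids)
        groups = {sid: grp for sid, (_t, grp) in ds.taxon_map.items()}
        calls = detect_incongruent_leaves(
            tree, {lf.taxon.label: groups[lf.taxon.label]
                   for lf in tree.leaf_node_iter()},
            support_min=60, ignore_groups={OUTGROUP_GROUP})
        assert {c[0] for c in calls} == ds.hgt_gene_ids

    def test_raising_support_min_is_monotone(self, std_dataset):
        ds = std_dataset
        tree = root_by_outgroup(
            bootstrap_support(ds.alignment, 100, "p", seed=5),
            ds.outgroup_ids)
        groups = {sid: grp for sid, (_t, grp) in ds.taxon_map.items()}
        leafmap = {lf.taxon.label: groups[lf.taxon.label]
                   for lf in tree.leaf_node_iter()}
        counts = [len(detect_incongruent_leaves(
            tree, leafmap, support_min=s, ignore_groups={OUTGROUP_GROUP}))
            for s in (0, 60, 90, 101)]
        assert counts == sorted(counts, reverse=True)


class TestNeighborhoods:
    def test_jaccard_identities(self):
        assert neighborhood_similarity(["a", "b"], ["a", "b"]) == 1.0
        assert neighborhood_similarity(["a"], ["b"]) == 0.0
        assert neighborhood_similarity(
            ["DUF1800", "DUF1501", "SE"],
            ["DUF1800", "DUF1501", "porin"]) == pytest.approx(0.5)

    def _table(self, rows):
        return NeighborhoodTable(pd.DataFrame(
            rows, columns=NeighborhoodTable.COLUMNS))

    def test_cross_group_shared_operon_one_component(self):
        rows = []
        for genome, gene in (("gA", "x"), ("gB", "y")):
            for k, fam in enumerate(["DUF1800", "DUF1501", "SE"], start=1):
                rows.append((genome, gene, k, fam, "+"))
        nb = self._table(rows)
        comps = detect_cotransfer(nb, {"gA": "p1", "gB": "p2"}, ["x", "y"],
                                  jaccard_min=0.5)
        assert len(comps) == 1
        assert comps[0].genomes == frozenset({"gA", "gB"})
        assert comps[0].shared_families == frozenset(
            {"DUF1800", "DUF1501", "SE"})

    def test_same_group_pairs_never_reported(self):
        rows = []
        for genome, gene in (("gA", "x"), ("gB", "y")):
            for k, fam in enumerate(["DUF1800", "DUF1501", "SE"], start=1):
                rows.append((genome, gene, k, fam, "+"))
        nb = self._table(rows)
        assert detect_cotransfer(nb, {"gA": "p1", "gB": "p1"},
                                 ["x", "y"], 0.5) == []

    def test_simulated_cotransfer_components(self, std_dataset):
        ds = std_dataset
        taxon_groups = {t: grp for _s, (t, grp) in ds.taxon_map.items()}
        comps = detect_cotransfer(ds.neighborhoods, taxon_groups,
                                  ds.neighborhoods.gene_ids, 0.5)
        flagged = set().union(*(c.gene_ids for c in comps))
        assert ds.hgt_gene_ids <= flagged
        for c in comps:
            assert set(ds.config.operon) <= set(c.shared_families)

    def test_raising_jaccard_min_never_flags_more_genes(self, std_dataset):
        ds = std_dataset
        taxon_groups = {t: grp for _s, (t, grp) in ds.taxon_map.items()}
        flagged = []
        for j in (0.2, 0.5, 0.8, 1.01):
            comps = detect_cotransfer(ds.neighborhoods, taxon_groups,
                                      ds.neighborhoods.gene_ids, j)
            flagged.append(set().union(*(c.gene_ids for c in comps))
                           if comps else set())
        for lo, hi in zip(flagged, flagged[1:]):
            assert hi <= lo


class TestCombineEvidence:
    def test_two_lines_make_strong(self):
        calls = combine_evidence([HgtCall("x", incongruent=True,
                                          composition_flag=True)])
        assert calls[0].verdict == "strong"

    def test_single_line_is_weak(self):
        calls = combine_evidence([HgtCall("x", synteny_flag=True)])
        assert calls[0].verdict == "weak"

    def test_no_evidence_is_none(self):
        assert combine_evidence([HgtCall("x")])[0].verdict == "none"


class TestIslandAnnotation:
    def test_bed_overlap_annotates_without_changing_verdicts(self, tmp_path):
        from chsphylo.hgt import annotate_island_overlap, read_bed
        bed = tmp_path / "islands.bed"
        bed.write_text("chr1\t100\t500\tprophage_A\nchr2\t0\t50\n")
        intervals = read_bed(bed)
        calls = combine_evidence([
            HgtCall("x", incongruent=True, composition_flag=True),
            HgtCall("y"),
        ])
        locs = {"x": ("chr1", 450, 900), "y": ("chr1", 600, 700)}
        out = annotate_island_overlap(calls, intervals, locs)
        assert out[0].island_annotations == ("prophage_A",)
        assert out[1].island_annotations == ()
        # annotations never decide calls
        assert out[0].verdict == "strong" and out[1].verdict == "none"
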