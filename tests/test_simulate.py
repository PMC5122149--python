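"""Simulator unit and property tests: every inference stage's ground truth
depends on these contracts holding."""

import math

import dendropy
import numpy as np
import pytest

from chsphylo.io import CodingGene
from chsphylo.motifs import detect_motif_duplication, find_catalytic_motifs
from chsphylo.phylo import rf_distance
from chsphylo.simulate import (EventRates, FixtureConfig, SpeciesTree,
                               apply_composition_shift, back_translate,
                               decay_motifs, emit_fixture, evolve_family,
                               evolve_sequences, gc_fraction,
                               make_recombinant, make_recombinant_aligned,
                               make_root_protein, n_gene_leaves,
                               replay_event_log, sample_species_tree,
                               translate_cds)


def _independent_path_lengths(tree: dendropy.Tree) -> list[float]:
    """Root-to-leaf path lengths by explicit upward traversal (oracle)."""
    out = []
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length
            nd = nd.parent_node
        out.append(d)
    return out


class TestSpeciesTree:
    def test_three_taxa_shape(self):
        sp = sample_species_tree(3, 1.0, 7)
        leaves = sp.leaf_labels
        internal = [nd for nd in sp.tree.preorder_node_iter()
                    if not nd.is_leaf()]
        assert len(leaves) == 3
        assert len(internal) == 2

    def test_seeded_determinism(self):
        a = sample_species_tree(8, 0.5, 1)
        b = sample_species_tree(8, 0.5, 1)
        assert (a.tree.as_string(schema="newick")
                == b.tree.as_string(schema="newick"))

    @pytest.mark.parametrize("n_groups", [1, 2])
    def test_ultrametric_exact_depth(self, n_groups):
        sp = sample_species_tree(16, 1.0, 42, n_groups=n_groups)
        for d in _independent_path_lengths(sp.tree):
            assert abs(d - 1.0) < 1e-9

    def test_rejects_tiny(self):
        with pytest.raises(ValueError):
            sample_species_tree(2, 1.0, 0)

    def test_groups_cover_all_leaves(self):
        sp = sample_species_tree(9, 0.7, 3)
        assert set(sp.taxon_groups) == set(sp.leaf_labels)
        assert set(sp.taxon_groups.values()) == {"g1", "g2"}


class TestEvolveFamily:
    def test_null_process_matches_species_tree(self):
        sp = sample_species_tree(8, 0.5, 1)
        gt, log = evolve_family(sp, EventRates(), 3)
        assert log == []
        labels = sorted(lf.taxon.label for lf in gt.leaf_node_iter())
        assert labels == sorted(f"{t}|g1" for t in sp.leaf_labels)
        # same topology once gene ids are stripped
        stripped = gt.clone(depth=1)
        for lf in stripped.leaf_node_iter():
            lf.taxon.label = lf.taxon.label.split("|")[0]
        assert rf_distance(stripped, sp.tree) == 0

    def test_duplications_match_log_replay(self):
        sp = sample_species_tree(8, 0.5, 1)
        gt, log = evolve_family(
            sp, EventRates(duplication_rate=1.0), 11)
        assert all(e.kind == "duplication" for e in log)
        assert n_gene_leaves(gt) == len(sp.leaf_labels) + sum(
            len(_descendant_taxa(sp, e.donor)) for e in log)
        assert replay_event_log(sp, log) == sorted(
            lf.taxon.label for lf in gt.leaf_node_iter())

    def test_hgt_only_crosses_clades(self):
        sp = sample_species_tree(10, 0.8, 5)
        gt, log = evolve_family(sp, EventRates(hgt_rate=1.5), 9)
        hgts = [e for e in log if e.kind == "hgt"]
        assert hgts, "expected at least one transfer at this rate"
        for e in hgts:
            assert e.donor != e.recipient
        assert replay_event_log(sp, log) == sorted(
            lf.taxon.label for lf in gt.leaf_node_iter())

    @pytest.mark.parametrize("seed", range(5))
    def test_replay_consistency_under_all_processes(self, seed):
        sp = sample_species_tree(8, 0.6, seed)
        rates = EventRates(duplication_rate=0.8, loss_rate=0.4, hgt_rate=0.4)
        gt, log = evolve_family(sp, rates, seed + 100)
        assert replay_event_log(sp, log) == sorted(
            lf.taxon.label for lf in gt.leaf_node_iter())

    def test_forced_hgt_lands_on_requested_branches(self):
        sp = sample_species_tree(8, 0.5, 1)
        donor, recip = sp.leaf_labels[0], sp.leaf_labels[-1]
        gt, log = evolve_family(sp, EventRates(), 3,
                                forced_hgts=[(donor, recip, 0.45)])
        assert [(e.kind, e.donor, e.recipient) for e in log] == [
            ("hgt", donor, recip)]
        extra = [lf.taxon.label for lf in gt.leaf_node_iter()
                 if lf.taxon.label.split("|")[0] == recip]
        assert len(extra) == 2  # native copy + acquired copy


def _descendant_taxa(sp: SpeciesTree, branch_label: str) -> list[str]:
    for nd in sp.tree.preorder_node_iter():
        lb = nd.taxon.label if nd.is_leaf() else nd.label
        if lb == branch_label:
            return [lf.taxon.label for lf in nd.leaf_iter()]
    raise KeyError(branch_label)


class TestEvolveSequences:
    def test_zero_rate_identity(self):
        sp = sample_species_tree(6, 0.5, 2)
        gt, _ = evolve_family(sp, EventRates(), 1)
        root = make_root_protein(120, seed=5)
        genes, aln = evolve_sequences(gt, root, 0.0, 0.0, seed=8)
        assert all(g.protein == root for g in genes)
        assert all("-" not in row for row in aln.rows)

    def test_motifs_survive_evolution(self):
        sp = sample_species_tree(8, 0.8, 4)
        gt, _ = evolve_family(sp, EventRates(), 1)
        genes, _ = evolve_sequences(gt, make_root_protein(250, seed=1),
                                    1.0, 0.05, seed=3)
        for g in genes:
            rep = find_catalytic_motifs(g.protein)
            assert rep.complete and rep.qxxxy_positions

    def test_p_distance_matches_closed_form(self):
        # two leaves separated by total branch length 0.5 at rate 1: the
        # 20-state uniform-jump chain gives
        # E[p] = (19/20) * (1 - exp(-20*r*t/19))
        tns = dendropy.TaxonNamespace()
        root = dendropy.Node()
        for lb in ("a|g1", "b|g2"):
            leaf = dendropy.Node(taxon=tns.new_taxon(lb))
            leaf.edge.length = 0.25
            root.add_child(leaf)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        n_sites = 2000
        prot = make_root_protein(n_sites, seed=9)
        genes, _ = evolve_sequences(tree, prot, 1.0, 0.0, seed=17)
        a, b = genes[0].protein, genes[1].protein
        n_anchor = 13  # 3 D + QXXRW + QXXXY positions never mutate
        free = n_sites - n_anchor
        diffs = sum(x != y for x, y in zip(a, b)) / free
        expect = (19 / 20) * (1 - math.exp(-20 * 0.5 / 19))
        sd = math.sqrt(expect * (1 - expect) / free)
        assert abs(diffs - expect) < 3 * sd

    def test_true_alignment_tracks_homology(self):
        sp = sample_species_tree(6, 0.5, 3)
        gt, _ = evolve_family(sp, EventRates(), 1)
        genes, aln = evolve_sequences(gt, make_root_protein(150, seed=2),
                                      0.8, 0.1, seed=5)
        for g in genes:
            assert aln.row(g.gene_id).replace("-", "") == g.protein


class TestComposition:
    def _gene(self, length, gc, seed=0):
        rng = np.random.default_rng(seed)
        prot = make_root_protein(length, seed=seed)
        return CodingGene("x|g1", "x", prot, cds=back_translate(prot, gc, rng),
                          host_gc=gc)

    def test_full_amelioration_reaches_host(self):
        g = self._gene(1000, 0.60, seed=1)
        out = apply_composition_shift(g, donor_gc=0.30, amelioration=1.0,
                                      seed=2)
        assert out.protein == g.protein
        assert abs(gc_fraction(out.cds) - 0.60) < 0.02

    def test_recent_transfer_keeps_donor_gc(self):
        g = self._gene(1000, 0.60, seed=3)  # cds length 3000
        out = apply_composition_shift(g, donor_gc=0.30, amelioration=0.0,
                                      seed=4)
        assert abs(gc_fraction(out.cds) - 0.30) <= 0.03

    def test_shift_is_synonymous_only(self):
        g = self._gene(300, 0.45, seed=5)
        out = apply_composition_shift(g, donor_gc=0.65, amelioration=0.25,
                                      seed=6)
        assert translate_cds(out.cds) == out.protein == g.protein

    def test_mixture_target_converges_at_long_length(self):
        # composition contract: length 30,000 nt, tolerance +/-0.01
        g = self._gene(10000, 0.60, seed=7)
        out = apply_composition_shift(g, donor_gc=0.30, amelioration=0.8,
                                      seed=8)
        target = 0.30 * 0.2 + 0.60 * 0.8
        assert abs(gc_fraction(out.cds) - target) <= 0.01

    def test_no_cds_rejected(self):
        g = CodingGene("y|g1", "y", make_root_protein(100, seed=1))
        with pytest.raises(ValueError):
            apply_composition_shift(g, 0.3, 0.0, 1)


class TestRecombinant:
    def test_forced_string_fusion(self):
        gN = CodingGene("n|g1", "n", "AAQWWWYAA")
        gC = CodingGene("c|g1", "c", "CCQRRRYCC")
        out = make_recombinant(gN, gC)
        assert out.protein == "AAQWWWYQRRRYCC"
        assert len(detect_motif_duplication(out.protein)) == 2
        assert out.is_recombinant

    def test_identical_inputs_tandem_duplication(self):
        g = CodingGene("a|g1", "a", "MMQAAAYKK")
        out = make_recombinant(g, g)
        assert out.protein == "MMQAAAYQAAAYKK"
        assert detect_motif_duplication(out.protein) == [2, 7]

    def test_missing_motif_rejected(self):
        gN = CodingGene("n|g1", "n", "AAQWWWYAA")
        bad = CodingGene("b|g1", "b", "MMMMMMMM")
        with pytest.raises(ValueError, match="b"):
            make_recombinant(gN, bad)

    def test_evolved_pair_scanner_finds_duplication(self, std_dataset):
        genes = [g for g in std_dataset.genes
                 if not g.is_hgt and not g.is_recombinant
                 and not g.taxon.startswith("outg")]
        out = make_recombinant(genes[0], genes[1])
        assert len(detect_motif_duplication(out.protein)) >= 2

    def test_aligned_fusion_consistent_with_sequence_fusion(self,
                                                            two_family_dataset):
        ds = two_family_dataset
        ids = [g.gene_id for g in ds.genes if g.true_class]
        aln2, chim = make_recombinant_aligned(ds.alignment, ids[0], ids[-1],
                                              new_id="q|chim")
        by_id = {g.gene_id: g for g in ds.genes}
        expect = make_recombinant(by_id[ids[0]], by_id[ids[-1]])
        assert chim.protein == expect.protein
        assert aln2.row("q|chim").replace("-", "") == chim.protein
        # reference rows unchanged up to inserted gap columns
        for sid in ds.alignment.ids:
            assert (aln2.row(sid).replace("-", "")
                    == ds.alignment.row(sid).replace("-", ""))


class TestDecay:
    def test_decay_destroys_filter_motifs(self, rng):
        prot = make_root_protein(200, seed=4)
        bad = decay_motifs(prot, rng)
        assert len(bad) == len(prot)
        assert not find_catalytic_motifs(bad).complete


class TestEmitFixture:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = FixtureConfig(n_taxa=6, n_forced_hgt=2, protein_length=150,
                            context_length=2000)
        sums = []
        for run in (1, 2):
            d = tmp_path / f"run{run}"
            emit_fixture(cfg, 11, d)
            sums.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
        assert sums[0] == sums[1]

    def test_event_log_rows_and_taxon_map_join(self, tmp_path):
        cfg = FixtureConfig(n_taxa=6, n_forced_hgt=2, protein_length=150,
                            context_length=2000)
        emit_fixture(cfg, 11, tmp_path)
        events = (tmp_path / "events.tsv").read_text().splitlines()[1:]
        assert sum(ln.startswith("hgt\t") for ln in events) == 2
        from chsphylo.io import read_fasta, read_taxon_map
        ids = list(read_fasta(tmp_path / "proteins.fasta"))
        tmap = read_taxon_map(tmp_path / "taxon_map.tsv")
        assert sorted(ids) == sorted(tmap)
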