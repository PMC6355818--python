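import math
import random

import dendropy
import pytest

from dupmode import SimConfig, simulate
from dupmode import dup_events as de
from dupmode.align_search import DNA_PARAMS, evalue
from dupmode.genome_io import GeneModel, GeneSequences
from dupmode.phylo import read_newick


def _model(gid, chrom, start, length=1000, **kw):
    end = start + length - 1
    return GeneModel(gid, chrom, "+", start, end, ((start, end),), **kw)


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestTandemClusters:
    def test_three_mutually_sister_genes_one_cluster(self):
        models = [_model("g1", "c1", 10_000), _model("g2", "c1", 40_000),
                  _model("g3", "c1", 70_000)]
        tree = _tree("((g1:1,g2:1):1,g3:2);")
        (cl,) = de.detect_tandem_clusters(models, tree)
        assert cl.members == ("g1", "g2", "g3")
        assert cl.sisterhood_fraction == 1.0 and cl.tandem_origin

    def test_genes_on_different_chromosomes_no_cluster(self):
        models = [_model("g1", "c1", 10_000), _model("g2", "c2", 12_000)]
        tree = _tree("(g1:1,g2:1);")
        assert de.detect_tandem_clusters(models, tree) == []

    def test_gap_limit_splits_chain(self):
        models = [_model("g1", "c1", 10_000), _model("g2", "c1", 500_000),
                  _model("g3", "c1", 520_000)]
        tree = _tree("((g2:1,g3:1):1,g1:2);")
        (cl,) = de.detect_tandem_clusters(models, tree, max_gap_bp=250_000)
        assert cl.members == ("g2", "g3")

    def test_intervening_gene_limit(self):
        fam = [_model("g1", "c1", 10_000), _model("g2", "c1", 100_000)]
        others = [_model(f"d{i}", "c1", 20_000 + 10_000 * i) for i in range(6)]
        tree = _tree("(g1:1,g2:1);")
        assert de.detect_tandem_clusters(fam, tree, max_intervening_genes=5,
                                         all_models=fam + others) == []
        assert de.detect_tandem_clusters(fam, tree, max_intervening_genes=6,
                                         all_models=fam + others) != []

    def test_order_independent(self):
        models = [_model("g1", "c1", 10_000), _model("g2", "c1", 40_000),
                  _model("g3", "c2", 70_000), _model("g4", "c1", 60_000)]
        tree = _tree("(((g1:1,g2:1):1,g4:1):1,g3:2);")
        ref = de.detect_tandem_clusters(models, tree)
        for seed in range(5):
            shuffled = models[:]
            random.Random(seed).shuffle(shuffled)
            got = de.detect_tandem_clusters(shuffled, tree)
            assert [c.members for c in got] == [c.members for c in ref]

    def test_gene_missing_from_tree_error(self):
        models = [_model("g1", "c1", 10_000), _model("gX", "c1", 40_000)]
        tree = _tree("(g1:1,g2:1);")
        with pytest.raises(de.DupEventsError, match="gX"):
            de.detect_tandem_clusters(models, tree)

    def test_planted_array_recovered_from_simulation(self):
        """A tandem-only simulation at zero divergence yields exactly one
        cluster holding every planted copy."""
        ds = simulate(SimConfig(seed=5, n_events=3,
                                event_type_counts=(3, 0, 0),
                                subs_rate_per_site_per_step=0.0))
        fam = [m for m in ds.models if m.source_tag == "sim_family"]
        tree = _tree(ds.true_tree_newick)
        (cl,) = de.detect_tandem_clusters(fam, tree, all_models=ds.models)
        assert set(cl.members) == set(ds.family_ids)
        assert len(cl.members) == 4


def _gene_seqs(gid, cds):
    return GeneSequences(gene_id=gid, cds=cds, protein="", flank5="", flank3="")


def _random_cds(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestSegmentalPairs:
    def _diverged(self, rng, cds, p):
        out = list(cds)
        for i in range(len(out)):
            if rng.random() < p:
                out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    def test_high_identity_pair_called(self):
        rng = random.Random(1)
        a = _random_cds(rng, 600)
        b = self._diverged(rng, a, 0.08)
        pairs = de.detect_segmental_pairs([_gene_seqs("a", a), _gene_seqs("b", b)])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.identity_pct > 80.0 and p.evalue < 1e-10
        assert p.reciprocal_best

    def test_low_identity_pair_not_called(self):
        rng = random.Random(2)
        a = _random_cds(rng, 600)
        b = self._diverged(rng, a, 0.30)
        assert de.detect_segmental_pairs(
            [_gene_seqs("a", a), _gene_seqs("b", b)]) == []

    def test_short_identical_cds_fails_evalue(self):
        """30 identical bp score S=30; at the DNA Karlin constants the
        closed form gives E ~ 2.6e-15 (well under 1e-10, so the pair is
        called); at 15 bp E ~ 3e-7 and the pair is rejected."""
        kp = DNA_PARAMS.karlin()
        assert evalue(30.0, 30, 30, kp) == pytest.approx(2.6e-15, rel=0.05)
        assert evalue(15.0, 15, 15, kp) == pytest.approx(3.0e-7, rel=0.05)
        short = "ATGGATAAAGATGAT"  # 15 bp
        assert de.detect_segmental_pairs(
            [_gene_seqs("a", short), _gene_seqs("b", short)]) == []
        cds30 = "ATGGATAAAGATGATATGGATAAAGATGCT"
        assert len(de.detect_segmental_pairs(
            [_gene_seqs("a", cds30), _gene_seqs("b", cds30)])) == 1

    def test_intra_cluster_pairs_excluded(self):
        rng = random.Random(3)
        a = _random_cds(rng, 600)
        cluster = de.TandemCluster("TC01", "c1", ("a", "b"), 1.0,
                                   {"a": True, "b": True})
        pairs = de.detect_segmental_pairs(
            [_gene_seqs("a", a), _gene_seqs("b", a)], clusters=[cluster])
        assert pairs == []

    def test_threshold_monotonicity(self):
        rng = random.Random(4)
        seqs = [_gene_seqs(f"g{i}", self._diverged(rng, _random_cds(rng, 300), 0.1))
                for i in range(4)]
        base = de.detect_segmental_pairs(seqs)
        tighter_id = de.detect_segmental_pairs(seqs, identity_threshold=90.0)
        tighter_e = de.detect_segmental_pairs(seqs, evalue_threshold=1e-40)
        as_set = lambda ps: {(p.gene_a, p.gene_b) for p in ps}
        assert as_set(tighter_id) <= as_set(base)
        assert as_set(tighter_e) <= as_set(base)

    def test_pairs_deduplicated_and_ordered(self):
        rng = random.Random(5)
        a = _random_cds(rng, 300)
        pairs = de.detect_segmental_pairs(
            [_gene_seqs("b", a), _gene_seqs("a", a)])
        assert len(pairs) == 1
        assert (pairs[0].gene_a, pairs[0].gene_b) == ("a", "b")


class TestAssignModes:
    def _setup(self):
        models = [_model("g1", "c1", 10_000), _model("g2", "c1", 14_000),
                  _model("g3", "c2", 50_000), _model("g4", "c3", 90_000)]
        cluster = de.TandemCluster("TC01", "c1", ("g1", "g2"), 1.0,
                                   {"g1": True, "g2": True})
        pairs = [de.SegmentalPair("g1", "g3", 92.0, 1e-30, True)]
        return models, [cluster], pairs

    def test_retro_precedence_with_tandem_membership(self):
        models, clusters, pairs = self._setup()
        calls = {c.gene_id: c for c in de.assign_modes(
            models, clusters, pairs, retro_primary={"g2"})}
        assert calls["g2"].primary_mode == "retro"
        assert calls["g2"].in_tandem_cluster and calls["g2"].retro_signature

    def test_tandem_call_excludes_upstream_founder(self):
        models, clusters, pairs = self._setup()
        calls = {c.gene_id: c.primary_mode for c in de.assign_modes(
            models, clusters, pairs, retro_primary=set())}
        assert calls["g2"] == "tandem"      # downstream copy
        assert calls["g1"] == "segmental"   # founder keeps its own origin

    def test_distant_chain_member_not_called_tandem(self):
        models = [_model("g1", "c1", 10_000), _model("g2", "c1", 80_000)]
        cluster = de.TandemCluster("TC01", "c1", ("g1", "g2"), 1.0,
                                   {"g1": True, "g2": True})
        calls = {c.gene_id: c.primary_mode for c in de.assign_modes(
            models, [cluster], [], retro_primary=set(),
            max_call_gap_bp=25_000)}
        assert calls["g2"] == "unclassified"

    def test_no_evidence_unclassified(self):
        models, clusters, pairs = self._setup()
        calls = {c.gene_id: c.primary_mode for c in de.assign_modes(
            models, clusters, pairs, retro_primary=set())}
        assert calls["g4"] == "unclassified"

    def test_duplicate_gene_ids_error(self):
        models = [_model("g1", "c1", 10_000), _model("g1", "c1", 40_000)]
        with pytest.raises(de.DupEventsError):
            de.assign_modes(models, [], [], retro_primary=set())

    def test_every_gene_called_once(self):
        models, clusters, pairs = self._setup()
        calls = de.assign_modes(models, clusters, pairs, retro_primary=set())
        assert sorted(c.gene_id for c in calls) == ["g1", "g2", "g3", "g4"]
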