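import numpy as np
import pytest

from thermobin.families import build_graph, mcl_cluster
from thermobin.homology import besthit_assign
from thermobin.io import Lineage
from thermobin.synthetic import (
    HitSimParams,
    TaxonModel,
    default_community,
    default_hit_params,
    default_references,
    default_scenario,
    generate_genome,
    identity_from_distance,
    js_divergence,
    make_transition_table,
    plant_protein_families,
    simulate_hit_table,
    simulate_reads,
    stationary_tetra_distribution,
)


def _model(transition, taxon_id="t1", abundance=1.0, length=2000):
    return TaxonModel(
        taxon_id=taxon_id,
        lineage=Lineage.from_names("Bacteria", "P1", "C1", "O1", "F1", "G1", "G1_sp"),
        genome_length=length,
        abundance=abundance,
        transition=transition,
    )


class TestGenerateGenome:
    def test_degenerate_chain_emits_only_a(self):
        table = np.zeros((64, 4))
        table[:, 0] = 1.0
        genome = generate_genome(_model(table), seed=5)
        # after the seeded context, the chain can only emit A
        assert set(genome[3:]) == {"A"} and len(genome) == 2000

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        table = make_transition_table(rng)
        m = _model(table)
        assert generate_genome(m, seed=11) == generate_genome(m, seed=11)
        assert generate_genome(m, seed=11) != generate_genome(m, seed=12)

    def test_invalid_transition_rejected(self):
        bad = np.full((64, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            _model(bad)

    def test_divergent_models_yield_divergent_empirical_profiles(self):
        # models whose stationary tetra distributions diverge by >= 0.05
        # must produce genomes diverging by more than half that target
        comm = default_community(seed=3, genome_length=60000)
        d0 = stationary_tetra_distribution(comm[0], seed=21)
        d1 = stationary_tetra_distribution(comm[1], seed=22)
        model_js = js_divergence(d0, d1)
        assert model_js >= 0.05
        from thermobin.tetra import tetra_freqs

        g0 = tetra_freqs(generate_genome(comm[0], seed=31))[0]
        g1 = tetra_freqs(generate_genome(comm[1], seed=32))[0]
        assert js_divergence(g0, g1) > 0.05 / 2


class TestSimulateReads:
    def test_single_taxon_truth(self):
        rng = np.random.default_rng(0)
        comm = [_model(make_transition_table(rng))]
        reads, truth = simulate_reads(comm, 10, length_mean=200, length_sd=20, seed=4)
        assert len(reads) == 10
        assert all(truth.taxon_of(r.id) == "t1" for r in reads)

    def test_truth_covers_exactly_the_read_set(self):
        comm = default_community(seed=1, genome_length=20000)
        reads, truth = simulate_reads(comm, 60, length_mean=300, length_sd=30, seed=4)
        assert {r.id for r in reads} == set(truth.origin)

    def test_abundance_skew_within_binomial_noise(self):
        rng = np.random.default_rng(1)
        t1 = _model(make_transition_table(rng), "t1", 0.9, 20000)
        t2 = _model(make_transition_table(rng), "t2", 0.1, 20000)
        n = 10000
        reads, truth = simulate_reads([t1, t2], n, length_mean=100, length_sd=10, seed=9)
        frac = sum(1 for r in reads if truth.taxon_of(r.id) == "t1") / n
        sd = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.9) <= 3 * sd

    def test_paired_reads_have_symmetric_mates(self):
        comm = default_community(seed=1, genome_length=20000)
        reads, _ = simulate_reads(
            comm, 40, length_mean=300, length_sd=30, paired=True, seed=4,
            fragment_mean=900, fragment_sd=50,
        )
        by_id = {r.id: r for r in reads}
        assert all(by_id[r.mate_id].mate_id == r.id for r in reads)

    def test_truth_coordinates_match_read_lengths(self):
        rng = np.random.default_rng(3)
        m = _model(make_transition_table(rng), length=5000)
        reads, truth = simulate_reads([m], 20, length_mean=150, length_sd=10, seed=7)
        for r in reads:
            _, s, e = truth.origin[r.id]
            assert r.length == e - s >= 50


class TestSimulateHitTable:
    def test_self_reference_recovers_truth(self):
        # distance 0: the reference is the organism itself, so the best hit
        # lineage must equal the truth lineage for (nearly) every hit-bearing read
        comm = default_community(seed=2, genome_length=20000, reference_distance=0.0)
        reads, truth = simulate_reads(comm, 300, length_mean=800, length_sd=80, seed=5)
        refs = default_references(comm)
        params = default_hit_params(comm, refs, search_type="nucleotide")
        hits = simulate_hit_table(reads, truth, refs, params, seed=6)
        assignments = besthit_assign(hits, refs, min_bit=300.0)
        taxon_genus = {m.taxon_id: m.lineage.name_at("genus") for m in comm}
        hit_bearing = [q for q in hits]
        correct = sum(
            1
            for q in hit_bearing
            if assignments[q].assigned
            and assignments[q].lineage.name_at("genus") == taxon_genus[truth.taxon_of(q)]
        )
        assert correct / len(hit_bearing) >= 0.99

    def test_self_reference_consensus_recovers_genus(self):
        # with the reference at distance 0, >= 95% of hit-bearing reads get
        # consensus assignments matching truth at genus level
        from thermobin.homology import LcaParams, consensus_assign, lca_assign

        comm = default_community(seed=4, genome_length=20000, reference_distance=0.0)
        reads, truth = simulate_reads(comm, 300, length_mean=800, length_sd=80, seed=8)
        refs = default_references(comm)
        prot = simulate_hit_table(
            reads, truth, refs, default_hit_params(comm, refs, "protein"), seed=9
        )
        nuc = simulate_hit_table(
            reads, truth, refs, default_hit_params(comm, refs, "nucleotide"), seed=10
        )
        consensus = consensus_assign(
            lca_assign(prot, refs, LcaParams()), besthit_assign(nuc, refs)
        )
        taxon_genus = {m.taxon_id: m.lineage.name_at("genus") for m in comm}
        hit_bearing = sorted(set(prot) | set(nuc))
        correct = sum(
            1
            for q in hit_bearing
            if consensus[q].assigned
            and consensus[q].lineage.name_at("genus") == taxon_genus[truth.taxon_of(q)]
        )
        assert correct / len(hit_bearing) >= 0.95

    def test_equal_identity_same_family_references_give_family_lca(self):
        # two references in one family at equal expected identity: the LCA
        # track lands at family (not genus) for most reads
        from thermobin.homology import LcaParams, lca_assign
        from thermobin.io import Lineage

        from dataclasses import replace

        model = replace(default_community(seed=5, genome_length=20000)[0], abundance=1.0)
        reads, truth = simulate_reads([model], 120, length_mean=800, length_sd=80, seed=6)
        fam = model.lineage.ranks[:5]
        refs = {
            "gA": Lineage(fam + ("GenusA", "GenusA_sp")),
            "gB": Lineage(fam + ("GenusB", "GenusB_sp")),
        }
        params = HitSimParams(
            identity={("aquificae_sp", "gA"): 85.0, ("aquificae_sp", "gB"): 85.0},
            hit_prob={("aquificae_sp", "gA"): 0.95, ("aquificae_sp", "gB"): 0.95},
        )
        hits = simulate_hit_table(reads, truth, refs, params, seed=7)
        out = lca_assign(hits, refs, LcaParams(min_support=1))
        ranks = [out[q].assigned_rank for q in hits]
        assert ranks.count("family") / len(ranks) > 0.5

    def test_zero_hit_probability_gives_empty_table(self):
        comm = default_community(seed=2, genome_length=20000)
        reads, truth = simulate_reads(comm, 20, length_mean=300, length_sd=30, seed=5)
        refs = default_references(comm)
        params = HitSimParams(identity={}, hit_prob={}, search_type="protein")
        assert simulate_hit_table(reads, truth, refs, params, seed=1) == {}

    def test_identity_monotone_in_reference_distance(self):
        assert identity_from_distance(0.0) == 100.0
        dists = np.linspace(0, 1, 11)
        ids = [identity_from_distance(d) for d in dists]
        assert all(a >= b for a, b in zip(ids, ids[1:]))
        # and end-to-end: mean simulated identity never rises with distance
        means = []
        for dist in (0.1, 0.4, 0.7):
            comm = default_community(seed=2, genome_length=20000, reference_distance=dist)
            reads, truth = simulate_reads(comm, 100, length_mean=400, length_sd=40, seed=5)
            refs = default_references(comm)
            params = default_hit_params(comm, refs)
            hits = simulate_hit_table(reads, truth, refs, params, seed=6)
            own = [
                h.percent_identity
                for grp in hits.values()
                for h in grp
                if h.subject_id.endswith("_refA")
            ]
            means.append(np.mean(own))
        assert means[0] >= means[1] >= means[2]

    def test_scenario_deterministic_under_seed(self):
        a = default_scenario(seed=5, n_reads=60)
        b = default_scenario(seed=5, n_reads=60)
        assert [r.sequence for r in a["reads"]] == [r.sequence for r in b["reads"]]
        assert a["protein_hits"] == b["protein_hits"]
        assert a["hit_free_ids"] == b["hit_free_ids"]


class TestPlantProteinFamilies:
    def test_zero_bridges_gives_connected_components(self):
        edges, _, truth = plant_protein_families(2, 5, between_prob=0.0, seed=1)
        g = build_graph(edges)
        clusters = mcl_cluster(g)
        assert len(clusters) == 2
        for c in clusters:
            assert len({truth[m] for m in c.members}) == 1

    def test_fully_labeled_families_transfer_everywhere(self):
        from thermobin.families import transfer_all

        edges, labels, truth = plant_protein_families(
            3, 6, labeled_fraction=0.5, between_prob=0.0, seed=2
        )
        clusters = mcl_cluster(build_graph(edges), ec_labels=labels)
        transferred = transfer_all(clusters, labels)
        unlabeled = [p for p in truth if p not in labels]
        assert unlabeled and all(p in transferred for p in unlabeled)

    def test_family_size_below_one_rejected(self):
        with pytest.raises(ValueError, match="family size"):
            plant_protein_families(2, [3, 0])
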