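"""Planted topologies, the cascade simulator, promoters and tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcgrn.motifs import registry_by_id, scan_sequence
from pcgrn.synthetic import (SimulationDesign, generate_grn_topology,
                             generate_promoters, simulate_expression,
                             simulate_verification_table)


class TestTopology:
    def test_minimal_chain_is_forced(self):
        net = generate_grn_topology(1, 1, 1, fan_in_max=1, seed=0)
        root, (a,), (b,), (g,) = (net.root_tf, net.layer2, net.layer3,
                                  net.layer4)
        assert net.edges == {(root, a), (a, b), (b, g)}

    def test_single_parent_edge_counts_at_published_scale(self):
        net = generate_grn_topology(20, 39, 247, fan_in_max=1, seed=7)
        layer = net.layer_map()
        counts = [0, 0, 0]
        for r, t in net.edges:
            counts[layer[r] - 1] += 1
        assert counts == [20, 39, 247] and len(net.edges) == 306

    def test_fan_in_bounds_by_enumeration(self):
        net = generate_grn_topology(3, 5, 10, fan_in_max=3, seed=1)
        for gene in (*net.layer3, *net.layer4):
            assert 1 <= len(net.parents(gene)) <= 3

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n2=st.integers(1, 6), n3=st.integers(1, 8), n4=st.integers(1, 10),
           fan=st.integers(1, 4), seed=st.integers(0, 10_000))
    def test_invariants_and_determinism(self, n2, n3, n4, fan, seed):
        net = generate_grn_topology(n2, n3, n4, fan_in_max=fan, seed=seed)
        layer = net.layer_map()
        assert all(layer[t] == layer[r] + 1 for r, t in net.edges)
        assert len(set(net.genes)) == 1 + n2 + n3 + n4
        again = generate_grn_topology(n2, n3, n4, fan_in_max=fan, seed=seed)
        assert net == again

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_grn_topology(0, 1, 1)
        with pytest.raises(ValueError):
            generate_grn_topology(1, 1, 1, fan_in_max=0)


class TestSimulateExpression:
    def test_chain_correlation_in_noiseless_limit(self):
        net = generate_grn_topology(1, 1, 1, fan_in_max=1, seed=0)
        design = SimulationDesign(noise_sd=1e-9, seed=3)
        expr = simulate_expression(net, design)
        for reg, tgt in net.edges:
            r = np.corrcoef(expr.gene_values(reg), expr.gene_values(tgt))[0, 1]
            assert r >= 0.999

    def test_column_count_follows_design(self):
        net = generate_grn_topology(1, 1, 1, seed=0)
        design = SimulationDesign(genotypes=("WT",), conditions=("control",),
                                  replicates=10, root_effect=(("WT", 1.0),),
                                  seed=0)
        expr = simulate_expression(net, design)
        assert expr.n_samples == 10
        assert all(s.genotype == "WT" for s in expr.samples)

    def test_fixed_seed_reproducible_bitwise(self, benchmark_net):
        d = SimulationDesign(seed=11)
        a = simulate_expression(benchmark_net, d)
        b = simulate_expression(benchmark_net, d)
        assert np.array_equal(a.values, b.values)

    def test_unlinked_components_uncorrelated_without_design_signal(self, rng):
        """Two genes with no directed path and no common ancestor: in a
        single-group design the only variance is independent noise, so
        correlation is near zero."""
        net = generate_grn_topology(2, 2, 2, fan_in_max=1, seed=5)
        design = SimulationDesign(genotypes=("WT",), conditions=("control",),
                                  replicates=200, root_effect=(("WT", 1.0),),
                                  seed=5)
        expr = simulate_expression(net, design)
        # the two layer-2 TFs share only the root; their residual noise
        # correlation is bounded well below the coexpression gate
        a, b = net.layer2
        r = np.corrcoef(expr.gene_values(a), expr.gene_values(b))[0, 1]
        assert abs(r) < 0.75

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SimulationDesign(replicates=1)
        with pytest.raises(ValueError):
            SimulationDesign(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimulationDesign(root_effect=(("OE", 0.2), ("WT", 1.0), ("RE", 0.3)))


class TestPromoters:
    def test_planted_element_recovered_at_recorded_position(self):
        ps = generate_promoters(["g1"], length=2000,
                                planted={"g1": ["GATA-box"]}, seed=9)
        seq = ps.sequences["g1"]
        planted = ps.planted["g1"][0]
        hits = scan_sequence(seq, registry_by_id()["GATA-box"], seq_id="g1")
        assert len(hits) >= 1
        assert any(h.offset == planted.core_hits[0].offset for h in hits)

    def test_no_room_for_background_gives_exact_site(self):
        ps = generate_promoters(["g"], length=9, planted={"g": ["GATA-box"]},
                                seed=0)
        assert ps.sequences["g"] in ("ATGATAAGG", "CCTTATCAT")

    def test_full_recovery_against_insertion_log(self):
        """Every planted element is found and no extra core hits exist."""
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        ids = list(registry_by_id())
        planted = {g: list(rng.choice(ids, size=rng.integers(1, 3),
                                      replace=False)) for g in genes}
        ps = generate_promoters(genes, length=2000, planted=planted, seed=4)
        for g in genes:
            expected = {(h.element_id, h.strand, h.offset)
                        for rec in ps.planted[g] for h in rec.core_hits}
            found = {(h.element_id, h.strand, h.offset)
                     for el in registry_by_id().values()
                     for h in scan_sequence(ps.sequences[g], el, seq_id=g)}
            assert found == expected

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            generate_promoters(["g"], length=10,
                               planted={"g": ["GATA-box", "GATA-box"]}, seed=0)


class TestVerificationTable:
    def test_all_direct(self, benchmark_net):
        recs = simulate_verification_table(benchmark_net, 20, p_direct=1.0,
                                           p_indirect=0.0, seed=1)
        assert all(r.classification == "direct" for r in recs)

    def test_all_unconfirmed(self, benchmark_net):
        recs = simulate_verification_table(benchmark_net, 5, p_direct=0.0,
                                           p_indirect=0.0, seed=1)
        assert all(r.classification == "unconfirmed" for r in recs)

    def test_direct_fraction_matches_probability(self, benchmark_net):
        """Monte-Carlo mean of the direct fraction ~ p_direct."""
        fractions = []
        for seed in range(40):
            recs = simulate_verification_table(benchmark_net, 30,
                                               p_direct=0.8,
                                               p_indirect=0.1333, seed=seed)
            fractions.append(np.mean([r.classification == "direct"
                                      for r in recs]))
        se = np.sqrt(0.8 * 0.2 / (30 * 40))
        assert np.mean(fractions) == pytest.approx(0.8, abs=4 * se)

    def test_parameter_validation(self, benchmark_net):
        with pytest.raises(ValueError):
            simulate_verification_table(benchmark_net, 5, p_direct=0.9,
                                        p_indirect=0.2, seed=0)
        with pytest.raises(ValueError):
            simulate_verification_table(benchmark_net, 10_000, seed=0)
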