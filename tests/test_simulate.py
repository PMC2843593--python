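"""Synthetic-data generator: determinism, generative rules, round-trips."""

import numpy as np
import pytest

from lanthirings.fragments import separating_bonds
from lanthirings.peptide import Topology
from lanthirings.simulate import (
    SimulationConfig,
    _sample_matching,
    generate_instance,
    observations_from_instance,
    simulate_stage_masses,
    simulate_variant_spectra,
)
from lanthirings.solver import RingTopologyModel


class TestGenerateInstance:
    def test_same_seed_identical_instances(self):
        a = generate_instance(SimulationConfig(seed=7))
        b = generate_instance(SimulationConfig(seed=7))
        assert a.precursor.sequence == b.precursor.sequence
        assert a.true_topology == b.true_topology
        assert a.variant_series == b.variant_series

    def test_different_seeds_differ(self):
        a = generate_instance(SimulationConfig(seed=7))
        b = generate_instance(SimulationConfig(seed=8))
        assert (
            a.precursor.sequence != b.precursor.sequence
            or a.true_topology != b.true_topology
        )

    def test_no_cys_empty_topology(self):
        inst = generate_instance(SimulationConfig(seed=1, n_cys=0))
        assert len(inst.true_topology) == 0
        assert inst.variant_series == [("WT", None, Topology())]

    def test_dehydro_classes_follow_residue(self):
        inst = generate_instance(SimulationConfig(seed=3))
        for pos, cls in inst.precursor.dehydro_positions().items():
            residue = inst.precursor.residue(pos)
            assert (cls, residue) in {("Dha", "S"), ("Dhb", "T")}

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_instance(
                SimulationConfig(seed=0, core_length=6, n_cys=4, n_dehydro=4)
            )
        with pytest.raises(ValueError):
            SimulationConfig(n_cys=5, n_dehydro=4).validate()

    def test_matching_distribution_uniform(self):
        """Each of the 4! = 24 matchings of fixed position sets is drawn
        with frequency 1/24 within 3 standard errors (10,000 draws)."""
        rng = np.random.default_rng(12345)
        cys, dehydro = [10, 20, 30, 40], [5, 15, 25, 35]
        n = 10_000
        counts = {}
        for _ in range(n):
            t = _sample_matching(rng, cys, dehydro, allow_crossing=True)
            counts[t.rings] = counts.get(t.rings, 0) + 1
        assert len(counts) == 24
        p = 1 / 24
        se = np.sqrt(p * (1 - p) / n)
        for rings, c in counts.items():
            assert abs(c / n - p) <= 3 * se + 1e-12, rings

    def test_non_crossing_option(self):
        for seed in range(10):
            inst = generate_instance(
                SimulationConfig(seed=seed, allow_crossing_rings=False)
            )
            ivals = sorted(tuple(sorted(r)) for r in inst.true_topology)
            for i, (a1, b1) in enumerate(ivals):
                for a2, b2 in ivals[i + 1 :]:
                    assert not (a1 < a2 < b1 < b2)


class TestStageMasses:
    def test_noiseless_shifts(self):
        inst = generate_instance(SimulationConfig(seed=5))
        masses = dict(simulate_stage_masses(inst))
        assert masses["dehydrated"] - masses["unmodified"] == pytest.approx(
            -72.0423, abs=1e-3
        )
        assert masses["cyclized"] == masses["dehydrated"]
        # all four Cys cyclized: IAA adds nothing
        assert masses["iaa"] - masses["cyclized"] == pytest.approx(0.0, abs=1e-9)

    def test_phospho_ladder_partial_counts(self):
        inst = generate_instance(SimulationConfig(seed=5))
        masses = dict(simulate_stage_masses(inst))
        for k in (2, 3, 4):
            assert masses[f"phospho_{k}"] - masses["unmodified"] == pytest.approx(
                k * 79.96633, abs=1e-3
            )

    def test_unmodified_mass_matches_peptide_model(self):
        inst = generate_instance(SimulationConfig(seed=5))
        masses = dict(simulate_stage_masses(inst))
        from lanthirings.peptide import ModifiedPeptide

        bare = ModifiedPeptide(id="bare", sequence=inst.precursor.sequence)
        assert masses["unmodified"] == pytest.approx(
            bare.neutral_mass(), abs=1e-9
        )


class TestVariantSpectra:
    def test_full_detection_roundtrip(self):
        """At p=1 and zero noise, matched evidence equals the separating
        bonds of each variant's true ring set."""
        inst = generate_instance(SimulationConfig(seed=11))
        obs = {o.variant_id: o for o in observations_from_instance(inst)}
        for variant_id, _sub, rings in inst.variant_series:
            expected = separating_bonds(inst.core_span, rings)
            assert obs[variant_id].evidence.cleavable_bonds == frozenset(expected)

    def test_p_zero_empty_peaklists(self):
        inst = generate_instance(SimulationConfig(seed=11, p_ion_detect=0.0))
        spectra = simulate_variant_spectra(inst)
        assert all(len(p) == 0 for p in spectra.values())

    def test_collateral_loss_removes_extra_ring(self):
        inst0 = generate_instance(SimulationConfig(seed=2))
        # pick one ring to lose collaterally when another Cys is mutated
        rings = sorted(inst0.true_topology.rings)
        victim, other = rings[0], rings[1]
        cfg = SimulationConfig(
            seed=2, collateral_loss={other[0]: frozenset({tuple(sorted(victim))})}
        )
        inst = generate_instance(cfg)
        by_id = {vid: r for vid, _s, r in inst.variant_series}
        assert victim not in by_id[f"C{other[0]}A"].rings

    def test_noise_peaks_added(self):
        inst = generate_instance(SimulationConfig(seed=4, n_noise_peaks=25))
        spectra = simulate_variant_spectra(inst)
        clean = simulate_variant_spectra(
            generate_instance(SimulationConfig(seed=4))
        )
        for vid in spectra:
            assert len(spectra[vid]) == len(clean[vid]) + 25


class TestPipelineRecovery:
    def test_strict_mode_contains_truth(self):
        """Soundness: in a noiseless full-coverage world the strict-mode
        candidate set always contains the hidden topology."""
        for seed in range(25):
            inst = generate_instance(SimulationConfig(seed=seed))
            obs = observations_from_instance(inst)
            res = RingTopologyModel(obs, span=inst.core_span).fit("strict")
            assert inst.true_topology in res.topologies, f"seed {seed}"

    def test_assertion_mode_unique_answers_are_correct(self):
        """Whenever protection-assertion mode returns a single topology it
        is the true one, and its unique-recovery rate is at least the
        strict-mode rate."""
        unique_assert = unique_strict = 0
        for seed in range(25):
            inst = generate_instance(SimulationConfig(seed=seed))
            obs = observations_from_instance(inst)
            model = RingTopologyModel(obs, span=inst.core_span)
            ra = model.fit("protection_assertion")
            rs = model.fit("strict")
            assert inst.true_topology in ra.topologies, f"seed {seed}"
            if ra.unique:
                unique_assert += 1
                assert ra.topology == inst.true_topology
            if rs.unique:
                unique_strict += 1
        assert unique_assert >= unique_strict

    def test_candidate_set_shrinks_with_detection_probability(self):
        """Average candidate-set size is non-increasing as ion coverage
        improves (the method's power curve)."""
        sizes = {}
        for p in (0.3, 0.7, 1.0):
            total = 0
            for seed in range(15):
                inst = generate_instance(
                    SimulationConfig(seed=seed, p_ion_detect=p)
                )
                obs = observations_from_instance(inst)
                res = RingTopologyModel(obs, span=inst.core_span).fit("strict")
                total += len(res.topologies)
            sizes[p] = total / 15
        assert sizes[1.0] <= sizes[0.7] <= sizes[0.3]
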