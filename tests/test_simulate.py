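"""Tests for the coalescent, copy-number and gene-conversion generators."""

import numpy as np
import pytest

from sdpop.popgen import sfs
from sdpop.simulate import (
    CNAlleleModel,
    DemographicEvent,
    DemographicModel,
    ModelValidationError,
    Population,
    SampleGroup,
    plant_igc,
    simulate_cn_genotypes,
    simulate_coalescent,
    simulate_star_genealogy,
    simulate_two_group_model,
)

MU = 1.25e-7  # inflated rate keeps fixture sizes small


def constant_model(n_e=1000, n=10, mu=MU):
    return DemographicModel.constant(n_e, n, mutation_rate=mu)


class TestModelValidation:
    def test_negative_size_rejected(self):
        with pytest.raises(ModelValidationError, match="size"):
            DemographicModel(populations=[Population("a", -5)],
                             samples=[SampleGroup("a", 2)])

    def test_disconnected_tree_rejected(self):
        with pytest.raises(ModelValidationError, match="not connected"):
            DemographicModel(
                populations=[Population("a", 100), Population("b", 100)],
                samples=[SampleGroup("a", 2), SampleGroup("b", 2)])

    def test_split_connects(self):
        m = DemographicModel(
            populations=[Population("a", 100), Population("b", 100)],
            samples=[SampleGroup("a", 2), SampleGroup("b", 2)],
            events=[DemographicEvent(50, "split",
                                     {"derived": "b", "ancestral": "a"})])
        assert m.events[0].kind == "split"

    def test_bad_event_named_in_error(self):
        with pytest.raises(ModelValidationError, match="split at t=50"):
            DemographicModel(
                populations=[Population("a", 100)],
                samples=[SampleGroup("a", 2)],
                events=[DemographicEvent(50, "split",
                                         {"derived": "zz", "ancestral": "a"})])

    def test_sampling_after_terminal_time_rejected(self):
        with pytest.raises(ModelValidationError, match="sampling time"):
            DemographicModel(
                populations=[Population("a", 100), Population("b", 100)],
                samples=[SampleGroup("a", 2), SampleGroup("b", 2, time=80)],
                events=[DemographicEvent(50, "split",
                                         {"derived": "b", "ancestral": "a"})])

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "mutation_rate: 1.0e-7\n"
            "generation_time: 25\n"
            "populations:\n"
            "  - {name: afr, size: 5000}\n"
            "  - {name: eur, size: 2000, growth_rate: 0.001}\n"
            "events:\n"
            "  - {time: 1500, kind: split, derived: eur, ancestral: afr}\n"
            "samples:\n"
            "  - {population: afr, n: 4}\n"
            "  - {population: eur, n: 4}\n")
        m = DemographicModel.from_config(cfg)
        assert m.generation_time == 25
        assert m.populations[1].growth_rate == 0.001
        rep = simulate_coalescent(m, 1000, seed=3)
        assert rep.haplotypes.n_haplotypes == 8


class TestCoalescentBasics:
    def test_single_haplotype_trivial(self):
        m = constant_model(n=1)
        rep = simulate_coalescent(m, 5000, seed=0)
        assert rep.haplotypes.n_sites == 0
        assert rep.tmrca == 0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_coalescent(constant_model(), 0, seed=0)

    def test_seed_determinism(self):
        a = simulate_coalescent(constant_model(), 2000, seed=7)
        b = simulate_coalescent(constant_model(), 2000, seed=7)
        assert np.array_equal(a.haplotypes.data, b.haplotypes.data)
        assert np.array_equal(a.haplotypes.positions, b.haplotypes.positions)
        assert a.tmrca == b.tmrca

    def test_positions_unique_and_in_range(self):
        rep = simulate_coalescent(constant_model(n_e=5000), 2000, seed=1)
        pos = rep.haplotypes.positions
        assert len(set(pos.tolist())) == len(pos)
        assert pos.min() >= 1 and pos.max() <= 2000

    def test_every_site_maps_to_one_branch(self):
        # infinite sites: every column is segregating (some subset, not all/none)
        rep = simulate_coalescent(constant_model(n_e=5000), 2000, seed=2)
        counts = rep.haplotypes.data.sum(axis=0)
        n = rep.haplotypes.n_haplotypes
        assert ((counts >= 1) & (counts < n)).all()

    def test_newick_tree_emitted(self):
        rep = simulate_coalescent(constant_model(n=4), 500, seed=0, with_tree=True)
        assert rep.tree.endswith(";") and rep.tree.count("pop0") == 4

    def test_watterson_mean_segregating_sites(self):
        # E[S] = theta * a1 within 3 Monte-Carlo SE over 2,000 replicates
        n_e, n, length = 1000, 10, 2000
        m = constant_model(n_e, n)
        ss = np.array([simulate_coalescent(m, length, seed=s).haplotypes.n_sites
                       for s in range(2000)], dtype=float)
        theta = 4 * n_e * MU * length
        expected = theta * sum(1 / i for i in range(1, n))
        se = ss.std(ddof=1) / np.sqrt(len(ss))
        assert abs(ss.mean() - expected) < 3 * se

    def test_pairwise_tmrca_expectation(self):
        # E[TMRCA] for n=2 is 2 N_e generations
        m = constant_model(n_e=1000, n=2)
        tm = np.array([simulate_coalescent(m, 100, seed=s).tmrca
                       for s in range(2000)])
        se = tm.std(ddof=1) / np.sqrt(len(tm))
        assert abs(tm.mean() - 2000) < 3 * se

    def test_sfs_matches_neutral_expectation(self):
        # E[S_i] = theta / i under constant size
        n_e, n, length = 1000, 8, 2000
        m = constant_model(n_e, n)
        theta = 4 * n_e * MU * length
        total = np.zeros(n - 1)
        reps = 2000
        for s in range(reps):
            rep = simulate_coalescent(m, length, seed=s)
            spec, _, _ = sfs(rep.haplotypes)
            total += spec
        mean = total / reps
        expected = theta / np.arange(1, n)
        # Poisson-ish MC error per class
        se = np.sqrt(np.maximum(total, 1)) / reps
        assert np.all(np.abs(mean - expected) < 4 * se + 0.05 * expected)

    def test_growth_shrinks_tmrca(self):
        flat = constant_model(n_e=2000, n=10, mu=1e-8)
        grown = DemographicModel(
            populations=[Population("pop0", 2000, 0.005)],
            samples=[SampleGroup("pop0", 10)],
            mutation_rate=1e-8)
        t_flat = np.mean([simulate_coalescent(flat, 100, s).tmrca
                          for s in range(300)])
        t_grown = np.mean([simulate_coalescent(grown, 100, s).tmrca
                           for s in range(300)])
        assert t_grown < t_flat

    def test_cross_validated_against_msprime(self):
        """Independent oracle: msprime under the identical constant-size model."""
        msprime = pytest.importorskip("msprime")
        n_e, n, length = 1000, 10, 2000
        m = constant_model(n_e, n)
        ours = np.array([simulate_coalescent(m, length, s).haplotypes.n_sites
                         for s in range(1000)], dtype=float)
        theirs = np.array([
            msprime.sim_mutations(ts, rate=MU, discrete_genome=False,
                                  random_seed=i + 1).num_sites
            for i, ts in enumerate(
                msprime.sim_ancestry(samples=n // 2, population_size=n_e,
                                     ploidy=2, sequence_length=length,
                                     num_replicates=1000, random_seed=42))])
        se = np.sqrt(ours.var(ddof=1) / 1000 + theirs.var(ddof=1) / 1000)
        assert abs(ours.mean() - theirs.mean()) < 3 * se


class TestTwoGroupModel:
    @staticmethod
    def model(t_split=4000, t_sample=1000, n_anc=1000):
        return DemographicModel.two_group(
            n_e_modern=1000, n_e_archaic=500, n_e_ancestral=n_anc,
            split_time=t_split, archaic_sampling_time=t_sample,
            n_modern=6, n_archaic=4, mutation_rate=MU)

    def test_requires_ancient_sampling(self):
        m = constant_model()
        with pytest.raises(ModelValidationError, match="ancient"):
            simulate_two_group_model(m, 1000, seed=0)

    def test_group_labels_preserved(self):
        rep = simulate_two_group_model(self.model(), 1000, seed=0)
        pops = rep.haplotypes.populations
        assert (pops == "modern").sum() == 6
        assert (pops == "archaic").sum() == 4

    def test_archaic_branch_shortening(self):
        """An ancient leaf's terminal branch is shorter than a modern leaf's
        by exactly the sampling time, so its private-mutation deficit is
        mu * L * t in expectation (branch-length bookkeeping)."""
        t_sample, length, reps = 2000.0, 2000, 2000
        m = DemographicModel(
            populations=[Population("g1", 500), Population("g2", 500)],
            samples=[SampleGroup("g1", 1, 0.0), SampleGroup("g2", 1, t_sample)],
            events=[DemographicEvent(t_sample + 1, "split",
                                     {"derived": "g2", "ancestral": "g1"})],
            mutation_rate=MU)
        diffs = []
        for s in range(reps):
            rep = simulate_two_group_model(m, length, seed=s)
            d = rep.haplotypes.data
            pops = rep.haplotypes.populations
            modern = int(d[pops == "g1"].sum())
            ancient = int(d[pops == "g2"].sum())
            diffs.append(modern - ancient)
        expected = MU * length * t_sample
        se = np.std(diffs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(diffs) - expected) < 3 * se

    def test_symmetric_model_exchangeable(self):
        """With equal sizes and equal (ancient) sampling times the two group
        labels are exchangeable: mean within-group diversity matches."""
        m = DemographicModel(
            populations=[Population("g1", 800), Population("g2", 800)],
            samples=[SampleGroup("g1", 5, 10.0), SampleGroup("g2", 5, 10.0)],
            events=[DemographicEvent(2000, "split",
                                     {"derived": "g2", "ancestral": "g1"})],
            mutation_rate=MU)
        pi1, pi2 = [], []
        for s in range(400):
            rep = simulate_two_group_model(m, 1000, seed=s)
            d = rep.haplotypes.data
            pops = rep.haplotypes.populations
            for arr, grp in ((pi1, "g1"), (pi2, "g2")):
                sub = d[pops == grp]
                arr.append(float(np.sum(sub.sum(0) * (5 - sub.sum(0)))))
        se = np.sqrt(np.var(pi1, ddof=1) / 400 + np.var(pi2, ddof=1) / 400)
        assert abs(np.mean(pi1) - np.mean(pi2)) < 3 * se

    def test_split_time_divergence_recovery(self):
        # E[cross-group pairwise diff per bp] = 2 mu (t_split + 2 N_anc)
        t_split, n_anc, length = 3000, 800, 2000
        m = DemographicModel(
            populations=[Population("g1", 500), Population("g2", 500)],
            samples=[SampleGroup("g1", 2, 0.0), SampleGroup("g2", 2, 1.0)],
            events=[
                DemographicEvent(t_split, "split",
                                 {"derived": "g2", "ancestral": "g1"}),
                DemographicEvent(t_split, "size_change",
                                 {"population": "g1", "size": n_anc}),
            ],
            mutation_rate=MU)
        divs = []
        for s in range(1500):
            rep = simulate_two_group_model(m, length, seed=s)
            d = rep.haplotypes.data
            pops = rep.haplotypes.populations
            g1 = d[pops == "g1"]
            g2 = d[pops == "g2"]
            pair_diffs = [(g1[i] != g2[j]).sum() for i in range(2) for j in range(2)]
            divs.append(np.mean(pair_diffs) / length)
        expected = 2 * MU * (t_split + 2 * n_anc - 0.5)  # -t_sample/2 correction
        se = np.std(divs, ddof=1) / np.sqrt(len(divs))
        assert abs(np.mean(divs) - expected) < 3 * se


class TestCNGenotypes:
    def test_single_class_fixed_cn2(self):
        model = CNAlleleModel({"archaic": {1: 1.0}})
        cn = simulate_cn_genotypes(model, 20, seed=0)
        assert np.all(cn.values == 2.0)

    def test_bounds_from_classes(self):
        model = CNAlleleModel({"p": {1: 0.3, 2: 0.4, 3: 0.3}})
        cn = simulate_cn_genotypes(model, 500, seed=1)
        assert cn.values.min() >= 2 and cn.values.max() <= 6

    def test_mean_is_twice_haploid_mean(self):
        freqs = {1: 0.2, 2: 0.5, 3: 0.3}
        model = CNAlleleModel({"p": freqs})
        cn = simulate_cn_genotypes(model, 20000, seed=2)
        hap_mean = sum(k * v for k, v in freqs.items())
        assert cn.values.mean() == pytest.approx(2 * hap_mean, rel=0.02)

    def test_class_frequencies_recovered(self):
        freqs = {1: 0.6, 3: 0.4}
        model = CNAlleleModel({"p": freqs})
        cn = simulate_cn_genotypes(model, 5000, seed=3)
        # haploid draws are hidden, but diploid CN=2 arises only from (1,1)
        p2 = float((cn.values == 2).mean())
        se = np.sqrt(0.36 * 0.64 / 5000)
        assert abs(p2 - 0.36) < 4 * se

    def test_empty_class_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CNAlleleModel({"p": {}})

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CNAlleleModel({"p": {1: 0.5, 2: 0.6}})


class TestPlantIGC:
    def test_zero_divergence_identical(self):
        a, b, _ = plant_igc(1000, 0.0, (100, 200), seed=0)
        assert a == b

    def test_tract_identical_flanks_diverged(self):
        a, b, tract = plant_igc(30000, 0.02, (10000, 20000), seed=1)
        a_arr = np.frombuffer(a.encode(), dtype="S1")
        b_arr = np.frombuffer(b.encode(), dtype="S1")
        inside = slice(*tract)
        assert np.all(a_arr[inside] == b_arr[inside])
        flank_mismatch = float((a_arr[:10000] != b_arr[:10000]).mean())
        assert flank_mismatch == pytest.approx(0.02, abs=0.005)

    def test_truth_coordinates_returned(self):
        _, _, tract = plant_igc(5000, 0.01, (1000, 1400), seed=2)
        assert tract == (1000, 1400)

    def test_tract_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            plant_igc(1000, 0.01, (900, 1100), seed=0)

    def test_bad_divergence_rejected(self):
        with pytest.raises(ValueError):
            plant_igc(1000, 1.5, (0, 10), seed=0)


class TestStarGenealogy:
    def test_all_mutations_are_singletons(self):
        rep = simulate_star_genealogy(10, 1000, 1e-5, 2000, seed=0)
        counts = rep.haplotypes.data.sum(axis=0)
        assert np.all(counts == 1)
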