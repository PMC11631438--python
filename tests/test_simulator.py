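import dataclasses

import numpy as np
import pytest

import kinfolk as kf
from kinfolk._intervals import total_length
from kinfolk.genome import GenomeLayout
from kinfolk.simulate import sample_gamete_map


TINY = GenomeLayout.uniform(2, 10_000_000)


def tiny_config(**kw):
    defaults = dict(layout=TINY, n_children=2, seed=0)
    defaults.update(kw)
    return kf.SimulationConfig(**defaults)


class TestFounders:
    def test_marker_count_tracks_density(self):
        cfg = tiny_config(marker_density=1e-3)
        founders = kf.simulate_founders(cfg)
        expected = TINY.total_bp * 1e-3
        assert abs(founders.n_sites - expected) < 5 * np.sqrt(expected)

    def test_fixed_half_frequency_heterozygosity(self):
        cfg = tiny_config(
            founder_spectrum=kf.FrequencySpectrum("fixed", (0.5,)))
        founders = kf.simulate_founders(cfg)
        mom = founders.samples["mother"]
        het = np.mean(mom.hap_a != mom.hap_b)
        assert het == pytest.approx(0.5, abs=0.02)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError, match="zero markers"):
            kf.simulate_founders(tiny_config(marker_density=1e-9, seed=3))

    def test_same_seed_identical_founders(self):
        a = kf.simulate_founders(tiny_config(seed=7))
        b = kf.simulate_founders(tiny_config(seed=7))
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.samples["father"].hap_a,
                              b.samples["father"].hap_a)


class TestMeiosis:
    def test_zero_map_density_transmits_one_haplotype(self):
        layout = GenomeLayout.uniform(1, 10_000_000, cm_per_mb=0.0)
        rng = np.random.default_rng(0)
        gm = sample_gamete_map(layout, rng)
        assert gm.breakpoints["chr1"] == ()

    def test_mean_one_crossover_per_morgan(self):
        layout = GenomeLayout.uniform(1, 100_000_000, cm_per_mb=1.0)
        rng = np.random.default_rng(1)
        counts = [len(sample_gamete_map(layout, rng).breakpoints["chr1"])
                  for _ in range(2000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.07)

    def test_gamete_alternates_parental_sources(self):
        cfg = tiny_config()
        founders = kf.simulate_founders(cfg)
        rng = np.random.default_rng(5)
        gamete, gmap = kf.simulate_meiosis(founders, "mother", TINY, rng)
        mom = founders.samples["mother"]
        for chrom in founders.chromosomes:
            sl = founders.chrom_slice(chrom)
            for i in range(sl.start, sl.stop):
                src = gmap.source_at(chrom, int(founders.pos[i]))
                expected = mom.hap_a[i] if src == 0 else mom.hap_b[i]
                assert gamete[i] == expected


class TestSimulateFamily:
    def test_zero_coefficients_plant_nothing(self):
        zero = kf.AgeModelCoefficients(
            per_type={t: kf.agemodel.TypeCoefficients(0, 0, 0, 0)
                      for t in kf.MUTATION_TYPES},
            reference_genome_bp=TINY.total_bp)
        sim = kf.simulate_family(tiny_config(coefficients=zero))
        assert sim.truth.dnms == []

    def test_planted_counts_match_analytic_mean(self):
        # aggregate across replicate families; per-child counts are
        # Poisson around the age-model expectation
        exp = kf.expected_counts(
            kf.default_truth_coefficients(TINY), 28.0, 32.0)
        totals = []
        for seed in range(30):
            sim = kf.simulate_family(tiny_config(
                n_children=1, marker_density=1e-4, seed=seed))
            totals.append(len(sim.truth.dnms))
        mean = np.mean(totals)
        lam = exp.grand_total
        assert abs(mean - lam) < 4 * np.sqrt(lam / len(totals))

    def test_maternal_mutator_inflates_only_maternal_target_type(self):
        fold = 4.0
        base = kf.expected_counts(
            kf.default_truth_coefficients(TINY), 28.0, 32.0)
        mat_ca = pat_ca = mat_other = 0
        n_reps = 40
        for seed in range(n_reps):
            sim = kf.simulate_family(tiny_config(
                n_children=1, marker_density=1e-4, seed=seed,
                mutator=kf.MutatorConfig("maternal", "C>A", fold)))
            for d in sim.truth.dnms:
                if d.spectrum_class == "C>A" and d.parent_of_origin == "maternal":
                    mat_ca += 1
                elif d.spectrum_class == "C>A" and d.parent_of_origin == "paternal":
                    pat_ca += 1
                elif d.parent_of_origin == "maternal":
                    mat_other += 1
        lam_mat_ca = fold * base.expected_mat["C>A"] * n_reps
        lam_pat_ca = base.expected_pat["C>A"] * n_reps
        lam_mat_other = sum(base.expected_mat[t] for t in kf.MUTATION_TYPES
                            if t != "C>A") * n_reps
        for obs, lam in ((mat_ca, lam_mat_ca), (pat_ca, lam_pat_ca),
                         (mat_other, lam_mat_other)):
            assert abs(obs - lam) < 4 * np.sqrt(lam)

    def test_embryonic_mutator_plants_unphased_excess(self):
        sim = kf.simulate_family(tiny_config(
            n_children=1, marker_density=1e-4, seed=1,
            mutator=kf.MutatorConfig("embryonic", "C>A", 6.0)))
        embryonic = [d for d in sim.truth.dnms
                     if d.parent_of_origin == "embryonic"]
        assert embryonic
        assert all(d.spectrum_class == "C>A" for d in embryonic)
        assert {d.haplotype for d in embryonic} <= {"A", "B"}

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            kf.MutatorConfig("maternal", "C>A", 0.5)

    def test_same_seed_byte_identical(self):
        a = kf.simulate_family(tiny_config(seed=9))
        b = kf.simulate_family(tiny_config(seed=9))
        assert np.array_equal(a.genotypes.pos, b.genotypes.pos)
        for s in a.genotypes.sample_ids:
            assert np.array_equal(a.genotypes.samples[s].hap_a,
                                  b.genotypes.samples[s].hap_a)
            assert np.array_equal(a.genotypes.samples[s].alt_depth,
                                  b.genotypes.samples[s].alt_depth)
        assert a.truth.dnms == b.truth.dnms

    def test_planted_dnms_absent_from_founders_and_panel(self, clean_family):
        g = clean_family.genotypes
        for d in clean_family.truth.dnms:
            i = g.site_index(d.chrom, d.pos)
            assert g.panel_alt_freq[i] == 0.0
            assert g.samples["mother"].is_hom_ref(i)
            assert g.samples["father"].is_hom_ref(i)

    def test_true_ibd_segments_partition_each_chromosome(self, clean_family):
        truth = clean_family.truth
        layout = clean_family.config.layout
        for parent in ("maternal", "paternal"):
            shared = truth.pair_sharing("child1", "child2", parent)
            for c in layout:
                assert all(0 <= s < e <= c.length_bp
                           for s, e in shared[c.name])

    def test_germline_het_vaf_centers_at_half(self, clean_family):
        g = clean_family.genotypes
        vafs = []
        for d in clean_family.truth.dnms:
            i = g.site_index(d.chrom, d.pos)
            v = g.vaf(d.child, i)
            if v == v:
                vafs.append(v)
        assert len(vafs) > 100
        se = np.std(vafs) / np.sqrt(len(vafs))
        assert abs(np.mean(vafs) - 0.5) < 3 * se


class TestBenchmark:
    def test_perfect_caller_on_clean_sim(self, clean_family):
        sim = clean_family
        config = kf.SurrogateConfiguration(
            real_parents=frozenset({"mother", "father"}))
        regs = kf.accessible_regions("child1", sim.pedigree, [], config,
                                     sim.config.layout)
        calls = kf.call_mendelian_violations(
            sim.genotypes, "child1", ["mother", "father"], regs)
        calls = kf.apply_site_filters(calls, sim.genotypes, sim.pedigree)
        res = kf.benchmark(calls, sim.truth, regs)
        assert res.precision == 1.0
        assert res.recall == 1.0
        assert res.recall_in_accessible == 1.0

    def test_inaccessible_truth_counted_separately(self, clean_family,
                                                   clean_family_segments):
        sim = clean_family
        config = kf.SurrogateConfiguration(
            real_parents=frozenset({"mother"}),
            surrogate_fathers=frozenset({"child2"}))
        regs = kf.accessible_regions("child1", sim.pedigree,
                                     clean_family_segments, config,
                                     sim.config.layout)
        calls = kf.call_mendelian_violations(
            sim.genotypes, "child1", ["mother", "child2"], regs)
        calls = kf.apply_site_filters(calls, sim.genotypes, sim.pedigree)
        res = kf.benchmark(calls, sim.truth, regs)
        assert res.precision == 1.0
        assert res.recall_in_accessible == 1.0
        assert res.fn_by_cause["missed"] == 0
        n_outside = sum(
            1 for d in sim.truth.dnms_of("child1")
            if not regs.contains(d.chrom, d.pos))
        assert res.fn_by_cause["inaccessible"] == n_outside

    def test_wrong_proband_rejected(self, clean_family):
        sim = clean_family
        config = kf.SurrogateConfiguration(
            real_parents=frozenset({"mother", "father"}))
        regs = kf.accessible_regions("child1", sim.pedigree, [], config,
                                     sim.config.layout)
        regs.proband = "nobody"
        with pytest.raises(ValueError, match="not a simulated child"):
            kf.benchmark([], sim.truth, regs)

    def test_gene_conversion_attributed_when_shared_filter_off(self):
        # heavy conversion, surrogate-only calling, no shared/panel rescue
        cfg = tiny_config(n_children=2, seed=12, gene_conversion_rate=30.0,
                          gene_conversion_tract_bp=5_000)
        sim = kf.simulate_family(cfg)
        segs = []
        s = kf.infer_sibling_ibd(
            sim.genotypes, ("child1", "child2"),
            kf.IBDParams(min_length_bp=500_000, min_markers=30))
        segs.extend(kf.classify_parental_origin(
            s, sim.genotypes, "mother",
            kf.IBDParams(min_length_bp=500_000, min_markers=30)))
        config = kf.SurrogateConfiguration(
            real_parents=frozenset({"mother"}),
            surrogate_fathers=frozenset({"child2"}))
        regs = kf.accessible_regions("child1", sim.pedigree, segs, config,
                                     cfg.layout)
        if regs.total_bp == 0:
            pytest.skip("no paternal sharing drawn in this replicate")
        calls = kf.call_mendelian_violations(
            sim.genotypes, "child1", ["mother", "child2"], regs)
        res = kf.benchmark(calls, sim.truth, regs)
        if res.n_fp:
            assert res.fp_by_cause["gene_conversion"] + \
                res.fp_by_cause["ibd_boundary"] > 0
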