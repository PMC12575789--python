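"""Synthetic-data generator: determinism, planted structure, model properties."""

import numpy as np
import pandas as pd
import pytest

from repeatscape import (
    GenomicInterval,
    PhasedLocusSpec,
    SimulationConfig,
    genome_median_depth,
    make_cohort,
    make_mini_reference,
    make_signature_matrix,
    simulate_depth_track,
    simulate_methylome,
    simulate_mutation_catalog,
    simulate_phased_locus,
    simulate_sv_callsets,
)
from repeatscape.coverage import filter_te_annotation
from repeatscape.simulate import ChromSpec, _rng


class TestReference:
    def test_contig_lengths_match_spec(self, reference, sim_config):
        assert reference.contigs == [(s.name, s.length) for s in sim_config.genome_spec]

    def test_byte_identical_under_fixed_seed(self, tmp_path, sim_config):
        ref1 = make_mini_reference(sim_config)
        ref2 = make_mini_reference(SimulationConfig(seed=sim_config.seed))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1, b1 = ref1.write(d1)
        f2, b2 = ref2.write(d2)
        assert f1.read_bytes() == f2.read_bytes()
        assert b1.read_bytes() == b2.read_bytes()

    def test_different_seed_different_sequence(self, sim_config, reference):
        other = make_mini_reference(SimulationConfig(seed=sim_config.seed + 1))
        assert other.sequences["chr1"] != reference.sequences["chr1"]

    def test_te_lengths_straddle_filters(self, reference):
        annot = list(reference.annotation)
        assert len(filter_te_annotation(annot, "L1HS", 6000)) == 4
        assert len([iv for iv in annot if iv.label == "L1HS"]) == 10
        assert len(filter_te_annotation(annot, "AluY", 300)) == 40
        assert len(filter_te_annotation(annot, "SVA", 1000)) == 8
        assert len(filter_te_annotation(annot, "ERV", 1000)) == 4

    def test_overlapping_same_class_spans_rejected(self):
        spec = (ChromSpec("chr1", 100_000,
                          ((1000, 5000, "L1HS"), (4000, 9000, "L1HS"))),)
        with pytest.raises(ValueError, match="overlap"):
            make_mini_reference(SimulationConfig(seed=0, genome_spec=spec))

    def test_cpg_sites_are_cg_dinucleotides(self, reference):
        seq = reference.sequences["chr1"]
        for pos in reference.cpg_sites["chr1"][:200]:
            assert seq[pos : pos + 2] == "CG"


class TestSeedStreams:
    def test_streams_independent_per_sample(self, sim_config):
        a = _rng(sim_config, "depth", "T1").integers(0, 1_000_000, 5)
        b = _rng(sim_config, "depth", "T2").integers(0, 1_000_000, 5)
        assert not np.array_equal(a, b)

    def test_adding_a_sample_does_not_reshuffle_others(self, reference):
        cfg2 = SimulationConfig(seed=1, n_pairs=2)
        cfg6 = SimulationConfig(seed=1, n_pairs=6)
        m2 = {m.sample_id: m for m in make_cohort(cfg2)}
        m6 = {m.sample_id: m for m in make_cohort(cfg6)}
        d2 = simulate_depth_track(cfg2, reference, m2["N1"])
        d6 = simulate_depth_track(cfg6, reference, m6["N1"])
        pd.testing.assert_frame_equal(d2, d6)


class TestDepth:
    def test_genome_median_near_target(self, sim_config, reference, cohort):
        for meta in cohort[:2]:
            depth = simulate_depth_track(sim_config, reference, meta)
            assert 28 <= genome_median_depth(depth) <= 32

    def test_tumor_te_dispersion_inflated(self, reference, cohort):
        cfg = SimulationConfig(seed=3, tumor_variance_inflation=6.0)
        tumor = next(m for m in cohort if m.group == "tumor")
        normal = next(m for m in cohort if m.group == "normal")
        te = [iv for iv in reference.annotation if iv.label == "L1HS"]

        def te_var(meta):
            d = simulate_depth_track(cfg, reference, meta)
            mask = np.zeros(len(d), dtype=bool)
            for iv in te:
                mask |= (d["chrom"] == iv.chrom) & (d["start"] >= iv.start) & (d["start"] < iv.end)
            return d.loc[mask, "depth"].var()

        assert te_var(tumor) > 2 * te_var(normal)

    def test_null_inflation_indistinguishable(self, reference, cohort):
        from repeatscape import compare_variance

        cfg = SimulationConfig(seed=4, tumor_variance_inflation=1.0)
        tumor = next(m for m in cohort if m.group == "tumor")
        normal = next(m for m in cohort if m.group == "normal")
        te = [iv for iv in reference.annotation if iv.label == "L1HS"]
        dt = simulate_depth_track(cfg, reference, tumor)
        dn = simulate_depth_track(cfg, reference, normal)

        def te_vals(d):
            mask = np.zeros(len(d), dtype=bool)
            for iv in te:
                mask |= (d["chrom"] == iv.chrom) & (d["start"] >= iv.start) & (d["start"] < iv.end)
            return d.loc[mask, "depth"].to_numpy()

        _, p = compare_variance(te_vals(dt), te_vals(dn))
        assert p > 0.01  # no planted effect to detect


class TestMethylome:
    def test_uniform_effect_recovered(self, reference):
        effects = {"background": (0.8, 0.8, 0.8)}
        cfg = SimulationConfig(seed=5, methylation_effects=effects)
        meta = make_cohort(cfg)[1]  # a normal
        meth = simulate_methylome(cfg, reference, meta)
        pooled = meth["n_mod"].sum() / meth["n_valid"].sum()
        assert pooled == pytest.approx(0.8, abs=0.02)

    def test_zero_coverage_sites_present(self, sim_config, reference, normal):
        meth = simulate_methylome(sim_config, reference, normal)
        assert (meth["n_valid"] == 0).any()
        assert len(meth) == sum(len(v) for v in reference.cpg_sites.values())

    def test_planted_group_ordering_in_satellites(self, sim_config, reference, cohort):
        from repeatscape import bin_methylation, make_bins

        sat = [iv for iv in reference.annotation if iv.label == "active_hor"]
        bins = make_bins(sat)
        by_group = {}
        picks = {
            "normal": next(m for m in cohort if m.group == "normal"),
            "high": next(m for m in cohort if m.group == "tumor" and m.hrd_score >= 63),
            "low": next(m for m in cohort if m.group == "tumor" and m.hrd_score < 63),
        }
        for name, meta in picks.items():
            meth = simulate_methylome(sim_config, reference, meta)
            by_group[name] = np.nanmean(bin_methylation(meth, bins))
        assert by_group["normal"] > by_group["high"] > by_group["low"]


class TestSvCallsets:
    def test_perfect_callers_reproduce_truth(self, reference, tumor):
        from repeatscape import merge_callsets

        cfg = SimulationConfig(
            seed=6, breakpoint_jitter_sd=0.0,
            caller_sensitivities={c: 1.0 for c in "abcd"}, n_fp_per_caller=0,
        )
        callsets, truth = simulate_sv_callsets(cfg, reference, tumor)
        cons = merge_callsets(callsets)
        expected = truth[(truth["svtype"] == "TRA") | (truth["svlen"] >= 50)]
        assert len(cons) == len(expected)
        got = {(c.representative.chrom1, c.representative.pos1) for c in cons}
        want = {(r.chrom1, r.pos1) for r in expected.itertuples(index=False)}
        assert got == want

    def test_two_perfect_two_blind_callers_support_two(self, reference, tumor):
        cfg = SimulationConfig(
            seed=7, caller_sensitivities={"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0},
            n_fp_per_caller=0,
        )
        callsets, truth = simulate_sv_callsets(cfg, reference, tumor)
        assert (truth["n_detected"] == 2).all()
        assert len(callsets["c"]) == 0 and len(callsets["d"]) == 0

    def test_truth_table_marks_detections(self, sim_config, reference, tumor):
        callsets, truth = simulate_sv_callsets(sim_config, reference, tumor)
        for caller, records in callsets.items():
            n_true_calls = int(truth[caller].sum())
            assert len(records) == n_true_calls + sim_config.n_fp_per_caller

    def test_determinism(self, sim_config, reference, tumor):
        c1, t1 = simulate_sv_callsets(sim_config, reference, tumor)
        c2, t2 = simulate_sv_callsets(SimulationConfig(seed=sim_config.seed),
                                      reference, tumor)
        assert c1 == c2
        pd.testing.assert_frame_equal(t1, t2)


class TestMutationCatalog:
    def test_pure_signature_catalog(self, sim_config, tumor):
        sigmat = make_signature_matrix(sim_config, n_signatures=2)
        cfg = SimulationConfig(seed=8, catalog_size=1000)
        cat, w = simulate_mutation_catalog(cfg, tumor, sigmat, weights=[1.0, 0.0])
        assert cat.total == 1000
        expected = 1000 * sigmat.table.to_numpy()[:, 0]
        assert np.abs(cat.counts - expected).max() < 5 * np.sqrt(expected.max() + 1)

    def test_law_of_large_numbers(self, sim_config, tumor):
        sigmat = make_signature_matrix(sim_config, n_signatures=3)
        w = np.array([0.5, 0.3, 0.2])
        cfg = SimulationConfig(seed=9, catalog_size=1_000_000)
        cat, _ = simulate_mutation_catalog(cfg, tumor, sigmat, weights=w)
        np.testing.assert_allclose(
            cat.counts / cat.total, sigmat.table.to_numpy() @ w, atol=1e-2
        )

    def test_bad_weights_rejected(self, sim_config, tumor):
        sigmat = make_signature_matrix(sim_config, n_signatures=2)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_mutation_catalog(sim_config, tumor, sigmat, weights=[0.9, 0.3])

    def test_fixed_seed_reproducible(self, sim_config, tumor):
        sigmat = make_signature_matrix(sim_config, n_signatures=2)
        c1, _ = simulate_mutation_catalog(sim_config, tumor, sigmat, weights=[0.6, 0.4])
        c2, _ = simulate_mutation_catalog(SimulationConfig(seed=sim_config.seed),
                                          tumor, sigmat, weights=[0.6, 0.4])
        np.testing.assert_array_equal(c1.counts, c2.counts)


class TestPhasedLocus:
    def test_low_support_sites_exist(self, sim_config):
        df = simulate_phased_locus(sim_config)
        assert (df["n_valid"] < 3).any()

    def test_haplotype_tags_well_formed(self, sim_config):
        df = simulate_phased_locus(sim_config)
        assert set(df["haplotype"]) == {"1", "2"}

    def test_planted_monoallelic_pattern_classified(self, sim_config):
        from repeatscape import classify_thor, site_methylation_by_haplotype

        locus = PhasedLocusSpec(hap_means_thor=(0.9, 0.1))
        df = simulate_phased_locus(sim_config, locus)
        tracks = site_methylation_by_haplotype(
            df, GenomicInterval(locus.chrom, *locus.promoter)
        )
        call = classify_thor(tracks, GenomicInterval(locus.chrom, *locus.thor))
        assert call.call == "monoallelic_hyper"
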