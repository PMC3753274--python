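"""chrM profiling: enrichment, uniformity, localized-site scan, replicates."""
import math

import numpy as np
import pandas as pd
import pytest

import mitochip as mc
from mitochip.coverage import StrandCoverage
from mitochip.mapping import PartitionResult
from mitochip.mito import site_annotation_distance
from mitochip.peaks import ScanParams, poisson_window_pvalues
from mitochip.simulate import smooth_bias_field

L_MT = 16_569


def _part(chrm=300, nuclear=700):
    counts = {"total": chrm + nuclear, "mapped": chrm + nuclear,
              "chrM_mapped": chrm, "nuclear_unique": nuclear, "multi": 0,
              "unmapped": 0}
    return PartitionResult(pd.DataFrame(), pd.DataFrame(), counts)


def _cov(plus, minus, circular=True, contig="chrM"):
    plus = np.asarray(plus, dtype=float)
    return StrandCoverage(contig, plus.size, plus,
                          np.asarray(minus, dtype=float), "end_density",
                          circular, int(plus.sum() + np.sum(minus)))


class TestEnrichment:
    def test_fraction_arithmetic(self):
        rep = mc.enrichment_fraction(_part(300, 700))
        assert rep.fraction_chrm == 30.0

    def test_zero_mapped_rejected(self):
        with pytest.raises(ValueError):
            mc.enrichment_fraction(_part(0, 0))

    def test_simulated_chip_fraction_meets_lower_bound(
            self, bundle, chrm_index, genome_index):
        lib = mc.simulate_library(
            mc.SimConfig(seed=40, n_fragments=100_000,
                         chip_mito_fraction=0.40), "coating", bundle)
        part = mc.partition(lib.reads, chrm_index, genome_index)
        frac = mc.enrichment_fraction(part).fraction_chrm
        sd = 100 * math.sqrt(0.4 * 0.6 / 100_000)
        assert abs(frac - 40.0) < 3 * sd
        assert frac >= 30.0

    def test_simulated_input_fraction(self, bundle, chrm_index, genome_index):
        lib = mc.simulate_library(
            mc.SimConfig(seed=41, n_fragments=100_000,
                         mito_mass_fraction=0.019), "input", bundle)
        part = mc.partition(lib.reads, chrm_index, genome_index)
        frac = mc.enrichment_fraction(part).fraction_chrm
        # NUMT reads that happen to match chrM add a small positive bias on
        # top of binomial noise at the 300-kb decoy scale
        assert abs(frac - 1.9) < 0.4


class TestUniformity:
    def test_proportional_tracks_give_r_one_and_no_flags(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, L_MT).astype(float)
        chip = _cov(3 * base, 3 * base)
        inp = _cov(base, base)
        rep = mc.uniformity(chip, inp, window=200)
        assert rep.chip_input_r == pytest.approx(1.0)
        assert rep.flagged.size == 0
        assert np.allclose(rep.log2_ratio, rep.log2_ratio[0])
        assert rep.n_windows == math.ceil(L_MT / 200)

    def test_all_zero_input_rejected(self):
        chip = _cov(np.ones(L_MT), np.ones(L_MT))
        with pytest.raises(ValueError):
            mc.uniformity(chip, _cov(np.zeros(L_MT), np.zeros(L_MT)))

    def test_window_bounds_enforced(self):
        chip = _cov(np.ones(L_MT), np.ones(L_MT))
        with pytest.raises(ValueError):
            mc.uniformity(chip, chip, window=10)

    def test_coating_tracks_input_under_shared_bias(self, chrm,
                                                    make_chrm_coverage):
        """ChIP and input window counts correlate strongly when the same
        sequencing-bias field shapes both (the uniform-coating picture)."""
        bias = smooth_bias_field(77, chrm.length, amplitude=0.4)
        chip_cov, _ = make_chrm_coverage("coating", 42, n=100_000, bias=bias)
        in_cov, _ = make_chrm_coverage("input", 43, n=100_000, bias=bias)
        rep = mc.uniformity(chip_cov, in_cov, window=200,
                            gc_codes=chrm.codes)
        assert rep.chip_input_r > 0.8
        # bias field was drawn independently of sequence, so GC explains
        # nothing at alpha = 0.01
        assert rep.gc_p > 0.01


class TestLocalizedScan:
    def test_poisson_pvalues_match_direct_tail(self):
        """Window p-values equal a hand-computed Poisson upper tail."""
        rng = np.random.default_rng(1)
        chip = _cov(rng.poisson(2.0, 2_000), rng.poisson(2.0, 2_000))
        inp = _cov(rng.poisson(2.0, 2_000), rng.poisson(2.0, 2_000))
        params = ScanParams(window=100, step=100)
        starts, counts, lam, pvals = poisson_window_pvalues(chip, inp, params)

        def tail(c, l):
            # P(X >= c) for X ~ Poisson(l), by direct series summation
            acc, term = 0.0, math.exp(-l)
            for k in range(int(c)):
                acc += term
                term *= l / (k + 1)
            return 1.0 - acc

        for j in range(starts.size):
            assert pvals[j] == pytest.approx(tail(counts[j], lam[j]),
                                             abs=1e-9)

    def test_pure_coating_yields_no_point_source(self, make_chrm_coverage):
        """Specificity: diffuse-only libraries give 0 point_source calls in
        at least 9 of 10 seeds at q < 0.01."""
        bad = 0
        for seed in range(10):
            chip_cov, _ = make_chrm_coverage("coating", 100 + seed, n=100_000)
            in_cov, _ = make_chrm_coverage("input", 200 + seed, n=100_000)
            sites = mc.scan_localized_sites(chip_cov, in_cov, 200)
            if any(s.classification == "point_source" for s in sites):
                bad += 1
        assert bad <= 1

    def test_planted_summit_recovered(self, make_chrm_coverage):
        """Parameter recovery: fold-10 site at 5175, 2x10^5 chrM reads ->
        summit within +/-50 bp in >= 9/10 seeds."""
        hits = 0
        for seed in range(10):
            chip_cov, lib = make_chrm_coverage("point_source_mix", 300 + seed,
                                               n=200_000)
            in_cov, _ = make_chrm_coverage("input", 400 + seed, n=200_000)
            sites = mc.scan_localized_sites(chip_cov, in_cov, 200)
            ps = [s for s in sites if s.classification == "point_source"]
            if ps and abs(ps[0].summit_1based - 5175) <= 50:
                hits += 1
        assert hits >= 9

    def test_fold_monotone_in_planted_enrichment(self, make_chrm_coverage):
        """10-seed mean called fold never decreases as the planted
        enrichment grows."""
        means = []
        for fold in (5.0, 10.0, 20.0):
            got = []
            for seed in range(10):
                chip_cov, _ = make_chrm_coverage(
                    "point_source_mix", 500 + seed, n=100_000,
                    site_enrichment=fold)
                sites = mc.scan_localized_sites(chip_cov, None, 200)
                got.append(sites[0].fold_enrichment if sites else 0.0)
            means.append(np.mean(got))
        assert means[0] <= means[1] <= means[2]

    def test_symmetric_enrichment_classified_artifact(self):
        """Identical +/- profiles at an enriched locus -> called, but
        labelled artifact, not point_source."""
        rng = np.random.default_rng(7)
        x = np.arange(L_MT)
        bump = 4000 * np.exp(-0.5 * ((x - 8000) / 80.0) ** 2) / 80.0
        lam = 2.0 + bump
        chip = _cov(rng.poisson(lam), rng.poisson(lam))
        inp = _cov(rng.poisson(2.0, L_MT), rng.poisson(2.0, L_MT))
        sites = mc.scan_localized_sites(chip, inp, 200)
        assert len(sites) >= 1
        top = sites[0]
        assert top.classification == "artifact"
        assert top.start <= 8000 <= top.end
        assert not any(s.classification == "point_source" for s in sites)

    def test_invalid_fragment_mean_rejected(self):
        chip = _cov(np.ones(L_MT), np.ones(L_MT))
        with pytest.raises(ValueError):
            mc.scan_localized_sites(chip, None, 0)


class TestAnnotationDistance:
    def test_summit_at_5175_is_546_upstream_of_o_l(self, annotation):
        assert site_annotation_distance(5174, annotation, "O_L", L_MT) == 546

    def test_zero_distance_at_feature_start(self, annotation):
        o_l = annotation.get("O_L")
        assert site_annotation_distance(o_l.start, annotation, "O_L",
                                        L_MT) == 0

    def test_wraps_across_origin(self, annotation):
        # feature O_H starts at 109 (0-based); a summit 100 bp before the
        # origin is 209 bp upstream through the wrap
        start = annotation.get("O_H").start
        assert site_annotation_distance(L_MT - 100, annotation, "O_H",
                                        L_MT) == start + 100

    def test_unknown_feature_rejected(self, annotation):
        with pytest.raises(KeyError):
            site_annotation_distance(0, annotation, "no_such_feature", L_MT)


class TestReplicateCorrelation:
    def test_track_against_itself(self, make_chrm_coverage):
        cov, _ = make_chrm_coverage("coating", 60, n=20_000)
        r, p, flags = mc.replicate_correlation([cov, cov], window=200)
        assert r.iloc[0, 1] == pytest.approx(1.0)
        assert not flags

    def test_independent_coating_replicates_correlate(self, chrm,
                                                      make_chrm_coverage):
        """Two replicates sharing the bias field correlate at p < 1e-4."""
        bias = smooth_bias_field(88, chrm.length, amplitude=0.4)
        a, _ = make_chrm_coverage("coating", 61, n=100_000, bias=bias)
        b, _ = make_chrm_coverage("coating", 62, n=100_000, bias=bias)
        r, p, _ = mc.replicate_correlation([a, b], window=200)
        assert p.iloc[0, 1] < 1e-4
        assert r.iloc[0, 1] > 0.5

    def test_anticorrelated_construction(self):
        x = np.linspace(0, 1, L_MT)
        a = _cov(1000 * x, 1000 * x)
        b = _cov(1000 * (1 - x), 1000 * (1 - x))
        r, p, _ = mc.replicate_correlation([a, b], window=200)
        assert r.iloc[0, 1] < 0

    def test_constant_track_flagged_not_thrown(self):
        a = _cov(np.zeros(L_MT), np.zeros(L_MT))
        rng = np.random.default_rng(0)
        b = _cov(rng.poisson(3, L_MT), rng.poisson(3, L_MT))
        r, p, flags = mc.replicate_correlation([a, b], window=200)
        assert len(flags) == 1
        assert np.isnan(r.iloc[0, 1])

    def test_requires_two_tracks(self, make_chrm_coverage):
        cov, _ = make_chrm_coverage("coating", 63, n=5_000)
        with pytest.raises(ValueError):
            mc.replicate_correlation([cov])
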