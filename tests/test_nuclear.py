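"""Nuclear genome: cross-correlation QC, peak calling, artifact triage."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mitochip as mc
from mitochip.coverage import StrandCoverage, build_coverage
from mitochip.nuclear import _shifted_pearson, locus_report, \
    mappability_fraction


@pytest.fixture(scope="module")
def input_part(bundle, chrm_index, genome_index):
    lib = mc.simulate_library(mc.SimConfig(seed=70, n_fragments=100_000),
                              "input", bundle)
    return mc.partition(lib.reads, chrm_index, genome_index)


def _partitioned(bundle, chrm_index, genome_index, model, seed, n=100_000,
                 **kw):
    lib = mc.simulate_library(mc.SimConfig(seed=seed, n_fragments=n, **kw),
                              model, bundle)
    return mc.partition(lib.reads, chrm_index, genome_index), lib


class TestCrossCorrelation:
    def test_shifted_pearson_matches_direct_computation(self):
        """Exact agreement with per-shift scipy.stats.pearsonr on the
        trimmed overlap (the stated oracle, small contig)."""
        rng = np.random.default_rng(5)
        plus = rng.poisson(0.05, 50_000).astype(float)
        minus = np.roll(plus, 180) + rng.poisson(0.02, 50_000)
        got = _shifted_pearson(plus, minus, 250)
        for s in (0, 36, 179, 180, 181, 250):
            expect = stats.pearsonr(plus[:plus.size - s], minus[s:]).statistic
            assert got[s] == pytest.approx(expect, abs=1e-10)

    def test_exact_shift_gives_unit_correlation(self):
        rng = np.random.default_rng(6)
        plus = rng.poisson(1.0, 10_000).astype(float)
        minus = np.roll(plus, 147)
        aln = None  # construct profile directly
        r = _shifted_pearson(plus[:-147], minus[:-147][:plus.size - 147], 200)
        # identical profiles at shift 147 over the overlap
        best = int(np.argmax(r))
        assert best == 147
        assert r[147] > 0.99

    def test_planted_point_sources_peak_at_fragment_length(
            self, bundle, chrm_index, genome_index, input_part):
        """Argmax shift approximates the 200-bp fragment length when true
        point sources exist on the nuclear contigs."""
        sites = [("nuc1", 40_000), ("nuc1", 110_000), ("nuc2", 70_000)]
        part2 = mc.partition(
            mc.simulate_library(
                mc.SimConfig(seed=71, n_fragments=100_000,
                             chip_mito_fraction=0.0, site_enrichment=20.0),
                "point_source_mix", bundle, sites=sites).reads,
            chrm_index, genome_index)
        ccp = mc.cross_correlation(part2.nuclear_reads,
                                   bundle.decoy.lengths)
        assert abs(ccp.fragment_length_estimate - 200) <= 25
        assert not ccp.read_length_peak_flag

    def test_input_vs_signal_free_chip_indistinguishable(
            self, bundle, chrm_index, genome_index, input_part):
        """A ChIP library with no true signal shows a cross-correlation
        profile within 0.05 of the input's at every shift."""
        chip_part, _ = _partitioned(bundle, chrm_index, genome_index,
                                    "input", 72)
        a = mc.cross_correlation(chip_part.nuclear_reads,
                                 bundle.decoy.lengths)
        b = mc.cross_correlation(input_part.nuclear_reads,
                                 bundle.decoy.lengths)
        assert np.max(np.abs(a.r - b.r)) < 0.05

    def test_insufficient_reads_rejected(self, bundle):
        few = pd.DataFrame({"contig": ["nuc1"] * 10, "pos": range(10),
                            "strand": "+"})
        with pytest.raises(ValueError):
            mc.cross_correlation(few, bundle.decoy.lengths)


class TestNuclearPeaks:
    def test_artifact_pileups_called_but_classified_artifact(
            self, bundle, chrm_index, genome_index, input_part):
        part, _ = _partitioned(bundle, chrm_index, genome_index,
                               "nuclear_artifact", 73,
                               artifact_fraction=0.05)
        rep = mc.call_nuclear_peaks(
            part.nuclear_reads, input_part.nuclear_reads,
            bundle.decoy.lengths, genome_index=genome_index,
            contig_codes=dict(bundle.decoy.contigs))
        assert rep.n_called >= 3
        assert rep.n_point_source == 0
        assert rep.n_artifact == rep.n_called
        assert any(p.repeat_adjacent for p in rep.peaks)

    def test_planted_nuclear_point_source_recovered(
            self, bundle, chrm_index, genome_index, input_part):
        """Positive control: one planted site yields one point_source call
        at the planted locus."""
        site = ("nuc2", 80_000)
        lib = mc.simulate_library(
            mc.SimConfig(seed=74, n_fragments=100_000,
                         chip_mito_fraction=0.0),
            "point_source_mix", bundle, sites=[site])
        part = mc.partition(lib.reads, chrm_index, genome_index)
        rep = mc.call_nuclear_peaks(part.nuclear_reads,
                                    input_part.nuclear_reads,
                                    bundle.decoy.lengths)
        ps = [p for p in rep.peaks if p.classification == "point_source"]
        assert len(ps) == 1
        assert ps[0].contig == "nuc2"
        assert abs(ps[0].summit - 80_000) <= 100

    def test_null_chip_gives_no_point_source_calls(
            self, bundle, chrm_index, genome_index, input_part):
        """False-positive control: coating ChIP (featureless nucleus) vs
        input gives zero nuclear point_source calls in >= 9/10 seeds."""
        bad = 0
        for seed in range(10):
            part, _ = _partitioned(bundle, chrm_index, genome_index,
                                   "coating", 80 + seed, n=50_000)
            rep = mc.call_nuclear_peaks(part.nuclear_reads,
                                        input_part.nuclear_reads,
                                        bundle.decoy.lengths)
            if rep.n_point_source > 0:
                bad += 1
        assert bad <= 1

    def test_missing_input_rejected(self, bundle):
        with pytest.raises(ValueError):
            mc.call_nuclear_peaks(pd.DataFrame(), None, bundle.decoy.lengths)

    def test_classifier_consistent_across_contig_types(
            self, chrm, make_chrm_coverage):
        """The shared asymmetry scorer gives the same verdict for the same
        site shape on a circular and a linear contig away from edges."""
        chip_cov, _ = make_chrm_coverage("point_source_mix", 75, n=200_000)
        sites = mc.scan_localized_sites(chip_cov, None, 200)
        ps = [s for s in sites if s.classification == "point_source"]
        assert ps
        lin = StrandCoverage("linear", chip_cov.length,
                             chip_cov.plus.copy(), chip_cov.minus.copy(),
                             "end_density", False, chip_cov.n_reads)
        lin_sites = mc.scan_peaks(lin, None, 200)
        lin_ps = [s for s in lin_sites
                  if s.classification == "point_source"]
        assert len(lin_ps) == len(ps)
        assert abs(lin_ps[0].summit - ps[0].summit) <= 5

    def test_narrowpeak_export(self, bundle, chrm_index, genome_index,
                               input_part, tmp_path):
        part, _ = _partitioned(bundle, chrm_index, genome_index,
                               "nuclear_artifact", 76)
        rep = mc.call_nuclear_peaks(part.nuclear_reads,
                                    input_part.nuclear_reads,
                                    bundle.decoy.lengths)
        path = tmp_path / "peaks.narrowPeak"
        rep.to_narrowpeak(path)
        lines = [l.split("\t") for l in path.read_text().splitlines()]
        assert len(lines) == rep.n_called
        assert all(len(l) == 10 for l in lines)


class TestMappability:
    def test_unique_sequence_fully_mappable(self, bundle, genome_index):
        name, codes = bundle.decoy.contigs[0]
        reg_spans = [(r["core_start"], r["core_end"])
                     for r in bundle.decoy.repeat_registry
                     if r["contig"] == name]
        start = 5_000  # chosen away from planted elements in this bundle
        assert all(not (s - 1000 < start < e + 1000) for s, e in reg_spans)
        frac = mappability_fraction(genome_index, name, start, start + 2_000,
                                    codes)
        assert frac == 1.0

    def test_repeat_core_not_uniquely_mappable(self, bundle, genome_index):
        reg = bundle.decoy.repeat_registry[0]
        codes = dict(bundle.decoy.contigs)[reg["contig"]]
        frac = mappability_fraction(genome_index, reg["contig"],
                                    reg["core_start"], reg["core_end"],
                                    codes)
        assert frac < 0.1


class TestLocusReport:
    def test_unenriched_locus_fold_near_one(
            self, bundle, chrm_index, genome_index, input_part):
        part, _ = _partitioned(bundle, chrm_index, genome_index, "input", 77)
        chip_cov = build_coverage(part.nuclear_reads, "nuc1", 150_000)
        in_cov = build_coverage(input_part.nuclear_reads, "nuc1", 150_000)
        rep = locus_report(chip_cov, in_cov, 50_000, 52_000)
        assert 0.5 <= rep["fold"] <= 2.0

    def test_planted_site_fold_matches_generative_truth(
            self, bundle, chrm_index, genome_index, input_part):
        """Interval fold enrichment agrees within 2-fold with the value
        derived from the generative model (planted read count over the
        background rate in the queried window)."""
        site = ("nuc1", 60_000)
        lib = mc.simulate_library(
            mc.SimConfig(seed=78, n_fragments=100_000,
                         chip_mito_fraction=0.0, site_enrichment=8.0),
            "point_source_mix", bundle, sites=[site])
        part = mc.partition(lib.reads, chrm_index, genome_index)
        chip_cov = build_coverage(part.nuclear_reads, "nuc1", 150_000)
        in_cov = build_coverage(input_part.nuclear_reads, "nuc1", 150_000)
        rep = locus_report(chip_cov, in_cov, 59_700, 60_300)
        frags = lib.fragments
        n_bg_here = int(((frags["origin"] == "background")
                         & (frags["contig"] == "nuc1")).sum())
        n_site = int(lib.truth.iloc[0]["n_planted"])
        bg_in_window = n_bg_here / 150_000 * 600
        expect = (bg_in_window + n_site) / bg_in_window
        assert expect / 2 <= rep["fold"] <= expect * 2
        assert rep["fold"] > 1.3  # clearly enriched over background

    def test_empty_interval_reports_zero_fold_with_note(self):
        chip = StrandCoverage("c", 1_000, np.zeros(1_000), np.zeros(1_000),
                              "end_density", False, 0)
        inp = StrandCoverage("c", 1_000, np.ones(1_000), np.ones(1_000),
                             "end_density", False, 2_000)
        rep = locus_report(chip, inp, 100, 200)
        assert rep["fold"] == 0.0
        assert rep["note"] is not None

    def test_out_of_bounds_rejected(self):
        chip = StrandCoverage("c", 1_000, np.zeros(1_000), np.zeros(1_000),
                              "end_density", False, 0)
        with pytest.raises(ValueError):
            locus_report(chip, None, 900, 1_100)
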