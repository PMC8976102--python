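"""K-mer counting, peak finding, and the spectrum mixture model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genomesurvey import _seq
from genomesurvey.kmer import (KmerSpectrum, NoPeakError, SpectrumFit,
                               SpectrumModel, count_kmers,
                               estimate_genome_size, find_peak,
                               fit_spectrum_model, infer_sex_system,
                               revised_genome_size)
from genomesurvey.simulate import ParameterError
from tests.conftest import random_dna


def naive_spectrum(reads: list[str], k: int) -> dict[int, int]:
    """Brute-force oracle: enumerate every window into a table."""
    table: dict[str, int] = {}
    for s in reads:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if any(c not in "ACGT" for c in km):
                continue
            canon = min(km, _seq.revcomp(km))
            table[canon] = table.get(canon, 0) + 1
    hist: dict[int, int] = {}
    for c in table.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


class TestCounting:
    def test_single_read_single_kmer(self):
        s = count_kmers(["ACGTACGTACGTACGTA"], 17)
        assert s.histogram == {1: 1} and s.total_kmer_mass == 1

    def test_canonicalization_merges_reverse_complement(self):
        r = "ACGTACGTACGTACGTA"
        s = count_kmers([r, _seq.revcomp(r)], 17)
        assert s.histogram == {2: 1}

    def test_matches_bruteforce_oracle_on_random_reads(self):
        rng = np.random.default_rng(0)
        reads = [random_dna(150, seed=i) for i in range(100)]
        # add duplicates and an N-containing read
        reads += reads[:10] + [reads[0][:70] + "N" + reads[0][71:]]
        spec = count_kmers(reads, 17)
        assert spec.histogram == naive_spectrum(reads, 17)
        assert spec.mass_check()

    def test_even_k_rejected_and_empty_input_ok(self):
        with pytest.raises(ParameterError, match="odd"):
            count_kmers(["ACGT" * 10], 16)
        s = count_kmers([], 17)
        assert s.histogram == {} and s.total_kmer_mass == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mass_equals_window_count(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(10, 60, size=8)
        reads = [random_dna(int(L), seed=seed + i)
                 for i, L in enumerate(lengths)]
        spec = count_kmers(reads, 11)
        assert spec.total_kmer_mass == sum(max(0, len(r) - 10) for r in reads)
        assert spec.mass_check()


class TestPeakAndFormulas:
    def test_peak_ignores_error_spike(self):
        s = KmerSpectrum(17, {1: 10**6, 57: 5000, 56: 4800, 58: 4700}, 0)
        assert find_peak(s, min_depth=5) == 57

    def test_single_bin(self):
        assert find_peak(KmerSpectrum(17, {40: 100}, 4000), min_depth=5) == 40

    def test_no_peak_raises(self):
        with pytest.raises(NoPeakError):
            find_peak(KmerSpectrum(17, {1: 100, 2: 10}, 120), min_depth=5)

    def test_genome_size_division(self):
        assert estimate_genome_size(KmerSpectrum(17, {}, 570), 57) == 10
        # k-mer mass back-computed from the printed male survey numbers
        assert estimate_genome_size(
            KmerSpectrum(17, {}, 98_861_484_456), 57) == 1_734_412_008

    def test_revised_size_product(self):
        assert revised_genome_size(1000, 0.0) == 1000
        assert revised_genome_size(100, 0.5) == 50
        assert round(revised_genome_size(1_734_412_008, 0.0362633) / 1e6, 2) \
            == 1671.52

    def test_zero_peak_rejected(self):
        with pytest.raises(ParameterError):
            estimate_genome_size(KmerSpectrum(17, {}, 100), 0)


class TestSpectrumModel:
    def test_simulated_peak_near_true_coverage(self, het_sim):
        _p, _g, _reads, spec = het_sim
        assert abs(find_peak(spec) - 60) <= 1

    def test_genome_size_within_two_percent(self, het_sim):
        p, _g, _reads, spec = het_sim
        est = estimate_genome_size(spec, find_peak(spec))
        assert abs(est - p.genome_length) / p.genome_length < 0.02

    def test_duplicating_reads_scales_histogram_not_size(self, het_sim):
        _p, _g, reads, spec = het_sim
        sub = reads.subset(np.arange(reads.n_pairs) < 20000)
        s1 = count_kmers(sub, 17)
        doubled = [_seq.decode(r) for r in sub.sequences()] * 2
        s2 = count_kmers(doubled, 17)
        d1, c1 = s1.as_arrays()
        assert {2 * d: int(c) for d, c in zip(d1, c1) if c} == \
            {int(d): int(c) for d, c in zip(*s2.as_arrays()) if c}
        g1 = estimate_genome_size(s1, find_peak(s1, min_depth=3))
        g2 = estimate_genome_size(s2, find_peak(s2, min_depth=3))
        assert abs(g1 - g2) / g1 < 0.01

    def test_null_case_reports_no_het_no_repeats(self):
        from genomesurvey.simulate import (SimulationParams,
                                           simulate_diploid_genome,
                                           simulate_reads)
        p = SimulationParams(genome_length=200_000, heterozygosity=0.0,
                             repeat_fraction=0.0, ssr_density=0,
                             sex_system="ZZ_male", coverage=60, seed=21)
        reads = simulate_reads(simulate_diploid_genome(p), p)
        fit = fit_spectrum_model(count_kmers(reads, 17))
        assert fit.heterozygosity <= 0.0005
        assert fit.repeat_fraction <= 0.02

    def test_heterozygosity_recovered_within_20_percent(self, het_sim):
        _p, _g, _reads, spec = het_sim
        fit = SpectrumModel(spec).fit()
        assert abs(fit.heterozygosity - 0.0039) / 0.0039 <= 0.20

    def test_repeat_fraction_recovered_within_5_points(self, repeat_sim):
        _p, _g, _reads, spec = repeat_sim
        fit = SpectrumModel(spec).fit()
        assert abs(fit.repeat_fraction - 0.326) <= 0.05

    def test_parameter_recovery_grid(self):
        """Median recovery error over a small het x repeat grid."""
        from genomesurvey.simulate import (SimulationParams,
                                           simulate_diploid_genome,
                                           simulate_reads)
        rel_errs, abs_errs = [], []
        for het in (0.001, 0.004, 0.01):
            for rep in (0.0, 0.2, 0.33):
                for seed in (1, 2):
                    p = SimulationParams(
                        genome_length=200_000, heterozygosity=het,
                        repeat_fraction=rep, ssr_density=0,
                        sex_system="ZZ_male", coverage=60 * 150 / 134,
                        seed=seed)
                    reads = simulate_reads(simulate_diploid_genome(p), p)
                    fit = fit_spectrum_model(count_kmers(reads, 17))
                    rel_errs.append(abs(fit.heterozygosity - het) / het)
                    abs_errs.append(abs(fit.repeat_fraction - rep))
        assert np.median(rel_errs) <= 0.20
        assert np.median(abs_errs) <= 0.05

    def test_summary_renders(self, het_sim):
        fit = SpectrumModel(het_sim[3]).fit()
        text = fit.summary()
        assert "Heterozygous ratio" in text and "Genome size" in text


def _fit(r, size_mb):
    return SpectrumFit(k=17, peak_depth=57, depth_refined=57.0,
                       genome_size_bp=int(size_mb * 1e6 / (1 - 0.036)),
                       error_rate=0.036,
                       revised_genome_size_bp=int(size_mb * 1e6),
                       het_kmer_fraction=0.0, heterozygosity=r,
                       repeat_fraction=0.33)


class TestSexSystemInference:
    def test_survey_pattern_calls_zw(self):
        male = _fit(0.0034, 1671.52)
        female = _fit(0.0039, 1645.68)
        assert infer_sex_system(male, female) == "ZW"

    def test_mirrored_pattern_calls_xy(self):
        male = _fit(0.0039, 1645.68)
        female = _fit(0.0034, 1671.52)
        assert infer_sex_system(male, female) == "XY"

    def test_symmetric_inputs_are_inconclusive(self):
        f = _fit(0.0034, 1671.52)
        assert infer_sex_system(f, f) == "inconclusive"
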