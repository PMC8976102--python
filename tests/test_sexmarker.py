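"""Subtractive W-marker discovery, primer design, in-silico PCR."""

import numpy as np
import pytest

from genomesurvey import _seq
from genomesurvey.sexmarker import (BOTH_SEXES, FEMALE_SPECIFIC, NO_PRODUCT,
                                    ONE_SIDED_FEMALE, PrimerConstraints,
                                    classify_primer_pair, design_primers,
                                    identify_w_candidates, primer_tm,
                                    run_sexmarker)
from genomesurvey.simulate import (SimulationParams, simulate_reads,
                                   simulate_survey_pair)
from tests.conftest import random_dna


def balanced_fragment(n: int, seed: int) -> str:
    """Random fragment at ~50% GC (primer-friendly)."""
    rng = np.random.default_rng(seed)
    return _seq.decode(rng.integers(0, 4, n).astype(np.uint8))


@pytest.fixture(scope="module")
def zw_candidates(zw_sim):
    _params, male, female, reads = zw_sim
    male_ref = {f"male_{h}": male.sequence(h) for h in male.haplotype_names}
    female_ref = {f"female_{h}": female.sequence(h)
                  for h in female.haplotype_names}
    cands, trace = identify_w_candidates(reads, male_ref, female_ref)
    return male, female, cands, trace


class TestSubtractivePipeline:
    def test_identical_genomes_yield_zero_candidates(self):
        p = SimulationParams(genome_length=80_000, heterozygosity=0.002,
                             repeat_fraction=0.1, coverage=25,
                             sex_system="ZZ_male", w_segment_count=0, seed=31)
        male, female = simulate_survey_pair(p)
        assert male.sequence("hap1") == female.sequence("hap1")
        reads = simulate_reads(female, p)
        cands, trace = identify_w_candidates(
            reads, {"m1": male.sequence("hap1"), "m2": male.sequence("hap2")},
            {"f1": female.sequence("hap1"), "f2": female.sequence("hap2")})
        assert cands == []
        assert trace["reads_unmapped"] == 0

    def test_planted_w_segments_recovered(self, zw_sim, zw_candidates):
        _male, female, cands, _trace = zw_candidates
        w_feats = female.features_of("w_segment")
        recovered = 0
        for wf in w_feats:
            best = 0
            for c in cands:
                for h in c.female_hits:
                    if h.mapped and h.ref_id == "female_hap2":
                        ov = min(h.ref_end, wf.end) - max(h.ref_start, wf.start)
                        best = max(best, ov)
            if best >= 0.5 * (wf.end - wf.start):
                recovered += 1
        assert recovered >= 8  # >= 8 of 10 planted segments

    def test_no_candidate_has_mapped_male_hit(self, zw_candidates):
        _male, _female, cands, _trace = zw_candidates
        for c in cands:
            assert not any(h.mapped for h in c.male_hits)
            assert any(h.mapped for h in c.female_hits)
            assert c.contig.length >= 200

    def test_stage_trace_monotone_nonincreasing(self, zw_candidates):
        _male, _female, _cands, trace = zw_candidates
        chain = [trace["contigs_assembled"], trace["contigs_length_filtered"],
                 trace["contigs_male_excluded"],
                 trace["candidates_female_mapped"]]
        assert all(a >= b for a, b in zip(chain, chain[1:]))


class TestPrimerDesign:
    def test_admissible_pair_on_balanced_fragment(self):
        pairs = design_primers(balanced_fragment(600, seed=33))
        assert pairs
        c = PrimerConstraints()
        for p in pairs:
            for primer, tm, gc in ((p.forward, p.tm_forward, p.gc_forward),
                                   (p.reverse, p.tm_reverse, p.gc_reverse)):
                assert 18 <= len(primer) <= 27
                assert c.gc_range[0] <= gc <= c.gc_range[1]
                assert c.tm_range[0] <= tm <= c.tm_range[1]
                assert primer_tm(primer) == pytest.approx(tm)
            assert abs(p.tm_forward - p.tm_reverse) <= c.max_tm_diff
            assert c.product_window[0] <= p.product_size <= c.product_window[1]

    def test_pure_at_fragment_yields_nothing(self):
        assert design_primers("AT" * 300) == []

    def test_product_size_round_trips_on_fragment(self):
        frag = balanced_fragment(600, seed=34)
        for p in design_primers(frag)[:5]:
            fwd_at = frag.index(p.forward)
            rev_at = frag.index(_seq.revcomp(p.reverse))
            assert fwd_at == p.forward_start
            assert rev_at + len(p.reverse) == p.reverse_end
            assert p.product_size == rev_at + len(p.reverse) - fwd_at

    def test_short_fragment_rejected(self):
        from genomesurvey.simulate import ParameterError
        with pytest.raises(ParameterError):
            design_primers(balanced_fragment(100, seed=35))


class TestInSilicoPcr:
    def _refs_with_fragment(self, frag, seed):
        bg_f = random_dna(8000, seed=seed)
        bg_m = random_dna(8000, seed=seed + 1)
        female = {"f": bg_f[:3000] + frag + bg_f[3000:]}
        male = {"m": bg_m}
        return male, female

    def test_planted_amplicon_is_female_specific(self):
        frag = balanced_fragment(700, seed=36)
        pairs = design_primers(
            frag, PrimerConstraints(product_window=(560, 568)))
        assert pairs, "no pair with a ~564 bp product"
        pair = pairs[0]
        assert pair.product_size == 564 or 560 <= pair.product_size <= 568
        male, female = self._refs_with_fragment(frag, seed=37)
        cls = classify_primer_pair(pair, male, female)
        assert cls.category == FEMALE_SPECIFIC
        assert cls.female_products[0][2] == pair.product_size

    def test_fragment_on_both_references_is_both_sexes(self):
        frag = balanced_fragment(700, seed=38)
        pair = design_primers(frag)[0]
        bg = random_dna(6000, seed=39)
        shared = {"s": bg[:2000] + frag + bg[2000:]}
        cls = classify_primer_pair(pair, shared, shared)
        assert cls.category == BOTH_SEXES

    def test_one_sided_female_placement(self):
        frag = balanced_fragment(700, seed=40)
        pair = design_primers(frag)[0]
        # forward primer present on the female reference, reverse nowhere
        female = {"f": random_dna(4000, seed=41)[:2000] + pair.forward
                       + random_dna(2000, seed=42)}
        male = {"m": random_dna(4000, seed=43)}
        cls = classify_primer_pair(pair, male, female)
        assert cls.category == ONE_SIDED_FEMALE

    def test_absent_primers_give_no_product(self):
        frag = balanced_fragment(700, seed=44)
        pair = design_primers(frag)[0]
        male = {"m": random_dna(3000, seed=45)}
        female = {"f": random_dna(3000, seed=46)}
        cls = classify_primer_pair(pair, male, female)
        assert cls.category == NO_PRODUCT


class TestEndToEnd:
    def test_zw_run_finds_female_specific_marker(self, zw_sim):
        _params, male, female, reads = zw_sim
        male_ref = {f"male_{h}": male.sequence(h)
                    for h in male.haplotype_names}
        female_ref = {f"female_{h}": female.sequence(h)
                      for h in female.haplotype_names}
        report = run_sexmarker(reads, male_ref, female_ref,
                               n_candidates=10, seed=7)
        fs = report["female_specific"]
        assert len(fs) >= 1
        # each female-specific amplicon lies inside a planted W segment
        w_feats = female.features_of("w_segment")
        male_seq = male.sequence("hap1") + "NN" + male.sequence("hap2")
        for item in fs:
            assert item["female_products"]
            ref_id, start, size = item["female_products"][0]
            assert ref_id == "female_hap2"
            assert any(wf.start <= start and start + size <= wf.end
                       for wf in w_feats)
            # soundness: exhaustive 31-mer check of the amplicon vs the male
            amplicon = female.sequence("hap2")[start : start + size]
            for i in range(len(amplicon) - 30):
                km = amplicon[i : i + 31]
                assert km not in male_seq and _seq.revcomp(km) not in male_seq

    def test_sampling_is_reproducible_subset(self, zw_sim):
        _params, male, female, reads = zw_sim
        male_ref = {"m": male.sequence("hap1"), "m2": male.sequence("hap2")}
        female_ref = {"female_hap1": female.sequence("hap1"),
                      "female_hap2": female.sequence("hap2")}
        r1 = run_sexmarker(reads, male_ref, female_ref, n_candidates=4, seed=9)
        r2 = run_sexmarker(reads, male_ref, female_ref, n_candidates=4, seed=9)
        assert r1 == r2
        assert r1["stage_trace"]["candidates_sampled"] \
            <= r1["stage_trace"]["candidates_female_mapped"]
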