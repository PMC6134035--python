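"""RAD-SSR mining and calling: motif scan, thresholds, clone detection."""

import numpy as np
import pytest

from fragdiv import FragdivError, ReadBundleSet, simulate_balding_nichols
from fragdiv.model import MISSING
from fragdiv.radssr import (
    AlleleRegistry,
    SsrGenotypeCall,
    call_dataset,
    call_genotype,
    clone_summary,
    detect_clones,
    filter_loci,
    find_dinucleotide_loci,
    longest_dinucleotide_repeat,
    trim_reads,
)
from fragdiv.synthetic import make_ssr_allele_sequences, simulate_rad_reads


class TestMotifScan:
    def test_ag8_detected_with_count(self):
        catalog = {"loc1": "TTT" + "AG" * 8 + "CCA"}
        loci = find_dinucleotide_loci(catalog, {"loc1": 80}, min_repeats=5,
                                      min_individuals=50)
        assert len(loci) == 1
        assert loci[0].motif == "AG"
        assert loci[0].repeat_count == 8

    def test_homopolymer_not_detected(self):
        assert longest_dinucleotide_repeat("AAAAAAAAAA") == ("", 0)
        loci = find_dinucleotide_loci({"x": "AAAAAAAAAA"}, {"x": 99},
                                      min_repeats=2, min_individuals=50)
        assert loci == []

    def test_presence_threshold_is_strict(self):
        catalog = {"x": "AG" * 10}
        at_50 = find_dinucleotide_loci(catalog, {"x": 50}, min_individuals=50)
        at_51 = find_dinucleotide_loci(catalog, {"x": 51}, min_individuals=50)
        assert at_50 == [] and len(at_51) == 1

    def test_empty_catalog_gives_empty_result(self):
        assert find_dinucleotide_loci({}, {}) == []

    def test_repeats_below_minimum_skipped(self):
        catalog = {"x": "CCC" + "AT" * 4 + "GGG"}
        assert find_dinucleotide_loci(catalog, {"x": 99}, min_repeats=5) == []


class TestTrimReads:
    def _bundle(self, rows):
        bundles = ReadBundleSet()
        for ind, locus, seq, count in rows:
            bundles.add(ind, locus, seq, count)
        return bundles

    def test_tail_removed(self):
        bundles = self._bundle([("i", "l", "ACGTACG", 5)])
        out = trim_reads(bundles, 3)
        assert out.bundle("i", "l") == {"ACGT": 5}

    def test_identical_after_trim_merge_counts(self):
        bundles = self._bundle([
            ("i", "l", "ACGT" + "AAAAAAA", 4),
            ("i", "l", "ACGT" + "CCCCCCC", 6),
        ])
        out = trim_reads(bundles, 7)
        assert out.bundle("i", "l") == {"ACGT": 10}

    def test_zero_tail_is_identity(self):
        bundles = self._bundle([("i", "l", "ACGT", 2)])
        assert trim_reads(bundles, 0) == bundles

    def test_too_short_read_rejected_with_name(self):
        bundles = self._bundle([("i7", "l2", "ACG", 2)])
        with pytest.raises(FragdivError, match="i7/l2"):
            trim_reads(bundles, 3)


class TestCallGenotype:
    def _call(self, bundle, **kw):
        return call_genotype(bundle, "ind", "loc", AlleleRegistry(), **kw)

    def test_single_sequence_called_homozygote(self):
        call = self._call({"AAAA": 12})
        assert call.alleles == (0, 0)

    def test_below_ten_reads_is_missing(self):
        assert self._call({"AAAA": 9}).is_missing

    def test_support_filter_precedes_fraction_rule(self):
        # 2 reads of Y fail the 3-read rule although 2/17 > 10%
        call = self._call({"AAAA": 15, "CCCC": 2})
        assert call.alleles == (0, 0)

    def test_second_sequence_above_fraction_called_heterozygote(self):
        call = self._call({"AAAA": 30, "CCCC": 5})  # 5/35 = 14% > 10%
        assert call.alleles == (0, 1)
        assert call.support == {0: 30, 1: 5}

    def test_fraction_boundary_is_strict(self):
        call = self._call({"AAAA": 27, "CCCC": 3})  # 3/30 = 10%, not > 10%
        assert call.alleles == (0, 0)

    def test_empty_bundle_is_missing_not_error(self):
        assert self._call({}).is_missing

    def test_more_than_two_sequences_takes_top_two_and_counts_extras(self):
        call = self._call({"AAAA": 20, "CCCC": 10, "GGGG": 8})
        assert call.alleles == (0, 1)
        assert call.extra_sequences == 1

    def test_total_below_threshold_after_support_filter_is_missing(self):
        # each sequence has >= 3 reads? no: all below 3 -> discarded -> missing
        assert self._call({"AAAA": 2, "CCCC": 2, "GGGG": 2,
                           "TTTT": 2, "AATT": 2}).is_missing


class TestFilterLoci:
    def _calls(self, genotypes):
        return [SsrGenotypeCall("i%d" % k, "l", g, {}) for k, g in enumerate(genotypes)]

    def test_41_unique_genotypes_dropped(self):
        calls = self._calls([(a, a) for a in range(41)])
        keep, reason = filter_loci(calls, max_unique=40)
        assert not keep and reason == "too_many_genotypes"

    def test_40_unique_genotypes_kept(self):
        keep, _ = filter_loci(self._calls([(a, a) for a in range(40)]),
                              max_unique=40)
        assert keep

    def test_all_missing_dropped_with_reason(self):
        calls = self._calls([(MISSING, MISSING)] * 3)
        keep, reason = filter_loci(calls)
        assert not keep and reason == "all_missing"


@pytest.fixture(scope="module")
def truth_and_calls():
    rng = np.random.default_rng(21)
    freqs = [rng.dirichlet([1.0] * 5) for _ in range(25)]
    truth = simulate_balding_nichols(freqs, [0.08] * 5, [10] * 5,
                                     seed=22, marker_kind="ssr_id")
    seqs = make_ssr_allele_sequences(truth, seed=23)
    bundles = simulate_rad_reads(truth, seqs, coverage_mean=40.0,
                                 error_rate=0.0, seed=24)
    called, registry = call_dataset(bundles, populations=truth.populations)
    return truth, seqs, called, registry


class TestRoundTripConcordance:
    def test_error_free_coverage40_concordance(self, truth_and_calls):
        truth, seqs, called, registry = truth_and_calls
        ind_idx = {i: k for k, i in enumerate(called.individuals)}
        loc_idx = {l: j for j, l in enumerate(called.loci)}
        checked = matched = 0
        for i, ind in enumerate(truth.individuals):
            for j, locus in enumerate(truth.loci):
                if locus not in loc_idx or ind not in ind_idx:
                    continue
                got = called.calls[ind_idx[ind], loc_idx[locus]]
                if got[0] == MISSING:
                    continue  # coverage dropout, not a miscall
                seq_map = registry.sequences(locus)
                got_seqs = {seq_map[int(a)] for a in got}
                want = truth.calls[i, j]
                want_seqs = {seqs[locus][int(a)] for a in want}
                checked += 1
                matched += got_seqs == want_seqs
        assert checked >= 1000
        assert matched / checked >= 0.995

    def test_calling_invariant_to_bundle_input_order(self, truth_and_calls):
        truth, seqs, called, _ = truth_and_calls
        bundles = simulate_rad_reads(truth, seqs, coverage_mean=40.0,
                                     error_rate=0.0, seed=24)
        reordered = ReadBundleSet()
        for (ind, locus), bundle in sorted(bundles.items(), reverse=True):
            for seq, count in sorted(bundle.items(), reverse=True):
                reordered.add(ind, locus, seq, count)
        again, reg2 = call_dataset(reordered, populations=truth.populations)
        _, reg1 = call_dataset(bundles, populations=truth.populations)
        # same (individual, locus) coverage and identical genotypes once
        # integer codes are translated back to sequences
        assert set(called.loci) == set(again.loci)
        assert set(called.individuals) == set(again.individuals)
        idx_a = {i: k for k, i in enumerate(called.individuals)}
        idx_b = {i: k for k, i in enumerate(again.individuals)}
        loc_a = {l: j for j, l in enumerate(called.loci)}
        loc_b = {l: j for j, l in enumerate(again.loci)}
        for ind in called.individuals:
            for l in called.loci:
                ga = called.calls[idx_a[ind], loc_a[l]]
                gb = again.calls[idx_b[ind], loc_b[l]]
                assert (ga[0] == MISSING) == (gb[0] == MISSING)
                if ga[0] == MISSING:
                    continue
                sa = {reg1.sequences(l)[int(x)] for x in ga}
                sb = {reg2.sequences(l)[int(x)] for x in gb}
                assert sa == sb

    def test_distinct_sequences_never_share_codes(self, truth_and_calls):
        _, _, _, registry = truth_and_calls
        for locus in list(registry._codes):
            seqs = registry.sequences(locus)
            assert len(set(seqs.values())) == len(seqs)


class TestCloneDetection:
    def test_duplicated_individual_flagged(self, bn_matrix):
        gm = bn_matrix
        calls = np.concatenate([gm.calls, gm.calls[:1]], axis=0)
        import fragdiv.model as m
        gm2 = m.GenotypeMatrix(
            individuals=gm.individuals + ["copy"],
            populations={**gm.populations, "copy": gm.populations[gm.individuals[0]]},
            regions=gm.regions, loci=gm.loci, marker_kinds=gm.marker_kinds,
            calls=calls)
        groups = detect_clones(gm2, min_shared_loci=5)
        assert groups == [[gm.individuals[0], "copy"]]
        assert clone_summary(groups, gm2.n_individuals)["n_clones"] == 1

    def test_no_duplicates_no_flags(self, bn_matrix):
        assert detect_clones(bn_matrix, min_shared_loci=5) == []

    def test_single_mismatch_breaks_clone_group(self):
        calls = np.zeros((2, 18, 2), dtype=np.int32)
        calls[1, 17] = (0, 1)  # identical at 17 loci, differ at 1
        import fragdiv.model as m
        gm = m.GenotypeMatrix(
            individuals=["x", "y"], populations={"x": "P", "y": "P"},
            regions={}, loci=[f"L{j}" for j in range(18)],
            marker_kinds=["ssr_id"] * 18, calls=calls)
        assert detect_clones(gm, min_shared_loci=10) == []

    def test_min_shared_loci_bounds_checked(self, bn_matrix):
        with pytest.raises(FragdivError, match="min_shared_loci"):
            detect_clones(bn_matrix, min_shared_loci=bn_matrix.n_loci + 1)
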