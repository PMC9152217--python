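"""Bait filtering, trimming and the diagnostic-deletion read classifier."""

import numpy as np
import pytest

from sexhap import longread, presets, sim
from sexhap.longread import (
    LABEL_NON_Y,
    LABEL_UNASSIGNED,
    LABEL_Y,
    bait_filter,
    classify_read,
    classify_reads,
    prepare_baits,
    trim_ends,
    align_to_target,
)
from sexhap.sim import GeneModel, LongReadErrorModel

from conftest import make_noisy


class TestBaits:
    def test_masked_intron_splits_gene_into_two_segments(self, study):
        baits = prepare_baits(study["genes"], study["x"])
        per_gene = {}
        for gene, _ in baits.segments:
            per_gene[gene] = per_gene.get(gene, 0) + 1
        assert per_gene == {"dot1l": 2, "oaz1": 1, "LOC100707471": 1, "amh": 1}

    def test_fully_masked_gene_contributes_nothing(self, caplog):
        x, _ = sim.generate_reference(5_000, seed=3)
        g = GeneModel("ghost", [(1_001, 2_000)], masked_intervals=[(1_001, 2_000)])
        with caplog.at_level("WARNING"):
            baits = prepare_baits([g], x)
        assert baits.segments == []
        assert "fully masked" in caplog.text

    def test_empty_bait_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bait_filter([("r", "ACGT" * 50)], longread.BaitSet(segments=[]))

    def test_exact_gene_read_is_retained_with_right_gene(self, study):
        baits = prepare_baits(study["genes"], study["x"])
        x = study["x"]
        read = x[30_200:31_200]  # inside amh
        kept = bait_filter([("r1", read)], baits)
        assert kept == [("r1", read, "amh")]
        # reverse complement hits too
        kept = bait_filter([("r2", longread.revcomp(read))], baits)
        assert kept and kept[0][2] == "amh"

    def test_masked_intron_read_is_not_retained(self, study):
        baits = prepare_baits(study["genes"], study["x"])
        read = study["x"][3_000:4_000]  # inside the masked dot1l intron
        assert bait_filter([("r", read)], baits) == []

    def test_random_reads_rarely_pass(self, study):
        baits = prepare_baits(study["genes"], study["x"])
        rng = np.random.default_rng(33)
        reads = [
            (f"r{i}", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)]))
            for i in range(200)
        ]
        assert len(bait_filter(reads, baits)) <= 2  # < 1% false positives

    def test_noisy_gene_read_still_passes(self, study):
        baits = prepare_baits(study["genes"], study["x"])
        read = make_noisy(study["x"][15_000:16_800], seed=4)  # oaz1, 6.44% error
        kept = bait_filter([("r", read)], baits)
        assert kept and kept[0][2] == "oaz1"


class TestTrim:
    def test_trims_both_ends(self):
        assert trim_ends("A" * 30 + "C" * 40 + "G" * 30, 30) == "C" * 40

    def test_default_trim_length(self):
        assert len(trim_ends("A" * 100)) == 100 - 2 * 23

    def test_too_short_read_dropped(self):
        assert trim_ends("A" * 46, 23) is None
        assert trim_ends("A" * 47, 23) == "A"

    def test_zero_trim_is_identity(self):
        assert trim_ends("ACGT", 0) == "ACGT"


class TestAlignToTarget:
    def test_exact_substring_full_identity(self, study):
        x = study["x"]
        aln = align_to_target(x[5_000:7_000], x)
        assert aln is not None and aln.identity == 1.0
        assert aln.target_start == 5_000

    def test_unrelated_sequence_unaligned(self, study):
        rng = np.random.default_rng(8)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2_000)])
        assert align_to_target(junk, study["x"]) is None

    def test_empty_read(self, study):
        assert align_to_target("", study["x"]) is None


class TestClassifyRead:
    def _call(self, study, read):
        spec = study["spec"]
        return classify_read(
            "r", read, study["x"], spec.diagnostic_x_interval(),
            spec.diagnostic_expected_length,
        )

    def test_y_read_detects_exact_deletion_length(self, study, diag_junction):
        read = study["true_y"][diag_junction - 2_000 : diag_junction + 2_000]
        call = self._call(study, read)
        assert call.label == LABEL_Y
        assert call.diagnostic.spans_locus
        assert call.diagnostic.observed_length == 275

    def test_x_read_spanning_locus_is_non_y(self, study):
        read = study["x"][15_000 : 19_500]
        call = self._call(study, read)
        assert call.label == LABEL_NON_Y
        assert call.diagnostic.spans_locus
        assert not call.diagnostic.deletion_detected

    def test_read_missing_the_locus_is_unassigned(self, study):
        read = study["x"][100_000 : 110_000]
        call = self._call(study, read)
        assert call.label == LABEL_UNASSIGNED
        assert not call.diagnostic.spans_locus

    def test_read_ending_inside_locus_is_unassigned(self, study):
        # covers the left flank but stops 50 bp before the right flank exists
        read = study["x"][15_000 : 17_050]
        call = self._call(study, read)
        assert call.label == LABEL_UNASSIGNED

    def test_reverse_complement_read_classified_identically(self, study,
                                                            diag_junction):
        read = study["true_y"][diag_junction - 2_000 : diag_junction + 2_000]
        fwd = self._call(study, read)
        rev = self._call(study, longread.revcomp(read))
        assert (fwd.label, fwd.diagnostic.observed_length) == (
            rev.label, rev.diagnostic.observed_length
        )

    def test_noisy_concordance_at_model_error_rate(self, study, diag_junction):
        """At the 6.44% model error, locus-spanning reads are still called
        correctly at least 95% of the time."""
        y_tpl = study["true_y"][diag_junction - 1_500 : diag_junction + 1_500]
        x_tpl = study["x"][15_500 : 18_775]
        correct = total = 0
        for i in range(40):
            call = self._call(study, make_noisy(y_tpl, seed=100 + i))
            total += 1
            correct += call.label == LABEL_Y
            call = self._call(study, make_noisy(x_tpl, seed=200 + i))
            total += 1
            correct += call.label == LABEL_NON_Y
        assert correct / total >= 0.95

    def test_locus_too_close_to_boundary_rejected(self, study):
        with pytest.raises(ValueError, match="flank"):
            classify_read("r", "ACGT" * 100, study["x"], (50, 324), 275)


@pytest.fixture(scope="module")
def mixed(study):
    model = LongReadErrorModel(error_rate=0.0, length_mean=8_000,
                               length_sigma=0.2, seed=17)
    reads, truth = sim.simulate_read_set(
        study["x"], study["true_y"], 120, 0.5, model
    )
    baits = prepare_baits(study["genes"], study["x"])
    result = classify_reads(reads, study["model"], baits)
    return reads, truth, result


class TestClassifyReads:
    def test_counts_are_a_partition(self, mixed):
        reads, truth, result = mixed
        counts = result.label_counts()
        assert sum(counts.values()) == len(result.calls)
        assert len(result.calls) == result.n_bait_pass - result.n_trim_dropped
        assert result.n_input == len(reads)

    def test_no_false_y_calls_without_error(self, mixed):
        """Error-free: every Y-specific call really is a Y-origin read, and
        no X-origin read that spans the locus is ever called Y."""
        _, truth, result = mixed
        y_called = result.subset(LABEL_Y)
        assert y_called  # the mixture must actually exercise the Y path
        assert all(truth.read_origins[rid] == "Y" for rid in y_called)
        # non-Y calls include X reads and Y reads from the intact original
        # copy; what must never happen is an X read called Y-specific
        for call in result.calls:
            if truth.read_origins[call.read_id] == "X":
                assert call.label != LABEL_Y

    def test_order_invariance(self, study, mixed):
        reads, _, result = mixed
        baits = prepare_baits(study["genes"], study["x"])
        rev = classify_reads(list(reversed(reads)), study["model"], baits)
        assert {c.read_id: c.label for c in rev.calls} == {
            c.read_id: c.label for c in result.calls
        }

    def test_empty_input(self, study):
        baits = prepare_baits(study["genes"], study["x"])
        result = classify_reads([], study["model"], baits)
        assert result.calls == [] and result.n_input == 0
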