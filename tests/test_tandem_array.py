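import itertools
import math
import random

import numpy as np
import pytest

from arrayscan.errors import ValidationError
from arrayscan.io_formats import GeneLocus
from arrayscan.tandem_array import (
    align_proteins,
    clade_ks_summary,
    codon_align,
    compare_arrays,
    divergence_time,
    jukes_cantor,
    neighbor_identity_profile,
    ng86_ks,
)
from conftest import make_record, nw_oracle


class TestAlignProteins:
    def test_identical_sequences(self):
        alignment = align_proteins("MGYGY", "MGYGY")
        assert alignment.identity == pytest.approx(1.0)
        assert alignment.p_distance == pytest.approx(0.0)

    def test_single_mismatch(self):
        alignment = align_proteins("GYGGY", "GYGAY")
        assert alignment.p_distance == pytest.approx(0.2)
        assert alignment.identity == pytest.approx(0.8)

    def test_gap_recovery(self):
        alignment = align_proteins("MGYGYGYGY", "MGYGYGY")
        assert alignment.aligned_a.replace("-", "") == "MGYGYGYGY"
        assert alignment.aligned_b.replace("-", "") == "MGYGYGY"
        assert len(alignment.aligned_a) == len(alignment.aligned_b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_proteins("", "MGY")

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValidationError):
            align_proteins("MGY", "MGY", matrix="NOSUCH99")

    def test_scores_match_oracle_random_pairs(self):
        rng = random.Random(42)
        alphabet = "GYCA"
        for _ in range(60):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 12)))
            assert align_proteins(a, b).score == pytest.approx(nw_oracle(a, b))

    def test_p_distance_symmetry(self):
        rng = random.Random(1)
        for _ in range(20):
            a = "".join(rng.choice("GYCAMW") for _ in range(10))
            b = "".join(rng.choice("GYCAMW") for _ in range(10))
            ab = align_proteins(a, b)
            ba = align_proteins(b, a)
            assert ab.p_distance == pytest.approx(ba.p_distance)
            assert (ab.p_distance == 0.0) == (a == b)

    def test_deterministic(self):
        one = align_proteins("MGYGGY", "MGYAGY")
        two = align_proteins("MGYGGY", "MGYAGY")
        assert (one.aligned_a, one.aligned_b) == (two.aligned_a, two.aligned_b)


class TestNeighborProfile:
    def _loci(self, ids, strands, contig="ctg1"):
        return [
            GeneLocus(g, contig, 1000 * i, 1000 * i + 300, s)
            for i, (g, s) in enumerate(zip(ids, strands))
        ]

    def test_identical_tandem_array(self):
        records = [make_record(f"g{i}", "ATGGGCTATGGCTAT") for i in range(3)]
        report = neighbor_identity_profile(
            records, self._loci(["g0", "g1", "g2"], "+++")
        )
        assert report.mean_neighbor_identity == pytest.approx(1.0)
        assert report.tail_to_head
        assert report.clade_sizes == (3,)
        assert len(report.neighbor_identities) == 2

    def test_strand_flip_breaks_tail_to_head(self):
        records = [make_record(f"g{i}", "ATGGGCTATGGCTAT") for i in range(3)]
        report = neighbor_identity_profile(
            records, self._loci(["g0", "g1", "g2"], "++-")
        )
        assert not report.tail_to_head

    def test_order_follows_start_coordinate(self):
        records = [make_record(f"g{i}", "ATGGGCTATGGCTAT") for i in range(2)]
        loci = [
            GeneLocus("g0", "ctg1", 5000, 5300, "+"),
            GeneLocus("g1", "ctg1", 100, 400, "+"),
        ]
        report = neighbor_identity_profile(records, loci)
        assert report.ordered_genes == ("g1", "g0")

    def test_clade_partition_sums(self):
        records = [
            make_record("g0", "ATGGGCTAT"),
            make_record("g1", "ATGGGCTAT"),
            make_record("g2", "ATGGGGTAT"),
        ]
        report = neighbor_identity_profile(records, self._loci(["g0", "g1", "g2"], "+++"))
        assert sum(report.clade_sizes) == 3
        assert sorted(report.clade_sizes) == [1, 2]

    def test_two_contigs_rejected(self):
        records = [make_record(f"g{i}", "ATGGGCTAT") for i in range(2)]
        loci = [
            GeneLocus("g0", "ctg1", 0, 300, "+"),
            GeneLocus("g1", "ctg2", 0, 300, "+"),
        ]
        with pytest.raises(ValidationError, match="contig"):
            neighbor_identity_profile(records, loci)

    def test_missing_record_rejected(self):
        records = [make_record("g0", "ATGGGCTAT")]
        with pytest.raises(ValidationError):
            neighbor_identity_profile(records, self._loci(["g0", "g1"], "++"))

    def test_overlap_warns_but_orders(self):
        records = [make_record(f"g{i}", "ATGGGCTAT") for i in range(2)]
        loci = [
            GeneLocus("g0", "ctg1", 0, 300, "+"),
            GeneLocus("g1", "ctg1", 200, 500, "+"),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            report = neighbor_identity_profile(records, loci)
        assert report.ordered_genes == ("g0", "g1")


class TestCompareArrays:
    def _report(self, identities):
        from arrayscan.tandem_array import ArrayReport

        return ArrayReport(
            contig="ctg",
            ordered_genes=tuple(f"g{i}" for i in range(len(identities) + 1)),
            neighbor_identities=tuple(identities),
            mean_neighbor_identity=float(np.mean(identities)),
            tail_to_head=True,
            clades=(),
        )

    def test_identical_samples_zero_f(self):
        f, _, _ = compare_arrays(self._report([0.9, 0.8]), self._report([0.9, 0.8]))
        assert f == pytest.approx(0.0)

    def test_hand_computed_f(self):
        f, df, _ = compare_arrays(
            self._report([1.0, 0.98, 0.99]), self._report([0.5, 0.52, 0.48])
        )
        # oracle: mean squares by hand
        a, b = [1.0, 0.98, 0.99], [0.5, 0.52, 0.48]
        grand = np.mean(a + b)
        ssb = 3 * (np.mean(a) - grand) ** 2 + 3 * (np.mean(b) - grand) ** 2
        ssw = sum((x - np.mean(a)) ** 2 for x in a) + sum((x - np.mean(b)) ** 2 for x in b)
        assert f == pytest.approx((ssb / 1) / (ssw / 4))
        assert df == (1, 4)

    def test_three_arrays_df(self):
        _, df, _ = compare_arrays(
            self._report([0.9, 0.8]), self._report([0.7, 0.6]), self._report([0.5, 0.4])
        )
        assert df[0] == 2

    def test_single_identity_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_arrays(self._report([0.9]), self._report([0.8, 0.7]))


class TestNg86:
    def test_identical_cds(self):
        a = make_record("a", "ATGGGCTATGGC")
        b = make_record("b", "ATGGGCTATGGC")
        est = ng86_ks(a, b)
        assert est.Sd == 0.0 and est.Ks == 0.0 and est.T == 0.0

    def test_ctt_ctc_worked_pair(self):
        a = make_record("a", "CTT" * 8)
        b = make_record("b", "CTT" * 7 + "CTC")
        est = ng86_ks(a, b)
        assert est.S == pytest.approx(8.0)
        assert est.N == pytest.approx(16.0)
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)
        assert est.pS == pytest.approx(0.125)
        assert est.Ks == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.125))
        assert est.Ks == pytest.approx(0.1367, abs=5e-5)

    def test_symmetry(self):
        a = make_record("a", "ATGGGCTATCTTGGC")
        b = make_record("b", "ATGGGATGTCTTGGA")
        ab, ba = ng86_ks(a, b), ng86_ks(b, a)
        assert ab.S == ba.S and ab.N == ba.N
        assert ab.Sd == ba.Sd and ab.Nd == ba.Nd
        assert ab.Ks == ba.Ks and ab.Ka == ba.Ka

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(2)
        from arrayscan.synthetic_data import _draw_cds

        a = make_record("a", _draw_cds(rng, 60))
        b = make_record("b", _draw_cds(rng, 60))
        est = ng86_ks(a, b)
        assert est.S + est.N == pytest.approx(3 * est.n_codons)

    def test_n_codons_excluded(self):
        a = make_record("a", "ATGNNNTATGGC")
        b = make_record("b", "ATGGGCTATGGC")
        est = ng86_ks(a, b)
        assert est.n_codons == 3
        assert est.n_excluded == 1

    def test_multi_path_average(self):
        # TTT (F) vs GTA (V): differs at positions 1 and 3; both pathway
        # orders avoid stops. Hand enumeration: path via GTT gives
        # (nonsyn, syn); path via TTA gives (nonsyn, nonsyn)
        # -> Sd = 0.5, Nd = 1.5.
        a = make_record("a", "TTT")
        b = make_record("b", "GTA")
        est = ng86_ks(a, b)
        assert est.Sd == pytest.approx(0.5)
        assert est.Nd == pytest.approx(1.5)

    def test_saturation_flagged(self):
        est_values = ng86_ks(
            make_record("a", "CTT" * 4 + "GGC" * 46),
            make_record("b", "CTA" * 4 + "GGC" * 46),
        )
        assert not est_values.saturated  # mild divergence stays defined
        # force saturation: every codon synonymous-different at 3rd position
        a = make_record("a", "CTT" * 8)
        b = make_record("b", "CTA" * 8)
        est = ng86_ks(a, b)
        assert est.pS >= 0.75
        assert est.saturated and math.isnan(est.Ks)

    def test_jukes_cantor_properties(self):
        assert jukes_cantor(0.0) == 0.0
        for p in (0.01, 0.05, 0.2, 0.5):
            assert jukes_cantor(p) >= p  # expansion property
        assert jukes_cantor(0.001) == pytest.approx(0.001, rel=1e-2)
        assert math.isnan(jukes_cantor(0.75))

    def test_clock_linearity(self):
        assert divergence_time(0.06) == pytest.approx(2 * divergence_time(0.03))

    def test_dating_formula(self):
        assert divergence_time(0.03, mu=2e-9) == pytest.approx(7.5e6)


class TestCodonAlign:
    def test_gap_free_equal_length(self):
        a = make_record("a", "ATGGGCTAT")
        b = make_record("b", "ATGGGATAT")
        assert codon_align(a, b) == ("ATGGGCTAT", "ATGGGATAT")

    def test_gapped_columns_dropped(self):
        a = make_record("a", "ATGGGCGGCGGCTATTATTGC")
        b = make_record("b", "ATGGGCGGCGGCTATTGC")
        cds_a, cds_b = codon_align(a, b)
        assert len(cds_a) == len(cds_b)
        assert len(cds_a) % 3 == 0
        assert len(cds_a) <= len(b.cds)


class TestCladeKsSummary:
    def test_identical_clade_zero(self):
        records = [make_record(f"g{i}", "ATGGGCTATGGCCTT") for i in range(3)] + [
            make_record("h1", "ATGGGATATGGCCTT"),
            make_record("h2", "ATGGGATATGGCCTT"),
        ]
        summary = clade_ks_summary(records, {"g0", "g1", "g2"}, {"h1", "h2"})
        assert summary.within_a.mean_ks == pytest.approx(0.0)
        assert summary.within_a.n_pairs == 3
        assert summary.within_b.mean_ks == pytest.approx(0.0)
        assert summary.between.n_pairs == 6

    def test_singleton_within_refused(self):
        records = [
            make_record("a1", "ATGGGCTATCTTGGC"),
            make_record("b1", "ATGGGATATCTTGGC"),
        ]
        summary = clade_ks_summary(records, {"a1"}, {"b1"})
        assert summary.within_a is None
        assert summary.between.n_pairs == 1

    def test_overlapping_clades_rejected(self):
        records = [make_record("a1", "ATGGGCTAT")]
        with pytest.raises(ValidationError):
            clade_ks_summary(records, {"a1"}, {"a1"})
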