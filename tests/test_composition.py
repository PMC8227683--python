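"""Composition statistics: skews, RSCU, start/stop codons, spacer accounting."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitokit.composition import (
    at_content,
    at_skew,
    base_counts,
    codon_usage,
    composition_by_partition,
    detect_start_stop,
    gc_skew,
    mean_rscu,
    rscu,
    spacers_and_overlaps,
)
from mitokit.records import (
    GeneAnnotation,
    MitogenomeRecord,
    reverse_complement,
    rotate_record,
)

dna = st.text(alphabet="ACGTN", min_size=0, max_size=300)


class TestBaseCountsAndSkews:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AATT", (2, 0, 0, 2, 0)),
            ("", (0, 0, 0, 0, 0)),
            ("ACGTN", (1, 1, 1, 1, 1)),
            ("acgt", (1, 1, 1, 1, 0)),
        ],
    )
    def test_counts(self, seq, expected):
        c = base_counts(seq)
        assert (c.A, c.C, c.G, c.T, c.other) == expected

    def test_skew_values(self):
        assert at_skew(base_counts("AATT")) == 0.0
        assert at_skew(base_counts("AAAT")) == pytest.approx(0.5)
        assert math.isnan(at_skew(base_counts("GGCC")))
        assert math.isnan(gc_skew(base_counts("AATT")))

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_skews_antisymmetric_under_base_exchange(self, seq):
        c = base_counts(seq)
        for skew, swapped in ((at_skew, c.swap_at()), (gc_skew, c.swap_gc())):
            a, b = skew(c), skew(swapped)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(-b)

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_reverse_complement_negates_both_skews(self, seq):
        c, rc = base_counts(seq), base_counts(reverse_complement(seq))
        for skew in (at_skew, gc_skew):
            a, b = skew(c), skew(rc)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(-b)


class TestCompositionByPartition:
    def test_all_A_genome(self):
        rec = MitogenomeRecord(
            taxon="x",
            sequence="A" * 100,
            annotations=[GeneAnnotation(name="cox1", start=0, end=99)],
        )
        whole = composition_by_partition(rec)[0]
        assert whole.at_content == 100.0
        assert whole.at_skew == 1.0

    def test_generated_genome_matches_configured_at_weight(self, default_dataset):
        """Generator targets ~82% AT overall; realized composition must land
        within 1.5 percentage points (direct count on the emitted sequence)."""
        rec = default_dataset.records[0]
        whole = composition_by_partition(rec)[0]
        direct = base_counts(rec.sequence)
        assert whole.at_content == pytest.approx(at_content(direct))
        assert abs(whole.at_content - 82.0) < 1.5

    def test_expected_partitions_present(self, small_dataset):
        parts = {s.partition for s in composition_by_partition(small_dataset.records[0])}
        assert parts == {
            "whole", "PCGs", "tRNAs", "rRNAs", "AT_rich",
            "codon_pos_1", "codon_pos_2", "codon_pos_3",
        }

    def test_missing_partition_warns_and_is_omitted(self):
        rec = MitogenomeRecord(
            taxon="x",
            sequence="ACGT" * 30,
            annotations=[GeneAnnotation(name="cox1", start=0, end=30)],
        )
        with pytest.warns(UserWarning):
            parts = {s.partition for s in composition_by_partition(rec)}
        assert "tRNAs" not in parts and "PCGs" in parts


class TestCodonUsageAndRSCU:
    def _single_cds_record(self, cds: str) -> MitogenomeRecord:
        return MitogenomeRecord(
            taxon="x",
            sequence=cds + "AAAA",
            annotations=[GeneAnnotation(name="cox1", start=0, end=len(cds))],
        )

    def test_terminal_stop_excluded(self):
        counts = codon_usage(self._single_cds_record("ATGTTATAA"))
        assert counts == Counter({"ATG": 1, "TTA": 1})

    def test_trailing_partial_codon_ignored(self):
        counts = codon_usage(self._single_cds_record("ATGTTAT"))
        assert counts == Counter({"ATG": 1, "TTA": 1})

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning, match="internal stop"):
            codon_usage(self._single_cds_record("ATGTAGTTATAA"))

    def test_equal_family_counts_give_rscu_one(self):
        leu = ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]
        table = rscu(Counter({c: 5 for c in leu}))
        assert table.set_index("codon").loc[leu, "rscu"].tolist() == pytest.approx([1.0] * 6)

    def test_single_codon_family_monopoly_gives_degeneracy(self):
        table = rscu(Counter({"TTA": 17}))
        assert table.set_index("codon").loc["TTA", "rscu"] == pytest.approx(6.0)

    def test_empty_family_gets_zero(self):
        table = rscu(Counter({"TTA": 1}))
        gly = table[table.aa == "G"]
        assert (gly.rscu == 0).all()

    def test_rscu_conserves_family_counts(self, small_dataset):
        counts = codon_usage(small_dataset.records[0])
        table = rscu(counts)
        for aa, fam in table.groupby("aa"):
            total = fam["count"].sum()
            if total:
                back = (fam.rscu * total / len(fam)).sum()
                assert back == pytest.approx(total)

    def test_at_rich_codons_dominate_usage(self, default_dataset):
        """The AT-biased stationary frequencies must surface as TTA-Leu
        having the top mean RSCU, as in real sawfly mitogenomes."""
        table = mean_rscu(default_dataset.records[:4]).sort_values("rscu", ascending=False)
        assert table.iloc[0]["codon"] == "TTA"
        assert table.iloc[0]["rscu"] > 2.0


class TestStartStopDetection:
    def _record_with(self, cds: str) -> MitogenomeRecord:
        return MitogenomeRecord(
            taxon="x",
            sequence=cds + "AA",
            annotations=[GeneAnnotation(name="cox1", start=0, end=len(cds))],
        )

    @pytest.mark.parametrize(
        "cds, start, stop",
        [
            ("ATGAAATAA", "ATG", "TAA"),
            ("ATTAAATAG", "ATT", "TAG"),
            ("ATAAAAT", "ATA", "T-"),
            ("ATGAAATA", "ATG", "TA-"),
            ("ATGAAAG", "ATG", "G"),
        ],
    )
    def test_start_and_stop_patterns(self, cds, start, stop):
        assert detect_start_stop(self._record_with(cds), "cox1") == (start, stop)

    def test_planted_partial_stops_in_generator_output(self, small_dataset):
        rec = small_dataset.records[0]
        assert detect_start_stop(rec, "cob")[1] == "T-"
        assert detect_start_stop(rec, "nad4")[1] == "TA-"
        start, stop = detect_start_stop(rec, "cox1")
        assert start[:2] == "AT" and stop == "TAA"


class TestSpacersAndOverlaps:
    def _rec(self, anns, length=40):
        return MitogenomeRecord(taxon="x", sequence="A" * length, annotations=anns)

    def test_abutting_genes_no_spacer_no_overlap(self):
        rep = spacers_and_overlaps(
            self._rec(
                [GeneAnnotation(name="cox1", start=0, end=10), GeneAnnotation(name="cox2", start=10, end=40)]
            )
        )
        assert rep.total_spacer_bp == 0 and rep.total_overlap_bp == 0

    def test_overlapping_genes(self):
        rep = spacers_and_overlaps(
            self._rec(
                [GeneAnnotation(name="cox1", start=0, end=10), GeneAnnotation(name="cox2", start=8, end=40)]
            )
        )
        assert rep.overlaps == [("cox1", "cox2", 2)]

    def test_gap_across_origin_counts_once(self):
        rep = spacers_and_overlaps(
            self._rec(
                [GeneAnnotation(name="cox1", start=2, end=10), GeneAnnotation(name="cox2", start=12, end=38)]
            )
        )
        assert sorted(s[2] for s in rep.spacers) == [2, 4]

    def test_totals_invariant_under_rotation(self, small_dataset):
        rec = small_dataset.records[0]
        base = spacers_and_overlaps(rec)
        for offset in (1, 137, rec.length // 2):
            rep = spacers_and_overlaps(rotate_record(rec, offset))
            assert rep.total_spacer_bp == base.total_spacer_bp
            assert rep.n_spacer_locations == base.n_spacer_locations
            assert rep.total_overlap_bp == base.total_overlap_bp

    def test_zero_spacer_config_yields_zero_spacer_bp(self):
        from mitokit.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_taxa=3, seed=2, length_scale=0.05, clade_size=0,
            spacer_length_range=(0, 0), outgroup=False,
        )
        ds = simulate_dataset(cfg)
        rep = spacers_and_overlaps(ds.records[0])
        assert rep.total_spacer_bp == 0
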