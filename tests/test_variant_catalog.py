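import numpy as np
import pytest
from hypothesis import given, strategies as st

from mtpopgen import annotation as ann
from mtpopgen import synthetic_data as synth
from mtpopgen import variant_catalog as vc
from mtpopgen.errors import ClassificationError, FormatError, InputError

from conftest import make_aligned


def brute_force_snv_count(seqs):
    """Independent per-column scan: k-1 variants per qualifying column."""
    total = 0
    for col in zip(*seqs):
        if "-" in col:
            continue
        bases = {c for c in col if c in "ACGT"}
        if len(bases) >= 2:
            total += len(bases) - 1
    return total


class TestIdentifySnvs:
    def test_singleton_column(self):
        aligned = make_aligned(["A" * 10] * 9 + ["C" + "A" * 9])
        table = vc.identify_snvs(aligned)
        assert len(table) == 1
        (rec,) = table.records
        assert rec.position == 1 and rec.ref == "A" and rec.alt == "C"
        assert rec.singleton and not rec.multiallelic
        assert rec.total_alt == 1

    def test_triallelic_position_counts_two_snvs(self):
        aligned = make_aligned(["AG", "AG", "CG", "TG"])
        table = vc.identify_snvs(aligned)
        assert len(table) == 2
        assert {r.position for r in table.records} == {1}
        assert all(r.multiallelic for r in table.records)
        assert {r.alt for r in table.records} == {"C", "T"}
        assert all(r.ref == "A" for r in table.records)

    def test_gap_disqualifies_whole_column(self):
        aligned = make_aligned(["ACG", "A-G", "TCG"])
        table = vc.identify_snvs(aligned)
        # column 1 is variant (A/T); column 2 is an indel site despite the
        # C majority; column 3 monomorphic
        assert [r.position for r in table.records] == [1]
        assert table.provenance["filter_log"]["excluded_indel_positions"] == [2]

    def test_ambiguity_codes_are_missing_calls(self):
        # variation only through an ambiguity code is not an SNV
        aligned = make_aligned(["AC", "AC", "RC", "NC"])
        assert len(vc.identify_snvs(aligned)) == 0
        # and an ambiguous genome leaves the site's denominator only
        aligned = make_aligned(["AC", "GC", "RC", "AC"])
        table = vc.identify_snvs(aligned)
        (rec,) = table.records
        assert rec.counts["AFR"] == (2, 1, 3)  # ref, alt, called

    def test_positions_on_ungapped_reference(self):
        # the excluded indel column still occupies a reference position
        aligned = make_aligned(["ACGT", "AC-T", "ACGA"])
        table = vc.identify_snvs(aligned)
        (rec,) = table.records
        assert rec.position == 4

    def test_all_missing_column_is_silently_nonvariant(self):
        aligned = make_aligned(["NA", "NA", "NC"])
        table = vc.identify_snvs(aligned)
        assert [r.position for r in table.records] == [2]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGTN-"), p=[0.3, 0.3, 0.2, 0.15,
                                                      0.03, 0.02], size=80))
                for _ in range(12)]
        seqs[0] = seqs[0].replace("-", "A")  # reference must be gap-free
        pops = ["AFR"] * 4 + ["ASI"] * 4 + ["EUR"] * 4
        t1 = vc.identify_snvs(make_aligned(seqs, pops))
        order = rng.permutation(12).tolist()
        order.remove(0)
        order = [0] + order  # keep the same coordinate reference
        t2 = vc.identify_snvs(
            make_aligned([seqs[i] for i in order], [pops[i] for i in order])
        )
        assert [(r.position, r.ref, r.alt, r.total_alt) for r in t1.records] \
            == [(r.position, r.ref, r.alt, r.total_alt) for r in t2.records]

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGTRN-"),
                                   p=[0.4, 0.3, 0.15, 0.1, 0.02, 0.02, 0.01],
                                   size=60)) for _ in range(15)]
        seqs[0] = seqs[0].replace("-", "C")
        table = vc.identify_snvs(make_aligned(seqs))
        assert len(table) == brute_force_snv_count(seqs)


class TestFilterSingletons:
    def test_counts_example(self):
        aligned = make_aligned(
            ["AAA", "CAC", "ACC", "AAA", "AAA"]  # alt counts 1, 1, 2
        )
        d1 = vc.identify_snvs(aligned)
        assert sorted(r.total_alt for r in d1.records) == [1, 1, 2]
        d2 = vc.filter_singletons(d1)
        assert len(d2) == 1 and d2.records[0].total_alt == 2
        assert d2.dataset == 2

    def test_empty_table_identity(self):
        d1 = vc.identify_snvs(make_aligned(["AC", "AC"]))
        assert len(vc.filter_singletons(d1)) == 0

    def test_triallelic_judged_per_allele(self):
        # C appears twice, T once: the position keeps one SNV in Dataset 2
        aligned = make_aligned(["A", "C", "C", "T", "A"])
        d2 = vc.filter_singletons(vc.identify_snvs(aligned))
        assert [(r.alt, r.multiallelic) for r in d2.records] == [("C", False)]

    def test_requires_dataset1(self, dataset2):
        with pytest.raises(InputError):
            vc.filter_singletons(dataset2)

    def test_dataset_count_identity(self, dataset1, dataset2):
        n_singletons = sum(1 for r in dataset1.records if r.singleton)
        assert len(dataset1) - len(dataset2) == n_singletons
        assert not any(r.singleton for r in dataset2.records)

    def test_position_count_identity(self, dataset1):
        beyond_first = sum(1 for _ in dataset1.records) - dataset1.n_positions
        assert len(dataset1) == dataset1.n_positions + beyond_first


class TestReadWrite:
    def test_read_alignment_roundtrip(self, study, tmp_path):
        vc.write_alignment(study.aligned, tmp_path / "a.fa", tmp_path / "l.tsv")
        back = vc.read_alignment(tmp_path / "a.fa", tmp_path / "l.tsv")
        assert back == study.aligned

    def test_two_records(self, tmp_path):
        (tmp_path / "a.fa").write_text(">x\nACGTACGTAC\n>y\nACGTACGTAC\n")
        (tmp_path / "l.tsv").write_text("x\tAFR\ny\tEUR\n")
        aligned = vc.read_alignment(tmp_path / "a.fa", tmp_path / "l.tsv")
        assert aligned.n_samples == 2 and aligned.n_columns == 10

    def test_unequal_lengths(self, tmp_path):
        (tmp_path / "a.fa").write_text(">x\nACGT\n>y\nACG\n")
        (tmp_path / "l.tsv").write_text("x\tAFR\ny\tEUR\n")
        with pytest.raises(FormatError):
            vc.read_alignment(tmp_path / "a.fa", tmp_path / "l.tsv")

    def test_missing_label(self, tmp_path):
        (tmp_path / "a.fa").write_text(">x\nACGT\n>y\nACGT\n")
        (tmp_path / "l.tsv").write_text("x\tAFR\n")
        with pytest.raises(InputError):
            vc.read_alignment(tmp_path / "a.fa", tmp_path / "l.tsv")

    def test_non_iupac_character(self, tmp_path):
        (tmp_path / "a.fa").write_text(">x\nAC?T\n>y\nACGT\n")
        (tmp_path / "l.tsv").write_text("x\tAFR\ny\tEUR\n")
        with pytest.raises(FormatError):
            vc.read_alignment(tmp_path / "a.fa", tmp_path / "l.tsv")


def _table_with_records(records):
    return vc.SNVTable(records=records, dataset=1, reference="", pop_sizes={})


def _record(position, ref, alt):
    return vc.SNVRecord(position=position, ref=ref, alt=alt,
                        counts={"AFR": (1, 1, 2)}, multiallelic=False,
                        singleton=False)


@pytest.fixture(scope="module")
def reference():
    ref = ["A"] * 16_569
    ref[3306:3309] = "TTA"  # first ND1 codon (plus strand)
    ref[3309:3312] = "ATA"  # second ND1 codon
    ref[14670:14673] = "TAA"  # last full ND6 codon (minus strand)
    return "".join(ref)


class TestClassifySites:
    def classify_one(self, record, reference):
        table = vc.SNVTable(records=[record], dataset=1, reference=reference,
                            pop_sizes={"AFR": 2})
        counts = vc.classify_sites(table, ann.rcrs_annotation())
        return record.cls, counts

    @pytest.mark.parametrize("position", [16_100, 300, 576, 16_024])
    def test_control_region(self, reference, position):
        cls, _ = self.classify_one(_record(position, "A", "G"), reference)
        assert cls == ann.CONTROL

    def test_rna_gene(self, reference):
        cls, _ = self.classify_one(_record(700, "A", "G"), reference)
        assert cls == ann.RNA

    def test_non_coding(self, reference):
        cls, _ = self.classify_one(_record(5_582, "A", "G"), reference)
        assert cls == ann.NONCODING

    def test_synonymous_third_position(self, reference):
        # TTA -> TTG is Leu -> Leu under the vertebrate mt code
        cls, counts = self.classify_one(_record(3_309, "A", "G"), reference)
        assert cls == vc.CLS_SYN and counts[vc.CLS_SYN] == 1

    def test_nonsynonymous_first_position(self, reference):
        # ATA (Met in mt code) -> GTA (Val)
        cls, _ = self.classify_one(_record(3_310, "A", "G"), reference)
        assert cls == vc.CLS_NON

    def test_minus_strand_synonymous(self, reference):
        # ND6 codon TAA reads TTA (Leu) on the coding strand; the change
        # at 14,671 gives CAA -> TTG, still Leu
        cls, _ = self.classify_one(_record(14_671, "T", "C"), reference)
        assert cls == vc.CLS_SYN

    def test_incomplete_codon_raises(self, reference):
        with pytest.raises(ClassificationError):
            self.classify_one(_record(4_262, "A", "G"), reference)

    def test_counts_partition_table(self, dataset1, study):
        counts = vc.classify_sites(dataset1, study.annotation)
        assert sum(counts.values()) == len(dataset1)
        assert all(r.cls in vc.SNV_CLASSES for r in dataset1.records)


def test_control_region_length():
    annotation = ann.rcrs_annotation()
    ctrl = annotation[annotation["cls"] == ann.CONTROL]
    assert int((ctrl["end"] - ctrl["start"] + 1).sum()) == 1_122


def test_annotation_bed_roundtrip(tmp_path):
    annotation = ann.rcrs_annotation()
    ann.write_annotation_bed(annotation, tmp_path / "a.bed")
    back = ann.read_annotation_bed(tmp_path / "a.bed")
    assert back.equals(annotation)
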