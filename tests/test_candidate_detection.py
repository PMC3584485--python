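import numpy as np
import pandas as pd
import pytest

from mtpopgen import candidate_detection as cand
from mtpopgen import synthetic_data as synth
from mtpopgen import variant_catalog as vc
from mtpopgen.errors import InputError


def small_table(records, reference):
    return vc.SNVTable(records=records, dataset=1, reference=reference,
                       pop_sizes={"AFR": 100})


def record(position, ref, alt, counts):
    return vc.SNVRecord(position=position, ref=ref, alt=alt, counts=counts,
                        multiallelic=False, singleton=False)


class TestDerivedFrequencies:
    def test_outgroup_matches_reference_allele(self):
        table = small_table(
            [record(2, "A", "G", {"AFR": (90, 10, 100)})], "AAA")
        out = cand.derived_frequencies(table, "AAA")
        row = out.iloc[0]
        assert row["derived"] == "G" and row["freq_AFR"] == pytest.approx(0.10)
        assert not row["unpolarized"]

    def test_outgroup_matches_variant_allele(self):
        # ancestral is the alignment's majority base: the derived allele
        # is then the majority (reference) allele
        table = small_table(
            [record(2, "A", "G", {"AFR": (90, 10, 100)})], "AAA")
        out = cand.derived_frequencies(table, "AGA")
        row = out.iloc[0]
        assert row["derived"] == "A" and row["freq_AFR"] == pytest.approx(0.90)

    def test_unpolarized_when_outgroup_base_unobserved(self):
        table = small_table(
            [record(2, "A", "G", {"AFR": (90, 10, 100)})], "AAA")
        out = cand.derived_frequencies(table, "ACA")
        assert bool(out.iloc[0]["unpolarized"])
        out = cand.derived_frequencies(table, "ANA")
        assert bool(out.iloc[0]["unpolarized"])

    def test_length_mismatch_rejected(self):
        table = small_table(
            [record(2, "A", "G", {"AFR": (90, 10, 100)})], "AAA")
        with pytest.raises(InputError):
            cand.derived_frequencies(table, "AAAA")


def freq_frame(rows):
    return pd.DataFrame(
        [{"position": p, "ref": "A", "alt": "G", "ancestral": "A",
          "derived": "G", "unpolarized": False, "freq_AFR": f}
         for p, f in rows]
    )


class TestClassifyCandidates:
    def test_strict_threshold_boundary(self):
        report = cand.classify_candidates(
            freq_frame([(1, 0.05), (2, 0.049), (3, 0.0)]), {"AFR": 0.05})
        # exactly at the threshold is NOT a candidate; zero is absent
        assert report.candidates["AFR"] == 1
        assert report.denominators["AFR"] == 2

    def test_all_above_threshold_empty(self):
        report = cand.classify_candidates(
            freq_frame([(1, 0.5), (2, 0.9)]), {"AFR": 0.1})
        assert report.candidates["AFR"] == 0

    def test_missing_threshold_rejected(self):
        with pytest.raises(InputError):
            cand.classify_candidates(freq_frame([(1, 0.5)]), {})

    def test_partition_property(self, dataset1, study):
        freqs = cand.derived_frequencies(dataset1, study.outgroup)
        thresholds = {"AFR": 0.3, "ASI": 0.12, "EUR": 0.1}
        report = cand.classify_candidates(freqs, thresholds)
        out = report.frequencies
        for p in thresholds:
            f = out[f"freq_{p}"]
            candidate = out[f"candidate_{p}"]
            unpol = out["unpolarized"]
            non_candidate = ~unpol & ~candidate
            assert (candidate.astype(int) + non_candidate.astype(int)
                    + unpol.astype(int) == 1).all()
            assert not (candidate & unpol).any()

    def test_threshold_monotonicity(self, dataset1, study):
        freqs = cand.derived_frequencies(dataset1, study.outgroup)
        lo = cand.classify_candidates(
            freqs, {"AFR": 0.05, "ASI": 0.05, "EUR": 0.05})
        hi = cand.classify_candidates(
            freqs, {"AFR": 0.5, "ASI": 0.5, "EUR": 0.5})
        for p in ("AFR", "ASI", "EUR"):
            assert hi.candidates[p] >= lo.candidates[p]
            low_set = lo.frequencies[f"candidate_{p}"]
            high_set = hi.frequencies[f"candidate_{p}"]
            assert (high_set | ~low_set).all()  # superset


class TestMatchPathogenic:
    def _report(self):
        return cand.classify_candidates(
            freq_frame([(1, 0.02), (2, 0.30)]), {"AFR": 0.1})

    def test_absent_entry_not_reported(self):
        catalog = cand.PathogenicCatalog([
            cand.CatalogEntry(99, "A", "G", "Confirmed", "x")])
        assert len(cand.match_pathogenic(self._report(), catalog)) == 0

    def test_empty_catalog(self):
        assert len(cand.match_pathogenic(
            self._report(), cand.PathogenicCatalog([]))) == 0

    def test_above_and_below_flags(self):
        catalog = cand.PathogenicCatalog([
            cand.CatalogEntry(1, "A", "G", "Confirmed", "below"),
            cand.CatalogEntry(2, "A", "G", "Reported", "above"),
        ])
        out = cand.match_pathogenic(self._report(), catalog)
        flags = dict(zip(out["position"], out["above_AFR"]))
        assert flags == {1: False, 2: True}

    def test_planted_confirmed_pattern(self, dataset1, study):
        # one planted confirmed allele is common in ASI only, mirroring
        # the classic LHON-like pattern
        freqs = cand.derived_frequencies(dataset1, study.outgroup)
        report = cand.classify_candidates(
            freqs, {"AFR": 0.3, "ASI": 0.12, "EUR": 0.1})
        out = cand.match_pathogenic(report, study.catalog)
        row = out[out["position"] == 11_778].iloc[0]
        assert row["above_ASI"] and not row["above_AFR"] and not row["above_EUR"]
        assert row["freq_ASI"] == pytest.approx(6 / 30)


class TestCatalogIO:
    def test_roundtrip(self, study, tmp_path):
        study.catalog.write_tsv(tmp_path / "cat.tsv")
        back = cand.PathogenicCatalog.read_tsv(tmp_path / "cat.tsv")
        assert back.entries == study.catalog.entries

    def test_duplicate_entries_rejected(self):
        with pytest.raises(InputError):
            cand.PathogenicCatalog([
                cand.CatalogEntry(1, "A", "G", "Confirmed", "x"),
                cand.CatalogEntry(1, "C", "G", "Reported", "y"),
            ])

    def test_unknown_status_rejected(self):
        with pytest.raises(InputError):
            cand.CatalogEntry(1, "A", "G", "Maybe", "x")


class TestMinSampleForDetection:
    @pytest.mark.parametrize("carriers,n,expected", [
        (13, 3_755, 289),
        (1, 685, 685),
        (12, 2_685, 224),
        (10, 100, 10),
    ])
    def test_values(self, carriers, n, expected):
        assert cand.min_sample_for_detection(carriers, n) == expected

    def test_zero_carriers_rejected(self):
        with pytest.raises(InputError):
            cand.min_sample_for_detection(0, 100)
        with pytest.raises(InputError):
            cand.min_sample_for_detection(10, 5)


def test_planted_derived_frequencies_recovered(dataset1, study):
    """Planted variants are recovered at their exact target frequencies."""
    freqs = cand.derived_frequencies(dataset1, study.outgroup)
    by_pos = {int(r["position"]): r for _, r in freqs.iterrows()}
    sizes = study.aligned.pop_sizes()
    for truth in study.truth:
        if truth.disposition in (synth.EXCLUDED_INDEL,
                                 synth.EXCLUDED_HETEROPLASMY):
            assert truth.position not in by_pos
            continue
        row = by_pos[truth.position]
        assert not row["unpolarized"]
        assert row["derived"] == truth.alleles[1]
        for pop, n in sizes.items():
            expected = truth.expected_counts.get(pop, 0) / n
            assert row[f"freq_{pop}"] == pytest.approx(expected)
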