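"""CAI weights and geometric mean, GC content, ORF extraction, copy number."""

import math
import warnings
from itertools import product

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from hypothesis import given
from hypothesis import strategies as st

import plasmidcost as pc
from plasmidcost.features import (
    SYNONYMOUS_FAMILIES,
    WEIGHT_FLOOR,
    DepthProfile,
    cai_detail,
)


def freq_table(overrides=None):
    freqs = {"".join(c): 10.0 for c in product("ACGT", repeat=3)}
    freqs.update(overrides or {})
    return freqs


class TestWeightTable:
    def test_family_ratio_and_floor(self):
        table = pc.build_weight_table(
            freq_table({"GGC": 400.0, "GGA": 100.0, "GGG": 0.0, "GGT": 0.0})
        )
        assert table.weights["GGC"] == 1.0
        assert table.weights["GGA"] == pytest.approx(0.25)
        assert table.weights["GGG"] == WEIGHT_FLOOR
        assert table.weights["GGT"] == WEIGHT_FLOOR

    def test_single_codon_families(self):
        table = pc.build_weight_table(freq_table())
        assert table.weights["ATG"] == 1.0  # Met
        assert table.weights["TGG"] == 1.0  # Trp

    def test_uniform_frequencies_give_unit_weights(self, uniform_frequencies):
        table = pc.build_weight_table(uniform_frequencies)
        assert all(w == 1.0 for w in table.weights.values())

    def test_missing_codons_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pc.build_weight_table({"ATG": 1.0})

    def test_rna_codons_accepted(self):
        freqs = {k.replace("T", "U"): v for k, v in freq_table().items()}
        table = pc.build_weight_table(freqs)
        assert table.weights["TTT"] == 1.0


class TestCai:
    def test_two_codon_geometric_mean(self):
        table = pc.build_weight_table(
            freq_table({"GGC": 400.0, "GGA": 100.0, "GGG": 50.0, "GGT": 50.0})
        )
        # weights 1.0 and 0.25 -> CAI = sqrt(0.25) = 0.5
        assert pc.cai("GGCGGA", table) == pytest.approx(0.5, abs=1e-12)

    def test_all_optimal_is_exactly_one(self, reference_table):
        seq = "".join(
            reference_table.optimal_codon(aa) for aa in sorted(SYNONYMOUS_FAMILIES)
        )
        assert pc.cai(seq, reference_table) == 1.0

    def test_concatenation_identity(self, reference_table):
        a = "ATGGAAGGTCTGAAACGT"
        b = "ATGCCGCCAGGGTTTTCA"
        ca, cb = pc.cai(a, reference_table), pc.cai(b, reference_table)
        n = len(a) // 3
        expected = math.exp((n * math.log(ca) + n * math.log(cb)) / (2 * n))
        assert pc.cai(a + b, reference_table) == pytest.approx(expected, abs=1e-12)

    def test_terminal_stop_excluded(self, reference_table):
        assert pc.cai("GGCGGATAA", reference_table) == pytest.approx(
            pc.cai("GGCGGA", reference_table)
        )

    def test_internal_stop_warns_but_computes(self, reference_table):
        with pytest.warns(UserWarning, match="internal stop"):
            value = pc.cai("GGCTAAGGA", reference_table)
        assert 0 < value <= 1

    def test_ambiguous_codons_skipped_and_counted(self, reference_table):
        value, n_used, n_amb = cai_detail("GGCGGNGGA", reference_table)
        assert n_used == 2 and n_amb == 1
        assert value == pytest.approx(pc.cai("GGCGGA", reference_table))

    def test_length_not_multiple_of_three_rejected(self, reference_table):
        with pytest.raises(ValueError, match="multiple of 3"):
            pc.cai("GGCGG", reference_table)

    def test_lower_weight_synonym_strictly_decreases(self):
        table = pc.build_weight_table(
            freq_table({"GGC": 400.0, "GGA": 100.0, "GGG": 50.0, "GGT": 50.0})
        )
        assert pc.cai("GGCGGC", table) > pc.cai("GGCGGA", table) > pc.cai(
            "GGAGGA", table
        )

    @given(n=st.integers(1, 30))
    def test_bounds(self, n, reference_table):
        from plasmidcost.features import SENSE_CODONS

        rng = np.random.default_rng(n)
        seq = "".join(rng.choice(sorted(SENSE_CODONS), size=n))
        assert 0 < pc.cai(seq, reference_table) <= 1


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 0.0), ("GCGC", 100.0), ("ATGC", 50.0)]
    )
    def test_basic(self, seq, expected):
        assert pc.gc_content(seq) == pytest.approx(expected)

    def test_ambiguity_codes_excluded(self):
        assert pc.gc_content("ATGCNN") == pytest.approx(50.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pc.gc_content("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_strand_invariance(self, seq):
        comp = str(Seq(seq).complement())
        assert pc.gc_content(seq) == pytest.approx(pc.gc_content(comp))


class TestCopyNumber:
    def test_ratio(self):
        plas = DepthProfile("p", 1500.0, 1000)
        chrom = DepthProfile("c", 100.0, 5000)
        assert pc.copy_number_proxy(plas, chrom) == pytest.approx(15.0)

    def test_scale_invariance(self):
        a = pc.copy_number_proxy(DepthProfile("p", 30.0, 10), DepthProfile("c", 10.0, 10))
        b = pc.copy_number_proxy(DepthProfile("p", 60.0, 10), DepthProfile("c", 20.0, 10))
        assert a == pytest.approx(b)

    def test_zero_chromosome_depth_rejected(self):
        with pytest.raises(ValueError):
            pc.copy_number_proxy(DepthProfile("p", 10.0, 5), DepthProfile("c", 0.0, 5))


class TestCodonTableIO:
    def test_bundled_table_loads(self, reference_table):
        assert len(reference_table.weights) == 61
        assert reference_table.weights["CTG"] == 1.0  # Leu: CTG dominates in E. coli

    def test_tsv_dialect(self, tmp_path):
        path = tmp_path / "usage.tsv"
        rows = [f"{codon}\t10" for codon in freq_table()]
        path.write_text("# comment\n" + "\n".join(rows) + "\n")
        freqs = pc.read_codon_table(path)
        assert len(freqs) == 64 and freqs["ATG"] == 10.0

    def test_emboss_dialect(self, tmp_path):
        path = tmp_path / "usage.cut"
        rows = [f"{codon} X 0.5 10.0 1000" for codon in freq_table()]
        path.write_text("\n".join(rows) + "\n")
        freqs = pc.read_codon_table(path)
        assert freqs["GGC"] == 1000.0

    def test_malformed_rejected(self, tmp_path):
        path = tmp_path / "bad.cut"
        path.write_text("NOTACODON 5\n")
        with pytest.raises(ValueError, match="codon"):
            pc.read_codon_table(path)

    def test_incomplete_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("ATG\t5\n")
        with pytest.raises(ValueError, match="64"):
            pc.read_codon_table(path)


class TestExtractOrfs:
    def test_plus_strand(self):
        rec = SeqRecord(Seq("ATGAAATTTT"), id="r")
        rec.features = [
            SeqFeature(FeatureLocation(0, 6, strand=1), type="CDS",
                       qualifiers={"locus_tag": ["orf1"]})
        ]
        (fid, start, end, strand, seq), = pc.extract_orfs(rec)
        assert (fid, start, end, strand, str(seq)) == ("orf1", 1, 6, "+", "ATGAAA")

    def test_minus_strand_reverse_complement(self):
        rec = SeqRecord(Seq("TTTCATGGGG"), id="r")
        rec.features = [SeqFeature(FeatureLocation(0, 6, strand=-1), type="CDS")]
        (_, _, _, strand, seq), = pc.extract_orfs(rec)
        assert strand == "-" and str(seq) == "ATGAAA"

    def test_circular_wraparound_join(self):
        # ORF spans the origin: ...GGG|ATG AAA TAA|... laid out as end+start
        rec = SeqRecord(Seq("AAATAACCCCCCATG"), id="r")
        rec.annotations["topology"] = "circular"
        loc = CompoundLocation(
            [FeatureLocation(12, 15, strand=1), FeatureLocation(0, 6, strand=1)]
        )
        rec.features = [SeqFeature(loc, type="CDS")]
        (_, _, _, _, seq), = pc.extract_orfs(rec)
        assert str(seq) == "ATGAAATAA"

    def test_out_of_range_named(self):
        rec = SeqRecord(Seq("ATGAAA"), id="r")
        rec.features = [
            SeqFeature(FeatureLocation(0, 9, strand=1), type="CDS",
                       qualifiers={"locus_tag": ["bad_orf"]})
        ]
        with pytest.raises(ValueError, match="bad_orf"):
            pc.extract_orfs(rec)

    def test_orf_features_exclude_stop_from_length(self, reference_table):
        rec = SeqRecord(Seq("ATGGGCGGATAA"), id="r")
        rec.features = [SeqFeature(FeatureLocation(0, 12, strand=1), type="CDS")]
        (feat,) = pc.orf_features(rec, reference_table)
        assert feat.length_codons == 3  # ATG GGC GGA, stop excluded
        assert feat.cai == pytest.approx(pc.cai("ATGGGCGGA", reference_table))


def test_plasmid_summary_fields(reference_table):
    rec = pc.simulate_plasmid_record(
        12_000, 0.52, n_orfs=4, codon_bias_strength=0.6, seed=3,
        table=reference_table,
    )
    tables = pc.simulate_depth_table(8.0, 100.0, noise_cv=0.0, seed=0)
    summary = pc.plasmid_summary(rec, reference_table, tables.plasmid, tables.chromosome)
    assert summary["size_bp"] == 12_000
    assert summary["n_orfs"] == 4
    assert 0 < summary["mean_cai"] <= 1
    assert summary["copy_number"] == pytest.approx(8.0)
    assert 51.0 <= summary["gc_percent"] <= 53.0
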