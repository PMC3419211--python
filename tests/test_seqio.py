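"""CDS and table I/O contracts."""

import numpy as np
import pytest

from hgtident.dataset import FEATURE_NAMES, HGT, NATIVE, UNKNOWN, LabeledDataset
from hgtident.seqio import (
    attach_labels,
    read_cds_fasta,
    read_feature_table,
    read_genbank_cds,
    write_feature_table,
)

MINIMAL_GENBANK = """\
LOCUS       TESTSEQ                    9 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test record.
ACCESSION   TESTSEQ
FEATURES             Location/Qualifiers
     CDS             complement(4..9)
                     /locus_tag="geneA"
ORIGIN
        1 aaatttccc
//
"""

JOIN_GENBANK = """\
LOCUS       JOINSEQ                    9 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test record.
ACCESSION   JOINSEQ
FEATURES             Location/Qualifiers
     CDS             join(1..3,7..9)
                     /locus_tag="geneJ"
ORIGIN
        1 atgnnnccc
//
"""

NO_CDS_GENBANK = """\
LOCUS       EMPTYSEQ                   9 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test record.
ACCESSION   EMPTYSEQ
FEATURES             Location/Qualifiers
     gene            1..9
ORIGIN
        1 atgaaataa
//
"""


class TestFasta:
    def test_parse_and_normalize(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">g1\natgAAA\n>g2 some description\nAUGCCC\n")
        bundle = read_cds_fasta(p)
        assert [g.id for g in bundle] == ["g1", "g2"]
        assert [g.seq for g in bundle] == ["ATGAAA", "ATGCCC"]  # upper, U->T
        assert all(g.label == UNKNOWN for g in bundle)

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "cds.fasta"
        p.write_text(">g1\nATGRYS\n")
        assert read_cds_fasta(p).genes[0].seq == "ATGNNN"

    def test_duplicate_id_is_error(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">g1\nATG\n>g1\nCCC\n")
        with pytest.raises(ValueError, match="g1"):
            read_cds_fasta(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_cds_fasta(p)


class TestGenBank:
    def test_minus_strand_cds_is_reverse_complemented(self, tmp_path):
        p = tmp_path / "one.gb"
        p.write_text(MINIMAL_GENBANK)
        bundle = read_genbank_cds(p)
        # complement(4..9) of AAATTTCCC: revcomp of TTTCCC
        assert bundle.genes[0].id == "geneA"
        assert bundle.genes[0].seq == "GGGAAA"

    def test_join_location_is_spliced(self, tmp_path):
        p = tmp_path / "join.gb"
        p.write_text(JOIN_GENBANK)
        assert read_genbank_cds(p).genes[0].seq == "ATGCCC"

    def test_no_cds_is_error(self, tmp_path):
        p = tmp_path / "nocds.gb"
        p.write_text(NO_CDS_GENBANK)
        with pytest.raises(ValueError, match="no CDS"):
            read_genbank_cds(p)


class TestLabels:
    def _bundle(self, tmp_path):
        p = tmp_path / "b.fasta"
        p.write_text(">g1\nATG\n>g2\nCCC\n>g3\nGGG\n")
        return read_cds_fasta(p)

    def test_partial_labeling(self, tmp_path):
        b = attach_labels(self._bundle(tmp_path), {"g1": HGT})
        assert b.label_counts() == {HGT: 1, NATIVE: 0, UNKNOWN: 2}

    def test_unknown_id_is_error(self, tmp_path):
        with pytest.raises(KeyError, match="gX"):
            attach_labels(self._bundle(tmp_path), {"gX": HGT})

    def test_repeated_id_last_write_wins(self, tmp_path):
        b = attach_labels(self._bundle(tmp_path), [("g1", HGT), ("g1", NATIVE)])
        assert b.gene("g1").label == NATIVE


class TestFeatureTable:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        ds = LabeledDataset(
            ids=[f"g{i}" for i in range(5)],
            X=rng.uniform(size=(5, 15)),
            y=np.array([1, 0, 0, 1, 0]),
        )
        p = tmp_path / "feat.tsv"
        write_feature_table(ds, p)
        back = read_feature_table(p)
        assert back.ids == ds.ids
        np.testing.assert_allclose(back.X, ds.X, atol=1e-9)
        np.testing.assert_array_equal(back.y, ds.y)

    def test_missing_column_is_error(self, tmp_path):
        ds = LabeledDataset(ids=["g"], X=np.zeros((1, 15)), y=np.array([0]))
        p = tmp_path / "feat.tsv"
        write_feature_table(ds, p)
        text = p.read_text().replace("JS-DN", "JS-XX")
        p.write_text(text)
        with pytest.raises(ValueError, match="JS-DN"):
            read_feature_table(p)

    def test_empty_dataset_round_trip(self, tmp_path):
        ds = LabeledDataset(ids=[], X=np.empty((0, 15)), y=np.empty(0, dtype=int))
        p = tmp_path / "feat.tsv"
        write_feature_table(ds, p)
        back = read_feature_table(p)
        assert back.n_genes == 0
        assert p.read_text().startswith("id\t" + FEATURE_NAMES[0])
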