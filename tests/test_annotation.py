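"""Annotation parsing, the filtering cascade, and table/BED output."""

import pytest
from hypothesis import given, settings, strategies as st

from ovgenes.annotation import (
    AnnotationParseError, AnnotationValidationError, FilterReport, GeneRecord,
    PRIMARY_CHROMOSOMES, filter_genes, normalize_strand, read_gene_annotation,
    write_bed, write_gene_table,
)
from conftest import make_gene


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

TSV_HEADER = "gene_id\tgene_name\tchromosome\tstart\tend\tstrand\tbiotype\tdescription\n"


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_tsv_line_maps_directly_to_record(tmp_path):
    path = write(tmp_path, "g.tsv",
                 TSV_HEADER + "G1\tALPHA\t1\t100\t500\t1\tprotein_coding\tfirst gene\n")
    (rec,) = read_gene_annotation(path, format="tsv")
    assert rec == GeneRecord("G1", "1", 100, 500, "+", "protein_coding",
                             "ALPHA", "first gene")


def test_biomart_headers_accepted(tmp_path):
    header = ("Gene stable ID\tGene name\tChromosome/scaffold name\t"
              "Gene start (bp)\tGene end (bp)\tStrand\tGene type\tGene description\n")
    path = write(tmp_path, "bm.tsv", header + "G1\tA\tX\t10\t20\t-1\tprotein_coding\td\n")
    (rec,) = read_gene_annotation(path, format="tsv")
    assert (rec.chromosome, rec.strand) == ("X", "-")


def test_gtf_gene_line_parsed_with_reverse_strand(tmp_path):
    gtf = ('1\tensembl\tgene\t100\t500\t.\t-\t.\t'
           'gene_id "G1"; gene_name "ALPHA"; gene_biotype "protein_coding";\n')
    path = write(tmp_path, "g.gtf", gtf)
    (rec,) = read_gene_annotation(path, format="gtf")
    assert rec.strand == "-"
    assert rec.biotype == "protein_coding"
    assert rec.start == 100 and rec.end == 500


def test_gtf_non_gene_features_skipped(tmp_path):
    gtf = ('1\tensembl\ttranscript\t100\t500\t.\t+\t.\tgene_id "G1";\n')
    path = write(tmp_path, "t.gtf", gtf)
    assert read_gene_annotation(path, format="gtf") == []


def test_malformed_line_error_names_line_number(tmp_path):
    path = write(tmp_path, "bad.tsv",
                 TSV_HEADER
                 + "G1\tA\t1\t100\t500\t+\tprotein_coding\td\n"
                 + "G2\tB\t1\tnotanumber\t900\t+\tprotein_coding\td\n")
    with pytest.raises(AnnotationParseError, match=":3"):
        read_gene_annotation(path, format="tsv")


def test_start_after_end_rejected(tmp_path):
    path = write(tmp_path, "inv.tsv",
                 TSV_HEADER + "G1\tA\t1\t500\t100\t+\tprotein_coding\td\n")
    with pytest.raises(AnnotationValidationError, match="coordinates"):
        read_gene_annotation(path, format="tsv")


def test_duplicate_gene_id_rejected(tmp_path):
    body = "G1\tA\t1\t100\t500\t+\tprotein_coding\td\n" * 2
    path = write(tmp_path, "dup.tsv", TSV_HEADER + body)
    with pytest.raises(AnnotationValidationError, match="duplicate gene_id"):
        read_gene_annotation(path, format="tsv")


@pytest.mark.parametrize("enc,expected", [
    ("+", "+"), ("-", "-"), ("1", "+"), ("-1", "-"),
    ("forward", "+"), ("reverse", "-"),
])
def test_strand_encodings_normalized(enc, expected):
    assert normalize_strand(enc) == expected


def test_unknown_strand_encoding_rejected():
    with pytest.raises(AnnotationValidationError):
        normalize_strand("*")


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def test_nonprimary_assembly_removed():
    recs = [
        make_gene("G1", 100, 500),
        make_gene("G2", 100, 500, chrom="KI270728.1"),
        make_gene("G3", 700, 900, chrom="X"),
    ]
    kept, report = filter_genes(recs)
    assert [g.gene_id for g in kept] == ["G1", "G3"]
    assert report.removed_nonprimary_assembly == 1


def test_duplicate_gene_name_keeps_smallest_id():
    recs = [
        make_gene("ENSG2", 100, 500, gene_name="SAME"),
        make_gene("ENSG1", 700, 900, gene_name="SAME"),
    ]
    kept, report = filter_genes(recs)
    assert [g.gene_id for g in kept] == ["ENSG1"]
    assert report.removed_duplicate_names == 1


def test_readthrough_detected_from_description_token():
    recs = [make_gene("G1", 1, 10, description="ABC-DEF Readthrough transcript")]
    kept, report = filter_genes(recs)
    assert kept == [] and report.removed_readthrough == 1


def test_novel_without_description_and_name_removed():
    recs = [make_gene("G1", 1, 10, gene_name=None, description=None),
            make_gene("G2", 20, 30, gene_name=None, description="described")]
    kept, report = filter_genes(recs)
    assert [g.gene_id for g in kept] == ["G2"]
    assert report.removed_novel_embedded == 1


def test_exclusion_list_and_biotype_stages():
    recs = [make_gene("G1", 1, 10),
            make_gene("G2", 20, 30, biotype="lincRNA"),
            make_gene("G3", 40, 50)]
    kept, report = filter_genes(recs, exclusion_ids={"G3"})
    assert [g.gene_id for g in kept] == ["G1"]
    assert report.removed_non_protein_coding == 1
    assert report.removed_via_exclusion_list == 1


def test_filter_is_idempotent(synthetic_dataset):
    genes = synthetic_dataset["genes"]
    again, report = filter_genes(genes)
    assert again == list(genes)
    assert report.total_removed() == 0


def test_empty_result_is_legal():
    kept, report = filter_genes([make_gene("G1", 1, 10, biotype="lincRNA")])
    assert kept == [] and report.retained == 0
    report.check()


@st.composite
def random_records(draw):
    n = draw(st.integers(0, 30))
    recs = []
    for i in range(n):
        start = draw(st.integers(1, 1000))
        name = draw(st.sampled_from([None, "A", "B", "C", f"N{i}"]))
        desc = draw(st.sampled_from([None, "plain", "a readthrough thing"]))
        recs.append(GeneRecord(
            gene_id=f"G{i:03d}",
            chromosome=draw(st.sampled_from(["1", "2", "X", "KI270.1"])),
            start=start,
            end=start + draw(st.integers(0, 500)),
            strand=draw(st.sampled_from(["+", "-"])),
            biotype=draw(st.sampled_from(["protein_coding", "lincRNA"])),
            gene_name=name,
            description=desc,
        ))
    return recs


@settings(max_examples=100, derandomize=True)
@given(random_records())
def test_filter_report_arithmetic_always_consistent(recs):
    kept, report = filter_genes(recs)
    assert report.input_records == len(recs)
    assert report.retained == len(kept)
    assert report.retained == report.input_records - report.total_removed()
    # a second pass removes nothing
    kept2, report2 = filter_genes(kept)
    assert kept2 == kept and report2.total_removed() == 0


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def test_gene_table_round_trip(tmp_path, synthetic_dataset):
    genes = synthetic_dataset["genes"]
    path = tmp_path / "genes.tsv"
    write_gene_table(genes, path)
    back = read_gene_annotation(path, format="tsv")
    assert back == list(genes)


def test_bed_output_is_zero_based_half_open(tmp_path):
    path = tmp_path / "g.bed"
    write_bed([make_gene("G1", 100, 500, strand="-")], path)
    assert path.read_text() == "1\t99\t500\tG1\t0\t-\n"


def test_empty_outputs(tmp_path):
    write_gene_table([], tmp_path / "empty.tsv")
    write_bed([], tmp_path / "empty.bed")
    assert read_gene_annotation(tmp_path / "empty.tsv", format="tsv") == []
    assert (tmp_path / "empty.bed").read_text() == ""
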