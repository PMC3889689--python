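"""Format readers/writers: coordinate conventions, longest-transcript
selection, FDR dialects, round trips, and the scaffold filter."""

import pytest
from hypothesis import given, settings, strategies as st

from tfdirect import annotation_io as aio
from tfdirect.models import (
    CountMatrix,
    GeneModel,
    GeneSetCollection,
    OrthologMap,
    Peak,
    ScaffoldSet,
    WeightedNetwork,
)


# ---------------------------------------------------------------------------
# scaffold filter


def test_filter_is_strictly_greater_than():
    s = ScaffoldSet({"a": 9_999, "b": 10_000, "c": 10_001})
    kept = aio.filter_scaffolds(s, 10_000)
    assert set(kept) == {"c"}


def test_filter_with_zero_min_length_is_identity():
    s = ScaffoldSet({"a": 1, "b": 10})
    assert aio.filter_scaffolds(s, 0) == s


@settings(derandomize=True, max_examples=50)
@given(
    lengths=st.dictionaries(st.text(min_size=1, max_size=4), st.integers(1, 50_000), max_size=20),
    m1=st.integers(0, 40_000),
    m2=st.integers(0, 40_000),
)
def test_filter_idempotent_and_monotone(lengths, m1, m2):
    s = ScaffoldSet(lengths)
    once = aio.filter_scaffolds(s, m1)
    assert aio.filter_scaffolds(once, m1) == once
    lo, hi = sorted((m1, m2))
    assert set(aio.filter_scaffolds(s, hi)) <= set(aio.filter_scaffolds(s, lo))


# ---------------------------------------------------------------------------
# gene models


def _write(path, text):
    path.write_text(text)
    return str(path)


def test_gff3_coordinates_are_converted_to_half_open(tmp_path):
    gff = _write(
        tmp_path / "g.gff3",
        "##gff-version 3\n"
        "s1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        "s1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "s1\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g1.t1\n",
    )
    genes = aio.read_gene_models(gff, "gff3", ScaffoldSet({"s1": 200}))
    assert genes == [GeneModel("g1", "s1", 0, 100, "+", 100)]


def test_longest_transcript_wins(tmp_path):
    # two transcripts with exonic lengths 300 and 500
    gff = _write(
        tmp_path / "g.gff3",
        "##gff-version 3\n"
        "s1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=g1\n"
        "s1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
        "s1\tsrc\texon\t1\t300\t.\t+\t.\tID=t1.e1;Parent=t1\n"
        "s1\tsrc\tmRNA\t1\t1000\t.\t+\t.\tID=t2;Parent=g1\n"
        "s1\tsrc\texon\t1\t250\t.\t+\t.\tID=t2.e1;Parent=t2\n"
        "s1\tsrc\texon\t751\t1000\t.\t+\t.\tID=t2.e2;Parent=t2\n",
    )
    genes = aio.read_gene_models(gff, "gff3", ScaffoldSet({"s1": 2000}))
    (g,) = genes
    assert g.transcript_length == 500
    assert (g.start, g.end) == (0, 1000)


def test_bed12_block_sizes_sum_to_transcript_length(tmp_path):
    bed = _write(
        tmp_path / "g.bed",
        "s1\t0\t500\tg1\t0\t+\t0\t500\t0\t2\t50,50\t0,450\n",
    )
    genes = aio.read_gene_models(bed, "bed12", ScaffoldSet({"s1": 1000}))
    assert genes[0].transcript_length == 100


def test_malformed_gff3_reports_line_number(tmp_path):
    gff = _write(tmp_path / "bad.gff3", "##gff-version 3\ns1\tsrc\tgene\tONE\t100\t.\t+\t.\tID=g\n")
    with pytest.raises(aio.ParseError, match=":2"):
        aio.read_gene_models(gff, "gff3", ScaffoldSet({"s1": 200}))


def test_gene_on_unknown_scaffold_rejected(tmp_path):
    gff = _write(tmp_path / "g.gff3", "##gff-version 3\nsX\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n")
    with pytest.raises(aio.ParseError, match="unknown scaffold"):
        aio.read_gene_models(gff, "gff3", ScaffoldSet({"s1": 200}))


@pytest.mark.parametrize("fmt", ["gff3", "bed12"])
def test_gene_model_round_trip(tmp_path, tiny_scaffolds, tiny_genes, fmt):
    # BED12 carries no ortholog attribute, so compare the representable fields
    path = tmp_path / f"genes.{fmt}"
    aio.write_gene_models(tiny_genes, path, format=fmt)
    back = aio.read_gene_models(path, fmt, tiny_scaffolds)
    if fmt == "gff3":
        assert back == sorted(tiny_genes, key=lambda g: (g.scaffold_id, g.start))
    else:
        stripped = lambda gs: sorted(
            (g.gene_id, g.scaffold_id, g.start, g.end, g.strand, g.transcript_length) for g in gs
        )
        assert stripped(back) == stripped(tiny_genes)


def test_gff3_round_trip_is_identity_on_file_bytes(tmp_path, tiny_scaffolds, tiny_genes):
    p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    aio.write_gene_models(tiny_genes, p1, format="gff3")
    aio.write_gene_models(aio.read_gene_models(p1, "gff3", tiny_scaffolds), p2, format="gff3")
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# peaks


def test_narrowpeak_neglog10_dialect(tmp_path):
    np_file = _write(tmp_path / "p.narrowPeak", "s1\t100\t200\tp1\t0\t.\t25.0\t-1\t2.0\t-1\n")
    (peak,) = aio.read_peaks(np_file, "narrowpeak", fdr_dialect="neglog10")
    assert peak.fdr == pytest.approx(0.01)
    assert peak.fold_enrichment == 25.0


def test_empty_peak_file_gives_empty_list(tmp_path):
    empty = _write(tmp_path / "empty.narrowPeak", "")
    assert aio.read_peaks(empty, "narrowpeak") == []


def test_tsv_peak_field_mapping(tmp_path):
    tsv = _write(
        tmp_path / "p.tsv",
        "scaffold_id\tstart\tend\tfdr\tfold_enrichment\ns1\t100\t200\t0.01\t25.0\n",
    )
    (peak,) = aio.read_peaks(tsv, "tsv")
    assert (peak.scaffold_id, peak.start, peak.end) == ("s1", 100, 200)
    assert (peak.fdr, peak.fold_enrichment) == (0.01, 25.0)
    assert peak.peak_id  # stable id assigned when absent


def test_invalid_peak_records_raise(tmp_path):
    bad = _write(tmp_path / "p.tsv", "scaffold_id\tstart\tend\tfdr\tfold_enrichment\ns1\t200\t100\t0.01\t5\n")
    with pytest.raises(aio.ParseError, match="start"):
        aio.read_peaks(bad, "tsv")
    neg = _write(tmp_path / "n.tsv", "scaffold_id\tstart\tend\tfdr\tfold_enrichment\ns1\t1\t2\t0.01\t-5\n")
    with pytest.raises(aio.ParseError, match="fold"):
        aio.read_peaks(neg, "tsv")


@pytest.mark.parametrize("fmt", ["narrowpeak", "tsv"])
def test_peak_round_trip(tmp_path, fmt):
    peaks = [
        Peak("pk_a", "s1", 10, 400, 0.002, 31.5),
        Peak("pk_b", "s2", 0, 120, 0.5, 3.25),
    ]
    path = tmp_path / "p.out"
    aio.write_peaks(peaks, path, format=fmt)
    assert aio.read_peaks(path, fmt) == sorted(peaks, key=lambda p: (p.scaffold_id, p.start))


# ---------------------------------------------------------------------------
# other formats round-trip


def test_scaffold_round_trip(tmp_path, tiny_scaffolds):
    path = tmp_path / "s.tsv"
    aio.write_scaffolds(tiny_scaffolds, path)
    assert aio.read_scaffolds(path) == tiny_scaffolds


def test_counts_round_trip(tmp_path):
    from conftest import make_count_matrix

    cm = make_count_matrix({"g1": [3, 4, 0, 2], "g2": [10, 11, 12, 13]})
    path = tmp_path / "c.tsv"
    aio.write_counts(cm, path)
    assert aio.read_counts(path, cm.group) == cm


def test_ortholog_map_round_trip_and_duplicate_error(tmp_path):
    om = OrthologMap({"g1.L": "H1", "g1.S": "H1", "g2.L": "H2"})
    path = tmp_path / "om.tsv"
    aio.write_ortholog_map(om, path)
    assert aio.read_ortholog_map(path) == om
    bad = tmp_path / "bad.tsv"
    bad.write_text("frog_gene_id\thuman_gene_id\ng1\tH1\ng1\tH2\n")
    with pytest.raises(aio.ParseError, match="more than one"):
        aio.read_ortholog_map(bad)


def test_network_round_trip_and_invariants(tmp_path):
    net = WeightedNetwork([("a", "b", 1.5), ("b", "c", 0.25)], nodes=["a", "b", "c", "d"])
    path = tmp_path / "net.tsv"
    aio.write_network(net, path)
    back = aio.read_network(path)
    assert back.edges() == net.edges()
    with pytest.raises(ValueError, match="self-loop"):
        WeightedNetwork([("a", "a", 1.0)])
    with pytest.raises(ValueError, match="weight"):
        WeightedNetwork([("a", "b", 0.0)])
    with pytest.raises(ValueError, match="duplicate"):
        WeightedNetwork([("a", "b", 1.0), ("b", "a", 2.0)])


def test_gene_sets_round_trip(tmp_path):
    gsc = GeneSetCollection(
        {"setA": ["g1", "g2"], "setB": ["g3"]},
        {"setA": "first", "setB": "second"},
    )
    path = tmp_path / "sets.gmt"
    aio.write_gene_sets(gsc, path)
    assert aio.read_gene_sets(path) == gsc
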