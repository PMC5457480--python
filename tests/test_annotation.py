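"""Annotation and expression-table IO: parsing, ordering, region assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dosagescan as ds
from dosagescan.annotation import AnnotationParseError, write_expression_tsv


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestBedAndGff:
    def test_bed_coordinates_become_one_based_inclusive(self, tmp_path):
        p = _write(tmp_path, "a.bed", "Chr11\t0\t100\tgeneA\t0\t+\n")
        cat = ds.load_gene_annotation(p)
        (g,) = cat.genes
        assert (g.start, g.end, g.strand) == (1, 100, "+")

    def test_gff3_gene_features_sorted_across_chromosomes(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "Chr2\tsrc\tgene\t50\t80\t.\t+\t.\tID=g3\n"
            "Chr1\tsrc\tgene\t200\t300\t.\t-\t.\tID=g2\n"
            "Chr1\tsrc\tmRNA\t200\t300\t.\t-\t.\tID=t1\n"
            "Chr1\tsrc\tgene\t100\t150\t.\t+\t.\tID=g1\n"
        )
        cat = ds.load_gene_annotation(_write(tmp_path, "a.gff3", gff))
        assert cat.gene_ids == ["g1", "g2", "g3"]
        assert cat.genes[1].strand == "-"

    def test_malformed_line_error_names_line_number(self, tmp_path):
        p = _write(tmp_path, "bad.bed", "Chr1\t0\t10\tg1\nChr1\tten\t20\tg2\n")
        with pytest.raises(AnnotationParseError, match=":2:"):
            ds.load_gene_annotation(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = _write(tmp_path, "dup.bed", "Chr1\t0\t10\tg\t0\t+\nChr1\t20\t30\tg\t0\t+\n")
        with pytest.raises(AnnotationParseError, match="duplicate"):
            ds.load_gene_annotation(p)

    def test_bed_round_trip_identity(self, tmp_path):
        genes = [
            ds.GeneModel("g1", "Chr1", 5, 50, "+"),
            ds.GeneModel("g2", "Chr1", 5, 60, "-"),
            ds.GeneModel("g3", "Chr2", 1, 10, "unknown"),
        ]
        cat = ds.GeneCatalog(genes)
        out = tmp_path / "rt.bed"
        cat.to_bed(out)
        reloaded = ds.load_gene_annotation(out)
        assert reloaded.genes == cat.genes

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["Chr1", "Chr2", "Chr11"]),
                st.integers(min_value=1, max_value=10_000),
                st.integers(min_value=0, max_value=500),
                st.sampled_from(["+", "-", "unknown"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_bed_round_trip_property(self, tmp_path_factory, gene_tuples):
        genes = [
            ds.GeneModel(f"g{i:03d}", chrom, start, start + length, strand)
            for i, (chrom, start, length, strand) in enumerate(gene_tuples)
        ]
        cat = ds.GeneCatalog(genes)
        out = tmp_path_factory.mktemp("rt") / "cat.bed"
        cat.to_bed(out)
        assert ds.load_gene_annotation(out).genes == cat.genes


class TestRegions:
    def make_partition(self):
        return ds.RegionPartition(
            [
                ds.Region("11S-1", "Chr11", 1, 5_399_999),
                ds.Region("11S-2", "Chr11", 5_400_000, 12_100_000),
            ]
        )

    def test_boundary_start_is_inside(self):
        part = self.make_partition()
        g = ds.GeneModel("g", "Chr11", 5_400_000, 5_400_100)
        assert part.region_of(g) == "11S-2"

    def test_default_region_is_chromosome_name(self):
        part = self.make_partition()
        g = ds.GeneModel("g", "Chr12", 100, 200)
        assert part.region_of(g) == "Chr12"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ds.RegionPartition(
                [
                    ds.Region("a", "Chr1", 1, 100),
                    ds.Region("b", "Chr1", 100, 200),
                ]
            )

    def test_duplication_span_holds_513_genes(self):
        """Genes placed across 5.4-12.1 Mb of Chr11 all map to the repeat
        region, matching the 513-gene repeat-segment bookkeeping."""
        starts = np.linspace(5_400_000, 12_100_000, 513).astype(int)
        cat = ds.GeneCatalog(
            [
                ds.GeneModel(f"g{i:04d}", "Chr11", int(s), int(s) + 100)
                for i, s in enumerate(starts)
            ]
        )
        mapping = ds.assign_regions(cat, ds.default_chr11_partition())
        assert sum(r == "11S-2" for r in mapping.values()) == 513

    def test_assignment_is_a_partition(self, reference_results):
        sizes = reference_results.summary_table.set_index("region_id")["n_expressed"]
        assert sizes.loc["Total"] == sizes.drop("Total").sum()


class TestExpressionPair:
    def test_identical_files_full_join(self, tmp_path):
        body = "".join(f"g{i}\t{i + 1}.5\n" for i in range(10))
        c = _write(tmp_path, "c.tsv", body)
        v = _write(tmp_path, "v.tsv", body)
        pair = ds.load_expression_pair(c, v)
        assert len(pair) == 10
        assert pair.n_control_only == pair.n_variant_only == 0

    def test_header_row_tolerated(self, tmp_path):
        c = _write(tmp_path, "c.tsv", "gene_id\tfpkm\ng1\t2.0\n")
        v = _write(tmp_path, "v.tsv", "g1\t4.0\n")
        pair = ds.load_expression_pair(c, v)
        assert pair.data.loc["g1", "control"] == 2.0

    def test_one_sided_gene_excluded_and_counted(self, tmp_path):
        c = _write(tmp_path, "c.tsv", "gX\t1.0\ng1\t2.0\n")
        v = _write(tmp_path, "v.tsv", "g1\t3.0\n")
        pair = ds.load_expression_pair(c, v)
        assert list(pair.gene_ids) == ["g1"]
        assert pair.n_control_only == 1

    def test_join_symmetric_in_gene_set(self, tmp_path):
        c = _write(tmp_path, "c.tsv", "gX\t1.0\ng1\t2.0\n")
        v = _write(tmp_path, "v.tsv", "g1\t3.0\ngY\t9.0\n")
        ab = ds.load_expression_pair(c, v)
        ba = ds.load_expression_pair(v, c)
        assert set(ab.gene_ids) == set(ba.gene_ids)
        assert ab.data.loc["g1", "control"] == ba.data.loc["g1", "variant"]

    @pytest.mark.parametrize("value", ["-1.0", "abc"])
    def test_bad_values_rejected(self, tmp_path, value):
        c = _write(tmp_path, "c.tsv", f"g1\t{value}\n")
        v = _write(tmp_path, "v.tsv", "g1\t1.0\n")
        with pytest.raises(AnnotationParseError):
            ds.load_expression_pair(c, v)

    def test_expression_tsv_round_trip_lossless(self, tmp_path):
        values = {"g1": 0.1 + 0.2, "g2": 2.0 / 3.0, "g3": 1e-7}
        p = tmp_path / "e.tsv"
        write_expression_tsv(values, p)
        other = _write(tmp_path, "o.tsv", "g1\t1\ng2\t1\ng3\t1\n")
        pair = ds.load_expression_pair(p, other)
        for g, v in values.items():
            assert pair.data.loc[g, "control"] == v
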