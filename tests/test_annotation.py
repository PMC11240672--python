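"""GTF/GFF3/QTLdb parsing, island-flank overlap and trait enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from rohscape.annotation import (
    features_in_islands,
    gene_length,
    qtl_enrichment,
    read_gene_annotation,
    read_qtl_database,
)

# the seven protein-coding genes of the OAR6 selection hotspot
HOTSPOT_GENES = [
    ("6", 33_699_466, 35_188_219, "CCSER1"),
    ("6", 36_709_616, 36_855_827, "HERC3"),
    ("6", 36_739_315, 36_741_723, "NAP1L5"),
    ("6", 36_902_696, 36_990_169, "PYURF"),
    ("6", 37_282_161, 37_348_326, "PKD2"),
    ("6", 37_369_583, 37_425_206, "SPP1"),
    ("6", 38_052_622, 38_222_929, "LCORL"),
]


def _island(chrom="6", start=34_253_440, end=38_238_124):
    return pd.DataFrame(
        [{"chromosome": chrom, "start_bp": start, "end_bp": end,
          "length_bp": end - start, "n_snps": 50, "peak_incidence": 0.6}]
    )


class TestGeneReader:
    def test_gtf_single_gene(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(
            '#!genome-version Oar_rambouillet\n'
            '6\tensembl\tgene\t33699466\t35188219\t.\t+\t.\t'
            'gene_id "ENSOARG00000007488"; gene_name "CCSER1"; '
            'gene_biotype "protein_coding";\n'
        )
        genes = read_gene_annotation(gtf)
        assert len(genes) == 1
        g = genes.iloc[0]
        assert g.gene_name == "CCSER1" and g.chromosome == "6"
        assert g.length_bp == 1_488_754
        assert g.biotype == "protein_coding"

    def test_transcript_and_exon_lines_skipped(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(
            '1\tsrc\tgene\t100\t500\t.\t+\t.\tgene_id "G1";\n'
            '1\tsrc\ttranscript\t100\t500\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            '1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        genes = read_gene_annotation(gtf)
        assert genes["gene_id"].tolist() == ["G1"]

    def test_gff3_dialect(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr2\tensembl\tgene\t10\t40\t.\t-\t.\t"
            "ID=gene:ENSG1;Name=MYGENE;biotype=protein_coding\n"
        )
        genes = read_gene_annotation(gff)
        g = genes.iloc[0]
        assert g.gene_id == "ENSG1" and g.gene_name == "MYGENE"
        assert g.chromosome == "2" and g.length_bp == 31

    def test_malformed_line_skipped_with_warning(self, tmp_path, caplog):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(
            '1\tsrc\tgene\tnotanumber\t500\t.\t+\t.\tgene_id "G1";\n'
            '1\tsrc\tgene\t100\t500\t.\t+\t.\tgene_id "G2";\n'
        )
        with caplog.at_level("WARNING"):
            genes = read_gene_annotation(gtf)
        assert genes["gene_id"].tolist() == ["G2"]
        assert "malformed" in caplog.text

    @pytest.mark.parametrize(
        "name,expected",
        [("CCSER1", 1_488_754), ("NAP1L5", 2_409), ("LCORL", 170_308)],
    )
    def test_inclusive_gene_lengths(self, name, expected):
        chrom, start, end, _ = next(g for g in HOTSPOT_GENES if g[3] == name)
        assert gene_length(start, end) == expected


class TestQTLReader:
    def test_qtldb_gff_dialect(self, tmp_path):
        f = tmp_path / "qtl.gff"
        f.write_text(
            "#QTLdb dump\n"
            'Chr.6\tAnimalQTLdb\tQTL\t34000000\t36000000\t.\t.\t.\t'
            'QTL_ID=1234;Name="Bone area";Abbrev=BONAR;trait_type=Meat_Carcass\n'
        )
        q = read_qtl_database(f)
        row = q.iloc[0]
        assert row.qtl_id == "1234" and row.trait == "Bone area"
        assert row.chromosome == "6" and row.qtl_type == "Meat_Carcass"

    def test_tsv_fallback(self, tmp_path):
        f = tmp_path / "qtl.tsv"
        f.write_text(
            "qtl_id\ttrait\tchromosome\tstart_bp\tend_bp\n"
            "q1\tbody weight\t6\t100\t200\n"
        )
        q = read_qtl_database(f)
        assert q.iloc[0].trait == "body weight"

    def test_tsv_missing_columns_fatal(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("qtl_id\ttrait\n1\tx\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_qtl_database(f)


class TestOverlap:
    def _genes(self):
        return pd.DataFrame(
            [
                {"gene_id": n, "gene_name": n, "chromosome": c,
                 "start_bp": s, "end_bp": e, "biotype": "protein_coding",
                 "length_bp": e - s + 1}
                for c, s, e, n in HOTSPOT_GENES
            ]
        )

    def test_gene_inside_island_hits(self):
        isl = _island()
        genes = self._genes()
        hits = features_in_islands(isl, genes, flank_bp=0)
        assert "PKD2" in hits["gene_name"].tolist()

    def test_flank_boundary(self):
        isl = _island(chrom="1", start=10_000_000, end=12_000_000)
        near = pd.DataFrame(
            [{"gene_id": "near", "gene_name": "near", "chromosome": "1",
              "start_bp": 12_400_000, "end_bp": 12_450_000,
              "biotype": "", "length_bp": 50_001},
             {"gene_id": "far", "gene_name": "far", "chromosome": "1",
              "start_bp": 12_600_000, "end_bp": 12_650_000,
              "biotype": "", "length_bp": 50_001}]
        )
        hits = features_in_islands(isl, near, flank_bp=500_000)
        assert hits["gene_name"].tolist() == ["near"]

    def test_all_seven_hotspot_genes_hit(self):
        """The published OAR6 island plus 500-kb flanks covers all seven
        hotspot genes (pure interval arithmetic on their coordinates)."""
        hits = features_in_islands(_island(), self._genes(), flank_bp=500_000)
        assert sorted(hits["gene_name"]) == sorted(g[3] for g in HOTSPOT_GENES)

    def test_flank_monotone(self):
        isl = _island()
        genes = self._genes()
        prev = -1
        for flank in (0, 100_000, 500_000, 2_000_000):
            n = len(features_in_islands(isl, genes, flank_bp=flank))
            assert n >= prev
            prev = n


class TestEnrichment:
    def _db(self, n_total=100, n_trait=10, trait="X"):
        rows = []
        for k in range(n_total):
            rows.append(
                {"qtl_id": f"q{k}", "trait": trait if k < n_trait else f"other{k % 7}",
                 "qtl_type": "", "chromosome": "1",
                 "start_bp": 1000 * k + 1, "end_bp": 1000 * k + 500}
            )
        return pd.DataFrame(rows)

    def test_exact_hypergeometric_oracle(self):
        """p-value equals the explicit hypergeometric tail sum
        P[X >= 3], X ~ Hypergeom(N=100, K=10, n=5); richness = 3/10."""
        db = self._db()
        hits = db.iloc[[0, 1, 2, 20, 30]].copy()  # 3 of trait X among 5 drawn
        hits["island_chromosome"] = "1"
        out = qtl_enrichment(hits, db)
        row = out.loc[out.trait == "X"].iloc[0]
        assert row.richness_factor == pytest.approx(0.3)
        expected = sum(
            comb(10, k) * comb(90, 5 - k) for k in range(3, 6)
        ) / comb(100, 5)
        assert row.p_value == pytest.approx(expected, rel=1e-12)

    def test_single_trait_database_p_one(self):
        db = self._db(n_total=20, n_trait=20)
        hits = db.iloc[:4].copy()
        out = qtl_enrichment(hits, db)
        assert out.iloc[0].p_value == pytest.approx(1.0)

    def test_zero_hits_empty_table(self):
        out = qtl_enrichment(self._db().iloc[0:0], self._db())
        assert out.empty

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(3)
        db = self._db()
        draw = rng.choice(100, size=12, replace=False)
        hits = db.iloc[draw].copy()
        out = qtl_enrichment(hits, db)
        assert ((out.p_value > 0) & (out.p_value <= 1)).all()
        assert (out.adjusted_p >= out.p_value - 1e-15).all()
        # BH-adjusted values are monotone nondecreasing in p-value rank
        assert out.sort_values("p_value").adjusted_p.is_monotonic_increasing
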