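import numpy as np
import pytest

from kmerdecomp.regions import (
    Feature,
    GenomeAnnotation,
    annotation_to_gff3,
    complement_intervals,
    derive_regions,
    extract_sequences,
    load_genome,
    merge_intervals,
    region_composition,
    regions_to_bed,
    subtract_intervals,
)

from .conftest import random_sequence


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_gff3(path, rows):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


class TestIntervalAlgebra:
    def test_merge(self):
        assert merge_intervals([(5, 10), (0, 3), (2, 6)]) == [(0, 10)]

    def test_subtract(self):
        assert subtract_intervals([(0, 10)], [(2, 4), (6, 8)]) == [(0, 2), (4, 6), (8, 10)]

    def test_complement(self):
        assert complement_intervals([(2, 4)], 10) == [(0, 2), (4, 10)]
        assert complement_intervals([], 10) == [(0, 10)]
        assert complement_intervals([(0, 10)], 10) == []


class TestLoadGenome:
    def test_gff_coordinate_convention(self, tmp_path):
        # 1-based inclusive [1,100] in GFF becomes [0,100) internally
        fa = tmp_path / "g.fasta"
        write_fasta(fa, {"chr1": "A" * 100})
        gff = tmp_path / "g.gff3"
        write_gff3(gff, [
            ("chr1", "src", "gene", 1, 100, ".", "+", ".", "ID=g1"),
        ])
        ann, seqs = load_genome(fa, gff)
        gene = ann.genes()[0]
        assert (gene.start, gene.end) == (0, 100)
        assert seqs["chr1"] == "A" * 100

    def test_missing_chromosome_named_in_error(self, tmp_path):
        fa = tmp_path / "g.fasta"
        write_fasta(fa, {"chr1": "ACGT" * 25})
        gff = tmp_path / "g.gff3"
        write_gff3(gff, [("chrZ", "src", "gene", 1, 10, ".", "+", ".", "ID=g1")])
        with pytest.raises(ValueError, match="chrZ"):
            load_genome(fa, gff)

    def test_exon_outside_gene_rejected(self, tmp_path):
        fa = tmp_path / "g.fasta"
        write_fasta(fa, {"chr1": "ACGT" * 50})
        gff = tmp_path / "g.gff3"
        write_gff3(gff, [
            ("chr1", "src", "gene", 10, 50, ".", "+", ".", "ID=g1"),
            ("chr1", "src", "exon", 5, 20, ".", "+", ".", "ID=e1;Parent=g1"),
        ])
        with pytest.raises(ValueError, match="outside parent gene"):
            load_genome(fa, gff)

    def test_sequences_uppercased_ambiguity_preserved(self, tmp_path):
        fa = tmp_path / "g.fasta"
        write_fasta(fa, {"chr1": "acgtn" * 20})
        gff = tmp_path / "g.gff3"
        write_gff3(gff, [("chr1", "src", "gene", 1, 10, ".", "+", ".", "ID=g1")])
        _, seqs = load_genome(fa, gff)
        assert seqs["chr1"].startswith("ACGTN")

    def test_exon_via_mrna_parent(self, tmp_path):
        fa = tmp_path / "g.fasta"
        write_fasta(fa, {"chr1": "ACGT" * 50})
        gff = tmp_path / "g.gff3"
        write_gff3(gff, [
            ("chr1", "src", "gene", 1, 100, ".", "+", ".", "ID=g1"),
            ("chr1", "src", "mRNA", 1, 100, ".", "+", ".", "ID=m1;Parent=g1"),
            ("chr1", "src", "exon", 1, 40, ".", "+", ".", "ID=e1;Parent=m1"),
        ])
        ann, _ = load_genome(fa, gff)
        exons = ann.by_type("exon")
        assert exons[0].gene_id == "g1"

    def test_genbank_reader(self, tmp_path):
        gb = tmp_path / "g.gb"
        seq = "ACGT" * 30
        gb.write_text(
            "LOCUS       chr1                     120 bp    DNA     linear   SYN 01-JAN-2000\n"
            "DEFINITION  synthetic.\n"
            "ACCESSION   chr1\n"
            "VERSION     chr1\n"
            "FEATURES             Location/Qualifiers\n"
            "     gene            11..100\n"
            "                     /locus_tag=\"g1\"\n"
            "     exon            11..50\n"
            "                     /locus_tag=\"g1\"\n"
            "     CDS             21..50\n"
            "                     /locus_tag=\"g1\"\n"
            "ORIGIN\n"
            + "".join(
                f"{i * 60 + 1:>9} " + " ".join(
                    seq[i * 60 + j : i * 60 + j + 10].lower() for j in range(0, 60, 10)
                ) + "\n"
                for i in range(2)
            )
            + "//\n"
        )
        ann, seqs = load_genome(None, gb)
        gene = ann.genes()[0]
        assert (gene.start, gene.end) == (10, 100)
        exon = ann.by_type("exon")[0]
        assert (exon.start, exon.end) == (10, 50)
        assert seqs["chr1"] == seq


def make_annotation(genes):
    """genes: list of (chrom, start, end, strand, exons=[(s,e),...])"""
    chroms = {}
    features = []
    for i, (chrom, start, end, strand, exons, length) in enumerate(genes):
        chroms[chrom] = length
        gid = f"g{i}"
        features.append(Feature(chrom, start, end, strand, "gene", gid))
        for es, ee in exons:
            features.append(Feature(chrom, es, ee, strand, "exon", gid))
            features.append(Feature(chrom, es, ee, strand, "CDS", gid))
    return GenomeAnnotation(chromosomes=chroms, features=features)


class TestDeriveRegions:
    def test_gene_covers_chromosome_with_one_exon(self):
        ann = make_annotation([("chr1", 0, 100, "+", [(0, 100)], 100)])
        regions = derive_regions(ann)
        assert regions["intergenic"].total_length() == 0
        assert regions["intronic"].total_length() == 0
        assert regions["exonic"].total_length() == 100

    def test_no_genes_all_intergenic(self):
        ann = GenomeAnnotation(chromosomes={"chr1": 500}, features=[])
        regions = derive_regions(ann)
        assert regions["intergenic"].total_length() == 500
        assert regions["genic"].total_length() == 0

    def test_intron_is_gene_minus_exons(self):
        ann = make_annotation([("chr1", 10, 110, "+", [(10, 40), (70, 110)], 200)])
        regions = derive_regions(ann)
        assert regions["intronic"].intervals["chr1"] == [(40, 70)]
        assert regions["intergenic"].intervals["chr1"] == [(0, 10), (110, 200)]

    def test_exon_of_other_gene_trumps_intron(self):
        # overlapping genes: a base exonic for gene B is never intronic
        ann = make_annotation([
            ("chr1", 0, 100, "+", [(0, 30), (80, 100)], 300),
            ("chr1", 20, 90, "-", [(20, 70)], 300),
        ])
        regions = derive_regions(ann)
        intronic = set()
        for s, e in regions["intronic"].intervals.get("chr1", []):
            intronic.update(range(s, e))
        exonic = set()
        for s, e in regions["exonic"].intervals["chr1"]:
            exonic.update(range(s, e))
        assert not (intronic & exonic)

    def test_random_fixture_against_per_base_oracle(self, rng):
        length = 10_000
        genes = []
        pos = 0
        for i in range(20):
            pos += int(rng.integers(20, 200))
            gene_len = int(rng.integers(100, 400))
            if pos + gene_len > length:
                break
            n_ex = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(1, gene_len), 2 * n_ex - 2,
                                        replace=False)) if n_ex > 1 else np.array([])
            cuts = [0, *bounds.tolist(), gene_len]
            exons = [(pos + cuts[j], pos + cuts[j + 1]) for j in range(0, len(cuts) - 1, 2)]
            exons = [(s, e) for s, e in exons if e > s]
            genes.append(("chr1", pos, pos + gene_len, "+", exons, length))
            pos += gene_len
        ann = make_annotation(genes)
        regions = derive_regions(ann)

        # brute-force per-base labeling oracle
        genic = np.zeros(length, bool)
        exonic = np.zeros(length, bool)
        for f in ann.features:
            if f.ftype == "gene":
                genic[f.start:f.end] = True
            elif f.ftype == "exon":
                exonic[f.start:f.end] = True
        intronic = genic & ~exonic
        intergenic = ~genic

        def covered(region):
            mask = np.zeros(length, bool)
            for s, e in region.intervals.get("chr1", []):
                mask[s:e] = True
            return mask

        assert np.array_equal(covered(regions["genic"]), genic)
        assert np.array_equal(covered(regions["exonic"]), exonic)
        assert np.array_equal(covered(regions["intronic"]), intronic)
        assert np.array_equal(covered(regions["intergenic"]), intergenic)


class TestComposition:
    def test_no_genes(self):
        ann = GenomeAnnotation(chromosomes={"chr1": 100}, features=[])
        comp = region_composition(derive_regions(ann), 100)
        assert comp["intergenic"] == 100.0
        assert comp["genic"] == 0.0

    def test_half_genic(self):
        ann = make_annotation([("chr1", 0, 500, "+", [(0, 500)], 1000)])
        comp = region_composition(derive_regions(ann), 1000)
        assert comp["genic"] == 50.0
        assert comp["intergenic"] == 50.0

    def test_genic_plus_intergenic_is_100(self, rng):
        ann = make_annotation([
            ("chr1", 10, 200, "+", [(10, 100)], 1000),
            ("chr1", 300, 700, "-", [(300, 500), (600, 700)], 1000),
        ])
        comp = region_composition(derive_regions(ann), 1000)
        assert comp["genic"] + comp["intergenic"] == pytest.approx(100.0, abs=0.01)

    def test_zero_length_error(self):
        ann = GenomeAnnotation(chromosomes={"chr1": 100}, features=[])
        with pytest.raises(ValueError):
            region_composition(derive_regions(ann), 0)


class TestExtractSequences:
    def test_plus_strand_exon(self):
        ann = make_annotation([("chr1", 0, 8, "+", [(0, 4)], 8)])
        regions = derive_regions(ann)
        seqs = extract_sequences(regions["exonic"], {"chr1": "ACGTACGT"})
        assert seqs == ["ACGT"]

    def test_minus_strand_palindrome(self):
        ann = make_annotation([("chr1", 0, 8, "-", [(0, 4)], 8)])
        regions = derive_regions(ann)
        seqs = extract_sequences(regions["CDS"], {"chr1": "ACGTACGT"})
        assert seqs == ["ACGT"]  # revcomp("ACGT") is itself

    def test_minus_strand_cds(self):
        ann = make_annotation([("chr1", 0, 8, "-", [(0, 3)], 8)])
        regions = derive_regions(ann)
        seqs = extract_sequences(regions["CDS"], {"chr1": "AACGTCGT"})
        assert seqs == ["GTT"]

    def test_intergenic_always_forward(self):
        ann = make_annotation([("chr1", 4, 8, "-", [(4, 8)], 8)])
        regions = derive_regions(ann)
        seqs = extract_sequences(regions["intergenic"], {"chr1": "AACGTCGT"})
        assert seqs == ["AACG"]

    def test_forward_policy_override(self):
        ann = make_annotation([("chr1", 0, 8, "-", [(0, 3)], 8)])
        regions = derive_regions(ann)
        seqs = extract_sequences(regions["CDS"], {"chr1": "AACGTCGT"},
                                 orientation="forward")
        assert seqs == ["AAC"]


class TestRoundTrip:
    def test_gff_reemission_identical_regions(self, tmp_path, rng):
        length = 5000
        seq = random_sequence(rng, length)
        genes = [
            ("chr1", 100, 800, "+", [(100, 300), (500, 800)], length),
            ("chr1", 1200, 2000, "-", [(1200, 1500), (1800, 2000)], length),
            ("chr1", 3000, 3500, "+", [(3000, 3500)], length),
        ]
        ann = make_annotation(genes)
        regions1 = derive_regions(ann)
        fa = tmp_path / "g.fasta"
        write_fasta(fa, {"chr1": seq})
        gff = tmp_path / "roundtrip.gff3"
        annotation_to_gff3(ann, gff)
        ann2, _ = load_genome(fa, gff)
        regions2 = derive_regions(ann2)
        for cls in ("genic", "exonic", "CDS", "intronic", "intergenic"):
            assert regions1[cls].intervals == regions2[cls].intervals

    def test_bed_export(self, tmp_path):
        ann = make_annotation([("chr1", 10, 90, "-", [(10, 50)], 100)])
        regions = derive_regions(ann)
        bed = tmp_path / "exonic.bed"
        regions_to_bed(regions["exonic"], bed)
        line = bed.read_text().strip().split("\t")
        assert line[:3] == ["chr1", "10", "50"]
        assert line[5] == "-"
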