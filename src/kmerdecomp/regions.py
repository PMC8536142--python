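"""Genome + annotation loading and derivation of the five region classes.

Internally every interval is 0-based half-open. GFF3 input (1-based
inclusive) and GenBank feature tables are normalized on load. Region
classes: genic = union of gene spans; exonic = union of exons; CDS = union
of CDS intervals; intronic = gene spans minus exons of *any* gene (so no
base is both exonic and intronic); intergenic = chromosome minus gene
spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from .kmers import reverse_complement

REGION_CLASSES = ("genic", "exonic", "CDS", "intronic", "intergenic")
FEATURE_TYPES = ("gene", "exon", "CDS")

Interval = tuple[int, int]


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' | '-'
    ftype: str  # gene | exon | CDS
    gene_id: str


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus gene/exon/CDS features in internal coordinates."""

    chromosomes: dict[str, int]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        genes = {f.gene_id: f for f in self.features if f.ftype == "gene"}
        for f in self.features:
            if f.chrom not in self.chromosomes:
                raise ValueError(
                    f"feature {f.ftype} {f.gene_id!r} references missing chromosome {f.chrom!r}"
                )
            L = self.chromosomes[f.chrom]
            if not (0 <= f.start < f.end <= L):
                raise ValueError(
                    f"feature {f.ftype} {f.gene_id!r} interval [{f.start},{f.end}) "
                    f"outside chromosome {f.chrom!r} (length {L})"
                )
            if f.ftype in ("exon", "CDS"):
                parent = genes.get(f.gene_id)
                if parent is None:
                    raise ValueError(
                        f"{f.ftype} at {f.chrom}:{f.start}-{f.end} has no parent "
                        f"gene {f.gene_id!r}"
                    )
                if f.chrom != parent.chrom or f.start < parent.start or f.end > parent.end:
                    raise ValueError(
                        f"{f.ftype} [{f.start},{f.end}) lies outside parent gene "
                        f"{f.gene_id!r} span [{parent.start},{parent.end})"
                    )

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.ftype == "gene"]

    def by_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]


@dataclass
class RegionSet:
    """Sorted, non-overlapping intervals of one region class per chromosome.

    ``strands`` parallels ``intervals``; for merged intervals assembled from
    features of conflicting strands the forward strand is recorded.
    """

    region_class: str
    intervals: dict[str, list[Interval]]
    strands: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        for chrom, ivs in self.intervals.items():
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping intervals on {chrom}")
            if not self.strands.get(chrom):
                self.strands[chrom] = ["+"] * len(ivs)

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


# ---------------------------------------------------------------------------
# interval algebra

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Set difference a \\ b for merged interval lists."""
    b = merge_intervals(b)
    out: list[Interval] = []
    for s, e in merge_intervals(a):
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def complement_intervals(intervals: Iterable[Interval], length: int) -> list[Interval]:
    return subtract_intervals([(0, length)], intervals)


# ---------------------------------------------------------------------------
# loading

def _load_fasta(path: str | Path) -> dict[str, str]:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def _gene_id_of(db: gffutils.FeatureDB, feature) -> str | None:
    if feature.featuretype == "gene":
        return feature.id
    for parent in db.parents(feature, featuretype="gene"):
        return parent.id
    # fall back to a direct Parent attribute (annotation without gene records)
    return feature.attributes.get("Parent", [None])[0]


def _parse_gff3(path: str | Path) -> list[Feature]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features = []
    for ftype in FEATURE_TYPES:
        for f in db.features_of_type(ftype):
            gid = _gene_id_of(db, f)
            if gid is None:
                raise ValueError(
                    f"{ftype} at {f.seqid}:{f.start}-{f.end} has no parent gene"
                )
            features.append(
                Feature(
                    chrom=f.seqid,
                    start=f.start - 1,  # GFF3 is 1-based inclusive
                    end=f.end,
                    strand=f.strand if f.strand in "+-" else "+",
                    ftype=ftype,
                    gene_id=gid,
                )
            )
    return features


def _parse_genbank(path: str | Path) -> tuple[dict[str, int], list[Feature], dict[str, str]]:
    lengths: dict[str, int] = {}
    features: list[Feature] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        lengths[rec.id] = len(rec.seq)
        try:
            seqs[rec.id] = str(rec.seq).upper()
        except Exception:  # contigs without sequence
            pass
        open_genes: list[tuple[str, int, int]] = []
        for feat in rec.features:
            if feat.type not in FEATURE_TYPES:
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            quals = feat.qualifiers
            name = (
                quals.get("locus_tag", quals.get("gene", [None]))[0]
            )
            if feat.type == "gene":
                gid = name or f"gene_{rec.id}_{start}"
                open_genes.append((gid, start, end))
                features.append(Feature(rec.id, start, end, strand, "gene", gid))
            else:
                gid = name
                if gid is None or gid not in {g for g, _, _ in open_genes}:
                    # fall back to the enclosing gene span
                    for g, gs, ge in open_genes:
                        if gs <= start and end <= ge:
                            gid = g
                            break
                if gid is None:
                    raise ValueError(
                        f"{feat.type} at {rec.id}:{start}-{end} has no parent gene"
                    )
                features.append(Feature(rec.id, start, end, strand, feat.type, gid))
    return lengths, features, seqs


def load_genome(
    fasta_path: str | Path | None, annotation_path: str | Path
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Read sequences + annotation; coordinates normalized to 0-based half-open.

    Sequences are upper-cased with non-ACGT letters preserved (the spectrum
    counter skips windows containing them). GFF3 and GenBank feature tables
    are recognized by file suffix.
    """
    annotation_path = Path(annotation_path)
    suffix = annotation_path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        lengths, features, gb_seqs = _parse_genbank(annotation_path)
        seqs = _load_fasta(fasta_path) if fasta_path is not None else gb_seqs
        lengths = {c: len(s) for c, s in seqs.items()} or lengths
    else:
        if fasta_path is None:
            raise ValueError("GFF3 annotation requires a FASTA file")
        seqs = _load_fasta(fasta_path)
        lengths = {c: len(s) for c, s in seqs.items()}
        features = _parse_gff3(annotation_path)
    return GenomeAnnotation(chromosomes=lengths, features=features), seqs


# ---------------------------------------------------------------------------
# region derivation

def _merge_stranded(
    features: list[Feature],
) -> tuple[dict[str, list[Interval]], dict[str, list[str]]]:
    by_chrom: dict[str, list[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    intervals: dict[str, list[Interval]] = {}
    strands: dict[str, list[str]] = {}
    for chrom, feats in by_chrom.items():
        merged = merge_intervals([(f.start, f.end) for f in feats])
        st = []
        for s, e in merged:
            contrib = {f.strand for f in feats if f.start < e and f.end > s}
            st.append(contrib.pop() if len(contrib) == 1 else "+")
        intervals[chrom] = merged
        strands[chrom] = st
    return intervals, strands


def derive_regions(annotation: GenomeAnnotation) -> dict[str, RegionSet]:
    """Derive the five region classes from gene/exon/CDS features."""
    gene_feats = annotation.by_type("gene")
    exon_feats = annotation.by_type("exon")
    cds_feats = annotation.by_type("CDS")

    genic_iv, _ = _merge_stranded(gene_feats)
    exonic_iv, exonic_st = _merge_stranded(exon_feats)
    cds_iv, cds_st = _merge_stranded(cds_feats)

    all_exons_by_chrom: dict[str, list[Interval]] = {
        c: ivs for c, ivs in exonic_iv.items()
    }
    intronic_iv: dict[str, list[Interval]] = {}
    exons_by_gene: dict[str, list[Interval]] = {}
    for f in exon_feats:
        exons_by_gene.setdefault(f.gene_id, []).append((f.start, f.end))
    for chrom in annotation.chromosomes:
        pieces: list[Interval] = []
        for g in gene_feats:
            if g.chrom != chrom:
                continue
            pieces.extend(
                subtract_intervals([(g.start, g.end)], exons_by_gene.get(g.gene_id, []))
            )
        # a base intronic for one gene but exonic for another is exonic
        pieces = subtract_intervals(pieces, all_exons_by_chrom.get(chrom, []))
        if pieces:
            intronic_iv[chrom] = pieces

    intergenic_iv = {
        chrom: complement_intervals(genic_iv.get(chrom, []), L)
        for chrom, L in annotation.chromosomes.items()
    }
    intergenic_iv = {c: ivs for c, ivs in intergenic_iv.items() if ivs}

    return {
        "genic": RegionSet("genic", genic_iv),
        "exonic": RegionSet("exonic", exonic_iv, exonic_st),
        "CDS": RegionSet("CDS", cds_iv, cds_st),
        "intronic": RegionSet("intronic", intronic_iv),
        "intergenic": RegionSet("intergenic", intergenic_iv),
    }


def region_composition(
    regions: Mapping[str, RegionSet], genome_length: int
) -> pd.Series:
    """Percent of the genome covered by each region class."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    return pd.Series(
        {
            cls: 100.0 * regions[cls].total_length() / genome_length
            for cls in REGION_CLASSES
            if cls in regions
        },
        name="percent",
    )


def extract_sequences(
    regions: RegionSet,
    sequences: Mapping[str, str],
    orientation: str = "auto",
) -> list[str]:
    """One sequence per maximal interval.

    ``auto``: intronic/intergenic taken from the forward assembly strand,
    exonic/CDS in annotated gene orientation (reverse-complemented for
    minus-strand genes). ``forward`` forces the assembly strand; ``gene``
    forces gene orientation for every class.
    """
    if orientation not in ("auto", "forward", "gene"):
        raise ValueError(f"unknown orientation policy {orientation!r}")
    use_strand = orientation == "gene" or (
        orientation == "auto" and regions.region_class in ("exonic", "CDS")
    )
    out = []
    for chrom in sorted(regions.intervals):
        seq = sequences[chrom]
        for (s, e), strand in zip(regions.intervals[chrom], regions.strands[chrom]):
            piece = seq[s:e]
            if use_strand and strand == "-":
                piece = _revcomp_loose(piece)
            out.append(piece)
    return out


def _revcomp_loose(seq: str) -> str:
    """Reverse complement tolerating ambiguity letters (kept as N)."""
    try:
        return reverse_complement(seq)
    except ValueError:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        return "".join(comp.get(ch, "N") for ch in reversed(seq))


# ---------------------------------------------------------------------------
# export

def regions_to_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(regions.intervals):
            for i, ((s, e), strand) in enumerate(
                zip(regions.intervals[chrom], regions.strands[chrom])
            ):
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{regions.region_class}_{i}\t0\t{strand}\n"
                )


def annotation_to_gff3(
    annotation: GenomeAnnotation, path: str | Path, source: str = "kmerdecomp"
) -> None:
    """Emit gene/exon/CDS features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in annotation.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        counters: dict[str, int] = {}
        for f in sorted(
            annotation.features,
            key=lambda f: (f.chrom, f.start, 0 if f.ftype == "gene" else 1),
        ):
            if f.ftype == "gene":
                attrs = f"ID={f.gene_id}"
            else:
                counters[f.gene_id] = counters.get(f.gene_id, 0) + 1
                attrs = (
                    f"ID={f.gene_id}.{f.ftype}{counters[f.gene_id]};Parent={f.gene_id}"
                )
            fh.write(
                f"{f.chrom}\t{source}\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )
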