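"""Annotated synthetic genomes with plantable STR structure.

Background sequence comes from a first-order Markov model at a target G+C;
genes with exon/intron structure are placed without overlap; CDS content is
drawn codon-wise from a position-biased table (period-3 signal); tandem
repeat tracts are overwritten at sampled loci with optional strand symmetry
and per-position mismatch injection following a substitution preference
vector. Every planted tract and injected mismatch is recorded in a ground
truth object so tests can assert recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .kmers import BASES, reverse_complement
from .markov import MarkovModel, simulate_sequence
from .regions import Feature, GenomeAnnotation, annotation_to_gff3, derive_regions

_MIN_EXON = 60
_MIN_INTRON = 30


@dataclass(frozen=True)
class StrPlanting:
    """Planting spec for one STR family in one region class."""

    region_class: str  # intergenic | intronic | exonic | CDS | genic
    unit: str  # repeat unit, e.g. "A", "AT", "GT"
    tracts_per_mbp: float
    mean_repeats: float = 20.0  # geometric mean number of unit copies
    fixed_repeats: int | None = None  # overrides the distribution
    strand_symmetric: bool = False  # plant reverse complement for half the tracts
    mismatch_rate: float = 0.0  # per-base substitution probability
    mismatch_prefs: Mapping[str, float] | None = None  # pi over substituted bases

    def __post_init__(self) -> None:
        if self.tracts_per_mbp < 0 or self.mismatch_rate < 0:
            raise ValueError("rates must be >= 0")
        if not self.unit or any(b not in BASES for b in self.unit):
            raise ValueError(f"unit must be a nonempty ACGT string, got {self.unit!r}")
        if self.mismatch_prefs is not None:
            total = sum(self.mismatch_prefs.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.mismatch_prefs.values()):
                raise ValueError("mismatch_prefs must be a distribution over bases")


@dataclass
class SyntheticGenomeConfig:
    chromosome_lengths: list[int] = field(default_factory=lambda: [1_000_000])
    gc_content: float = 0.40
    markov_persistence: float = 0.02
    genes_per_mbp: float = 100.0
    mean_exons_per_gene: float = 3.0
    exon_length_mean: int = 200
    intron_length_mean: int = 400
    utr_length: int = 30
    codon_bias: float = 0.5  # 0 = no period-3 structure
    plantings: list[StrPlanting] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if any(l < 1000 for l in self.chromosome_lengths):
            raise ValueError("chromosomes must be >= 1 kb")
        if not 0 <= self.codon_bias <= 1:
            raise ValueError("codon_bias must be in [0, 1]")


@dataclass
class PlantedTract:
    chrom: str
    start: int
    end: int
    unit: str
    strand: str  # '+' planted as given, '-' planted as reverse complement
    mismatches: list[tuple[int, str, str]]  # (position, original, substituted)


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    truth: list[PlantedTract]
    config: SyntheticGenomeConfig

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        annotation_to_gff3(self.annotation, path)

    def write_truth_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.truth):
                fh.write(
                    f"{t.chrom}\t{t.start}\t{t.end}\t({t.unit})n_{i}\t0\t{t.strand}\n"
                )

    def write_truth_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([asdict(t) for t in self.truth], indent=1)
        )


# codon-position base profiles blended with the background distribution;
# chosen to give CDS a clear period-3 signal when codon_bias > 0
_CODON_PROFILE = np.array(
    [
        [0.32, 0.18, 0.34, 0.16],  # position 1: purine-leaning
        [0.34, 0.21, 0.15, 0.30],  # position 2
        [0.18, 0.30, 0.30, 0.22],  # position 3: G+C-leaning wobble
    ]
)


def _codon_position_probs(config: SyntheticGenomeConfig) -> np.ndarray:
    background = MarkovModel.order0(config.gc_content).base_probs
    beta = config.codon_bias
    probs = (1 - beta) * background[None, :] + beta * _CODON_PROFILE
    return probs / probs.sum(axis=1, keepdims=True)


def _geometric_at_least(rng: np.random.Generator, mean: float, minimum: int) -> int:
    """Geometric draw shifted to respect a minimum, keeping roughly the mean."""
    excess = max(mean - minimum, 1.0)
    return minimum + int(rng.geometric(1.0 / excess)) - 1


def _sample_gene_structure(
    rng: np.random.Generator, config: SyntheticGenomeConfig
) -> list[int]:
    """Alternating exon/intron lengths: [e1, i1, e2, i2, ..., en]."""
    n_exons = 1 + rng.poisson(max(config.mean_exons_per_gene - 1, 0))
    lengths = []
    for i in range(n_exons):
        lengths.append(_geometric_at_least(rng, config.exon_length_mean, _MIN_EXON))
        if i < n_exons - 1:
            lengths.append(
                _geometric_at_least(rng, config.intron_length_mean, _MIN_INTRON)
            )
    return lengths


def _place_genes(
    rng: np.random.Generator, chrom: str, length: int, config: SyntheticGenomeConfig
) -> list[Feature]:
    """Non-overlapping genes with exon/intron structure and UTR-trimmed CDS."""
    target = config.genes_per_mbp * length / 1e6
    if target <= 0:
        return []
    mean_gene = config.mean_exons_per_gene * config.exon_length_mean + max(
        config.mean_exons_per_gene - 1, 0
    ) * config.intron_length_mean
    mean_gap = max((length - target * mean_gene) / (target + 1), 50.0)
    features: list[Feature] = []
    pos = _geometric_at_least(rng, mean_gap, 1)
    gene_idx = 0
    while True:
        structure = _sample_gene_structure(rng, config)
        gene_len = sum(structure)
        if pos + gene_len > length:
            break
        gene_idx += 1
        gid = f"{chrom}_g{gene_idx}"
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = pos
        features.append(Feature(chrom, gstart, gstart + gene_len, strand, "gene", gid))
        cursor = gstart
        exon_bounds = []
        for j, seg in enumerate(structure):
            if j % 2 == 0:
                exon_bounds.append((cursor, cursor + seg))
            cursor += seg
        utr = min(config.utr_length, _MIN_EXON // 3)
        for j, (es, ee) in enumerate(exon_bounds):
            features.append(Feature(chrom, es, ee, strand, "exon", gid))
            cs, ce = es, ee
            first = j == 0 if strand == "+" else j == len(exon_bounds) - 1
            last = j == len(exon_bounds) - 1 if strand == "+" else j == 0
            if first:
                cs += utr
            if last:
                ce -= utr
            if cs < ce:
                features.append(Feature(chrom, cs, ce, strand, "CDS", gid))
        pos = gstart + gene_len + _geometric_at_least(rng, mean_gap, 1)
    return features


def _imprint_cds(
    seq: np.ndarray,
    features: list[Feature],
    rng: np.random.Generator,
    config: SyntheticGenomeConfig,
) -> None:
    """Overwrite CDS intervals with codon-sampled content in gene orientation."""
    if config.codon_bias == 0:
        return
    probs = _codon_position_probs(config)
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    by_gene: dict[str, list[Feature]] = {}
    for f in features:
        if f.ftype == "CDS":
            by_gene.setdefault(f.gene_id, []).append(f)
    for gid, cds in by_gene.items():
        cds = sorted(cds, key=lambda f: f.start)
        strand = cds[0].strand
        total = sum(f.end - f.start for f in cds)
        n_codons = total // 3 + 1
        draws = np.empty((n_codons, 3), dtype=np.int8)
        for p in range(3):
            draws[:, p] = rng.choice(4, size=n_codons, p=probs[p])
        codes = draws.reshape(-1)[:total]
        if strand == "-":
            # gene orientation reads right-to-left: write the reverse
            # complement of the codon stream onto the forward strand
            comp = np.array([3, 2, 1, 0], dtype=np.int8)
            codes = comp[codes][::-1]
        stream = base_arr[codes]
        offset = 0
        for f in cds:
            n = f.end - f.start
            seq[f.start : f.end] = stream[offset : offset + n]
            offset += n


def _plant_tracts(
    seq_by_chrom: dict[str, np.ndarray],
    annotation: GenomeAnnotation,
    rng: np.random.Generator,
    config: SyntheticGenomeConfig,
) -> list[PlantedTract]:
    if not config.plantings:
        return []
    regions = derive_regions(annotation)
    truth: list[PlantedTract] = []
    for spec in config.plantings:
        region = regions.get(spec.region_class)
        if region is None or region.total_length() == 0:
            raise ValueError(
                f"cannot plant into empty region class {spec.region_class!r}"
            )
        intervals = [
            (chrom, s, e)
            for chrom, ivs in region.intervals.items()
            for s, e in ivs
        ]
        lengths = np.array([e - s for _, s, e in intervals], dtype=float)
        total_len = lengths.sum()
        n_tracts = rng.poisson(spec.tracts_per_mbp * total_len / 1e6)
        mean_tract_bp = (
            spec.fixed_repeats if spec.fixed_repeats else spec.mean_repeats
        ) * len(spec.unit)
        if n_tracts * mean_tract_bp > 0.5 * total_len:
            raise ValueError(
                f"planting {spec.unit!r} in {spec.region_class}: requested tract "
                f"mass exceeds half the region capacity"
            )
        weights = lengths / total_len
        pref_bases = None
        pref_p = None
        if spec.mismatch_prefs:
            pref_bases = list(spec.mismatch_prefs)
            pref_p = np.array([spec.mismatch_prefs[b] for b in pref_bases])
        for _ in range(n_tracts):
            chrom, s, e = intervals[rng.choice(len(intervals), p=weights)]
            if spec.fixed_repeats:
                repeats = spec.fixed_repeats
            else:
                repeats = max(int(rng.geometric(1.0 / spec.mean_repeats)), 2)
            tract = spec.unit * repeats
            strand = "+"
            if spec.strand_symmetric and rng.random() < 0.5:
                tract = reverse_complement(tract)
                strand = "-"
            max_start = e - len(tract)
            if max_start <= s:
                continue  # tract longer than the interval: skip
            start = int(rng.integers(s, max_start))
            arr = np.frombuffer(tract.encode(), dtype=np.uint8).copy()
            mismatches: list[tuple[int, str, str]] = []
            if spec.mismatch_rate > 0:
                hits = np.nonzero(rng.random(len(arr)) < spec.mismatch_rate)[0]
                for pos in hits:
                    orig = chr(arr[pos])
                    if pref_bases is not None:
                        # condition the preference vector on != original
                        mask = np.array([b != orig for b in pref_bases], dtype=float)
                        p = pref_p * mask
                        if p.sum() == 0:
                            continue
                        sub = pref_bases[rng.choice(len(pref_bases), p=p / p.sum())]
                    else:
                        others = [b for b in BASES if b != orig]
                        sub = others[rng.integers(3)]
                    arr[pos] = ord(sub)
                    mismatches.append((int(start + pos), orig, sub))
            seq_by_chrom[chrom][start : start + len(arr)] = arr
            truth.append(
                PlantedTract(
                    chrom=chrom,
                    start=start,
                    end=start + len(arr),
                    unit=spec.unit,
                    strand=strand,
                    mismatches=mismatches,
                )
            )
    return truth


def generate_genome(config: SyntheticGenomeConfig) -> SyntheticGenome:
    """Deterministic synthetic genome: identical config+seed, identical bytes."""
    rng = np.random.default_rng(config.seed)
    model = MarkovModel.order1_gc(config.gc_content, config.markov_persistence)
    sequences_arr: dict[str, np.ndarray] = {}
    all_features: list[Feature] = []
    chromosomes: dict[str, int] = {}
    for ci, length in enumerate(config.chromosome_lengths):
        chrom = f"chr{ci + 1}"
        chromosomes[chrom] = length
        seq = simulate_sequence(model, length, rng)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        feats = _place_genes(rng, chrom, length, config)
        _imprint_cds(arr, feats, rng, config)
        sequences_arr[chrom] = arr
        all_features.extend(feats)
    annotation = GenomeAnnotation(chromosomes=chromosomes, features=all_features)
    truth = _plant_tracts(sequences_arr, annotation, rng, config)
    sequences = {c: a.tobytes().decode("ascii") for c, a in sequences_arr.items()}
    return SyntheticGenome(
        sequences=sequences, annotation=annotation, truth=truth, config=config
    )


def emulation_report(genome: SyntheticGenome) -> dict:
    """Verify realized G+C, region composition and mismatch base frequencies."""
    from .regions import region_composition  # local import to avoid cycle noise

    config = genome.config
    total_len = sum(len(s) for s in genome.sequences.values())
    gc = sum(s.count("G") + s.count("C") for s in genome.sequences.values())
    regions = derive_regions(genome.annotation)
    composition = region_composition(regions, total_len).to_dict()
    mismatch_freqs: dict[str, dict[str, float]] = {}
    for spec in config.plantings:
        subs = [
            m[2]
            for t in genome.truth
            if t.unit == spec.unit
            for m in t.mismatches
        ]
        if subs:
            mismatch_freqs[spec.unit] = {
                b: subs.count(b) / len(subs) for b in BASES
            }
    planted_bp = sum(t.end - t.start for t in genome.truth)
    return {
        "length": total_len,
        "gc_realized": gc / total_len,
        "gc_target": config.gc_content,
        "composition_percent": composition,
        "n_tracts": len(genome.truth),
        "planted_bp": planted_bp,
        "mismatch_base_frequencies": mismatch_freqs,
    }
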