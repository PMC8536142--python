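"""End-to-end orchestration: genomes -> regions -> spectra -> tables.

Every artifact is a TSV with a JSON sidecar; a manifest records the config
hash and seed so outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import decomposition as dc
from . import kmers, markov, patterns
from .regions import derive_regions, extract_sequences, load_genome, region_composition
from .synthetic import SyntheticGenomeConfig, StrPlanting, generate_genome

DEFAULT_REGION_CLASSES = ("intergenic", "intronic", "exonic", "CDS")


@dataclass
class RunConfig:
    genomes: list[tuple[str, str]] = field(default_factory=list)  # (fasta, annotation)
    synthetic: list[dict] = field(default_factory=list)  # SyntheticGenomeConfig kwargs
    ks: list[int] = field(default_factory=lambda: [7])
    region_classes: list[str] = field(default_factory=lambda: list(DEFAULT_REGION_CLASSES))
    ref_order: int = 1
    ref_length: int = 1_000_000
    ref_replicates: int = 5
    ref_gc: float | None = None  # default: mean realized G+C of the inputs
    ref_persistence: float = 0.02
    tol_strand: float = 0.25
    gc_bin_edges: list[float] = field(default_factory=lambda: [25.0, 50.0, 75.0, 100.0])
    seed: int = 0
    out_dir: str = "kmerdecomp_out"
    plots: bool = False

    def __post_init__(self) -> None:
        if any(not 1 <= k <= kmers.MAX_K for k in self.ks):
            raise ValueError(f"k values must be in 1..{kmers.MAX_K}")
        if not self.genomes and not self.synthetic:
            raise ValueError("config needs input genomes or synthetic configs")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_config_file(path: str | Path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    raw["genomes"] = [tuple(g) for g in raw.get("genomes", [])]
    return RunConfig(**raw)


def _synthetic_config(entry: dict, default_seed: int) -> SyntheticGenomeConfig:
    entry = dict(entry)
    plantings = [StrPlanting(**p) for p in entry.pop("plantings", [])]
    entry.setdefault("seed", default_seed)
    return SyntheticGenomeConfig(plantings=plantings, **entry)


def _write_table(df: pd.DataFrame, path: Path, meta: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"columns": list(df.columns), **meta}, indent=1))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, label: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {label!r}: {cause}")
        self.stage = stage
        self.label = label


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a result bundle (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"tables": {}, "genomes": []}

    # ---- genomes ---------------------------------------------------------
    genome_seqs: dict[str, dict[str, str]] = {}
    genome_regions: dict[str, dict] = {}
    names: list[str] = []
    for fasta, ann_path in config.genomes:
        name = Path(fasta).stem
        try:
            annotation, seqs = load_genome(fasta, ann_path)
        except Exception as exc:
            raise PipelineError("load_genome", name, exc) from exc
        names.append(name)
        genome_seqs[name] = seqs
        genome_regions[name] = derive_regions(annotation)
    for i, entry in enumerate(config.synthetic):
        name = entry.get("name") or f"synthetic{i + 1}"
        entry = {k: v for k, v in entry.items() if k != "name"}
        scfg = _synthetic_config(entry, config.seed + i)
        try:
            genome = generate_genome(scfg)
        except Exception as exc:
            raise PipelineError("generate_genome", name, exc) from exc
        names.append(name)
        genome_seqs[name] = genome.sequences
        genome_regions[name] = derive_regions(genome.annotation)
    bundle["genomes"] = names

    # ---- composition -----------------------------------------------------
    comp_rows = []
    for name in names:
        total = sum(len(s) for s in genome_seqs[name].values())
        comp = region_composition(genome_regions[name], total)
        comp_rows.append({"genome": name, **comp.to_dict()})
    comp_df = pd.DataFrame(comp_rows)
    _write_table(comp_df, out / "region_composition.tsv", {"table": "composition"})
    bundle["tables"]["region_composition"] = comp_df

    # ---- spectra ---------------------------------------------------------
    spectra: dict[tuple[str, str, int], kmers.Spectrum] = {}
    mean_gc = []
    for name in names:
        seqs = genome_seqs[name]
        joined = "".join(seqs.values())
        acgt = sum(joined.count(b) for b in "ACGT")
        gc = (joined.count("G") + joined.count("C")) / max(acgt, 1)
        mean_gc.append(gc)
        for cls in config.region_classes:
            region = genome_regions[name][cls]
            pieces = extract_sequences(region, seqs)
            for k in config.ks:
                try:
                    spectra[(name, cls, k)] = kmers.compute_spectrum(
                        pieces, k, label=f"{name}:{cls}"
                    )
                except Exception as exc:
                    raise PipelineError("spectrum", f"{name}:{cls}:k={k}", exc) from exc

    # ---- reference ensembles --------------------------------------------
    ref_gc = config.ref_gc if config.ref_gc is not None else float(np.mean(mean_gc))
    if config.ref_order == 0:
        model = markov.MarkovModel.order0(ref_gc)
    else:
        model = markov.MarkovModel.order1_gc(ref_gc, config.ref_persistence)
    ensembles = {
        k: markov.build_reference_ensemble(
            model, k, config.ref_length, config.ref_replicates, seed=config.seed
        )
        for k in config.ks
    }

    region_pairs = [
        (c1, c2)
        for i, c1 in enumerate(config.region_classes)
        for c2 in config.region_classes[i:]
    ]

    # ---- correlation matrices + mean correlation table -------------------
    mean_rows = []
    for k in config.ks:
        ref_mean, ref_sd, _ = ensembles[k].pairwise_statistic(
            lambda a, b: dc.pearson_correlation(a, b).r
        )
        for c1, c2 in region_pairs:
            mat = np.full((len(names), len(names)), np.nan)
            vals = []
            for i, gi in enumerate(names):
                for j, gj in enumerate(names):
                    if c1 == c2 and j < i:
                        mat[i, j] = mat[j, i]
                        continue
                    try:
                        r = dc.pearson_correlation(
                            spectra[(gi, c1, k)], spectra[(gj, c2, k)]
                        ).r
                    except ValueError:
                        r = np.nan
                    mat[i, j] = r
                    if not (c1 == c2 and i == j) and np.isfinite(r):
                        vals.append(r)
            mat_df = pd.DataFrame(mat, index=names, columns=names)
            fname = f"correlations_k{k}_{c1}_{c2}.tsv"
            mat_df.to_csv(out / fname, sep="\t")
            bundle["tables"][f"correlations_k{k}_{c1}_{c2}"] = mat_df
            if vals:
                mc = dc.mean_correlation_with_reference(
                    vals, [ref_mean], group=f"{c1}-{c2}"
                )
                mean_rows.append(
                    {
                        "k": k,
                        "pair": f"{c1}-{c2}",
                        "mean_r": mc.mean_real,
                        "sd_r": mc.sd_real,
                        "reference_r": ref_mean,
                        "reference_sd": ref_sd,
                        "difference": mc.mean_real - ref_mean,
                        "error": float(np.hypot(mc.sd_real, ref_sd)),
                    }
                )
            if config.plots:
                _plot_heatmap(mat_df, out / f"heatmap_k{k}_{c1}_{c2}.png", f"{c1}-{c2} k={k}")
    mean_df = pd.DataFrame(mean_rows)
    _write_table(mean_df, out / "mean_correlation.tsv", {"table": "mean_correlation"})
    bundle["tables"]["mean_correlation"] = mean_df

    # ---- contributions ---------------------------------------------------
    genome_pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]]
    for k in config.ks:
        if k < 3:
            continue
        b_sets = [kmers.enumerate_str_words(k, b) for b in (1, 2, 3)]
        families = kmers.word_family_sets(k)
        fam_sets = [families[n] for n in (
            "polyW", "polyS", "homoW", "homoS", "homoR", "homoY", "homoK", "homoM"
        )]
        gc_sets = kmers.gc_bin_sets(k, config.gc_bin_edges)
        str16 = sorted(kmers.str_words_b_le2(k).words)

        contrib_rows, fam_rows, gc_rows, word_rows = [], [], [], []
        fam_word_values: dict[str, dict[str, list[float]]] = {}
        for c1, c2 in region_pairs:
            per_pair_b, per_pair_fam, per_pair_gc = [], [], []
            word_acc: dict[str, list] = {w: [] for w in str16}
            for gi, gj in genome_pairs:
                x, y = spectra[(gi, c1, k)], spectra[(gj, c2, k)]
                try:
                    per_pair_b.append(
                        dc.grouped_contributions(x, y, b_sets, add_remainder=True)
                    )
                    per_pair_fam.append(dc.grouped_contributions(x, y, fam_sets))
                    per_pair_gc.append(dc.grouped_contributions(x, y, gc_sets))
                    ratio = dc.contribution_ratio_table(x, y, str16)
                except ValueError:
                    continue
                for _, row in ratio.iterrows():
                    word_acc[row["word"]].append((row["c0"], row["c1"], row["rank"]))
            if not per_pair_b:
                continue
            for dfs, rows, label in (
                (per_pair_b, contrib_rows, "b"),
                (per_pair_fam, fam_rows, "family"),
                (per_pair_gc, gc_rows, "gc"),
            ):
                merged = pd.concat(dfs).groupby("set", sort=False)["contribution"].mean()
                for set_name, val in merged.items():
                    rows.append(
                        {"k": k, "pair": f"{c1}-{c2}", "set": set_name, "contribution": val}
                    )
            pair_label = f"{c1}-{c2}"
            fam_word_values[pair_label] = {}
            for w, acc in word_acc.items():
                if not acc:
                    continue
                c0 = float(np.mean([a[0] for a in acc]))
                c1v = float(np.mean([a[1] for a in acc]))
                word_rows.append(
                    {
                        "k": k,
                        "pair": pair_label,
                        "word": w,
                        "c0": c0,
                        "c1": c1v,
                        "ratio": c1v / c0 if c0 != 0 else np.nan,
                        "mean_rank": float(np.mean([a[2] for a in acc])),
                    }
                )
                fam_word_values[pair_label][w] = c0

        for rows, fname in (
            (contrib_rows, f"contrib_b_k{k}.tsv"),
            (fam_rows, f"contrib_families_k{k}.tsv"),
            (gc_rows, f"contrib_gc_k{k}.tsv"),
            (word_rows, f"str_words_k{k}.tsv"),
        ):
            df = pd.DataFrame(rows)
            _write_table(df, out / fname, {"table": fname.rsplit(".", 1)[0], "k": k})
            bundle["tables"][fname.rsplit(".", 1)[0]] = df

        # ---- strand-pattern calls (per family, IIR-style pairs) ---------
        call_rows = []
        for pair_label, values in fam_word_values.items():
            for fam_name in ("polyW", "polyS", "homoW", "homoS", "homoR", "homoY", "homoK", "homoM"):
                rep = sorted(families[fam_name].words)[0]
                try:
                    call = patterns.classify_strand_pattern(
                        values, rep, tol=config.tol_strand
                    )
                except ValueError:
                    continue
                call_rows.append(
                    {
                        "k": k,
                        "pair": pair_label,
                        "family": fam_name,
                        "word": rep,
                        "call": call.call,
                        "tol": config.tol_strand,
                    }
                )
        call_df = pd.DataFrame(call_rows)
        _write_table(call_df, out / f"strand_patterns_k{k}.tsv", {"table": "strand_patterns", "k": k})
        bundle["tables"][f"strand_patterns_k{k}"] = call_df

        # ---- deviation profiles over pooled non-coding spectra ----------
        dev_rows = []
        profiles = []
        iir_classes = [c for c in ("intronic", "intergenic") if c in config.region_classes]
        for w in str16:
            pcts_acc: dict[str, list[float]] = {}
            for name in names:
                pooled_counts = None
                total = 0.0
                for cls in iir_classes:
                    sp = spectra[(name, cls, k)]
                    pooled_counts = (
                        sp.counts.copy() if pooled_counts is None else pooled_counts + sp.counts
                    )
                    total += sp.total_windows
                if pooled_counts is None:
                    continue
                pooled = kmers.Spectrum(k, pooled_counts, total, label=f"{name}:IIR")
                prof = patterns.deviation_profile(pooled, w)
                if prof.empty:
                    continue
                for base, pct in prof.percentages.items():
                    pcts_acc.setdefault(base, []).append(pct)
            if not pcts_acc:
                continue
            mean_counts = {b: float(np.mean(v)) for b, v in pcts_acc.items()}
            prof = patterns.DeviationProfile(word=w, counts=mean_counts)
            profiles.append(prof)
            flags = patterns.classify_ambiguity(prof)
            row = {"k": k, "word": w, "ambiguous": flags.ambiguous,
                   "strong_tendency": flags.strong_tendency}
            row.update({f"pct_{b}": p for b, p in prof.percentages.items()})
            dev_rows.append(row)
        dev_df = pd.DataFrame(dev_rows)
        _write_table(dev_df, out / f"deviations_k{k}.tsv", {"table": "deviations", "k": k})
        bundle["tables"][f"deviations_k{k}"] = dev_df
        if profiles:
            cov = patterns.rule_coverage(profiles)
            cov_payload = {
                "n": cov.n,
                "covered": cov.covered,
                "ambiguous": cov.ambiguous,
                "uncovered": cov.uncovered,
                "details": [
                    {**d, "observed": list(d["observed"]), "expected": list(d["expected"])}
                    for d in cov.details
                ],
            }
            (out / f"rule_coverage_k{k}.json").write_text(json.dumps(cov_payload, indent=1))
            bundle["tables"][f"rule_coverage_k{k}"] = cov_payload

    # ---- manifest --------------------------------------------------------
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "genomes": names,
        "ks": config.ks,
        "ref_gc": ref_gc,
        "files": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle


def _plot_heatmap(df: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    # color scale floored at -0.4 for readability
    im = ax.imshow(df.values, vmin=-0.4, vmax=1.0, cmap="RdYlBu_r")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
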