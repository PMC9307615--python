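"""End-to-end orchestration: ingest -> annotate -> merge -> Ka/Ks ->
null tests -> noncoding summaries -> sample metrics, with a single JSON+TSV
report bundle and seeds recorded for every stochastic step."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .concordance import merge_replicates, shared_positions, shared_variants, write_merged_tsv
from .effect_annotator import read_vcf, write_annotated_tsv
from .genome_model import AnnotatedGenome, DepthTrack, breadth_of_coverage, read_genome
from .kaks_analysis import (
    format_ratio,
    genome_wide_kaks,
    per_gene_kaks,
    select_genes_of_interest,
    write_genome_kaks_tsv,
    write_per_gene_tsv,
)
from .noncoding_analysis import (
    distance_distribution,
    noncoding_summary,
    substitution_spectrum,
    window_scan,
    write_spectrum_tsv,
    write_windows_bed,
)
from .null_models import (
    NullTestResult,
    benjamini_hochberg,
    continuum_randomization,
    global_positions,
    pascal_probability,
    two_sample_t,
)
from .synthetic_data import read_classification_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_fasta: str
    genome_gff3: str
    # condition -> replicate id -> vcf path
    vcfs: dict[str, dict[str, str]]
    # condition -> replicate id -> depth TSV path
    depth_tracks: dict[str, dict[str, str]] = field(default_factory=dict)
    classification_tsv: Optional[str] = None
    out_dir: str = "scvartools_out"
    min_support: int = 2
    min_depth: int = 1
    kaks_upper: float = 1.0
    kaks_syn_dense: float = 0.2
    min_conditions: int = 2
    iterations: int = 100_000
    seed: int = 0
    target_genus: str = "Nostoc"
    distance_threshold_bp: int = 10_000
    window_bp: int = 35_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.genome_fasta, self.genome_gff3, self.classification_tsv]
            + [p for reps in self.vcfs.values() for p in reps.values()]
            + [p for reps in self.depth_tracks.values() for p in reps.values()]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        for cond, reps in self.vcfs.items():
            if not reps:
                raise ValueError(f"condition {cond!r} has no replicates")


@dataclass
class SampleMetrics:
    sample_id: str
    purity: float  # target-genus read fraction; nan if no classified reads
    genome_coverage: float
    n_reads: int


def compute_sample_metrics(
    classification_rows: Sequence[tuple[str, str, int]],
    tracks_by_sample: dict[str, DepthTrack],
    genome: AnnotatedGenome,
    target_genus: str,
    min_depth: int = 1,
) -> list[SampleMetrics]:
    """Purity (fraction of classified reads assigned to the target genus)
    and whole-genome breadth of coverage per sample."""
    totals: dict[str, int] = {}
    target: dict[str, int] = {}
    for sample, taxon, count in classification_rows:
        totals[sample] = totals.get(sample, 0) + count
        if taxon == target_genus:
            target[sample] = target.get(sample, 0) + count
    out = []
    for sample in totals:
        n = totals[sample]
        purity = target.get(sample, 0) / n if n > 0 else math.nan
        if n == 0:
            logger.warning("sample %s has zero classified reads; purity undefined", sample)
        track = tracks_by_sample.get(sample)
        if track is None:
            cov = math.nan
        else:
            covered = sum(
                breadth_of_coverage(track, cid, 0, len(seq), min_depth) * len(seq)
                for cid, seq in genome.contigs.items()
            )
            cov = covered / genome.total_length
        out.append(SampleMetrics(sample, purity, cov, n))
    return out


def group_comparisons(
    metrics: Sequence[SampleMetrics],
    groups: dict[str, Sequence[str]],
    value: str = "purity",
) -> list[dict]:
    """Pairwise pooled-variance t tests between named sample groups."""
    by_id = {m.sample_id: m for m in metrics}
    rows = []
    for (ga, ids_a), (gb, ids_b) in combinations(groups.items(), 2):
        va = [getattr(by_id[s], value) for s in ids_a if s in by_id]
        vb = [getattr(by_id[s], value) for s in ids_b if s in by_id]
        va = [x for x in va if not math.isnan(x)]
        vb = [x for x in vb if not math.isnan(x)]
        if len(va) < 2 or len(vb) < 2:
            logger.warning("skipping %s vs %s: need >=2 samples per group", ga, gb)
            continue
        t, df, p = two_sample_t(va, vb)
        rows.append(
            {
                "group_a": ga, "group_b": gb, "value": value,
                "mean_a": sum(va) / len(va), "mean_b": sum(vb) / len(vb),
                "n_a": len(va), "n_b": len(vb), "t": t, "df": df, "p": p,
            }
        )
    return rows


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("scvartools")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report: dict = {"version": __version__, "parameters": {
        "min_support": config.min_support, "min_depth": config.min_depth,
        "kaks_upper": config.kaks_upper, "kaks_syn_dense": config.kaks_syn_dense,
        "min_conditions": config.min_conditions, "iterations": config.iterations,
        "seed": config.seed,
    }}
    try:
        stage = "ingest"
        genome = read_genome(config.genome_fasta, config.genome_gff3)
        report["genome"] = {
            "contigs": len(genome.contigs),
            "total_length": genome.total_length,
            "genes": len(genome.genes),
        }

        stage = "merge"
        merged = {}
        replicate_counts = {}
        for cond, reps in config.vcfs.items():
            rep_sets = [read_vcf(path, condition=cond, replicate=rep)
                        for rep, path in reps.items()]
            replicate_counts[cond] = {rep: len(s) for rep, s in
                                      zip(reps, rep_sets)}
            merged[cond] = merge_replicates(rep_sets, condition=cond,
                                            min_support=config.min_support)

        stage = "annotate"
        for cond, mset in merged.items():
            mset.annotate(genome)
            write_merged_tsv(mset, out / f"merged_{cond.replace('/', '_')}.tsv")
            write_annotated_tsv(mset.annotated(),
                                out / f"annotated_{cond.replace('/', '_')}.tsv")
        report["merged_counts"] = {c: len(m) for c, m in merged.items()}
        report["replicate_counts"] = replicate_counts
        report["effect_counts"] = {
            c: {
                e: sum(1 for a in m.annotations.values() if a.effect == e)
                for e in ("synonymous", "non_synonymous", "intragenic_noncoding",
                          "intergenic", "multi_bp", "unknown")
            }
            for c, m in merged.items()
        }

        stage = "kaks"
        tracks = {
            cond: [DepthTrack.from_tsv(p, rep) for rep, p in reps.items()]
            for cond, reps in config.depth_tracks.items()
        }
        genome_rows = [genome_wide_kaks(m) for m in merged.values()]
        write_genome_kaks_tsv(genome_rows, out / "genome_kaks.tsv")
        report["genome_kaks"] = {
            r.condition: {"ka": r.ka_total, "ks": r.ks_total,
                          "ratio": None if math.isnan(r.ratio) else round(r.ratio, 4)}
            for r in genome_rows
        }
        per_gene = {}
        excluded = {}
        for cond, mset in merged.items():
            res, excl = per_gene_kaks(genome, mset, tracks.get(cond),
                                      min_depth=config.min_depth)
            per_gene[cond] = res
            excluded[cond] = excl
        write_per_gene_tsv(per_gene, genome, out / "per_gene_kaks.tsv")
        goi = select_genes_of_interest(
            per_gene, upper=config.kaks_upper, syn_dense=config.kaks_syn_dense,
            min_conditions=config.min_conditions,
        )
        report["genes_of_interest"] = [
            {"gene_id": g.gene_id, "direction": g.direction,
             "n_conditions": g.n_conditions, "total_variants": g.total_variants,
             "ratios": {c: format_ratio(r) for c, r in g.ratios.items()}}
            for g in goi
        ]
        with open(out / "genes_of_interest.json", "w") as fh:
            json.dump(report["genes_of_interest"], fh, indent=1)

        stage = "null_tests"
        observed = {c: global_positions(genome, m.variants) for c, m in merged.items()}
        null_result = continuum_randomization(
            genome, observed, iterations=config.iterations, seed=config.seed,
        )
        report["continuum_randomization"] = null_result.to_dict()
        with open(out / "null_test.json", "w") as fh:
            json.dump(null_result.to_dict(), fh, indent=1)
        gene_by_id = {g.gene_id: g for g in genome.genes}
        pascal_rows = []
        for g in goi:
            gene = gene_by_id[g.gene_id]
            shared = _shared_variant_count(merged, gene)
            if shared > 0:
                pascal_rows.append(
                    {"gene_id": g.gene_id, "length_bp": gene.length,
                     "shared_variants": shared,
                     "p": pascal_probability(gene.length, shared)}
                )
        qvals = benjamini_hochberg([r["p"] for r in pascal_rows])
        for row, q in zip(pascal_rows, qvals):
            row["q_bh"] = q
        report["pascal_probabilities"] = pascal_rows

        stage = "noncoding"
        summaries, sharing = noncoding_summary(merged, genome)
        report["noncoding"] = {
            s.condition: {"intragenic_noncoding": s.intragenic_noncoding,
                          "intergenic": s.intergenic}
            for s in summaries
        }
        report["noncoding_sharing"] = {
            f"{a}|{b}": v for (a, b), v in sharing.items()
        }
        spectra = []
        distance_report = {}
        for cond, mset in merged.items():
            anns = mset.annotated()
            spectra.append(substitution_spectrum(anns, condition=cond))
            inter = [a for a in anns if a.effect == "intergenic"]
            dd = distance_distribution(inter, genome, config.distance_threshold_bp)
            distance_report[cond] = {
                "n": dd.n, "n_within": dd.n_within,
                "fraction_within": None if math.isnan(dd.fraction_within)
                else dd.fraction_within,
                "max_distance": dd.max_distance,
            }
        write_spectrum_tsv(spectra, out / "spectrum.tsv")
        report["distance_to_gene"] = distance_report
        report["spectrum"] = {
            t.condition: {"gc_increase": t.gc_increase, "gc_decrease": t.gc_decrease,
                          "gc_neutral": t.gc_neutral, "mnv": t.mnv_count}
            for t in spectra
        }
        hits = window_scan(merged, genome, window_bp=config.window_bp)
        write_windows_bed(hits, out / "hotspot_windows.bed")

        stage = "metrics"
        if config.classification_tsv:
            rows = read_classification_tsv(config.classification_tsv)
            tracks_by_sample = {}
            for cond, reps in config.depth_tracks.items():
                for rep, path in reps.items():
                    sample = f"{cond.replace('/', '_')}_{rep}"
                    tracks_by_sample[sample] = DepthTrack.from_tsv(path, sample)
            metrics = compute_sample_metrics(rows, tracks_by_sample, genome,
                                             config.target_genus, config.min_depth)
            report["sample_metrics"] = [
                {"sample_id": m.sample_id,
                 "purity": None if math.isnan(m.purity) else m.purity,
                 "genome_coverage": None if math.isnan(m.genome_coverage)
                 else m.genome_coverage,
                 "n_reads": m.n_reads}
                for m in metrics
            ]
            groups = {}
            for cond in config.vcfs:
                prefix = cond.replace("/", "_") + "_"
                groups[cond] = [m.sample_id for m in metrics
                                if m.sample_id.startswith(prefix)]
            report["purity_comparisons"] = group_comparisons(metrics, groups, "purity")
            report["coverage_comparisons"] = group_comparisons(
                metrics, groups, "genome_coverage")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _shared_variant_count(merged: dict, gene) -> int:
    """Positions in ``gene`` carrying the same variant in >=2 conditions."""
    from collections import Counter

    counter: Counter = Counter()
    for mset in merged.values():
        for (contig, pos, ref, alt) in mset.variants:
            if contig == gene.contig and gene.contains(pos):
                counter[(contig, pos, ref, alt)] += 1
    return sum(1 for v in counter.values() if v >= 2)
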