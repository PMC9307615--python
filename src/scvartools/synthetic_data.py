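"""Synthetic input generator.

Produces a complete, self-consistent input bundle — multi-contig genome
with stop-free CDS on both strands, per-replicate VCFs with planted
hotspot variants and replicate-unique singleton noise, partial depth
tracks, and a read-classification table — together with the ground truth
needed to score parameter recovery. Identical config (including seed)
yields byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .effect_annotator import VariantCall, classify
from .genome_model import (
    AnnotatedGenome,
    DepthTrack,
    GeneRecord,
    revcomp,
    translate_codon,
    write_fasta,
    write_gff3,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

#: Transition-enriched default substitution spectrum.
DEFAULT_SPECTRUM = {
    "A>G": 6.0, "T>C": 6.0, "C>T": 6.0, "G>A": 6.0,
    "A>C": 1.0, "A>T": 1.0, "C>A": 1.0, "C>G": 1.0,
    "G>C": 1.0, "G>T": 1.0, "T>A": 1.0, "T>G": 1.0,
}

DEFAULT_CONDITIONS = ("Ground_UV", "ISS_UV", "ISS_Dark")


class InfeasibleConfigError(ValueError):
    """Raised when a configuration cannot be satisfied."""


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000
    n_genes: int = 40
    mean_gene_length: int = 900
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 4
    hotspot_genes: int = 5
    hotspot_variants_per_gene: int = 8
    hotspot_nonsyn_fraction: float = 0.1
    shared_across_conditions: float = 1.0
    singleton_noise_rate: float = 50.0  # variants / Mb / replicate
    replicate_detection_prob: float = 0.9
    breadth_mean: float = 0.85
    spectrum_weights: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    mnv_rate: float = 0.05
    contamination_fraction: float = 0.2
    target_genus: str = "Nostoc"
    n_rrna_genes: int = 2
    min_intergenic_gap: int = 50

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        for name in (
            "hotspot_nonsyn_fraction", "shared_across_conditions",
            "replicate_detection_prob", "breadth_mean", "mnv_rate",
            "contamination_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in (
            "n_contigs", "contig_length", "n_genes", "mean_gene_length",
            "replicates_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hotspot_genes < 0 or self.hotspot_variants_per_gene < 0:
            raise ValueError("hotspot counts must be non-negative")
        if self.singleton_noise_rate < 0:
            raise ValueError("singleton_noise_rate must be non-negative")
        if self.hotspot_genes > self.n_genes:
            raise InfeasibleConfigError("more hotspot genes than genes")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    hotspot_gene_ids: list[str]
    # condition -> list of truth variant dicts (contig, pos, ref, alt, effect, gene_id)
    truth_by_condition: dict[str, list[dict]]
    # condition -> replicate -> list of emitted truth keys [contig, pos, ref, alt]
    detected: dict[str, dict[str, list[list]]]
    # condition -> replicate -> list of noise keys
    noise: dict[str, dict[str, list[list]]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimResult:
    config: SimConfig
    genome: AnnotatedGenome
    # condition -> replicate id -> list of VariantCall
    calls: dict[str, dict[str, list[VariantCall]]]
    # condition -> replicate id -> DepthTrack
    tracks: dict[str, dict[str, DepthTrack]]
    # rows of (sample_id, taxon, read_count)
    classification: list[tuple[str, str, int]]
    truth: GroundTruth
    out_dir: Optional[Path] = None


def _safe(name: str) -> str:
    return name.replace("/", "_").replace(" ", "_")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + stop."""
    sense = [c for c in ("".join(t) for t in itertools.product(_BASES, repeat=3))
             if c not in _STOPS]
    middle = rng.choice(len(sense), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(sense[i] for i in middle) + stop


def build_genome(config: SimConfig, rng: np.random.Generator) -> AnnotatedGenome:
    """Random multi-contig genome with non-overlapping genes on both strands,
    every CDS in frame and stop-free internally."""
    contigs: dict[str, str] = {}
    seqs: dict[str, np.ndarray] = {}
    for i in range(config.n_contigs):
        cid = f"contig_{i + 1}"
        seqs[cid] = rng.integers(0, 4, size=config.contig_length)

    total_genes = config.n_genes + config.n_rrna_genes
    per_contig = [total_genes // config.n_contigs] * config.n_contigs
    for i in range(total_genes % config.n_contigs):
        per_contig[i] += 1

    all_kinds = ["CDS"] * config.n_genes + ["rRNA"] * config.n_rrna_genes
    order = rng.permutation(total_genes)
    all_kinds = [all_kinds[i] for i in order]

    genes: list[GeneRecord] = []
    gi = 0
    cids = list(seqs)
    base_lookup = np.array(list(_BASES))
    kind_iter = iter(all_kinds)
    for ci, cid in enumerate(cids):
        cursor = config.min_intergenic_gap
        arr = seqs[cid]
        kinds = [next(kind_iter) for _ in range(per_contig[ci])]
        for kind in kinds:
            n_codons = max(30, int(round(rng.normal(config.mean_gene_length / 3,
                                                    config.mean_gene_length / 9))))
            length = 3 * n_codons if kind == "CDS" else int(rng.integers(120, 1600))
            gap = config.min_intergenic_gap + int(rng.geometric(1 / 200.0))
            start = cursor + gap
            end = start + length
            if end + config.min_intergenic_gap > len(arr):
                raise InfeasibleConfigError(
                    f"cannot place {total_genes} genes of mean length "
                    f"{config.mean_gene_length} on contigs of length {config.contig_length}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            if kind == "CDS":
                cds = _random_cds(rng, n_codons)
                ins = cds if strand == "+" else revcomp(cds)
                arr[start:end] = [_BASES.index(b) for b in ins]
                product = f"hypothetical protein {gi}"
            else:
                product = "ribosomal RNA"
            genes.append(GeneRecord(f"gene_{gi:04d}", cid, start, end, strand, kind, product))
            cursor = end
    for cid in cids:
        contigs[cid] = "".join(base_lookup[seqs[cid]])
    genome = AnnotatedGenome(contigs, genes)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, options: Sequence, weights: Sequence[float]):
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(options))
    return options[rng.choice(len(options), p=w / w.sum())]


def _site_mutation(
    genome: AnnotatedGenome,
    gene: GeneRecord,
    rng: np.random.Generator,
    want_synonymous: bool,
    spectrum: dict,
    taken: set[int],
) -> VariantCall:
    seq = genome.contigs[gene.contig]
    positions = np.array([p for p in range(gene.start, gene.end) if p not in taken])
    rng.shuffle(positions)
    for pos in (int(p) for p in positions):
        codon, off, aa = genome.codon_context(gene, pos)
        if len(codon) < 3 or any(b not in _BASES for b in codon):
            continue
        feasible = []
        weights = []
        for b in _BASES:
            if b == codon[off]:
                continue
            alt_aa = translate_codon(codon[:off] + b + codon[off + 1 :])
            if (alt_aa == aa) != want_synonymous:
                continue
            alt_genomic = b if gene.strand == "+" else revcomp(b)
            feasible.append(alt_genomic)
            weights.append(spectrum.get(f"{seq[pos]}>{alt_genomic}", 1.0))
        if feasible:
            alt = _weighted_choice(rng, feasible, weights)
            return VariantCall(gene.contig, pos, seq[pos], alt)
    kind = "synonymous" if want_synonymous else "non-synonymous"
    raise InfeasibleConfigError(
        f"gene {gene.gene_id} has no untaken position with a {kind} substitution"
    )


def synonymous_site_mutation(
    genome: AnnotatedGenome, gene: GeneRecord, rng: np.random.Generator,
    spectrum: Optional[dict] = None, taken: Optional[set[int]] = None,
) -> VariantCall:
    """An SNV in ``gene`` verified synonymous by codon comparison."""
    return _site_mutation(genome, gene, rng, True, spectrum or DEFAULT_SPECTRUM,
                          taken if taken is not None else set())


def nonsynonymous_site_mutation(
    genome: AnnotatedGenome, gene: GeneRecord, rng: np.random.Generator,
    spectrum: Optional[dict] = None, taken: Optional[set[int]] = None,
) -> VariantCall:
    """An SNV in ``gene`` verified non-synonymous by codon comparison."""
    return _site_mutation(genome, gene, rng, False, spectrum or DEFAULT_SPECTRUM,
                          taken if taken is not None else set())


def _noise_variant(
    genome: AnnotatedGenome,
    rng: np.random.Generator,
    config: SimConfig,
    used_keys: set,
) -> VariantCall:
    """A replicate-unique noise substitution (SNV, or adjacent 2-bp MNV
    with probability mnv_rate); keys never collide with ``used_keys``."""
    cids = genome.contig_order
    lengths = np.array([len(genome.contigs[c]) for c in cids], dtype=float)
    for _ in range(10_000):
        cid = cids[rng.choice(len(cids), p=lengths / lengths.sum())]
        seq = genome.contigs[cid]
        is_mnv = rng.random() < config.mnv_rate
        width = 2 if is_mnv else 1
        pos = int(rng.integers(0, len(seq) - width))
        ref = seq[pos : pos + width]
        if any(b not in _BASES for b in ref):
            continue
        alt = "".join(
            _weighted_choice(
                rng,
                [b for b in _BASES if b != r],
                [config.spectrum_weights.get(f"{r}>{b}", 1.0) for b in _BASES if b != r],
            )
            for r in ref
        )
        key = (cid, pos, ref, alt)
        if key in used_keys:
            continue
        used_keys.add(key)
        return VariantCall(cid, pos, ref, alt)
    raise InfeasibleConfigError("could not place a unique noise variant")


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

def _depth_track(
    genome: AnnotatedGenome,
    rng: np.random.Generator,
    breadth_mean: float,
    replicate_id: str,
    force_covered: Sequence[tuple[str, int]] = (),
) -> DepthTrack:
    """Alternating covered/uncovered geometric runs with overall breadth
    ~ breadth_mean; positions in ``force_covered`` are covered regardless."""
    mean_cov_run = 3000.0
    runs: dict[str, np.ndarray] = {}
    forced: dict[str, list[int]] = {}
    for cid, pos in force_covered:
        forced.setdefault(cid, []).append(pos)
    for cid, seq in genome.contigs.items():
        n = len(seq)
        mask = np.zeros(n, dtype=bool)
        if breadth_mean >= 1.0:
            mask[:] = True
        elif breadth_mean > 0.0:
            mean_gap_run = mean_cov_run * (1 - breadth_mean) / breadth_mean
            cursor = 0
            covered = rng.random() < breadth_mean
            while cursor < n:
                run = int(rng.geometric(1 / (mean_cov_run if covered else mean_gap_run)))
                if covered:
                    mask[cursor : cursor + run] = True
                cursor += run
                covered = not covered
        for pos in forced.get(cid, []):
            mask[pos : pos + 2] = True
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        if len(starts):
            depth = rng.integers(5, 30, size=len(starts))
            runs[cid] = np.column_stack([starts, ends, depth]).astype(np.int64)
        else:
            runs[cid] = np.zeros((0, 3), dtype=np.int64)
    return DepthTrack(replicate_id, runs)


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, out_dir=None) -> SimResult:
    """Generate the full synthetic input bundle (optionally written to disk)."""
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config, rng)
    cds_genes = [g for g in genome.genes if g.kind == "CDS"]
    if config.hotspot_genes > len(cds_genes):
        raise InfeasibleConfigError("more hotspot genes than CDS genes")
    if config.hotspot_variants_per_gene > min((g.length for g in cds_genes), default=0):
        raise InfeasibleConfigError("more hotspot variants than gene positions")

    hot_idx = rng.choice(len(cds_genes), size=config.hotspot_genes, replace=False)
    hotspot = [cds_genes[i] for i in sorted(hot_idx)]

    used_keys: set = set()
    truth_by_condition: dict[str, list[dict]] = {c: [] for c in config.conditions}
    for gene in hotspot:
        taken: set[int] = set()
        for _ in range(config.hotspot_variants_per_gene):
            want_syn = rng.random() >= config.hotspot_nonsyn_fraction
            v = _site_mutation(genome, gene, rng, want_syn, config.spectrum_weights, taken)
            taken.add(v.pos)
            used_keys.add(v.key)
            ann = classify(genome, v)  # label honesty check at generation time
            expected = "synonymous" if want_syn else "non_synonymous"
            assert ann.effect == expected, (v, ann.effect, expected)
            if rng.random() < config.shared_across_conditions:
                conds = list(config.conditions)
            else:
                conds = [config.conditions[rng.integers(0, len(config.conditions))]]
            entry = {"contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "effect": ann.effect, "gene_id": gene.gene_id}
            for c in conds:
                truth_by_condition[c].append(dict(entry))

    calls: dict[str, dict[str, list[VariantCall]]] = {}
    detected: dict[str, dict[str, list[list]]] = {}
    noise: dict[str, dict[str, list[list]]] = {}
    mb = genome.total_length / 1e6
    for cond in config.conditions:
        calls[cond] = {}
        detected[cond] = {}
        noise[cond] = {}
        for r in range(1, config.replicates_per_condition + 1):
            rep = f"rep{r}"
            rep_calls: list[VariantCall] = []
            det_keys: list[list] = []
            for t in truth_by_condition[cond]:
                if rng.random() < config.replicate_detection_prob:
                    rep_calls.append(
                        VariantCall(t["contig"], t["pos"], t["ref"], t["alt"],
                                    condition=cond, replicate=rep)
                    )
                    det_keys.append([t["contig"], t["pos"], t["ref"], t["alt"]])
            n_noise = int(rng.poisson(config.singleton_noise_rate * mb))
            noise_keys: list[list] = []
            for _ in range(n_noise):
                v = _noise_variant(genome, rng, config, used_keys)
                rep_calls.append(VariantCall(v.contig, v.pos, v.ref, v.alt,
                                             condition=cond, replicate=rep))
                noise_keys.append(list(v.key))
            rep_calls.sort(key=lambda v: v.key)
            calls[cond][rep] = rep_calls
            detected[cond][rep] = det_keys
            noise[cond][rep] = noise_keys

    tracks: dict[str, dict[str, DepthTrack]] = {}
    for cond in config.conditions:
        tracks[cond] = {}
        for rep, rep_calls in calls[cond].items():
            force = [(v.contig, v.pos) for v in rep_calls]
            tracks[cond][rep] = _depth_track(
                genome, rng, config.breadth_mean, f"{_safe(cond)}_{rep}", force
            )

    classification: list[tuple[str, str, int]] = []
    contaminants = ("Pseudomonas", "Escherichia", "Bacillus")
    for cond in config.conditions:
        for rep in calls[cond]:
            sample = f"{_safe(cond)}_{rep}"
            n_reads = int(rng.integers(500_000, 2_000_000))
            n_target = int(rng.binomial(n_reads, 1.0 - config.contamination_fraction))
            rest = n_reads - n_target
            split = rng.multinomial(rest, [1 / 3] * 3)
            classification.append((sample, config.target_genus, n_target))
            for taxon, cnt in zip(contaminants, split):
                classification.append((sample, taxon, int(cnt)))

    truth = GroundTruth(
        hotspot_gene_ids=[g.gene_id for g in hotspot],
        truth_by_condition=truth_by_condition,
        detected=detected,
        noise=noise,
    )
    result = SimResult(config, genome, calls, tracks, classification, truth,
                       Path(out_dir) if out_dir else None)
    if out_dir:
        write_bundle(result, Path(out_dir))
    return result


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def write_vcf(calls: Sequence[VariantCall], contigs: dict[str, str],
              sample_name: str, path) -> None:
    """Minimal single-sample haploid VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=scvartools-simulate\n")
        for cid, seq in contigs.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for v in sorted(calls, key=lambda v: v.key):
            fh.write(f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t100\tPASS\t.\tGT\t1\n")


def write_classification_tsv(rows: Sequence[tuple[str, str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttaxon\tread_count\n")
        for sample, taxon, count in rows:
            fh.write(f"{sample}\t{taxon}\t{count}\n")


def read_classification_tsv(path) -> list[tuple[str, str, int]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            sample, taxon, count = line.rstrip("\n").split("\t")
            rows.append((sample, taxon, int(count)))
    return rows


def write_bundle(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "vcf").mkdir(exist_ok=True)
    (out_dir / "depth").mkdir(exist_ok=True)
    write_fasta(result.genome.contigs, out_dir / "genome.fasta")
    write_gff3(result.genome, out_dir / "genes.gff3")
    for cond, reps in result.calls.items():
        for rep, rep_calls in reps.items():
            sample = f"{_safe(cond)}_{rep}"
            write_vcf(rep_calls, result.genome.contigs, sample,
                      out_dir / "vcf" / f"{sample}.vcf")
    for cond, reps in result.tracks.items():
        for rep, track in reps.items():
            track.to_tsv(out_dir / "depth" / f"{_safe(cond)}_{rep}.tsv")
    write_classification_tsv(result.classification, out_dir / "classification.tsv")
    result.truth.to_json(out_dir / "ground_truth.json")
    result.config.to_yaml(out_dir / "sim_config.yaml")
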