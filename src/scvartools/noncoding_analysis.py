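"""Noncoding-variant characterization: intragenic/intergenic tallies,
cross-condition sharing, distance-to-gene distributions, substitution
spectrum with GC-direction rollup, and a descriptive window scan."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .concordance import ConditionVariantSet
from .effect_annotator import AnnotatedVariant, gc_direction
from .genome_model import AnnotatedGenome

#: The 12 ordered single-base substitution pairs.
SPECTRUM_PAIRS = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


@dataclass
class SpectrumTable:
    condition: str
    counts: dict[str, int] = field(default_factory=lambda: {p: 0 for p in SPECTRUM_PAIRS})
    mnv_count: int = 0

    @property
    def snv_total(self) -> int:
        return sum(self.counts.values())

    @property
    def gc_increase(self) -> int:
        return sum(n for p, n in self.counts.items() if gc_direction(*p.split(">")) == "increase")

    @property
    def gc_decrease(self) -> int:
        return sum(n for p, n in self.counts.items() if gc_direction(*p.split(">")) == "decrease")

    @property
    def gc_neutral(self) -> int:
        return sum(n for p, n in self.counts.items() if gc_direction(*p.split(">")) == "neutral")


def substitution_spectrum(
    variants: Iterable, condition: str = ""
) -> SpectrumTable:
    """12-pair substitution table; multi-base substitutions increment
    ``mnv_count`` only. Accepts VariantCall or AnnotatedVariant inputs."""
    table = SpectrumTable(condition=condition)
    for item in variants:
        v = item.variant if isinstance(item, AnnotatedVariant) else item
        if len(v.ref) > 1:
            table.mnv_count += 1
            continue
        pair = f"{v.ref.upper()}>{v.alt.upper()}"
        if pair in table.counts:
            table.counts[pair] += 1
    return table


@dataclass
class NoncodingSummary:
    condition: str
    intragenic_noncoding: int
    intergenic: int


def noncoding_summary(
    merged_by_condition: Mapping[str, ConditionVariantSet],
    genome: AnnotatedGenome,
) -> tuple[list[NoncodingSummary], dict[tuple[str, str], dict[str, int]]]:
    """Per-condition noncoding tallies plus pairwise sharing counts.

    Returns (summaries, sharing) where ``sharing[(a, b)]`` holds
    ``exact`` (same contig/pos/ref/alt in both conditions' noncoding sets)
    and ``positions`` (same contig/pos, any allele).
    """
    summaries = []
    nc_keys: dict[str, set] = {}
    for cond, merged in merged_by_condition.items():
        if not merged.annotations:
            merged.annotate(genome)
        effects = [a.effect for a in merged.annotations.values()]
        summaries.append(
            NoncodingSummary(
                condition=cond,
                intragenic_noncoding=effects.count("intragenic_noncoding"),
                intergenic=effects.count("intergenic"),
            )
        )
        nc_keys[cond] = {
            a.key
            for a in merged.annotations.values()
            if a.effect in ("intragenic_noncoding", "intergenic")
        }
    sharing: dict[tuple[str, str], dict[str, int]] = {}
    conds = list(merged_by_condition)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            exact = nc_keys[a] & nc_keys[b]
            pos_a = {(c, p) for (c, p, _, _) in nc_keys[a]}
            pos_b = {(c, p) for (c, p, _, _) in nc_keys[b]}
            sharing[(a, b)] = {"exact": len(exact), "positions": len(pos_a & pos_b)}
    return summaries, sharing


@dataclass
class DistanceDistribution:
    distances: list[int]
    threshold_bp: int

    @property
    def n(self) -> int:
        return len(self.distances)

    @property
    def n_within(self) -> int:
        return sum(1 for d in self.distances if d <= self.threshold_bp)

    @property
    def fraction_within(self) -> float:
        return self.n_within / self.n if self.n else math.nan

    @property
    def max_distance(self) -> Optional[int]:
        return max(self.distances) if self.distances else None


def distance_distribution(
    intergenic_variants: Sequence[AnnotatedVariant],
    genome: AnnotatedGenome,
    threshold_bp: int = 10_000,
) -> DistanceDistribution:
    """Distances to the nearest gene for intergenic variants, plus the
    fraction within ``threshold_bp`` and the maximum distance."""
    from .effect_annotator import distance_to_nearest_gene

    distances: list[int] = []
    for av in intergenic_variants:
        if av.effect != "intergenic":
            raise ValueError(f"variant {av.key} is not intergenic ({av.effect})")
        d = av.distance_to_nearest_gene
        if d is None:
            d, _ = distance_to_nearest_gene(genome, av.variant.contig, av.variant.pos)
        if d is not None:
            distances.append(d)
    return DistanceDistribution(distances=distances, threshold_bp=threshold_bp)


@dataclass
class WindowHit:
    contig: str
    start: int
    end: int
    counts: dict[str, int]  # condition -> variants in window

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def window_scan(
    merged_by_condition: Mapping[str, ConditionVariantSet],
    genome: AnnotatedGenome,
    window_bp: int = 35_000,
    step_bp: Optional[int] = None,
    min_total: int = 2,
) -> list[WindowHit]:
    """Descriptive sliding-window variant density per condition (no
    inference attached). Windows with pooled count >= min_total returned."""
    step = step_bp or window_bp // 2
    hits: list[WindowHit] = []
    pos_by_cond: dict[str, dict[str, np.ndarray]] = {}
    for cond, merged in merged_by_condition.items():
        d: dict[str, list[int]] = {}
        for (contig, pos, _, _) in merged.variants:
            d.setdefault(contig, []).append(pos)
        pos_by_cond[cond] = {c: np.sort(np.array(v)) for c, v in d.items()}
    for contig, seq in genome.contigs.items():
        for start in range(0, max(len(seq) - window_bp, 0) + step, step):
            end = min(start + window_bp, len(seq))
            counts = {}
            for cond, by_contig in pos_by_cond.items():
                arr = by_contig.get(contig)
                if arr is None:
                    counts[cond] = 0
                else:
                    counts[cond] = int(
                        np.searchsorted(arr, end) - np.searchsorted(arr, start)
                    )
            if sum(counts.values()) >= min_total:
                hits.append(WindowHit(contig, start, end, counts))
    return hits


def write_spectrum_tsv(tables: Sequence[SpectrumTable], path) -> None:
    conds = [t.condition for t in tables]
    with open(path, "w") as fh:
        fh.write("pair\t" + "\t".join(conds) + "\n")
        for pair in SPECTRUM_PAIRS:
            fh.write(pair + "\t" + "\t".join(str(t.counts[pair]) for t in tables) + "\n")
        fh.write("MNV\t" + "\t".join(str(t.mnv_count) for t in tables) + "\n")
        for row in ("gc_increase", "gc_decrease", "gc_neutral"):
            fh.write(row + "\t" + "\t".join(str(getattr(t, row)) for t in tables) + "\n")


def write_windows_bed(hits: Sequence[WindowHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\thotspot_window\t{h.total}\t.\n")
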