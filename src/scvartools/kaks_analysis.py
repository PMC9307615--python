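"""Ka/Ks statistics.

Genome-wide ratios use raw effect-class counts. Per-gene ratios are
normalized by Nei-Gojobori-style synonymous / non-synonymous site
opportunity restricted to positions covered in enough replicates, so that
partially recovered genes are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .concordance import ConditionVariantSet
from .genome_model import AnnotatedGenome, DepthTrack, GeneRecord, revcomp, translate_codon

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass
class GenomeKaKs:
    condition: str
    ka_total: int
    ks_total: int

    @property
    def ratio(self) -> float:
        if self.ks_total == 0:
            if self.ka_total == 0:
                return math.nan
            logger.warning("condition %s: Ks total is 0, ratio is infinite", self.condition)
            return math.inf
        return self.ka_total / self.ks_total


@dataclass
class GeneKaKs:
    gene_id: str
    condition: str
    ka_count: int
    ks_count: int
    covered_fraction: float
    syn_sites: float
    nonsyn_sites: float

    @property
    def ka_rate(self) -> float:
        return self.ka_count / self.nonsyn_sites if self.nonsyn_sites > 0 else math.nan

    @property
    def ks_rate(self) -> float:
        return self.ks_count / self.syn_sites if self.syn_sites > 0 else math.nan

    @property
    def n_variants(self) -> int:
        return self.ka_count + self.ks_count

    @property
    def ratio(self) -> float:
        """ka_rate / ks_rate; inf when only Ka observed, nan when no variants."""
        if self.n_variants == 0:
            return math.nan
        ka, ks = self.ka_rate, self.ks_rate
        if math.isnan(ka) or math.isnan(ks):
            return math.nan
        if ks == 0:
            return math.inf if ka > 0 else math.nan
        return ka / ks


def genome_wide_kaks(merged: ConditionVariantSet) -> GenomeKaKs:
    """Raw non-synonymous / synonymous count ratio for a merged condition set."""
    if not merged.annotations:
        raise ValueError("merged set must be effect-annotated first")
    effects = [a.effect for a in merged.annotations.values()]
    return GenomeKaKs(
        condition=merged.condition,
        ka_total=effects.count("non_synonymous"),
        ks_total=effects.count("synonymous"),
    )


def potential_sites(
    genome: AnnotatedGenome,
    gene: GeneRecord,
    covered_mask: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """(syn_sites, nonsyn_sites) over covered CDS positions.

    Each covered position contributes f to syn_sites and 1-f to
    nonsyn_sites, where f is the fraction of its 3 possible substitutions
    that preserve the amino acid; the two always sum to the number of
    covered positions (positions in codons containing N are skipped).
    """
    if gene.kind != "CDS":
        raise ValueError(f"{gene.gene_id} is not a CDS")
    cds = genome.cds_sequence(gene)
    n = len(cds)
    if covered_mask is None:
        covered_mask = np.ones(gene.length, dtype=bool)
    if len(covered_mask) != gene.length:
        raise ValueError("covered_mask length must equal gene length")
    # mask is in genomic orientation; flip for '-' strand coding order
    coding_mask = covered_mask if gene.strand == "+" else covered_mask[::-1]

    syn = 0.0
    total = 0
    for i in range(n - n % 3):
        if not coding_mask[i]:
            continue
        ci, off = i // 3, i % 3
        codon = cds[3 * ci : 3 * ci + 3]
        if any(b not in _BASES for b in codon):
            continue
        aa = translate_codon(codon)
        nsyn = sum(
            translate_codon(codon[:off] + b + codon[off + 1 :]) == aa
            for b in _BASES
            if b != codon[off]
        )
        syn += nsyn / 3.0
        total += 1
    return syn, total - syn


def condition_covered_mask(
    gene: GeneRecord,
    tracks: Sequence[DepthTrack],
    min_depth: int = 1,
    min_covered_replicates: int = 2,
) -> np.ndarray:
    """Positions of the gene covered at depth >= min_depth in enough replicates
    (mirrors the >=2-replicate variant concordance rule)."""
    need = min(min_covered_replicates, max(len(tracks), 1))
    counts = np.zeros(gene.length, dtype=np.int32)
    for t in tracks:
        counts += t.covered_mask(gene.contig, gene.start, gene.end, min_depth)
    return counts >= need


def per_gene_kaks(
    genome: AnnotatedGenome,
    merged: ConditionVariantSet,
    tracks: Optional[Sequence[DepthTrack]] = None,
    min_depth: int = 1,
    min_covered_replicates: int = 2,
) -> tuple[list[GeneKaKs], list[str]]:
    """Coverage-normalized per-gene Ka/Ks for one condition.

    Returns (results, excluded_gene_ids); genes with zero covered positions
    are excluded from results and listed.
    """
    if not merged.annotations:
        raise ValueError("merged set must be effect-annotated first")
    ka: dict[str, int] = {}
    ks: dict[str, int] = {}
    for ann in merged.annotations.values():
        if ann.effect == "non_synonymous":
            ka[ann.gene_id] = ka.get(ann.gene_id, 0) + 1
        elif ann.effect == "synonymous":
            ks[ann.gene_id] = ks.get(ann.gene_id, 0) + 1

    results: list[GeneKaKs] = []
    excluded: list[str] = []
    for gene in genome.genes:
        if gene.kind != "CDS":
            continue
        if tracks:
            mask = condition_covered_mask(gene, tracks, min_depth, min_covered_replicates)
        else:
            mask = np.ones(gene.length, dtype=bool)
        if not mask.any():
            excluded.append(gene.gene_id)
            continue
        syn_sites, nonsyn_sites = potential_sites(genome, gene, mask)
        results.append(
            GeneKaKs(
                gene_id=gene.gene_id,
                condition=merged.condition,
                ka_count=ka.get(gene.gene_id, 0),
                ks_count=ks.get(gene.gene_id, 0),
                covered_fraction=float(mask.mean()),
                syn_sites=syn_sites,
                nonsyn_sites=nonsyn_sites,
            )
        )
    if excluded:
        logger.info("condition %s: %d gene(s) with zero covered positions excluded",
                    merged.condition, len(excluded))
    return results, excluded


@dataclass
class GeneOfInterest:
    gene_id: str
    direction: str  # synonymous_dense | non_synonymous_enriched
    n_conditions: int
    total_variants: int
    ratios: dict[str, float]


def select_genes_of_interest(
    per_condition: dict[str, list[GeneKaKs]],
    upper: float = 1.0,
    lower: float = 1.0,
    syn_dense: float = 0.2,
    min_conditions: int = 2,
) -> list[GeneOfInterest]:
    """Select genes with consistent Ka/Ks direction across conditions.

    synonymous_dense: ratio strictly below ``syn_dense`` (with >=1 variant)
    in >= ``min_conditions`` conditions; non_synonymous_enriched: ratio
    strictly above ``upper``. Boundary values are excluded (strict
    inequalities). Sorted by total variant count, descending.
    """
    by_gene: dict[str, dict[str, GeneKaKs]] = {}
    for cond, results in per_condition.items():
        for r in results:
            by_gene.setdefault(r.gene_id, {})[cond] = r

    out: list[GeneOfInterest] = []
    for gene_id, conds in by_gene.items():
        n_dense = sum(
            1 for r in conds.values() if r.n_variants >= 1 and r.ratio < syn_dense
        )
        n_enriched = sum(
            1
            for r in conds.values()
            if r.n_variants >= 1 and not math.isnan(r.ratio) and r.ratio > upper
        )
        total = sum(r.n_variants for r in conds.values())
        ratios = {c: r.ratio for c, r in conds.items()}
        if n_dense >= min_conditions:
            out.append(GeneOfInterest(gene_id, "synonymous_dense", n_dense, total, ratios))
        elif n_enriched >= min_conditions:
            out.append(
                GeneOfInterest(gene_id, "non_synonymous_enriched", n_enriched, total, ratios)
            )
    out.sort(key=lambda g: (-g.total_variants, g.gene_id))
    return out


def format_ratio(x: float) -> str:
    """2-decimal table formatting with sentinels.

    Values are truncated toward zero, not rounded: the reference tables
    print 64/117 = 0.547 as 0.54 and 44/113 = 0.389 as 0.38.
    """
    if math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "inf"
    return f"{math.floor(x * 100 + 1e-9) / 100:.2f}"


def write_genome_kaks_tsv(rows: Iterable[GenomeKaKs], path) -> None:
    with open(path, "w") as fh:
        fh.write("condition\tka\tks\tratio\n")
        for r in rows:
            fh.write(f"{r.condition}\t{r.ka_total}\t{r.ks_total}\t{format_ratio(r.ratio)}\n")


def write_per_gene_tsv(per_condition: dict[str, list[GeneKaKs]], genome, path) -> None:
    conditions = list(per_condition)
    by_gene: dict[str, dict[str, GeneKaKs]] = {}
    for cond, results in per_condition.items():
        for r in results:
            by_gene.setdefault(r.gene_id, {})[cond] = r
    products = {g.gene_id: g.product for g in genome.genes}
    with open(path, "w") as fh:
        fh.write("gene_id\tproduct\t" + "\t".join(conditions) + "\n")
        for gene_id in sorted(by_gene):
            cells = [
                format_ratio(by_gene[gene_id][c].ratio) if c in by_gene[gene_id] else "NA"
                for c in conditions
            ]
            fh.write(f"{gene_id}\t{products.get(gene_id, '')}\t" + "\t".join(cells) + "\n")
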