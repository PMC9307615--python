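"""Codon-level variant effect classification from first principles.

Each substitution is classified against the annotation as synonymous,
non-synonymous, intragenic-noncoding, intergenic, multi-bp, or unknown by
rebuilding the affected codon on the coding strand and translating both
alleles with the bacterial code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .genome_model import AnnotatedGenome, GeneRecord, revcomp, translate_codon

logger = logging.getLogger(__name__)

EFFECTS = (
    "synonymous",
    "non_synonymous",
    "intragenic_noncoding",
    "intergenic",
    "multi_bp",
    "unknown",
)

#: Classes that enter Ka/Ks counting.
CODING_EFFECTS = ("synonymous", "non_synonymous")


@dataclass(frozen=True)
class VariantCall:
    """One substitution observed in one replicate. Substitutions only:
    ``len(ref) == len(alt)`` is enforced at construction."""

    contig: str
    pos: int  # 0-based position of the first changed base
    ref: str
    alt: str
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != len(self.alt):
            raise ValueError(
                f"{self.contig}:{self.pos} {self.ref}>{self.alt}: "
                "indels are not supported (substitutions only)"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.pos}: ref == alt")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: VariantCall
    effect: str
    gene_id: Optional[str] = None
    aa_change: Optional[tuple[str, int, str]] = None  # (ref_aa, 1-based protein pos, alt_aa)
    distance_to_nearest_gene: Optional[int] = None
    gc_direction_label: str = "neutral"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


def gc_direction(ref_base: str, alt_base: str) -> str:
    """GC-content direction of a single-base substitution."""
    strong, weak = {"G", "C"}, {"A", "T"}
    r, a = ref_base.upper(), alt_base.upper()
    if r not in strong | weak or a not in strong | weak:
        return "unknown"
    if r in weak and a in strong:
        return "increase"
    if r in strong and a in weak:
        return "decrease"
    return "neutral"


def distance_to_nearest_gene(
    genome: AnnotatedGenome, contig: str, pos: int
) -> tuple[Optional[int], Optional[str]]:
    """(distance_bp, gene_id) of the nearest gene on the same contig.

    0 if inside a gene; gap measured to the nearest interval edge (a
    position immediately adjacent to a gene boundary is at distance 1).
    Ties go to the lower-coordinate gene. (None, None) if the contig has
    no genes.
    """
    glist = genome.genes_on(contig)
    if not glist:
        return None, None
    best: tuple[int, int, str] = None  # (distance, start, gene_id)
    for g in glist:
        if g.contains(pos):
            return 0, g.gene_id
        d = g.start - pos if pos < g.start else pos - (g.end - 1)
        cand = (d, g.start, g.gene_id)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return best[0], best[2]


def classify(genome: AnnotatedGenome, v: VariantCall) -> AnnotatedVariant:
    """Classify one variant. Pure function of (genome, variant).

    Raises ValueError if the stated ref allele disagrees with the genome
    (this guards against coordinate drift between inputs).
    """
    observed = genome.sequence(v.contig, v.pos, v.pos + len(v.ref))
    if observed != v.ref.upper():
        raise ValueError(
            f"ref mismatch at {v.contig}:{v.pos}: variant says {v.ref!r}, "
            f"genome has {observed!r}"
        )

    gdir = gc_direction(v.ref, v.alt) if v.is_snv else "neutral"

    if not v.is_snv:
        genes = genome.gene_at(v.contig, v.pos)
        gid = genes[0].gene_id if genes else None
        return AnnotatedVariant(v, "multi_bp", gene_id=gid, gc_direction_label="neutral")

    genes = genome.gene_at(v.contig, v.pos)
    cds = [g for g in genes if g.kind == "CDS"]
    if cds:
        gene = cds[0]  # default genomes are non-overlapping; first in coord order
        codon, offset, ref_aa = genome.codon_context(gene, v.pos)
        if len(codon) < 3 or any(b not in "ACGT" for b in codon):
            return AnnotatedVariant(v, "unknown", gene_id=gene.gene_id,
                                    gc_direction_label=gdir)
        alt_base = v.alt if gene.strand == "+" else revcomp(v.alt)
        mutated = codon[:offset] + alt_base + codon[offset + 1 :]
        alt_aa = translate_codon(mutated)
        if alt_aa == "X":
            return AnnotatedVariant(v, "unknown", gene_id=gene.gene_id,
                                    gc_direction_label=gdir)
        if gene.strand == "+":
            protein_pos = (v.pos - gene.start) // 3 + 1
        else:
            protein_pos = ((gene.end - 1) - v.pos) // 3 + 1
        effect = "synonymous" if alt_aa == ref_aa else "non_synonymous"
        return AnnotatedVariant(
            v, effect, gene_id=gene.gene_id,
            aa_change=(ref_aa, protein_pos, alt_aa), gc_direction_label=gdir,
        )
    if genes:  # inside an annotated non-CDS feature (rRNA etc.)
        return AnnotatedVariant(v, "intragenic_noncoding", gene_id=genes[0].gene_id,
                                gc_direction_label=gdir)
    dist, _near = distance_to_nearest_gene(genome, v.contig, v.pos)
    return AnnotatedVariant(v, "intergenic", distance_to_nearest_gene=dist,
                            gc_direction_label=gdir)


def classify_all(genome: AnnotatedGenome, variants: Iterable[VariantCall]) -> list[AnnotatedVariant]:
    return [classify(genome, v) for v in variants]


# ---------------------------------------------------------------------------
# VCF / TSV I/O
# ---------------------------------------------------------------------------

def read_vcf(path, condition: str = "", replicate: str = "") -> list[VariantCall]:
    """Read substitution calls from a VCF 4.2 file.

    Multi-allelic records are split into one call per ALT; indels and
    symbolic alleles are skipped with a warning.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or "*" in alt:
                    logger.warning("skipping symbolic allele at %s:%d", rec.contig, rec.pos)
                    continue
                if len(rec.ref) != len(alt):
                    logger.warning(
                        "skipping indel %s>%s at %s:%d (substitutions only)",
                        rec.ref, alt, rec.contig, rec.pos,
                    )
                    continue
                calls.append(
                    VariantCall(rec.contig, rec.pos - 1, rec.ref.upper(), alt.upper(),
                                condition=condition, replicate=replicate)
                )
    return calls


def write_annotated_tsv(annotated: Iterable[AnnotatedVariant], path) -> None:
    """TSV with 1-based output positions (external convention)."""
    cols = ("contig", "pos", "ref", "alt", "condition", "replicate",
            "effect", "gene_id", "aa_change", "distance_to_nearest_gene", "gc_direction")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for av in annotated:
            v = av.variant
            aa = ""
            if av.aa_change:
                aa = f"{av.aa_change[0]}{av.aa_change[1]}{av.aa_change[2]}"
            fh.write(
                "\t".join(
                    [
                        v.contig, str(v.pos + 1), v.ref, v.alt, v.condition, v.replicate,
                        av.effect, av.gene_id or "", aa,
                        "" if av.distance_to_nearest_gene is None
                        else str(av.distance_to_nearest_gene),
                        av.gc_direction_label,
                    ]
                )
                + "\n"
            )
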