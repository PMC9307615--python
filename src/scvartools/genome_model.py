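"""Reference genome + annotation model: the coordinate authority.

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and VCF (1-based) coordinates are converted at I/O boundaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# Bacterial / archaeal translation table; stops encoded as '*'.
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TABLE: dict[str, str] = dict(_TABLE11.forward_table)
CODON_TABLE.update({c: "*" for c in _TABLE11.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: GFF3 feature types that are containers, not loci of their own.
_SKIP_FEATURETYPES = {"region", "gene", "mRNA", "exon", "source", "chromosome", "contig"}


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid ('*' = stop, 'X' = untranslatable, e.g. with N)."""
    return CODON_TABLE.get(codon.upper(), "X")


@dataclass(frozen=True)
class GeneRecord:
    """A single-interval annotated feature (bacterial: no splicing)."""

    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    kind: str = "CDS"  # CDS | rRNA | other
    product: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class AnnotatedGenome:
    """Contig sequences plus gene intervals; every stage queries this."""

    contigs: dict[str, str]
    genes: list[GeneRecord]
    frame_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_contig: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.gene_id} references unknown contig {g.contig!r}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(
                    f"gene {g.gene_id} interval [{g.start},{g.end}) exceeds "
                    f"contig {g.contig} length {len(self.contigs[g.contig])}"
                )
            self._by_contig.setdefault(g.contig, []).append(g)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        for glist in self._by_contig.values():
            glist.sort(key=lambda g: (g.start, g.end))
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (
                np.array([g.start for g in glist], dtype=np.int64),
                np.array([g.end for g in glist], dtype=np.int64),
            )
            for c, glist in self._by_contig.items()
        }

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def contig_order(self) -> list[str]:
        return list(self.contigs)

    def genes_on(self, contig: str) -> list[GeneRecord]:
        return self._by_contig.get(contig, [])

    def validate(self) -> None:
        """Strict invariant check (CDS in frame); raises on violation."""
        for g in self.genes:
            if g.kind == "CDS" and g.length % 3 != 0:
                raise ValueError(f"CDS {g.gene_id} length {g.length} is not a multiple of 3")

    def gene_at(self, contig: str, pos: int) -> list[GeneRecord]:
        """All genes whose interval contains ``pos``, in coordinate order."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        if not 0 <= pos < len(self.contigs[contig]):
            raise ValueError(f"position {pos} outside contig {contig}")
        glist = self._by_contig.get(contig)
        if not glist:
            return []
        starts, ends = self._arrays[contig]
        hit = np.flatnonzero((starts <= pos) & (pos < ends))
        return [glist[i] for i in hit]

    def sequence(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def cds_sequence(self, gene: GeneRecord) -> str:
        """Coding-strand sequence of a gene, 5'->3'."""
        s = self.contigs[gene.contig][gene.start : gene.end]
        return revcomp(s) if gene.strand == "-" else s

    def codon_context(self, gene: GeneRecord, pos: int) -> tuple[str, int, str]:
        """(codon, offset_in_codon, amino_acid) for a genomic position in a CDS.

        The codon is read 5'->3' on the coding strand; '-' strand genes are
        reverse-complemented. Translation uses the bacterial code.
        """
        if gene.kind != "CDS":
            raise ValueError(f"gene {gene.gene_id} is not a CDS")
        if not gene.contains(pos):
            raise ValueError(f"position {pos} outside gene {gene.gene_id}")
        if gene.strand == "+":
            idx = pos - gene.start
            ci = idx // 3
            codon = self.contigs[gene.contig][gene.start + 3 * ci : gene.start + 3 * ci + 3]
        else:
            idx = (gene.end - 1) - pos
            ci = idx // 3
            codon = revcomp(self.contigs[gene.contig][gene.end - 3 * ci - 3 : gene.end - 3 * ci])
        return codon, idx % 3, translate_codon(codon)


@dataclass
class DepthTrack:
    """Run-length encoded per-base depth for one replicate.

    ``runs[contig]`` is an (n, 3) int array of (start, end, depth) rows,
    sorted and non-overlapping. Positions not covered by any run have depth 0.
    """

    replicate_id: str
    runs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for contig, arr in self.runs.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 3)
            self.runs[contig] = arr
            if arr.size == 0:
                continue
            if np.any(arr[:, 0] >= arr[:, 1]) or np.any(arr[:, 2] < 0):
                raise ValueError(f"track {self.replicate_id}/{contig}: malformed run")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"track {self.replicate_id}/{contig}: overlapping/unsorted runs")

    def depth_at(self, contig: str, pos: int) -> int:
        arr = self.runs.get(contig)
        if arr is None or arr.size == 0:
            return 0
        i = np.searchsorted(arr[:, 0], pos, side="right") - 1
        if i >= 0 and pos < arr[i, 1]:
            return int(arr[i, 2])
        return 0

    def covered_mask(self, contig: str, start: int, end: int, min_depth: int = 1) -> np.ndarray:
        """Boolean per-base mask of positions in [start, end) with depth >= min_depth."""
        mask = np.zeros(end - start, dtype=bool)
        arr = self.runs.get(contig)
        if arr is None or arr.size == 0:
            return mask
        for s, e, d in arr:
            if d >= min_depth and s < end and e > start:
                mask[max(s, start) - start : min(e, end) - start] = True
        return mask

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for contig in self.runs:
                for s, e, d in self.runs[contig]:
                    fh.write(f"{contig}\t{s}\t{e}\t{d}\n")

    @classmethod
    def from_tsv(cls, path, replicate_id: str) -> "DepthTrack":
        runs: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                runs.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), int(parts[3]))
                )
        return cls(replicate_id, {c: np.array(v, dtype=np.int64) for c, v in runs.items()})


def breadth_of_coverage(
    track: DepthTrack, contig: str, start: int, end: int, min_depth: int = 1
) -> float:
    """Fraction of positions in [start, end) with depth >= min_depth."""
    if end <= start:
        raise ValueError(f"empty interval [{start},{end})")
    arr = track.runs.get(contig)
    if arr is None or arr.size == 0:
        return 0.0
    sel = arr[arr[:, 2] >= min_depth]
    if sel.size == 0:
        return 0.0
    overlap = np.minimum(sel[:, 1], end) - np.maximum(sel[:, 0], start)
    covered = int(overlap[overlap > 0].sum())
    return covered / (end - start)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Emit genes as GFF3 (1-based inclusive), attributes ID and product."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
            ftype = g.kind if g.kind in ("CDS", "rRNA") else "misc_feature"
            attrs = f"ID={g.gene_id};product={g.product or 'unknown'}"
            fh.write(
                f"{g.contig}\tscvartools\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t{'0' if g.kind == 'CDS' else '.'}\t{attrs}\n"
            )


def read_genome(fasta_path, gff3_path) -> AnnotatedGenome:
    """Load FASTA + GFF3 into an AnnotatedGenome (internal 0-based half-open).

    Out-of-frame CDS are flagged in ``frame_warnings`` and logged, never
    silently dropped. A GFF3 record on a contig absent from the FASTA, or
    extending past its contig end, is a hard error.
    """
    import gffutils

    contigs = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.all_features():
        if feat.featuretype in _SKIP_FEATURETYPES:
            continue
        if feat.seqid not in contigs:
            raise ValueError(
                f"GFF3 record {feat.id!r} references contig {feat.seqid!r} missing from FASTA"
            )
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if start < 0 or end > len(contigs[feat.seqid]):
            raise ValueError(
                f"GFF3 record {feat.id!r} [{feat.start},{feat.end}] out of bounds "
                f"for contig {feat.seqid} (length {len(contigs[feat.seqid])})"
            )
        kind = feat.featuretype if feat.featuretype in ("CDS", "rRNA") else "other"
        gid = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [""])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(GeneRecord(gid, feat.seqid, start, end, strand, kind, product))

    genome = AnnotatedGenome(contigs, genes)
    for g in genome.genes:
        if g.kind == "CDS" and g.length % 3 != 0:
            msg = f"CDS {g.gene_id} length {g.length} not a multiple of 3"
            genome.frame_warnings.append(msg)
            logger.warning(msg)
    return genome


def cumulative_offsets(genome: AnnotatedGenome) -> dict[str, int]:
    """Contig -> offset in the concatenated ("continuum") coordinate system."""
    offsets: dict[str, int] = {}
    run = 0
    for cid, seq in genome.contigs.items():
        offsets[cid] = run
        run += len(seq)
    return offsets
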