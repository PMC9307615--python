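"""Replicate-concordance merge: retain a variant only when the identical
call (contig, pos, ref, alt) appears in at least ``min_support`` replicates
of the same condition. This removes replicate-unique amplification artifacts."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .effect_annotator import AnnotatedVariant, VariantCall

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]


@dataclass
class ConditionVariantSet:
    """Concordance-merged variants for one condition."""

    condition: str
    variants: dict[Key, VariantCall] = field(default_factory=dict)
    support: dict[Key, int] = field(default_factory=dict)
    annotations: dict[Key, AnnotatedVariant] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[Key]:
        return set(self.variants)

    def annotate(self, genome) -> None:
        from .effect_annotator import classify

        for key, v in self.variants.items():
            self.annotations[key] = classify(genome, v)

    def annotated(self) -> list[AnnotatedVariant]:
        return list(self.annotations.values())


def merge_replicates(
    replicate_sets: Sequence[Sequence[VariantCall]],
    condition: str | None = None,
    min_support: int = 2,
) -> ConditionVariantSet:
    """Merge per-replicate call lists into a per-condition consensus.

    A variant is retained iff its exact key occurs in >= ``min_support``
    distinct replicates. Duplicate keys within one replicate count once
    (with a warning). Conditions with fewer than ``min_support`` replicates
    produce an empty consensus and a loud warning rather than an error.
    """
    if not replicate_sets:
        raise ValueError("need at least one replicate")
    if condition is None:
        for reps in replicate_sets:
            for v in reps:
                if v.condition:
                    condition = v.condition
                    break
            if condition:
                break
        condition = condition or ""
    if len(replicate_sets) < min_support:
        logger.warning(
            "condition %r has %d replicate(s) < min_support=%d: consensus is empty",
            condition, len(replicate_sets), min_support,
        )

    counts: Counter[Key] = Counter()
    first_seen: dict[Key, VariantCall] = {}
    for i, reps in enumerate(replicate_sets):
        seen: set[Key] = set()
        for v in reps:
            if v.key in seen:
                logger.warning("duplicate key %s within replicate %d: counted once", v.key, i)
                continue
            seen.add(v.key)
            counts[v.key] += 1
            first_seen.setdefault(v.key, v)

    out = ConditionVariantSet(condition=condition)
    for key, n in sorted(counts.items()):
        if n >= min_support:
            v = first_seen[key]
            out.variants[key] = VariantCall(v.contig, v.pos, v.ref, v.alt,
                                            condition=condition, replicate="")
            out.support[key] = n
    return out


def shared_variants(a: ConditionVariantSet, b: ConditionVariantSet) -> set[Key]:
    """Exact-key intersection of two merged sets."""
    return a.keys() & b.keys()


def shared_positions(a: ConditionVariantSet, b: ConditionVariantSet) -> set[tuple[str, int]]:
    """Intersection on (contig, pos) only — catches same-site, different-allele
    recurrences."""
    pa = {(c, p) for (c, p, _, _) in a.variants}
    pb = {(c, p) for (c, p, _, _) in b.variants}
    return pa & pb


def support_histogram(replicate_sets: Sequence[Sequence[VariantCall]]) -> dict[int, int]:
    """Histogram of replicate support over all distinct keys (pre-filter)."""
    counts: Counter[Key] = Counter()
    for reps in replicate_sets:
        for key in {v.key for v in reps}:
            counts[key] += 1
    hist: Counter[int] = Counter(counts.values())
    return dict(sorted(hist.items()))


def write_merged_tsv(merged: ConditionVariantSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tcondition\tsupport\teffect\tgene_id\n")
        for key in sorted(merged.variants):
            v = merged.variants[key]
            ann = merged.annotations.get(key)
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{merged.condition}\t"
                f"{merged.support[key]}\t{ann.effect if ann else ''}\t"
                f"{(ann.gene_id or '') if ann else ''}\n"
            )
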