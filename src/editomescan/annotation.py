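"""Map editing sites onto gene models, resolve strand, type the substitution
on the transcribed strand, and attach gene-region and repeat context.

Sites overlapping no transcript are discarded as unannotated; sites
overlapping transcripts on both strands are discarded as strand-ambiguous —
on such sites the edited strand, and hence the substitution type, cannot be
resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import BASES, COMPLEMENT, InputError, RepeatInterval, TranscriptModel

#: Region precedence when a site overlaps several same-strand transcripts.
REGION_PRECEDENCE = ("CDS", "UTR3", "UTR5", "Exon", "Intron")
_REGION_RANK = {r: i for i, r in enumerate(REGION_PRECEDENCE)}

EDITING_TYPES = tuple(
    f"{r}-to-{a}" for r in BASES for a in BASES if r != a
)  # the 12 ordered base substitutions


def type_variant(ref: str, alt: str, strand: str) -> str:
    """Substitution type on the transcribed strand.

    Plus-strand sites are typed as ``ref-to-alt`` directly; minus-strand
    sites are complemented first, so a genomic T-to-C on a minus-strand
    transcript is an A-to-G editing event.
    """
    if strand not in ("+", "-"):
        raise InputError(f"unresolved strand {strand!r}")
    if ref == alt or ref not in BASES or alt not in BASES:
        raise InputError(f"invalid substitution {ref}->{alt}")
    if strand == "-":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}-to-{alt}"


@dataclass
class AnnotatedSite:
    """An editing site with resolved strand, gene and repeat context."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    gene_id: str
    gene_biotype: str
    region: str
    strand: str
    editing_type: str
    repeat_context: str = "non-repetitive"
    presence: frozenset[str] = frozenset()
    pattern: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        """Site identity across samples: the same nucleotide change on the
        same strand, not merely the same position."""
        return (self.chrom, self.pos, self.ref, self.alt, self.strand)


@dataclass(frozen=True)
class DiscardedSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    reason: str  # "unannotated" | "strand-ambiguous"


def _transcript_tree(models: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end + 1, m)
    return trees


def assign_gene_context(
    sites: Sequence,
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[AnnotatedSite], list[DiscardedSite]]:
    """Annotate sites against gene models.

    A site is annotated iff it overlaps at least one transcript and all
    overlapping transcripts share one strand. Among same-strand overlaps the
    region label follows the precedence CDS > UTR3 > UTR5 > Exon > Intron,
    evaluated per transcript and then maximized across transcripts; at equal
    precedence a coding transcript wins over a lncRNA, then the
    lexicographically smallest transcript_id (a site is counted once, never
    per isoform). ``sites`` need chrom/pos/ref and an alt attribute
    (``alt`` or ``rna_alt``).
    """
    trees = _transcript_tree(transcripts)
    annotated: list[AnnotatedSite] = []
    discarded: list[DiscardedSite] = []
    for site in sites:
        alt = getattr(site, "alt", None) or getattr(site, "rna_alt")
        overlapping = [
            iv.data for iv in trees.get(site.chrom, IntervalTree())[site.pos]
        ]
        if not overlapping:
            discarded.append(
                DiscardedSite(site.chrom, site.pos, site.ref, alt, "unannotated")
            )
            continue
        strands = {m.strand for m in overlapping}
        if len(strands) > 1:
            discarded.append(
                DiscardedSite(site.chrom, site.pos, site.ref, alt, "strand-ambiguous")
            )
            continue
        strand = strands.pop()
        best = min(
            overlapping,
            key=lambda m: (
                _REGION_RANK[m.region_at(site.pos)],
                0 if m.biotype == "coding" else 1,
                m.transcript_id,
            ),
        )
        region = best.region_at(site.pos)
        annotated.append(
            AnnotatedSite(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=alt,
                transcript_id=best.transcript_id,
                gene_id=best.gene_id,
                gene_biotype=best.biotype,
                region=region,
                strand=strand,
                editing_type=type_variant(site.ref, alt, strand),
            )
        )
    return annotated, discarded


def assign_repeat_context(
    sites: Sequence[AnnotatedSite], repeats: Sequence[RepeatInterval]
) -> list[AnnotatedSite]:
    """Attach repeat context in place: Alu beats repetitive non-Alu beats
    non-repetitive when intervals overlap."""
    trees: dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
    for s in sites:
        hits = [iv.data for iv in trees.get(s.chrom, IntervalTree())[s.pos]]
        if any(r.is_alu for r in hits):
            s.repeat_context = "Alu"
        elif hits:
            s.repeat_context = "repetitive non-Alu"
        else:
            s.repeat_context = "non-repetitive"
    return list(sites)


def region_distribution(
    sites: Iterable[AnnotatedSite],
    patterns: Mapping[tuple, str] | None = None,
) -> pd.DataFrame:
    """Contingency of site counts per (pattern, biotype, region).

    ``patterns`` maps site keys to pattern labels; sites carrying their own
    ``pattern`` attribute need no mapping. Row sums over (biotype, region)
    equal the number of annotated sites per pattern.
    """
    rows = []
    for s in sites:
        pattern = s.pattern
        if patterns is not None:
            pattern = patterns.get(s.key, pattern)
        rows.append(
            {
                "pattern": pattern if pattern is not None else "unassigned",
                "biotype": s.gene_biotype,
                "region": s.region,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["pattern", "biotype", "region", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["pattern", "biotype", "region"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["pattern", "biotype", "region"])
        .reset_index(drop=True)
    )
    return out
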