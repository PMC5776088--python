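"""Functional consequences of editing: miRNA-target enrichment of 3'UTR
sites, synonymous/non-synonymous recoding in CDS, and expression-change
comparison of edited versus background transcripts.

The miRNA-target enrichment uses a base-resolution hypergeometric null:
every 3'UTR base is a trial and target-covered 3'UTR bases are successes, so
the upper-tail probability asks whether the observed number of 3'UTR editing
sites falling in targets exceeds what uniform placement over the 3'UTR
universe would give.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy import stats

from .annotation import AnnotatedSite
from .io_formats import COMPLEMENT, InputError, TranscriptModel

logger = logging.getLogger(__name__)

EXPRESSION_CATEGORIES = (
    "UTR5",
    "CDS",
    "miRNA-target UTR3",
    "non-target UTR3",
    "Intron",
)

#: Pseudo-count (FPKM) added to both sides of the log2 expression ratio so
#: zero-expression transcripts remain comparable.
FPKM_EPSILON = 0.01


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap test: k of n sites in targets, K of N universe
    bases target-covered; p_value is the upper tail P[X >= k]."""

    k: int
    n: int
    K: int
    N: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.K):
            raise InputError(f"inconsistent counts k={self.k}, n={self.n}, K={self.K}")
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def target_fraction(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class RecodingCall:
    """A CDS editing site's codon change and amino-acid effect."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    gene_id: str
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    effect: str  # "synonymous" | "non-synonymous"
    damaging_label: str | None = None


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    prev_end = None
    for s, e in sorted(intervals):
        if prev_end is not None and s <= prev_end:
            s = prev_end + 1
        if e >= s:
            total += e - s + 1
            prev_end = max(prev_end, e) if prev_end is not None else e
    return total


def _clip_to_universe(
    targets: Sequence[tuple[str, int, int, str]],
    universe: Mapping[str, Sequence[tuple[int, int]]],
) -> list[tuple[str, int, int, str]]:
    trees = {
        chrom: IntervalTree.from_tuples((s, e + 1) for s, e in ivs)
        for chrom, ivs in universe.items()
        if ivs
    }
    clipped = []
    for chrom, s, e, name in targets:
        for iv in trees.get(chrom, IntervalTree()).overlap(s, e + 1):
            clipped.append((chrom, max(s, iv.begin), min(e, iv.end - 1), name))
    return clipped


def mirna_target_enrichment(
    utr3_sites: Sequence[AnnotatedSite],
    target_intervals: Sequence[tuple[str, int, int, str]],
    utr3_universe: Mapping[str, Sequence[tuple[int, int]]],
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Hypergeometric enrichment of 3'UTR editing sites in miRNA targets.

    ``utr3_universe`` maps chrom -> 1-based closed 3'UTR intervals; N is the
    union length, K the target-covered bases within it. Also returns the
    per-miRNA ranking by number of distinct edited target sites (ties broken
    lexicographically); a site in targets of several miRNAs counts once for
    k but once per miRNA in the ranking.
    """
    if not utr3_sites:
        raise InputError("enrichment undefined: no 3'UTR sites supplied")
    N = sum(_interval_union_length(ivs) for ivs in utr3_universe.values())
    clipped = _clip_to_universe(target_intervals, utr3_universe)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _ in clipped:
        by_chrom.setdefault(chrom, []).append((s, e))
    K = sum(_interval_union_length(ivs) for ivs in by_chrom.values())
    if K > N:
        raise InputError(f"target-covered bases K={K} exceed universe N={N}")

    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, name in clipped:
        trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, name)
    k = 0
    per_mirna: dict[str, set[tuple]] = {}
    for site in utr3_sites:
        hits = trees.get(site.chrom, IntervalTree())[site.pos]
        if hits:
            k += 1
        for iv in hits:
            per_mirna.setdefault(iv.data, set()).add(site.key)
    n = len(utr3_sites)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    ranking = pd.DataFrame(
        sorted(
            ((m, len(keys)) for m, keys in per_mirna.items()),
            key=lambda t: (-t[1], t[0]),
        ),
        columns=["mirna", "edited_targets"],
    )
    return EnrichmentResult(k=k, n=n, K=K, N=N, p_value=p), ranking


def call_recoding(
    cds_sites: Sequence[AnnotatedSite],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    damaging_table: Mapping[tuple[str, int], str] | None = None,
) -> list[RecodingCall]:
    """Identify the codon change of each CDS editing site.

    The codon is read from spliced CDS coordinates on the transcribed strand
    (minus-strand CDS on the reverse complement), the substitution applied,
    and both codons translated with the standard genetic code. Transcripts
    whose spliced CDS length is not divisible by 3 are flagged and their
    sites skipped with a warning. Codons spanning exon junctions are handled
    naturally by the spliced coordinates.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    flagged: set[str] = set()
    calls: list[RecodingCall] = []
    for site in cds_sites:
        tx = by_id.get(site.transcript_id)
        if tx is None:
            raise InputError(f"unknown transcript {site.transcript_id}")
        cds_seq = tx.cds_sequence(genome)
        if len(cds_seq) % 3 != 0:
            if tx.transcript_id not in flagged:
                flagged.add(tx.transcript_id)
                logger.warning(
                    "%s: CDS length %d not divisible by 3; its sites are skipped",
                    tx.transcript_id, len(cds_seq),
                )
            continue
        idx = tx.cds_index_of(site.pos)
        if idx is None:
            raise InputError(
                f"site {site.chrom}:{site.pos} not in CDS of {site.transcript_id}"
            )
        alt_tx = site.alt if tx.strand == "+" else COMPLEMENT[site.alt]
        codon_i = idx // 3
        within = idx % 3
        codon_before = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        codon_after = (
            codon_before[:within] + alt_tx + codon_before[within + 1 :]
        )
        aa_before = str(Seq(codon_before).translate())
        aa_after = str(Seq(codon_after).translate())
        effect = "synonymous" if aa_before == aa_after else "non-synonymous"
        label = None
        if damaging_table is not None:
            label = damaging_table.get((site.chrom, site.pos))
        calls.append(
            RecodingCall(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=site.alt,
                transcript_id=site.transcript_id,
                gene_id=site.gene_id,
                codon_before=codon_before,
                codon_after=codon_after,
                aa_before=aa_before,
                aa_after=aa_after,
                effect=effect,
                damaging_label=label,
            )
        )
    return calls


def log2_expression_change(
    expression: pd.DataFrame,
    tumor_sample: str,
    normal_sample: str,
    epsilon: float = FPKM_EPSILON,
) -> pd.Series:
    """Per-transcript log2((FPKM_tumor + eps) / (FPKM_normal + eps))."""
    wide = expression.pivot_table(
        index="transcript_id", columns="sample", values="fpkm"
    )
    for s in (tumor_sample, normal_sample):
        if s not in wide.columns:
            raise InputError(f"sample {s} absent from expression table")
    wide = wide.dropna(subset=[tumor_sample, normal_sample])
    return np.log2((wide[tumor_sample] + epsilon) / (wide[normal_sample] + epsilon))


def expression_change_test(
    edited_transcripts_by_category: Mapping[str, Iterable[str]],
    expression: pd.DataFrame,
    tumor_sample: str,
    normal_sample: str,
    epsilon: float = FPKM_EPSILON,
) -> pd.DataFrame:
    """Two-sample Kolmogorov–Smirnov comparison of expression changes.

    For each editing category the log2 expression-change distribution of its
    transcripts (edited in the tumor sample but not in the non-cancerous
    liver — the caller supplies the category membership) is compared with the
    background distribution over all expressed transcripts; the asymptotic
    two-sided p-value is reported. Categories with fewer than two transcripts
    are skipped and marked.
    """
    changes = log2_expression_change(expression, tumor_sample, normal_sample, epsilon)
    background = changes.to_numpy()
    rows = []
    for category in edited_transcripts_by_category:
        tids = sorted(set(edited_transcripts_by_category[category]))
        values = changes.loc[changes.index.intersection(tids)].to_numpy()
        if len(values) < 2:
            rows.append(
                {
                    "sample": tumor_sample,
                    "category": category,
                    "n": len(values),
                    "D": np.nan,
                    "p_value": np.nan,
                    "skipped": True,
                }
            )
            continue
        res = stats.ks_2samp(values, background, method="asymp")
        rows.append(
            {
                "sample": tumor_sample,
                "category": category,
                "n": len(values),
                "D": float(res.statistic),
                "p_value": float(res.pvalue),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def damaging_gene_lists(
    recoding_calls: Sequence[RecodingCall],
    presence_by_site: Mapping[tuple, Iterable[str]],
) -> dict[str, list[str]]:
    """Per-sample gene lists for external GO/pathway enrichment.

    A gene is listed for a sample when it carries at least one damaging
    non-synonymous editing site present in that sample. Site keys in
    ``presence_by_site`` are (chrom, pos, ref, alt, strand) or
    (chrom, pos, ref, alt); both are matched.
    """
    genes: dict[str, set[str]] = {}
    for call in recoding_calls:
        if call.effect != "non-synonymous" or call.damaging_label != "damaging":
            continue
        presence = None
        for key, pres in presence_by_site.items():
            if key[0] == call.chrom and key[1] == call.pos and key[3] == call.alt:
                presence = pres
                break
        if presence is None:
            continue
        for sample in presence:
            genes.setdefault(sample, set()).add(call.gene_id)
    return {s: sorted(g) for s, g in sorted(genes.items())}
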