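"""RNA editing-site detection cascade.

Per sample: merge the two DNA callers by union and the two RNA callers by
intersection, keep RNA–DNA differences only (RNA genotype must differ from
the DNA genotype; homozygous-reference where DNA shows no variant but is
covered), drop sites whose RNA evidence displays more than one non-reference
base type, apply the four evidence filters, and finally subtract known
germline polymorphism positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import InputError, PileupColumn, VariantCall

logger = logging.getLogger(__name__)

FILTER_NAMES = ("base_quality", "depth", "end_distance", "alt_reads")


class EvidenceMissingError(InputError):
    """A candidate site has no pileup column to evaluate."""


@dataclass(frozen=True)
class FilterConfig:
    """Evidence thresholds for candidate editing sites.

    Defaults: variant-supporting base quality >= 20, covered depth >= 5,
    distance of the site to its supporting reads' ends >= 15 bases, and
    >= 2 supporting reads.
    """

    min_base_qual: int = 20
    min_depth: int = 5
    min_end_distance: int = 15
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        for name in ("min_base_qual", "min_depth", "min_end_distance", "min_alt_reads"):
            if getattr(self, name) < 0:
                raise InputError(f"FilterConfig.{name} must be >= 0")


@dataclass
class CandidateSite:
    """An RNA–DNA difference candidate before evidence filtering.

    ``dna_genotype`` is the called DNA allele pair, or the homozygous
    reference pair where no DNA variant was called but DNA coverage was
    sufficient.
    """

    chrom: str
    pos: int
    ref: str
    rna_alt: str
    sample: str
    dna_genotype: tuple[str, str]
    rna_genotype: tuple[str, str]
    provenance: str = ""
    evidence: PileupColumn | None = None
    depth: int = 0
    alt_support: int = 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.rna_alt)


def _check_mergeable(
    calls_by_caller: Mapping[str, Sequence[VariantCall]], modality: str
) -> None:
    samples = set()
    for caller, calls in calls_by_caller.items():
        for c in calls:
            if c.modality != modality:
                raise InputError(
                    f"caller {caller}: expected {modality} calls, got {c.modality} "
                    f"at {c.chrom}:{c.pos}"
                )
            samples.add(c.sample)
    if len(samples) > 1:
        raise InputError(f"calls span multiple samples: {sorted(samples)}")


def _combine(a: VariantCall, b: VariantCall) -> VariantCall:
    """Evidence for a site reported by both callers: maximum depth/support,
    genotype from the caller with higher depth."""
    primary = a if a.depth >= b.depth else b
    quals = [q for q in (a.base_qual, b.base_qual) if q is not None]
    return VariantCall(
        chrom=a.chrom,
        pos=a.pos,
        ref=a.ref,
        alt=a.alt,
        sample=a.sample,
        modality=a.modality,
        caller=f"{a.caller}+{b.caller}",
        genotype=primary.genotype,
        depth=max(a.depth, b.depth),
        alt_support=max(a.alt_support, b.alt_support),
        base_qual=min(quals) if quals else None,
    )


def merge_dna_calls(
    calls_by_caller: Mapping[str, Sequence[VariantCall]]
) -> list[VariantCall]:
    """Union of the two DNA callers' variants, keyed by (chrom, pos, ref, alt)."""
    _check_mergeable(calls_by_caller, "DNA")
    merged: dict[tuple, VariantCall] = {}
    for caller in sorted(calls_by_caller):
        for c in calls_by_caller[caller]:
            merged[c.key] = _combine(merged[c.key], c) if c.key in merged else c
    return [merged[k] for k in sorted(merged)]


def merge_rna_calls(
    calls_by_caller: Mapping[str, Sequence[VariantCall]]
) -> list[VariantCall]:
    """Intersection of the two RNA callers' variants, keyed by
    (chrom, pos, ref, alt)."""
    _check_mergeable(calls_by_caller, "RNA")
    callers = sorted(calls_by_caller)
    indexed = [
        {c.key: c for c in calls_by_caller[caller]} for caller in callers
    ]
    if not indexed:
        return []
    common = set(indexed[0])
    for idx in indexed[1:]:
        common &= set(idx)
    out = []
    for key in sorted(common):
        combined = indexed[0][key]
        for idx in indexed[1:]:
            combined = _combine(combined, idx[key])
        out.append(combined)
    return out


def _hom_ref(ref: str) -> tuple[str, str]:
    return (ref, ref)


def identify_rdd(
    rna_variants: Sequence[VariantCall],
    dna_variants: Sequence[VariantCall],
    reference: Mapping[str, str],
    *,
    rna_pileups: Mapping[tuple[str, int], PileupColumn] | None = None,
    dna_pileups: Mapping[tuple[str, int], PileupColumn] | None = None,
    config: FilterConfig | None = None,
) -> list[CandidateSite]:
    """Identify RNA–DNA differences (RDDs) among merged RNA variants.

    A candidate is emitted iff the RNA genotype at the position differs from
    the DNA genotype (homozygous reference where no DNA variant was called),
    and the RNA evidence does not display more than one non-reference base
    type with at least ``min_alt_reads`` support. Positions with no DNA
    variant call and DNA pileup depth below ``min_depth`` are discarded as
    DNA-uncovered (the genotype there is unknown, not reference).
    """
    config = config or FilterConfig()
    dna_by_pos: dict[tuple[str, int], VariantCall] = {}
    for d in dna_variants:
        prev = dna_by_pos.get((d.chrom, d.pos))
        # at multi-allelic DNA positions keep the best-supported genotype
        if prev is None or d.alt_support > prev.alt_support:
            dna_by_pos[(d.chrom, d.pos)] = d

    rna_by_pos: dict[tuple[str, int], list[VariantCall]] = {}
    for r in rna_variants:
        rna_by_pos.setdefault((r.chrom, r.pos), []).append(r)

    candidates: list[CandidateSite] = []
    for r in rna_variants:
        try:
            ref_base = reference[r.chrom][r.pos - 1].upper()
        except (KeyError, IndexError) as exc:
            raise InputError(
                f"reference base unavailable at {r.chrom}:{r.pos}"
            ) from exc
        pos_key = (r.chrom, r.pos)
        dna_call = dna_by_pos.get(pos_key)
        if dna_call is not None:
            dna_genotype = dna_call.genotype
        else:
            if dna_pileups is not None:
                dna_col = dna_pileups.get(pos_key)
                if dna_col is None or dna_col.depth < config.min_depth:
                    continue  # DNA-uncovered: genotype unknown
            dna_genotype = _hom_ref(ref_base)
        if r.genotype == dna_genotype:
            continue  # RNA genotype matches DNA: not an RNA-DNA difference

        # more-than-one-non-reference-type rule, on pileup evidence when
        # available, else on the called alternates at the position
        evidence = rna_pileups.get(pos_key) if rna_pileups is not None else None
        if evidence is not None:
            counts = evidence.base_counts()
            alt_types = {
                b
                for b, n in counts.items()
                if b != ref_base and n >= config.min_alt_reads
            }
        else:
            alt_types = {
                c.alt
                for c in rna_by_pos[pos_key]
                if c.alt_support >= config.min_alt_reads
            }
        if len(alt_types) > 1:
            continue

        candidates.append(
            CandidateSite(
                chrom=r.chrom,
                pos=r.pos,
                ref=ref_base,
                rna_alt=r.alt,
                sample=r.sample,
                dna_genotype=dna_genotype,
                rna_genotype=r.genotype,
                provenance=r.caller,
                evidence=evidence,
                depth=r.depth,
                alt_support=r.alt_support,
            )
        )
    candidates.sort(key=lambda c: c.key)
    return candidates


def _first_failed_filter(
    col: PileupColumn, alt: str, config: FilterConfig
) -> str | None:
    """Name of the first filter a candidate fails, in the listed order, or
    None if it survives all four. A site with no supporting observations
    passes the (vacuous) quality and end-distance minima and is charged to
    the depth or support filter."""
    supporting = col.supporting(alt)
    if supporting and min(o.qual for o in supporting) < config.min_base_qual:
        return "base_quality"
    if col.depth < config.min_depth:
        return "depth"
    if supporting and (
        min(min(o.dist5, o.dist3) for o in supporting) < config.min_end_distance
    ):
        return "end_distance"
    if len(supporting) < config.min_alt_reads:
        return "alt_reads"
    return None


def apply_site_filters(
    candidates: Sequence[CandidateSite],
    pileups: Mapping[tuple[str, int], PileupColumn],
    config: FilterConfig | None = None,
) -> tuple[list[CandidateSite], dict[str, int]]:
    """Apply the four evidence filters; returns survivors and per-filter
    removal counts.

    A candidate survives iff: minimum Phred quality among variant-supporting
    observations >= min_base_qual; total observations >= min_depth; minimum
    over variant-supporting observations of the nearer read-end distance
    >= min_end_distance; and the number of supporting observations
    >= min_alt_reads. Removal is charged to the first failed filter in that
    order; survival is order-independent (a conjunction).
    """
    config = config or FilterConfig()
    missing = [
        c.key
        for c in candidates
        if c.evidence is None and (c.chrom, c.pos) not in pileups
    ]
    if missing:
        raise EvidenceMissingError(
            f"no pileup column for candidate site(s): {missing}"
        )
    audit = {name: 0 for name in FILTER_NAMES}
    kept: list[CandidateSite] = []
    for c in candidates:
        col = c.evidence if c.evidence is not None else pileups[(c.chrom, c.pos)]
        failed = _first_failed_filter(col, c.rna_alt, config)
        if failed is None:
            supporting = col.supporting(c.rna_alt)
            c.evidence = col
            c.depth = col.depth
            c.alt_support = len(supporting)
            kept.append(c)
        else:
            audit[failed] += 1
    return kept, audit


def subtract_germline(
    sites: Sequence[CandidateSite],
    snp_tables: Sequence[set[tuple[str, int]]],
) -> tuple[list[CandidateSite], list[int]]:
    """Remove sites at known polymorphism positions (allele-agnostic).

    A site is removed if its (chrom, pos) appears in ANY table; the returned
    counts report, per table, how many input sites matched it (a site in two
    tables counts once per table but is removed once).
    """
    counts = [0] * len(snp_tables)
    kept = []
    for s in sites:
        hit = False
        for i, table in enumerate(snp_tables):
            if (s.chrom, s.pos) in table:
                counts[i] += 1
                hit = True
        if not hit:
            kept.append(s)
    return kept, counts


@dataclass
class DetectionResult:
    """Per-sample detection output with funnel accounting."""

    sample: str
    sites: list[CandidateSite]
    funnel: dict[str, int] = field(default_factory=dict)


def detect_sample(
    *,
    sample: str,
    dna_calls_by_caller: Mapping[str, Sequence[VariantCall]],
    rna_calls_by_caller: Mapping[str, Sequence[VariantCall]],
    reference: Mapping[str, str],
    rna_pileups: Mapping[tuple[str, int], PileupColumn],
    dna_pileups: Mapping[tuple[str, int], PileupColumn] | None = None,
    snp_tables: Sequence[set[tuple[str, int]]] = (),
    config: FilterConfig | None = None,
) -> DetectionResult:
    """Run the full per-sample cascade: merge, RDD, filters, germline
    subtraction. The funnel records input/output counts at every stage so
    that in = out + removed holds throughout."""
    config = config or FilterConfig()
    dna = merge_dna_calls(dna_calls_by_caller)
    rna = merge_rna_calls(rna_calls_by_caller)
    candidates = identify_rdd(
        rna,
        dna,
        reference,
        rna_pileups=rna_pileups,
        dna_pileups=dna_pileups,
        config=config,
    )
    filtered, audit = apply_site_filters(candidates, rna_pileups, config)
    final, germline_counts = subtract_germline(filtered, snp_tables)
    n_germline_removed = len(filtered) - len(final)
    funnel = {
        "rna_calls_merged": len(rna),
        "dna_calls_merged": len(dna),
        "rdd_candidates": len(candidates),
        "rdd_removed": len(rna) - len(candidates),
        **{f"filter_removed_{k}": v for k, v in audit.items()},
        "after_filters": len(filtered),
        "germline_removed": n_germline_removed,
        **{f"germline_table_{i}_hits": c for i, c in enumerate(germline_counts)},
        "final_sites": len(final),
    }
    logger.info(
        "%s: %d merged RNA calls -> %d candidates -> %d filtered -> %d final",
        sample, len(rna), len(candidates), len(filtered), len(final),
    )
    return DetectionResult(sample=sample, sites=final, funnel=funnel)
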