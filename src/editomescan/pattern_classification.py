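"""Cross-stage pattern classification of editing sites.

Each site's presence profile across the four samples (NL = non-cancerous
liver, PT = primary tumor, IM = intrahepatic metastasis, PTVV = portal vein
tumor thrombus) maps to exactly one of seven patterns:

- ``ALL``  — present in all four samples;
- ``STN``  — shared by the non-cancerous liver and some but not all tumors;
- ``ST``   — shared by two or three tumor samples, absent from NL;
- ``NL`` / ``PT`` / ``IM`` / ``PTVV`` — unique to that sample.

The 15 non-empty presence subsets partition exactly into these 7 labels. A
"stage-specific" site is any site with pattern != ALL.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .io_formats import DEFAULT_SAMPLES, InputError

PATTERN_LABELS = ("ALL", "STN", "ST", "NL", "PT", "IM", "PTVV")


@dataclass(frozen=True)
class PatternAssignment:
    site_key: tuple
    presence: frozenset[str]
    pattern: str


def classify_pattern(
    presence: Iterable[str],
    samples: Sequence[str] = DEFAULT_SAMPLES,
    normal: str = "NL",
) -> str:
    """Map a non-empty presence subset to its pattern label.

    Deterministic function of the presence set alone: the full set is ALL,
    singletons map to their sample, multi-sample subsets containing the
    normal sample are STN, and normal-free multi-sample subsets are ST.
    """
    pres = frozenset(presence)
    if not pres:
        raise InputError("empty presence set")
    unknown = pres - set(samples)
    if unknown:
        raise InputError(f"unknown sample id(s): {sorted(unknown)}")
    if pres == set(samples):
        return "ALL"
    if len(pres) == 1:
        return next(iter(pres))
    return "STN" if normal in pres else "ST"


def classify_sites(
    presence_by_site: Mapping[tuple, Iterable[str]],
    samples: Sequence[str] = DEFAULT_SAMPLES,
    normal: str = "NL",
) -> dict[tuple, PatternAssignment]:
    return {
        key: PatternAssignment(
            site_key=key,
            presence=frozenset(pres),
            pattern=classify_pattern(pres, samples, normal),
        )
        for key, pres in presence_by_site.items()
    }


def presence_from_site_sets(
    sets_by_sample: Mapping[str, Iterable[tuple]]
) -> dict[tuple, frozenset[str]]:
    """Invert per-sample site-key sets into per-site presence subsets."""
    presence: dict[tuple, set[str]] = {}
    for sample in sets_by_sample:
        for key in sets_by_sample[sample]:
            presence.setdefault(key, set()).add(sample)
    return {k: frozenset(v) for k, v in presence.items()}


def overlap_table(
    sets_by_sample: Mapping[str, Iterable[tuple]],
    samples: Sequence[str] = DEFAULT_SAMPLES,
) -> dict[frozenset[str], int]:
    """Counts of every region of the 4-set Venn diagram.

    One count per non-empty sample subset (15 for four samples); counts sum
    to the size of the union of the four sets.
    """
    keyed = {s: set(sets_by_sample.get(s, ())) for s in samples}
    table: dict[frozenset[str], int] = {}
    for r in range(1, len(samples) + 1):
        for combo in combinations(samples, r):
            table[frozenset(combo)] = 0
    for key, pres in presence_from_site_sets(keyed).items():
        table[pres] += 1
    return table


def stage_specific_fraction(
    assignments: Iterable[PatternAssignment] | Mapping[tuple, PatternAssignment]
) -> float:
    """Proportion of sites absent from at least one sample (pattern != ALL)."""
    if isinstance(assignments, Mapping):
        assignments = list(assignments.values())
    else:
        assignments = list(assignments)
    if not assignments:
        raise InputError("stage_specific_fraction undefined on empty input")
    return sum(1 for a in assignments if a.pattern != "ALL") / len(assignments)


def pattern_counts(
    assignments: Iterable[PatternAssignment] | Mapping[tuple, PatternAssignment]
) -> dict[str, int]:
    if isinstance(assignments, Mapping):
        assignments = assignments.values()
    counts = {label: 0 for label in PATTERN_LABELS}
    for a in assignments:
        counts[a.pattern] += 1
    return counts
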