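"""Readers, writers and in-memory types for every external format the pipeline touches.

All coordinates are 1-based inclusive internally, matching VCF and GTF; BED
inputs are converted on read. Every reader accepts plain or gzip-compressed
files.
"""

from __future__ import annotations

import gzip
import logging
import textwrap
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The four samples of the cross-stage design: non-cancerous liver, primary
#: tumor, intrahepatic metastasis, portal vein tumor thrombus.
DEFAULT_SAMPLES = ("NL", "PT", "IM", "PTVV")


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ParseError(InputError):
    """A file could not be parsed; carries file context."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    """One SNV at one position in one sample from one caller/modality.

    ``genotype`` is an unordered allele pair (stored sorted); phasing is
    ignored. ``base_qual`` summarizes the Phred quality of variant-supporting
    bases as their minimum, and may be ``None`` when the source VCF carries no
    such annotation (a pileup sidecar then supplies it downstream).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    modality: str  # "DNA" | "RNA"
    caller: str
    genotype: tuple[str, str]
    depth: int
    alt_support: int
    base_qual: int | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InputError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise InputError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_support <= self.depth:
            raise InputError(
                f"alt_support {self.alt_support} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise InputError(f"non-positive position {self.pos}")
        object.__setattr__(self, "genotype", tuple(sorted(self.genotype)))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Observation:
    """One read base covering one position, with its read-end distances."""

    base: str
    qual: int
    dist5: int
    dist3: int
    read_id: str


@dataclass
class PileupColumn:
    """All read observations covering one genomic position."""

    chrom: str
    pos: int
    ref: str
    observations: list[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)

    def supporting(self, alt: str) -> list[Observation]:
        return [o for o in self.observations if o.base == alt]

    def base_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for o in self.observations:
            counts[o.base] = counts.get(o.base, 0) + 1
        return counts


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


@dataclass(frozen=True)
class TranscriptModel:
    """Stranded multi-exon gene model with optional CDS.

    ``exons`` and ``cds`` are sorted 1-based closed intervals. Coding
    transcripts carry a non-empty CDS; lncRNA transcripts carry none. UTRs are
    derived (exon bases outside the CDS, split by genomic side and strand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    biotype: str = "lncRNA"  # "coding" | "lncRNA"

    def __post_init__(self) -> None:
        exons = _merge_intervals(self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        for s, e in exons:
            if s > e:
                raise InputError(f"{self.transcript_id}: empty exon {s}-{e}")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in exons):
                raise InputError(
                    f"{self.transcript_id}: CDS {s}-{e} outside exon union"
                )
        if self.biotype == "coding" and not self.cds:
            raise InputError(f"{self.transcript_id}: coding transcript without CDS")
        if self.biotype == "lncRNA" and self.cds:
            raise InputError(f"{self.transcript_id}: lncRNA transcript with CDS")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def _exon_minus_cds(self) -> tuple[tuple[int, int], ...]:
        if not self.cds:
            return ()
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        out = []
        for s, e in self.exons:
            if e < cds_lo or s > cds_hi:
                out.append((s, e))
            else:
                if s < cds_lo:
                    out.append((s, cds_lo - 1))
                if e > cds_hi:
                    out.append((cds_hi + 1, e))
        return tuple(out)

    @property
    def utr5(self) -> tuple[tuple[int, int], ...]:
        if not self.cds:
            return ()
        cds_lo = self.cds[0][0]
        utr = self._exon_minus_cds()
        left = tuple(iv for iv in utr if iv[1] < cds_lo)
        right = tuple(iv for iv in utr if iv[0] > self.cds[-1][1])
        return left if self.strand == "+" else right

    @property
    def utr3(self) -> tuple[tuple[int, int], ...]:
        if not self.cds:
            return ()
        cds_lo = self.cds[0][0]
        utr = self._exon_minus_cds()
        left = tuple(iv for iv in utr if iv[1] < cds_lo)
        right = tuple(iv for iv in utr if iv[0] > self.cds[-1][1])
        return right if self.strand == "+" else left

    def region_at(self, pos: int) -> str | None:
        """Gene-region label at ``pos``: CDS/UTR5/UTR3 (coding), Exon (lncRNA),
        Intron (within span but outside exons), or None outside the span."""
        if not (self.start <= pos <= self.end):
            return None
        in_exon = any(s <= pos <= e for s, e in self.exons)
        if not in_exon:
            return "Intron"
        if self.biotype != "coding":
            return "Exon"
        if any(s <= pos <= e for s, e in self.cds):
            return "CDS"
        if any(s <= pos <= e for s, e in self.utr5):
            return "UTR5"
        return "UTR3"

    def cds_index_of(self, pos: int) -> int | None:
        """0-based index of ``pos`` in the spliced CDS (5'→3' on the
        transcribed strand), or None if ``pos`` is not in the CDS."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                idx = offset + (pos - s)
                break
            offset += e - s + 1
        else:
            return None
        if self.strand == "-":
            total = sum(e - s + 1 for s, e in self.cds)
            idx = total - 1 - idx
        return idx

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS sequence on the transcribed strand."""
        seq = "".join(genome[self.chrom][s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = "".join(COMPLEMENT[b] for b in reversed(seq))
        return seq.upper()


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat-masker style interval; Alu families are flagged."""

    chrom: str
    start: int  # 1-based closed
    end: int
    family: str

    @property
    def is_alu(self) -> bool:
        return self.family.startswith("Alu")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str, sample: str, modality: str, caller: str) -> list[VariantCall]:
    """Read biallelic SNVs from a VCF 4.x file as :class:`VariantCall` records.

    Multi-allelic records are split into one call per alternate allele;
    indels and symbolic alleles are skipped (counted in a log message);
    records with a non-PASS FILTER are dropped. Depth and allele support come
    from the per-sample DP/AD fields; records missing them are skipped with a
    warning. A custom ``MBQ`` FORMAT field, when present, supplies the minimum
    variant-supporting base quality.
    """
    calls: list[VariantCall] = []
    n_indels = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.filter.keys() and "PASS" not in rec.filter.keys():
                continue
            if rec.alts is None:
                continue
            sdata = rec.samples[0] if rec.samples else None
            alleles = [rec.ref] + list(rec.alts)
            for ai, alt in enumerate(rec.alts, start=1):
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in BASES:
                    n_indels += 1
                    continue
                if sdata is None or sdata.get("DP") is None:
                    logger.warning(
                        "%s:%s skipped: missing depth/support fields", rec.chrom, rec.pos
                    )
                    continue
                depth = int(sdata["DP"])
                ad = sdata.get("AD")
                if ad is None or len(ad) <= ai or ad[ai] is None:
                    logger.warning(
                        "%s:%s skipped: missing AD for allele %s", rec.chrom, rec.pos, alt
                    )
                    continue
                gt = sdata.get("GT")
                if gt is None or any(g is None for g in gt):
                    genotype = (rec.ref, alt)
                else:
                    genotype = tuple(alleles[g] for g in gt)  # type: ignore[misc]
                mbq = sdata.get("MBQ")
                if isinstance(mbq, tuple):
                    mbq = mbq[0]
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        sample=sample,
                        modality=modality,
                        caller=caller,
                        genotype=genotype,  # type: ignore[arg-type]
                        depth=depth,
                        alt_support=int(ad[ai]),
                        base_qual=None if mbq is None else int(mbq),
                    )
                )
    if n_indels:
        logger.info("%s: skipped %d non-SNV allele(s)", path, n_indels)
    return calls


def write_vcf(
    calls: Sequence[VariantCall],
    path: str,
    contigs: Mapping[str, int],
    sample_name: str = "SAMPLE",
) -> None:
    """Write calls as a VCF 4.2 file with GT:DP:AD:MBQ per-sample fields.

    Calls at the same position with the same ref are emitted as one
    (possibly multi-allelic) record.
    """
    header = pysam.VariantHeader()
    for name in contigs:
        header.contigs.add(name, length=contigs[name])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref first)")
    header.formats.add(
        "MBQ", 1, "Integer", "Minimum base quality of variant-supporting reads"
    )
    header.add_sample(sample_name)

    grouped: dict[tuple[str, int, str], list[VariantCall]] = {}
    for c in calls:
        grouped.setdefault((c.chrom, c.pos, c.ref), []).append(c)

    with pysam.VariantFile(path, "w", header=header) as out:
        for (chrom, pos, ref) in sorted(grouped):
            group = sorted(grouped[(chrom, pos, ref)], key=lambda c: c.alt)
            alts = [c.alt for c in group]
            alleles = [ref] + alts
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=tuple(alleles)
            )
            gt_alleles = group[0].genotype
            rec.samples[sample_name]["GT"] = tuple(
                alleles.index(a) if a in alleles else 0 for a in gt_alleles
            )
            depth = max(c.depth for c in group)
            ad = [depth - sum(c.alt_support for c in group)] + [
                c.alt_support for c in group
            ]
            rec.samples[sample_name]["DP"] = depth
            rec.samples[sample_name]["AD"] = tuple(ad)
            quals = [c.base_qual for c in group if c.base_qual is not None]
            if quals:
                rec.samples[sample_name]["MBQ"] = min(quals)
            out.write(rec)


def read_snp_positions(path: str) -> set[tuple[str, int]]:
    """Read a known-SNP list (VCF or chrom/pos table) as a (chrom, pos) set."""
    name = path[:-3] if path.endswith(".gz") else path
    if name.endswith(".vcf"):
        out: set[tuple[str, int]] = set()
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                out.add((rec.chrom, rec.pos))
        return out
    df = pd.read_csv(path, sep="\t", comment="#", header=None, usecols=[0, 1])
    return set(zip(df[0].astype(str), df[1].astype(int)))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str) -> list[TranscriptModel]:
    """Load transcript models from a GTF, grouped by transcript_id.

    A transcript with at least one CDS feature is coding; otherwise lncRNA.
    Exons are sorted and merged; CDS outside the exon union is a validation
    error naming the transcript.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (gid, feat.seqid, feat.strand)
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))
    models = []
    for tid in sorted(meta):
        gid, chrom, strand = meta[tid]
        tx_cds = tuple(sorted(cds.get(tid, [])))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons.get(tid, []))),
                cds=tx_cds,
                biotype="coding" if tx_cds else "lncRNA",
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models as GTF with exon/CDS/UTR features."""

    def attrs(m: TranscriptModel) -> str:
        biotype = "protein_coding" if m.biotype == "coding" else "lncRNA"
        return (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_biotype "{biotype}";'
        )

    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            rows = [("exon", iv) for iv in m.exons]
            rows += [("CDS", iv) for iv in m.cds]
            rows += [("five_prime_utr", iv) for iv in m.utr5]
            rows += [("three_prime_utr", iv) for iv in m.utr3]
            for ftype, (s, e) in sorted(rows, key=lambda r: (r[1], r[0])):
                fh.write(
                    f"{m.chrom}\teditomescan\t{ftype}\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"{attrs(m)}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _read_bed6(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    df["start"] = df["start"].astype(int) + 1  # to 1-based closed
    df["end"] = df["end"].astype(int)
    return df


def read_repeats_bed(path: str) -> list[RepeatInterval]:
    """Read a BED6 repeat annotation; name column is the repeat family."""
    df = _read_bed6(path)
    return [
        RepeatInterval(chrom=r.chrom, start=r.start, end=r.end, family=str(r.name))
        for r in df.itertuples(index=False)
    ]


def read_targets_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read a BED6 miRNA-target file as (chrom, start, end, mirna) tuples."""
    df = _read_bed6(path)
    return [
        (r.chrom, r.start, r.end, str(r.name)) for r in df.itertuples(index=False)
    ]


def write_bed6(
    rows: Sequence[tuple[str, int, int, str, str]], path: str
) -> None:
    """Write (chrom, start1, end1, name, strand) rows as BED6 (0-based)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in rows:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Pileup and expression tables
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["chrom", "pos", "ref", "base", "qual", "dist5", "dist3", "read_id"]


def read_pileup(path: str) -> dict[tuple[str, int], PileupColumn]:
    """Read a tab-delimited pileup summary into columns keyed by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=PILEUP_COLUMNS)
    columns: dict[tuple[str, int], PileupColumn] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        col = columns.get(key)
        if col is None:
            col = columns[key] = PileupColumn(
                chrom=key[0], pos=key[1], ref=str(row.ref)
            )
        col.observations.append(
            Observation(
                base=str(row.base),
                qual=int(row.qual),
                dist5=int(row.dist5),
                dist3=int(row.dist3),
                read_id=str(row.read_id),
            )
        )
    return columns


def write_pileup(columns: Iterable[PileupColumn], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(PILEUP_COLUMNS) + "\n")
        for col in sorted(columns, key=lambda c: (c.chrom, c.pos)):
            for o in col.observations:
                fh.write(
                    f"{col.chrom}\t{col.pos}\t{col.ref}\t{o.base}\t{o.qual}\t"
                    f"{o.dist5}\t{o.dist3}\t{o.read_id}\n"
                )


def read_expression(path: str) -> pd.DataFrame:
    """Read a transcript expression table (transcript_id, sample, fpkm)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["transcript_id", "sample", "fpkm"],
    )
    df["fpkm"] = df["fpkm"].astype(float)
    return df


def read_damaging_table(path: str) -> dict[tuple[str, int], str]:
    """Read a damaging/tolerated annotation table keyed by (chrom, pos)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "pos", "effect"]
    )
    bad = set(df["effect"]) - {"damaging", "tolerated"}
    if bad:
        raise ParseError(f"{path}: unknown effect label(s) {sorted(bad)}")
    return {
        (str(r.chrom), int(r.pos)): str(r.effect) for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(sequences[name], width) + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a small genome fully into memory as {name: sequence}."""
    from Bio import SeqIO

    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# Read-level QC
# ---------------------------------------------------------------------------


def filter_reads(
    records: Iterable[tuple[str, Sequence[int]]]
) -> list[tuple[str, Sequence[int]]]:
    """Low-quality read removal.

    A read is removed iff more than 10% of its bases are unknown (N) or more
    than 50% of its bases have a base quality below 5; both bounds are strict
    ("more than"), so a read exactly at 10% N or 50% low-quality is kept.
    """
    kept = []
    for bases, quals in records:
        if len(bases) != len(quals):
            raise InputError(
                f"bases/quals length mismatch ({len(bases)} vs {len(quals)})"
            )
        n = len(bases)
        if n == 0:
            continue
        n_frac = sum(1 for b in bases if b.upper() == "N") / n
        lowq_frac = sum(1 for q in quals if q < 5) / n
        if n_frac > 0.10 or lowq_frac > 0.50:
            continue
        kept.append((bases, quals))
    return kept
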