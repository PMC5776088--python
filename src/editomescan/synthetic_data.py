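"""Self-consistent toy dataset generator with known ground truth.

Emulates the study design the pipeline targets: four samples from one
patient (non-cancerous liver NL, primary tumor PT, intrahepatic metastasis
IM, portal vein tumor thrombus PTVV), each with matched DNA and RNA
evidence. The generator writes a toy diploid genome, stranded multi-exon
gene models, Alu-like repeats, planted germline SNPs and A-to-I-dominated
editing events with per-sample presence patterns and editing rates,
per-sample per-caller VCFs, pileup evidence tables, expression tables, and
miRNA-target / damaging-annotation tables.

Pileups are generated directly (no read simulation or alignment): each
observed base carries a synthetic read placement, drawn uniformly along the
read, so read-end-distance filtering is exercisable. The two variant callers
are derived from the same pileup with different sensitivity knobs (the
VarScan-like caller misses variants below a minimum allele fraction), so the
union-versus-intersection merge rules have observable effect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from . import io_formats
from .editing_detection import FilterConfig, _first_failed_filter
from .io_formats import (
    BASES,
    COMPLEMENT,
    DEFAULT_SAMPLES,
    Observation,
    PileupColumn,
    TranscriptModel,
    VariantCall,
)
from .pattern_classification import PATTERN_LABELS, classify_pattern


class ConfigurationError(ValueError):
    """A SimulationConfig field violates its invariant."""


_ALU_FAMILIES = ("AluY", "AluSx", "AluJb")
_NONALU_FAMILIES = ("L1", "L2", "MIR", "LTR12")
_MIRNA_POOL = tuple(f"miR-{i}" for i in range(1, 16))

#: Default pattern sampling probabilities. ALL is rare (most editing is
#: stage-specific); singletons dominate, as in tumor-stage editomes.
DEFAULT_PATTERN_WEIGHTS = {
    "ALL": 0.07,
    "STN": 0.10,
    "ST": 0.13,
    "NL": 0.15,
    "PT": 0.20,
    "IM": 0.175,
    "PTVV": 0.175,
}

_CALLER_MIN_FRAC = {"gatk": 0.02, "varscan": 0.10}


def _pattern_subsets(samples: Sequence[str], normal: str) -> dict[str, list[frozenset]]:
    """All presence subsets compatible with each of the seven patterns."""
    out: dict[str, list[frozenset]] = {label: [] for label in PATTERN_LABELS}
    for r in range(1, len(samples) + 1):
        for combo in combinations(samples, r):
            out[classify_pattern(combo, samples, normal)].append(frozenset(combo))
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the toy dataset; defaults define the standard study
    conditions: 30x depth both modalities, 90-bp reads, 300 planted editing
    events at rates 0.3-0.6, 80% of them A-to-I."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_transcripts: int = 36
    frac_noncoding: float = 0.25
    n_alu: int = 40
    alu_length_range: tuple[int, int] = (250, 350)
    n_germline_snps: int = 60
    n_editing_sites: int = 300
    editing_rate_range: tuple[float, float] = (0.3, 0.6)
    dna_depth: int = 30
    rna_depth: int = 30
    read_length: int = 90
    seq_error_rate: float = 0.005
    pattern_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_WEIGHTS)
    )
    frac_a_to_g: float = 0.8
    n_background_positions: int = 300
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    normal_sample: str = "NL"

    def validate(self) -> None:
        for name in ("frac_noncoding", "seq_error_rate", "frac_a_to_g"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.editing_rate_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(
                f"editing_rate_range must satisfy 0 < low <= high <= 1, got {lo}, {hi}"
            )
        if set(self.pattern_weights) != set(PATTERN_LABELS):
            raise ConfigurationError(
                "pattern_weights must cover exactly the seven pattern labels"
            )
        total = sum(self.pattern_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"pattern_weights must sum to 1, got {total}")
        if self.read_length <= 2 * FilterConfig().min_end_distance:
            raise ConfigurationError(
                "read_length must exceed twice the read-end distance threshold, "
                f"got {self.read_length}"
            )
        for name in (
            "n_chromosomes", "chrom_length", "n_transcripts", "n_alu",
            "n_germline_snps", "dna_depth", "rna_depth",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_editing_sites < 0:
            raise ConfigurationError("n_editing_sites must be >= 0")


@dataclass(frozen=True)
class PlantedSite:
    """One planted editing event, in genome coordinates: ``ref``/``alt`` are
    the genomic bases (a minus-strand A-to-I event appears as T-to-C)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strand: str
    editing_type: str
    transcript_id: str
    region: str
    presence: frozenset[str]
    rates: Mapping[str, float]
    recoding_effect: str | None = None  # for CDS sites

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GroundTruth:
    """Everything the generator planted, for validation against pipeline
    output; also carries the simulation context (genome, transcripts,
    covered positions, expression factors) needed to regenerate pileups.

    ``expression_factors`` maps (transcript_id, sample) to the relative
    expression of that transcript (mean 1 across the transcriptome); RNA
    coverage of a transcript scales with it, so lowly expressed transcripts
    are shallowly covered, as in real RNA-seq.
    """

    planted_sites: list[PlantedSite]
    planted_snps: list[tuple[str, int, str, str, tuple[str, str]]]
    expected_pattern: dict[tuple, str]
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    covered_positions: list[tuple[str, int]]
    expression_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    samples: tuple[str, ...] = DEFAULT_SAMPLES

    def site_at(self, chrom: str, pos: int) -> PlantedSite | None:
        return self._site_index.get((chrom, pos))

    @property
    def _site_index(self) -> dict[tuple[str, int], PlantedSite]:
        idx = getattr(self, "__site_index", None)
        if idx is None:
            idx = {(s.chrom, s.pos): s for s in self.planted_sites}
            object.__setattr__(self, "__site_index", idx)
        return idx

    @property
    def snp_positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _, _ in self.planted_snps}


def _rng(seed: int, tag: str) -> np.random.Generator:
    # one independent, process-stable stream per output component
    return np.random.default_rng([seed % 2**31, zlib.crc32(tag.encode())])


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------


def _make_genome(config: SimulationConfig) -> dict[str, str]:
    rng = _rng(config.seed, "genome")
    return {
        f"chr{i + 1}": "".join(
            rng.choice(list(BASES), size=config.chrom_length)
        )
        for i in range(config.n_chromosomes)
    }


def _spliced_to_genomic(
    exons: Sequence[tuple[int, int]], strand: str, offset: int, length: int
) -> list[tuple[int, int]]:
    """Genomic intervals of spliced positions [offset, offset+length) taken
    in transcription order."""
    order = list(exons) if strand == "+" else list(reversed(exons))
    out: list[tuple[int, int]] = []
    walked = 0
    remaining = length
    for s, e in order:
        exlen = e - s + 1
        if remaining <= 0:
            break
        skip = max(0, offset - walked)
        take = min(exlen - skip, remaining)
        if take > 0:
            if strand == "+":
                out.append((s + skip, s + skip + take - 1))
            else:
                out.append((e - skip - take + 1, e - skip))
            remaining -= take
        walked += exlen
    return sorted(out)


def _make_transcripts(
    config: SimulationConfig, genome: Mapping[str, str]
) -> list[TranscriptModel]:
    rng = _rng(config.seed, "transcripts")
    chroms = sorted(genome)
    cursors = {c: 500 for c in chroms}
    models: list[TranscriptModel] = []
    for i in range(config.n_transcripts):
        chrom = chroms[i % len(chroms)]
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(200, 801, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom]
        if start + span > len(genome[chrom]) - 500:
            continue  # chromosome full; generate fewer transcripts
        cursors[chrom] = start + span + int(rng.integers(200, 601))
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j]) - 1))
            pos = exons[-1][1] + 1 + (int(intron_lens[j]) if j < n_exons - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= config.frac_noncoding
        cds: tuple[tuple[int, int], ...] = ()
        spliced = int(exon_lens.sum())
        if coding:
            utr5 = int(rng.integers(50, 151))
            utr3 = int(rng.integers(80, 251))
            cds_len = spliced - utr5 - utr3
            cds_len -= cds_len % 3
            if cds_len >= 60:
                cds = tuple(_spliced_to_genomic(exons, strand, utr5, cds_len))
            else:
                coding = False
        models.append(
            TranscriptModel(
                transcript_id=f"TX{i:03d}",
                gene_id=f"GENE{i:03d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds=cds,
                biotype="coding" if coding else "lncRNA",
            )
        )
    return models


def _make_repeats(
    config: SimulationConfig,
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
) -> list[io_formats.RepeatInterval]:
    rng = _rng(config.seed, "repeats")
    repeats: list[io_formats.RepeatInterval] = []

    def place(length: int, prefer_transcript: bool) -> tuple[str, int]:
        if prefer_transcript and transcripts and rng.random() < 0.7:
            tx = transcripts[int(rng.integers(len(transcripts)))]
            hi = max(tx.start + 1, tx.end - length)
            return tx.chrom, int(rng.integers(tx.start, hi))
        chrom = sorted(genome)[int(rng.integers(len(genome)))]
        return chrom, int(rng.integers(1, len(genome[chrom]) - length))

    lo, hi = config.alu_length_range
    for _ in range(config.n_alu):
        length = int(rng.integers(lo, hi + 1))
        chrom, start = place(length, prefer_transcript=True)
        family = _ALU_FAMILIES[int(rng.integers(len(_ALU_FAMILIES)))]
        repeats.append(
            io_formats.RepeatInterval(chrom, start, start + length - 1, family)
        )
    for _ in range(max(4, config.n_alu // 2)):
        length = int(rng.integers(150, 601))
        chrom, start = place(length, prefer_transcript=False)
        family = _NONALU_FAMILIES[int(rng.integers(len(_NONALU_FAMILIES)))]
        repeats.append(
            io_formats.RepeatInterval(chrom, start, start + length - 1, family)
        )
    return repeats


# ---------------------------------------------------------------------------
# Planted variation
# ---------------------------------------------------------------------------


def _make_snps(
    config: SimulationConfig, genome: Mapping[str, str]
) -> list[tuple[str, int, str, str, tuple[str, str]]]:
    rng = _rng(config.seed, "snps")
    snps = []
    used: set[tuple[str, int]] = set()
    chroms = sorted(genome)
    while len(snps) < config.n_germline_snps:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, len(genome[chrom]) + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome[chrom][pos - 1]
        alt = sorted(set(BASES) - {ref})[int(rng.integers(3))]
        genotype = (ref, alt) if rng.random() < 0.7 else (alt, alt)
        snps.append((chrom, pos, ref, alt, genotype))
    return sorted(snps)


def _make_editing_sites(
    config: SimulationConfig,
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    repeats: Sequence[io_formats.RepeatInterval],
    snp_positions: set[tuple[str, int]],
) -> list[PlantedSite]:
    rng = _rng(config.seed, "editing")
    subsets = _pattern_subsets(config.samples, config.normal_sample)
    labels = sorted(config.pattern_weights)
    weights = np.array([config.pattern_weights[l] for l in labels])
    weights = weights / weights.sum()
    other_types = [
        (r, a) for r in BASES for a in BASES if r != a and (r, a) != ("A", "G")
    ]
    arrays = {c: np.frombuffer(genome[c].encode(), dtype="S1") for c in genome}
    alu_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        if r.is_alu:
            alu_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))

    used: set[tuple[str, int]] = set(snp_positions)
    sites: list[PlantedSite] = []
    lo, hi = config.editing_rate_range
    for _ in range(config.n_editing_sites):
        pattern = labels[int(rng.choice(len(labels), p=weights))]
        options = subsets[pattern]
        presence = options[int(rng.integers(len(options)))]
        a2g = rng.random() < config.frac_a_to_g
        t_ref, t_alt = ("A", "G") if a2g else other_types[int(rng.integers(11))]

        placed = None
        for _attempt in range(30):
            tx = transcripts[int(rng.integers(len(transcripts)))]
            g_ref = t_ref if tx.strand == "+" else COMPLEMENT[t_ref]
            g_alt = t_alt if tx.strand == "+" else COMPLEMENT[t_alt]
            span = arrays[tx.chrom][tx.start - 1 : tx.end]
            cand = np.nonzero(span == g_ref.encode())[0] + tx.start
            if a2g and rng.random() < 0.6:
                alus = alu_by_chrom.get(tx.chrom, [])
                in_alu = np.zeros(len(cand), dtype=bool)
                for s, e in alus:
                    in_alu |= (cand >= s) & (cand <= e)
                if in_alu.any():
                    cand = cand[in_alu]
            cand = [int(p) for p in cand if (tx.chrom, int(p)) not in used]
            if cand:
                pos = cand[int(rng.integers(len(cand)))]
                placed = (tx, pos, g_ref, g_alt)
                break
        if placed is None:
            continue
        tx, pos, g_ref, g_alt = placed
        used.add((tx.chrom, pos))
        region = tx.region_at(pos)
        effect = None
        if region == "CDS":
            effect = _recoding_effect(tx, genome, pos, g_alt)
        sites.append(
            PlantedSite(
                chrom=tx.chrom,
                pos=pos,
                ref=g_ref,
                alt=g_alt,
                strand=tx.strand,
                editing_type=f"{t_ref}-to-{t_alt}",
                transcript_id=tx.transcript_id,
                region=region,
                presence=presence,
                rates={
                    s: float(rng.uniform(lo, hi)) for s in sorted(presence)
                },
                recoding_effect=effect,
            )
        )
    return sorted(sites, key=lambda s: (s.chrom, s.pos))


def _recoding_effect(
    tx: TranscriptModel, genome: Mapping[str, str], pos: int, g_alt: str
) -> str | None:
    from Bio.Seq import Seq

    cds_seq = tx.cds_sequence(genome)
    if len(cds_seq) % 3 != 0:
        return None
    idx = tx.cds_index_of(pos)
    if idx is None:
        return None
    alt_tx = g_alt if tx.strand == "+" else COMPLEMENT[g_alt]
    codon_i, within = divmod(idx, 3)
    before = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    after = before[:within] + alt_tx + before[within + 1 :]
    return (
        "synonymous"
        if str(Seq(before).translate()) == str(Seq(after).translate())
        else "non-synonymous"
    )


# ---------------------------------------------------------------------------
# Pileups and naive calling
# ---------------------------------------------------------------------------


def simulate_pileup(
    truth: GroundTruth,
    sample: str,
    modality: str,
    depth: int,
    error_rate: float,
    seed: int,
    read_length: int = 90,
) -> list[PileupColumn]:
    """Simulate per-position read evidence for one sample and modality.

    RNA pileups cover transcript-overlapping positions only and show the
    edited base at the planted editing rate in samples where the site is
    present; DNA pileups show only reference/germline alleles plus error.
    RNA coverage of a position scales with the expression factor of its
    transcript (``depth`` is the transcriptome-wide mean), so coverage is
    dispersed as in real RNA-seq; DNA coverage is uniform. Read placement
    along each read is uniform, so the distance of the site to the read
    ends varies over [0, read_length-1].
    """
    if sample not in truth.samples:
        raise io_formats.InputError(f"unknown sample id {sample!r}")
    if modality not in ("DNA", "RNA"):
        raise io_formats.InputError(f"modality must be DNA or RNA, got {modality!r}")
    rng = _rng(seed, f"pileup:{modality}:{sample}")
    snps = {(c, p): (ref, alt, gt) for c, p, ref, alt, gt in truth.planted_snps}
    tx_by_span: dict[str, list[tuple[int, int, TranscriptModel]]] = {}
    for tx in truth.transcripts:
        tx_by_span.setdefault(tx.chrom, []).append((tx.start, tx.end, tx))

    columns: list[PileupColumn] = []
    counter = 0
    bases = list(BASES)
    for chrom, pos in truth.covered_positions:
        host_tx = next(
            (tx for s, e, tx in tx_by_span.get(chrom, []) if s <= pos <= e), None
        )
        if modality == "RNA" and host_tx is None:
            continue
        ref = truth.genome[chrom][pos - 1]
        mean_depth = depth
        if modality == "RNA" and host_tx is not None:
            mean_depth = depth * truth.expression_factors.get(
                (host_tx.transcript_id, sample), 1.0
            )
        n_reads = int(rng.poisson(mean_depth))
        if n_reads == 0:
            continue
        site = truth.site_at(chrom, pos)
        snp = snps.get((chrom, pos))
        col = PileupColumn(chrom=chrom, pos=pos, ref=ref)
        for _ in range(n_reads):
            offset = int(rng.integers(0, read_length))
            if snp is not None:
                _, _, gt = snp
                base = gt[int(rng.integers(2))]
            elif (
                site is not None
                and modality == "RNA"
                and sample in site.presence
                and rng.random() < site.rates[sample]
            ):
                base = site.alt
            else:
                base = ref
            if error_rate > 0 and rng.random() < error_rate:
                base = sorted(set(bases) - {base})[int(rng.integers(3))]
            qual = (
                int(rng.integers(10, 20))
                if rng.random() < 0.03
                else int(rng.integers(30, 41))
            )
            counter += 1
            col.observations.append(
                Observation(
                    base=base,
                    qual=qual,
                    dist5=offset,
                    dist3=read_length - 1 - offset,
                    read_id=f"{sample}.{modality}.r{counter}",
                )
            )
        columns.append(col)
    return columns


def naive_caller(
    columns: Sequence[PileupColumn],
    sample: str,
    modality: str,
    caller: str,
    min_alt_frac: float,
    min_alt_reads: int = 2,
) -> list[VariantCall]:
    """Threshold caller over pileup evidence, standing in for the external
    callers: an alternate allele with enough supporting reads and allele
    fraction becomes a variant; allele fraction >= 0.85 is called homozygous."""
    calls: list[VariantCall] = []
    for col in columns:
        counts = col.base_counts()
        depth = col.depth
        if depth == 0:
            continue
        for alt in sorted(counts):
            n_alt = counts[alt]
            if alt == col.ref or alt not in BASES:
                continue
            if n_alt < min_alt_reads or n_alt / depth < min_alt_frac:
                continue
            genotype = (alt, alt) if n_alt / depth >= 0.85 else (col.ref, alt)
            quals = [o.qual for o in col.supporting(alt)]
            calls.append(
                VariantCall(
                    chrom=col.chrom,
                    pos=col.pos,
                    ref=col.ref,
                    alt=alt,
                    sample=sample,
                    modality=modality,
                    caller=caller,
                    genotype=genotype,
                    depth=depth,
                    alt_support=n_alt,
                    base_qual=min(quals),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the full toy dataset under ``outdir``; returns the file map
    and the ground truth. The same seed yields byte-identical files."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = _make_genome(config)
    transcripts = _make_transcripts(config, genome)
    repeats = _make_repeats(config, genome, transcripts)
    snps = _make_snps(config, genome)
    snp_positions = {(c, p) for c, p, _, _, _ in snps}
    sites = _make_editing_sites(config, genome, transcripts, repeats, snp_positions)

    rng_bg = _rng(config.seed, "background")
    used = set(snp_positions) | {(s.chrom, s.pos) for s in sites}
    covered = set(used)
    chroms = sorted(genome)
    while len(covered) < len(used) + config.n_background_positions:
        chrom = chroms[int(rng_bg.integers(len(chroms)))]
        covered.add((chrom, int(rng_bg.integers(1, len(genome[chrom]) + 1))))

    # relative expression per (transcript, sample); lognormal with mean 1,
    # shared between the FPKM table and the RNA coverage model
    rng_expr = _rng(config.seed, "expression")
    sigma = 0.9
    expression_factors = {
        (tx.transcript_id, sample): float(
            rng_expr.lognormal(-sigma**2 / 2, sigma)
        )
        for tx in transcripts
        for sample in config.samples
    }

    truth = GroundTruth(
        planted_sites=sites,
        planted_snps=snps,
        expected_pattern={
            s.key: classify_pattern(s.presence, config.samples, config.normal_sample)
            for s in sites
        },
        genome=genome,
        transcripts=transcripts,
        covered_positions=sorted(covered),
        expression_factors=expression_factors,
        samples=config.samples,
    )

    files: dict[str, Path] = {}
    contigs = {c: len(genome[c]) for c in sorted(genome)}

    files["genome"] = outdir / "genome.fa"
    io_formats.write_fasta(genome, str(files["genome"]))
    files["genes"] = outdir / "genes.gtf"
    io_formats.write_gtf(transcripts, str(files["genes"]))
    files["repeats"] = outdir / "repeats.bed"
    io_formats.write_bed6(
        [(r.chrom, r.start, r.end, r.family, "+") for r in
         sorted(repeats, key=lambda r: (r.chrom, r.start))],
        str(files["repeats"]),
    )

    files["dbsnp"] = outdir / "dbsnp.vcf"
    _write_site_vcf(snps, contigs, str(files["dbsnp"]))
    rng_snp = _rng(config.seed, "snp_tables")
    subset = [s for s in snps if rng_snp.random() < 0.6]
    files["g1k"] = outdir / "g1k_snps.tsv"
    with open(files["g1k"], "w") as fh:
        fh.write("# chrom\tpos\n")
        for c, p, *_ in subset:
            fh.write(f"{c}\t{p}\n")

    for sample in config.samples:
        for modality, depth in (("DNA", config.dna_depth), ("RNA", config.rna_depth)):
            columns = simulate_pileup(
                truth,
                sample,
                modality,
                depth,
                config.seq_error_rate,
                config.seed,
                config.read_length,
            )
            key = f"pileup_{modality}_{sample}"
            files[key] = outdir / f"{key}.tsv"
            io_formats.write_pileup(columns, str(files[key]))
            for caller in sorted(_CALLER_MIN_FRAC):
                calls = naive_caller(
                    columns, sample, modality, caller, _CALLER_MIN_FRAC[caller]
                )
                vkey = f"{modality}_{caller}_{sample}_vcf"
                files[vkey] = outdir / f"{modality.lower()}_{caller}_{sample}.vcf"
                io_formats.write_vcf(
                    calls, str(files[vkey]), contigs, sample_name=sample
                )

    files["expression"] = outdir / "expression.tsv"
    with open(files["expression"], "w") as fh:
        fh.write("# transcript_id\tsample\tfpkm\n")
        for tx in transcripts:
            for sample in config.samples:
                fpkm = round(10.0 * expression_factors[(tx.transcript_id, sample)], 3)
                fh.write(f"{tx.transcript_id}\t{sample}\t{fpkm}\n")

    rng_mir = _rng(config.seed, "mirna")
    target_rows = []
    for tx in transcripts:
        if tx.biotype != "coding":
            continue
        for s, e in tx.utr3:
            if rng_mir.random() < 0.3 or e - s + 1 < 10:
                continue
            for _ in range(int(rng_mir.integers(1, 4))):
                length = int(rng_mir.integers(8, 23))
                if e - s + 1 <= length:
                    continue
                start = int(rng_mir.integers(s, e - length + 1))
                name = _MIRNA_POOL[int(rng_mir.integers(len(_MIRNA_POOL)))]
                target_rows.append((tx.chrom, start, start + length - 1, name, tx.strand))
    files["mirna_targets"] = outdir / "mirna_targets.bed"
    io_formats.write_bed6(sorted(target_rows), str(files["mirna_targets"]))

    rng_dmg = _rng(config.seed, "damaging")
    files["damaging"] = outdir / "damaging.tsv"
    with open(files["damaging"], "w") as fh:
        fh.write("# chrom\tpos\teffect\n")
        for s in sites:
            if s.recoding_effect == "non-synonymous":
                label = "damaging" if rng_dmg.random() < 0.5 else "tolerated"
                fh.write(f"{s.chrom}\t{s.pos}\t{label}\n")

    return files, truth


def _write_site_vcf(
    snps: Sequence[tuple[str, int, str, str, tuple[str, str]]],
    contigs: Mapping[str, int],
    path: str,
) -> None:
    header = pysam.VariantHeader()
    for name in contigs:
        header.contigs.add(name, length=contigs[name])
    with pysam.VariantFile(path, "w", header=header) as out:
        for chrom, pos, ref, alt, _gt in snps:
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=(ref, alt)
            )
            out.write(rec)


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------


def eligible_presence(
    truth: GroundTruth,
    rna_pileups: Mapping[str, Mapping[tuple[str, int], PileupColumn]],
    dna_pileups: Mapping[str, Mapping[tuple[str, int], PileupColumn]] | None = None,
    config: FilterConfig | None = None,
) -> dict[tuple, frozenset[str]]:
    """Samples in which each planted site satisfies the evidence thresholds.

    A (site, sample) pair is eligible when the site is planted present there,
    its RNA pileup passes all four filters for the planted alternate allele,
    and (when DNA pileups are given) the DNA position is covered at the
    minimum depth. Sensitivity of the pipeline is measured against these
    pairs: a planted event whose simulated evidence fails the thresholds is
    not recoverable by construction.
    """
    config = config or FilterConfig()
    out: dict[tuple, frozenset[str]] = {}
    for site in truth.planted_sites:
        ok: set[str] = set()
        for sample in sorted(site.presence):
            col = rna_pileups[sample].get((site.chrom, site.pos))
            if col is None or _first_failed_filter(col, site.alt, config) is not None:
                continue
            if dna_pileups is not None:
                dcol = dna_pileups[sample].get((site.chrom, site.pos))
                if dcol is None or dcol.depth < config.min_depth:
                    continue
            ok.add(sample)
        out[site.key] = frozenset(ok)
    return out


def detection_metrics(
    truth: GroundTruth,
    detected_by_sample: Mapping[str, set[tuple[str, int, str, str]]],
    eligible: Mapping[tuple, frozenset[str]],
) -> dict[str, float]:
    """Sensitivity/precision of detected (site, sample) pairs against the
    planted truth, plus the count of germline SNP positions reported."""
    eligible_pairs = {
        (key, s) for key, samples in eligible.items() for s in samples
    }
    planted_pairs = {
        (site.key, s) for site in truth.planted_sites for s in site.presence
    }
    detected_pairs = {
        (key, sample)
        for sample in detected_by_sample
        for key in detected_by_sample[sample]
    }
    tp_eligible = len(detected_pairs & eligible_pairs)
    tp_planted = len(detected_pairs & planted_pairs)
    snp_positions = truth.snp_positions
    germline_reported = len(
        {
            key
            for key, _sample in detected_pairs
            if (key[0], key[1]) in snp_positions
        }
    )
    return {
        "n_eligible_pairs": len(eligible_pairs),
        "n_detected_pairs": len(detected_pairs),
        "sensitivity": tp_eligible / len(eligible_pairs) if eligible_pairs else float("nan"),
        "precision": tp_planted / len(detected_pairs) if detected_pairs else float("nan"),
        "germline_reported": germline_reported,
    }
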