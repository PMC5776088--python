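"""End-to-end orchestration: simulate (or load inputs) → detect → annotate →
classify → analyze, with a run manifest for reproducibility.

All tabular outputs are TSV with a header line beginning '#'. Given fixed
inputs and seed, two runs produce byte-identical stage outputs; the manifest
records the configuration snapshot, input checksums and per-stage record
counts (consistent: in = out + removed at every stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from . import io_formats
from .annotation import (
    AnnotatedSite,
    assign_gene_context,
    assign_repeat_context,
    region_distribution,
)
from .editing_detection import DetectionResult, FilterConfig, detect_sample
from .functional_impact import (
    EXPRESSION_CATEGORIES,
    call_recoding,
    damaging_gene_lists,
    expression_change_test,
    mirna_target_enrichment,
)
from .io_formats import DEFAULT_SAMPLES, InputError
from .pattern_classification import (
    classify_sites,
    overlap_table,
    pattern_counts,
    stage_specific_fraction,
)
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    detection_metrics,
    eligible_presence,
)

logger = logging.getLogger(__name__)


class ConfigurationError(InputError):
    """Pipeline configuration is incomplete; names the missing piece."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "editome_run"
    simulate: bool = True
    sim: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    filters: FilterConfig = field(default_factory=FilterConfig)
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    normal_sample: str = "NL"
    callers: tuple[str, ...] = ("gatk", "varscan")


@dataclass
class RunResult:
    outdir: Path
    manifest: dict[str, Any]
    detections: dict[str, DetectionResult]
    annotated: list[AnnotatedSite]
    assignments: dict
    truth: GroundTruth | None = None


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _required_inputs(config: PipelineConfig) -> list[str]:
    keys = ["genome", "genes", "repeats", "expression", "mirna_targets"]
    for sample in config.samples:
        for modality in ("DNA", "RNA"):
            keys.append(f"pileup_{modality}_{sample}")
            for caller in config.callers:
                keys.append(f"{modality}_{caller}_{sample}_vcf")
    return keys


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Run every stage; outputs are written under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    if config.simulate:
        from .synthetic_data import generate_dataset

        sim = config.sim or SimulationConfig(seed=config.seed)
        files, truth = generate_dataset(sim, outdir / "data")
        files = {k: str(v) for k, v in files.items()}
        snp_table_paths = [files["dbsnp"], files["g1k"]]
    else:
        files = dict(config.inputs)
        missing = [k for k in _required_inputs(config) if k not in files]
        if missing:
            raise ConfigurationError(f"missing input(s): {', '.join(missing)}")
        snp_table_paths = [
            files[k] for k in sorted(files) if k in ("dbsnp", "g1k")
        ] or [files[k] for k in sorted(files) if k.startswith("snp")]
    for key in sorted(files):
        if not Path(files[key]).exists():
            raise ConfigurationError(f"input file for {key!r} not found: {files[key]}")

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "simulate": config.simulate,
            "samples": list(config.samples),
            "normal_sample": config.normal_sample,
            "filters": asdict(config.filters),
            "sim": asdict(config.sim) if config.sim else asdict(SimulationConfig(seed=config.seed)) if config.simulate else None,
        },
        "input_checksums": {k: _sha256(files[k]) for k in sorted(files)},
        "stages": {},
        "status": "running",
    }

    try:
        result = _run_stages(config, files, snp_table_paths, outdir, manifest, truth)
    except Exception:
        manifest["status"] = "failed"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    manifest["status"] = "ok"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def _run_stages(
    config: PipelineConfig,
    files: Mapping[str, str],
    snp_table_paths: list[str],
    outdir: Path,
    manifest: dict[str, Any],
    truth: GroundTruth | None,
) -> RunResult:
    genome = io_formats.read_fasta(files["genome"])
    transcripts = io_formats.read_gtf(files["genes"])
    repeats = io_formats.read_repeats_bed(files["repeats"])
    snp_tables = [io_formats.read_snp_positions(p) for p in snp_table_paths]

    # ---- detect ----------------------------------------------------------
    detections: dict[str, DetectionResult] = {}
    rna_pileups: dict[str, dict] = {}
    dna_pileups: dict[str, dict] = {}
    for sample in config.samples:
        rna_pileups[sample] = io_formats.read_pileup(files[f"pileup_RNA_{sample}"])
        dna_pileups[sample] = io_formats.read_pileup(files[f"pileup_DNA_{sample}"])
        dna_calls = {
            caller: io_formats.read_vcf(
                files[f"DNA_{caller}_{sample}_vcf"], sample, "DNA", caller
            )
            for caller in config.callers
        }
        rna_calls = {
            caller: io_formats.read_vcf(
                files[f"RNA_{caller}_{sample}_vcf"], sample, "RNA", caller
            )
            for caller in config.callers
        }
        det = detect_sample(
            sample=sample,
            dna_calls_by_caller=dna_calls,
            rna_calls_by_caller=rna_calls,
            reference=genome,
            rna_pileups=rna_pileups[sample],
            dna_pileups=dna_pileups[sample],
            snp_tables=snp_tables,
            config=config.filters,
        )
        detections[sample] = det
        rows = [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.rna_alt,
                "sample": sample,
                "depth": s.depth,
                "alt_reads": s.alt_support,
                "min_qual": min(
                    (o.qual for o in s.evidence.supporting(s.rna_alt)), default=""
                )
                if s.evidence
                else "",
                "min_end_dist": min(
                    (min(o.dist5, o.dist3) for o in s.evidence.supporting(s.rna_alt)),
                    default="",
                )
                if s.evidence
                else "",
                "provenance": s.provenance,
            }
            for s in det.sites
        ]
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=[
                    "chrom", "pos", "ref", "alt", "sample", "depth", "alt_reads",
                    "min_qual", "min_end_dist", "provenance",
                ],
            ),
            outdir / f"sites_{sample}.tsv",
        )
        manifest["stages"][f"detect_{sample}"] = det.funnel

    # ---- annotate --------------------------------------------------------
    unique: dict[tuple, Any] = {}
    for sample in config.samples:
        for s in detections[sample].sites:
            unique.setdefault(s.key, s)
    annotated, discarded = assign_gene_context(
        [unique[k] for k in sorted(unique)], transcripts
    )
    annotated = assign_repeat_context(annotated, repeats)
    manifest["stages"]["annotate"] = {
        "unique_sites": len(unique),
        "annotated": len(annotated),
        "discarded": len(discarded),
        "discarded_unannotated": sum(
            1 for d in discarded if d.reason == "unannotated"
        ),
        "discarded_strand_ambiguous": sum(
            1 for d in discarded if d.reason == "strand-ambiguous"
        ),
    }
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom": a.chrom, "pos": a.pos, "ref": a.ref, "alt": a.alt,
                    "transcript_id": a.transcript_id, "biotype": a.gene_biotype,
                    "region": a.region, "strand": a.strand,
                    "editing_type": a.editing_type,
                    "repeat_context": a.repeat_context,
                }
                for a in annotated
            ],
            columns=[
                "chrom", "pos", "ref", "alt", "transcript_id", "biotype",
                "region", "strand", "editing_type", "repeat_context",
            ],
        ),
        outdir / "annotated_sites.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [
                {"chrom": d.chrom, "pos": d.pos, "ref": d.ref, "alt": d.alt,
                 "discard_reason": d.reason}
                for d in discarded
            ],
            columns=["chrom", "pos", "ref", "alt", "discard_reason"],
        ),
        outdir / "discarded_sites.tsv",
    )

    # ---- classify --------------------------------------------------------
    annotated_by_pos = {(a.chrom, a.pos, a.ref, a.alt): a for a in annotated}
    sets_by_sample = {
        sample: {
            annotated_by_pos[s.key].key
            for s in detections[sample].sites
            if s.key in annotated_by_pos
        }
        for sample in config.samples
    }
    presence_by_site: dict[tuple, frozenset] = {}
    for sample in config.samples:
        for key in sets_by_sample[sample]:
            presence_by_site.setdefault(key, frozenset())
            presence_by_site[key] = presence_by_site[key] | {sample}
    assignments = classify_sites(
        presence_by_site, config.samples, config.normal_sample
    )
    for a in annotated:
        assignment = assignments.get(a.key)
        if assignment is not None:
            a.presence = assignment.presence
            a.pattern = assignment.pattern
    venn = overlap_table(sets_by_sample, config.samples)
    counts = pattern_counts(assignments)
    frac = stage_specific_fraction(assignments) if assignments else None
    manifest["stages"]["classify"] = {
        "sites_classified": len(assignments),
        "pattern_counts": counts,
        "stage_specific_fraction": frac,
    }
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
                    "strand": k[4],
                    "presence": ",".join(sorted(assignments[k].presence)),
                    "pattern": assignments[k].pattern,
                }
                for k in sorted(assignments)
            ],
            columns=["chrom", "pos", "ref", "alt", "strand", "presence", "pattern"],
        ),
        outdir / "patterns.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [
                {"subset": ",".join(s for s in config.samples if s in key),
                 "count": venn[key]}
                for key in sorted(
                    venn, key=lambda k: (len(k), tuple(sorted(k)))
                )
            ],
            columns=["subset", "count"],
        ),
        outdir / "venn_counts.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [{"pattern": p, "count": n} for p, n in counts.items()],
            columns=["pattern", "count"],
        ),
        outdir / "pattern_counts.tsv",
    )

    # ---- analyze ---------------------------------------------------------
    _write_tsv(region_distribution(annotated), outdir / "region_distribution.tsv")
    spectra = (
        pd.DataFrame(
            [
                {"editing_type": a.editing_type, "repeat_context": a.repeat_context}
                for a in annotated
            ],
            columns=["editing_type", "repeat_context"],
        )
        .groupby(["repeat_context", "editing_type"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    _write_tsv(spectra, outdir / "type_spectra.tsv")

    utr3_sites = [a for a in annotated if a.region == "UTR3"]
    utr3_universe: dict[str, list[tuple[int, int]]] = {}
    for tx in transcripts:
        for iv in tx.utr3:
            utr3_universe.setdefault(tx.chrom, []).append(iv)
    targets = io_formats.read_targets_bed(files["mirna_targets"])
    analyze_stage: dict[str, Any] = {"utr3_sites": len(utr3_sites)}
    if utr3_sites:
        enrichment, ranking = mirna_target_enrichment(
            utr3_sites, targets, utr3_universe
        )
        _write_tsv(
            pd.DataFrame(
                [{"k": enrichment.k, "n": enrichment.n, "K": enrichment.K,
                  "N": enrichment.N, "p_value": enrichment.p_value,
                  "target_fraction": enrichment.target_fraction}]
            ),
            outdir / "mirna_enrichment.tsv",
        )
        _write_tsv(ranking, outdir / "mirna_ranking.tsv")
        analyze_stage["mirna_target_fraction"] = enrichment.target_fraction
        analyze_stage["mirna_enrichment_p"] = enrichment.p_value
    else:
        logger.info("no 3'UTR sites: miRNA enrichment skipped")

    cds_sites = [a for a in annotated if a.region == "CDS"]
    damaging = (
        io_formats.read_damaging_table(files["damaging"])
        if "damaging" in files
        else None
    )
    recoding = call_recoding(cds_sites, transcripts, genome, damaging)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                    "transcript_id": r.transcript_id,
                    "codon_before": r.codon_before, "codon_after": r.codon_after,
                    "aa_before": r.aa_before, "aa_after": r.aa_after,
                    "effect": r.effect,
                    "damaging_label": r.damaging_label or "",
                }
                for r in recoding
            ],
            columns=[
                "chrom", "pos", "ref", "alt", "transcript_id", "codon_before",
                "codon_after", "aa_before", "aa_after", "effect", "damaging_label",
            ],
        ),
        outdir / "recoding.tsv",
    )
    n_nonsyn = sum(1 for r in recoding if r.effect == "non-synonymous")
    analyze_stage["cds_sites"] = len(cds_sites)
    analyze_stage["recoding_calls"] = len(recoding)
    analyze_stage["nonsynonymous_fraction"] = (
        n_nonsyn / len(recoding) if recoding else None
    )

    expression = io_formats.read_expression(files["expression"])
    target_keys = _target_site_keys(utr3_sites, targets)
    ks_frames = []
    tumor_samples = [s for s in config.samples if s != config.normal_sample]
    for tumor in tumor_samples:
        categories = _expression_categories(
            annotated, tumor, config.normal_sample, target_keys
        )
        ks_frames.append(
            expression_change_test(categories, expression, tumor, config.normal_sample)
        )
    ks = (
        pd.concat(ks_frames, ignore_index=True)
        if ks_frames
        else pd.DataFrame(columns=["sample", "category", "n", "D", "p_value", "skipped"])
    )
    _write_tsv(ks, outdir / "ks_expression.tsv")

    presence_map = {a.key: sorted(a.presence) for a in annotated if a.presence}
    gene_lists = damaging_gene_lists(recoding, presence_map)
    for sample in config.samples:
        (outdir / f"genelist_{sample}.txt").write_text(
            "\n".join(gene_lists.get(sample, [])) + ("\n" if gene_lists.get(sample) else "")
        )
    analyze_stage["damaging_gene_list_sizes"] = {
        s: len(gene_lists.get(s, [])) for s in config.samples
    }
    manifest["stages"]["analyze"] = analyze_stage

    # ---- evaluation against ground truth (simulated runs) ---------------
    if truth is not None:
        eligible = eligible_presence(
            truth, rna_pileups, dna_pileups, FilterConfig(**asdict(config.filters))
        )
        detected_by_sample = {
            sample: {s.key for s in detections[sample].sites}
            for sample in config.samples
        }
        manifest["evaluation"] = detection_metrics(
            truth, detected_by_sample, eligible
        )

    return RunResult(
        outdir=outdir,
        manifest=manifest,
        detections=detections,
        annotated=annotated,
        assignments=assignments,
        truth=truth,
    )


def _target_site_keys(utr3_sites, targets) -> set[tuple]:
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, _name in targets:
        trees.setdefault(chrom, IntervalTree()).addi(s, e + 1)
    return {
        a.key
        for a in utr3_sites
        if trees.get(a.chrom) and trees[a.chrom][a.pos]
    }


def _expression_categories(
    annotated, tumor: str, normal: str, target_keys: set[tuple]
) -> dict[str, set[str]]:
    """Transcripts edited in the tumor sample but not in the non-cancerous
    liver, grouped by editing category."""
    categories: dict[str, set[str]] = {c: set() for c in EXPRESSION_CATEGORIES}
    for a in annotated:
        if not a.presence or tumor not in a.presence or normal in a.presence:
            continue
        if a.region == "UTR5":
            categories["UTR5"].add(a.transcript_id)
        elif a.region == "CDS":
            categories["CDS"].add(a.transcript_id)
        elif a.region == "UTR3":
            if a.key in target_keys:
                categories["miRNA-target UTR3"].add(a.transcript_id)
            else:
                categories["non-target UTR3"].add(a.transcript_id)
        elif a.region == "Intron":
            categories["Intron"].add(a.transcript_id)
    return categories
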