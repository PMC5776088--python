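"""Detection cascade: caller merging, RNA-DNA difference logic, the four
evidence filters (with a brute-force oracle), and germline subtraction."""

import random

import pytest

from editomescan.editing_detection import (
    CandidateSite,
    EvidenceMissingError,
    FilterConfig,
    apply_site_filters,
    detect_sample,
    identify_rdd,
    merge_dna_calls,
    merge_rna_calls,
    subtract_germline,
)
from editomescan.io_formats import (
    InputError,
    Observation,
    PileupColumn,
    VariantCall,
)


def _call(pos, alt="G", ref="A", modality="RNA", caller="gatk", sample="PT",
          genotype=None, depth=30, support=10, qual=35):
    return VariantCall(
        chrom="chr1", pos=pos, ref=ref, alt=alt, sample=sample,
        modality=modality, caller=caller,
        genotype=genotype or (ref, alt), depth=depth, alt_support=support,
        base_qual=qual,
    )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def test_dna_merge_is_union_rna_merge_is_intersection():
    a = [_call(1, modality="DNA"), _call(2, modality="DNA")]
    b = [_call(2, modality="DNA"), _call(3, modality="DNA")]
    union = merge_dna_calls({"gatk": a, "varscan": b})
    assert sorted(c.pos for c in union) == [1, 2, 3]

    a = [_call(1), _call(2)]
    b = [_call(2), _call(3)]
    inter = merge_rna_calls({"gatk": a, "varscan": b})
    assert [c.pos for c in inter] == [2]


def test_merge_empty_and_idempotent():
    assert merge_dna_calls({"gatk": [], "varscan": []}) == []
    assert merge_rna_calls({"gatk": [], "varscan": []}) == []
    calls = [_call(1, modality="DNA"), _call(5, modality="DNA")]
    assert len(merge_dna_calls({"gatk": calls, "varscan": calls})) == len(calls)


def test_rna_subset_intersection():
    a = [_call(1), _call(2)]
    b = a + [_call(3)]
    assert sorted(c.pos for c in merge_rna_calls({"x": a, "y": b})) == [1, 2]


def test_union_contains_intersection():
    rng = random.Random(7)
    a = [_call(p) for p in rng.sample(range(1, 200), 40)]
    b = [_call(p) for p in rng.sample(range(1, 200), 40)]
    dna_a = [_call(c.pos, modality="DNA") for c in a]
    dna_b = [_call(c.pos, modality="DNA") for c in b]
    union = {c.key for c in merge_dna_calls({"x": dna_a, "y": dna_b})}
    inter = {c.key for c in merge_rna_calls({"x": a, "y": b})}
    assert inter <= union


def test_merge_modality_mismatch_rejected():
    with pytest.raises(InputError, match="DNA"):
        merge_dna_calls({"gatk": [_call(1, modality="RNA")]})
    with pytest.raises(InputError, match="RNA"):
        merge_rna_calls({"gatk": [_call(1, modality="DNA")]})


def test_merge_combines_evidence_from_deeper_caller():
    a = _call(9, modality="DNA", depth=40, support=18, genotype=("A", "G"), qual=31)
    b = _call(9, modality="DNA", depth=25, support=20, genotype=("G", "G"), qual=28)
    (merged,) = merge_dna_calls({"gatk": [a], "varscan": [b]})
    assert merged.depth == 40
    assert merged.alt_support == 20
    assert merged.genotype == ("A", "G")  # from the deeper caller
    assert merged.base_qual == 28


# ---------------------------------------------------------------------------
# RNA-DNA difference identification
# ---------------------------------------------------------------------------

REF = {"chr1": "A" * 1000}


def _dna_col(pos, depth=30):
    return {
        ("chr1", pos): PileupColumn(
            "chr1", pos, "A",
            [Observation("A", 35, 40, 49, f"d{i}") for i in range(depth)],
        )
    }


def test_rdd_kept_when_dna_is_reference():
    rna = [_call(100)]
    out = identify_rdd(rna, [], REF, dna_pileups=_dna_col(100))
    assert len(out) == 1
    assert out[0].dna_genotype == ("A", "A")
    assert out[0].rna_alt == "G"


def test_rdd_removed_when_genotypes_match():
    rna = [_call(100, genotype=("A", "G"))]
    dna = [_call(100, modality="DNA", genotype=("A", "G"))]
    assert identify_rdd(rna, dna, REF) == []


def test_rdd_kept_when_genotypes_differ_despite_dna_variant():
    rna = [_call(100, genotype=("G", "G"))]
    dna = [_call(100, modality="DNA", genotype=("A", "G"))]
    out = identify_rdd(rna, dna, REF)
    assert len(out) == 1


def test_rdd_removed_with_two_alternate_types():
    obs = (
        [Observation("A", 35, 40, 49, f"r{i}") for i in range(10)]
        + [Observation("G", 35, 40, 49, "g1"), Observation("G", 35, 41, 48, "g2")]
        + [Observation("T", 35, 42, 47, "t1"), Observation("T", 35, 43, 46, "t2")]
    )
    pileups = {("chr1", 100): PileupColumn("chr1", 100, "A", obs)}
    rna = [_call(100)]
    assert identify_rdd(rna, [], REF, rna_pileups=pileups) == []
    # a single stray error read of a second type does not kill the site
    pileups[("chr1", 100)].observations = obs[:-1]
    assert len(identify_rdd(rna, [], REF, rna_pileups=pileups)) == 1


def test_rdd_discards_dna_uncovered_positions():
    rna = [_call(100)]
    assert identify_rdd(rna, [], REF, dna_pileups=_dna_col(100, depth=3)) == []
    assert identify_rdd(rna, [], REF, dna_pileups={}) == []


def test_rdd_reference_lookup_error():
    with pytest.raises(InputError, match="reference"):
        identify_rdd([_call(100)], [], {"chr9": "A"})


# ---------------------------------------------------------------------------
# the four site filters
# ---------------------------------------------------------------------------


def _column(n_ref=3, supp=((20, 15), (20, 15)), read_length=90):
    """Pileup with n_ref reference reads and supporting reads given as
    (qual, nearer_end_distance) pairs."""
    obs = [Observation("A", 35, 40, read_length - 41, f"r{i}") for i in range(n_ref)]
    for i, (q, d) in enumerate(supp):
        obs.append(Observation("G", q, d, read_length - 1 - d, f"s{i}"))
    return PileupColumn("chr1", 100, "A", obs)


def _candidate():
    return CandidateSite(
        chrom="chr1", pos=100, ref="A", rna_alt="G", sample="PT",
        dna_genotype=("A", "A"), rna_genotype=("A", "G"),
    )


def test_filters_pass_at_exact_thresholds():
    """depth 5, two supporting reads at qual 20 and end distance 15: every
    threshold is met at its boundary and the site survives."""
    col = _column(n_ref=3, supp=((20, 15), (20, 20)))
    kept, audit = apply_site_filters([_candidate()], {("chr1", 100): col})
    assert len(kept) == 1
    assert audit == {"base_quality": 0, "depth": 0, "end_distance": 0, "alt_reads": 0}


@pytest.mark.parametrize(
    "col, failed",
    [
        (_column(n_ref=3, supp=((19, 15), (20, 20))), "base_quality"),
        (_column(n_ref=2, supp=((20, 15), (20, 20))), "depth"),
        (_column(n_ref=3, supp=((20, 14), (20, 20))), "end_distance"),
        (_column(n_ref=4, supp=((20, 15),)), "alt_reads"),
    ],
)
def test_each_filter_catches_its_boundary_violation(col, failed):
    kept, audit = apply_site_filters([_candidate()], {("chr1", 100): col})
    assert kept == []
    assert audit[failed] == 1
    assert sum(audit.values()) == 1


def test_missing_pileup_is_an_error():
    with pytest.raises(EvidenceMissingError, match="chr1"):
        apply_site_filters([_candidate()], {})


def _brute_force_survives(col, alt, cfg):
    """Independent re-evaluation of the four predicates."""
    supp = [o for o in col.observations if o.base == alt]
    if any(o.qual < cfg.min_base_qual for o in supp):
        return False
    if len(col.observations) < cfg.min_depth:
        return False
    if any(min(o.dist5, o.dist3) < cfg.min_end_distance for o in supp):
        return False
    return len(supp) >= cfg.min_alt_reads


def test_filters_match_brute_force_oracle_on_random_columns():
    rng = random.Random(42)
    cfg = FilterConfig()
    n_checked = 0
    for i in range(1000):
        depth = rng.randint(0, 12)
        obs = []
        for j in range(depth):
            base = rng.choice("AG")
            qual = rng.randint(15, 40)
            d5 = rng.randint(0, 89)
            obs.append(Observation(base, qual, d5, 89 - d5, f"r{i}.{j}"))
        col = PileupColumn("chr1", 100, "A", obs)
        cand = _candidate()
        kept, _ = apply_site_filters([cand], {("chr1", 100): col}, cfg)
        assert bool(kept) == _brute_force_survives(col, "G", cfg), f"case {i}"
        n_checked += 1
    assert n_checked == 1000


# ---------------------------------------------------------------------------
# germline subtraction
# ---------------------------------------------------------------------------


def test_germline_subtraction_semantics():
    sites = [_candidate()]
    kept, counts = subtract_germline(sites, [{("chr1", 100)}, set()])
    assert kept == [] and counts == [1, 0]
    # a site present in both tables is removed once, counted once per table
    kept, counts = subtract_germline(sites, [{("chr1", 100)}, {("chr1", 100)}])
    assert kept == [] and counts == [1, 1]
    kept, counts = subtract_germline(sites, [])
    assert kept == sites and counts == []
    kept, counts = subtract_germline(sites, [set(), {("chr2", 5)}])
    assert kept == sites and counts == [0, 0]


# ---------------------------------------------------------------------------
# full cascade properties
# ---------------------------------------------------------------------------


def _shuffled_detect(small_dataset, order_seed):
    from editomescan import io_formats

    files, _ = small_dataset
    sample = "PT"
    genome = io_formats.read_fasta(str(files["genome"]))
    rna_p = io_formats.read_pileup(str(files[f"pileup_RNA_{sample}"]))
    dna_p = io_formats.read_pileup(str(files[f"pileup_DNA_{sample}"]))
    snps = [io_formats.read_snp_positions(str(files["dbsnp"]))]
    calls = {}
    for modality in ("DNA", "RNA"):
        calls[modality] = {}
        for caller in ("gatk", "varscan"):
            cs = io_formats.read_vcf(
                str(files[f"{modality}_{caller}_{sample}_vcf"]), sample, modality, caller
            )
            random.Random(order_seed).shuffle(cs)
            calls[modality][caller] = cs
    return detect_sample(
        sample=sample,
        dna_calls_by_caller=calls["DNA"],
        rna_calls_by_caller=calls["RNA"],
        reference=genome,
        rna_pileups=rna_p,
        dna_pileups=dna_p,
        snp_tables=snps,
    )


def test_detection_invariant_under_input_record_order(small_dataset):
    a = _shuffled_detect(small_dataset, order_seed=1)
    b = _shuffled_detect(small_dataset, order_seed=99)
    assert [s.key for s in a.sites] == [s.key for s in b.sites]
    assert a.funnel == b.funnel


def test_error_free_detection_has_perfect_precision(tmp_path):
    """With no sequencing error and SNP tables supplied, every detected site
    is a planted editing event present in that sample."""
    from editomescan.pipeline import PipelineConfig, run_pipeline
    from editomescan.synthetic_data import SimulationConfig

    sim = SimulationConfig(
        seed=23, seq_error_rate=0.0, n_chromosomes=1, chrom_length=40_000,
        n_transcripts=12, n_alu=12, n_germline_snps=20, n_editing_sites=80,
        n_background_positions=40,
    )
    res = run_pipeline(
        PipelineConfig(seed=23, outdir=str(tmp_path / "run"), sim=sim)
    )
    truth = res.truth
    planted = {
        (s.key, sample) for s in truth.planted_sites for sample in s.presence
    }
    detected = {
        (site.key, sample)
        for sample, det in res.detections.items()
        for site in det.sites
    }
    assert detected, "expected at least one detected site"
    assert detected <= planted
    assert res.manifest["evaluation"]["precision"] == 1.0
    assert res.manifest["evaluation"]["germline_reported"] == 0
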