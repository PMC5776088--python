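"""Hypergeometric enrichment, codon recoding, and KS expression tests,
each checked against an independent oracle."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from editomescan.annotation import AnnotatedSite
from editomescan.functional_impact import (
    damaging_gene_lists,
    call_recoding,
    expression_change_test,
    log2_expression_change,
    mirna_target_enrichment,
)
from editomescan.io_formats import COMPLEMENT, InputError, TranscriptModel


def _site(pos, chrom="chr1", ref="A", alt="G", region="UTR3", tx="TX0",
          strand="+", presence=()):
    return AnnotatedSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, transcript_id=tx, gene_id=f"G_{tx}",
        gene_biotype="coding", region=region, strand=strand,
        editing_type="A-to-G", presence=frozenset(presence),
    )


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------


def _hypergeom_upper_tail(k, N, K, n):
    """Direct PMF summation oracle: P[X >= k] for X ~ Hypergeom(N, K, n)."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


def test_enrichment_all_sites_in_targets_closed_form():
    """N=100, K=50, n=10, k=10: p = C(50,10)/C(100,10) ~ 5.93e-4."""
    universe = {"chr1": [(1, 100)]}
    targets = [("chr1", 1, 50, "miR-1")]
    sites = [_site(p) for p in range(10, 50, 4)]
    result, ranking = mirna_target_enrichment(sites, targets, universe)
    assert (result.k, result.n, result.K, result.N) == (10, 10, 50, 100)
    expected = math.comb(50, 10) / math.comb(100, 10)
    assert result.p_value == pytest.approx(expected, abs=1e-12)
    assert ranking.iloc[0]["mirna"] == "miR-1"
    assert ranking.iloc[0]["edited_targets"] == 10


def test_enrichment_zero_hits_gives_certain_event():
    universe = {"chr1": [(1, 100)]}
    targets = [("chr1", 1, 50, "miR-1")]
    sites = [_site(p) for p in range(60, 70)]
    result, _ = mirna_target_enrichment(sites, targets, universe)
    assert result.k == 0
    assert result.p_value == 1.0


def test_enrichment_target_fraction_mirror():
    """A site set built with 52 of 100 sites inside targets reports a 0.52
    target fraction."""
    universe = {"chr1": [(1, 200)]}
    targets = [("chr1", 1, 52, "miR-7")]
    sites = [_site(p) for p in range(1, 101)]
    result, _ = mirna_target_enrichment(sites, targets, universe)
    assert result.k == 52 and result.n == 100
    assert result.target_fraction == pytest.approx(0.52)


def test_enrichment_pvalue_matches_pmf_summation_oracle():
    rng = random.Random(13)
    for _ in range(25):
        N = rng.randint(50, 10_000)
        K = rng.randint(1, N)
        n = rng.randint(1, min(200, N))
        universe = {"chr1": [(1, N)]}
        targets = [("chr1", 1, K, "miR-1")]
        positions = rng.sample(range(1, N + 1), n)
        sites = [_site(p) for p in positions]
        result, _ = mirna_target_enrichment(sites, targets, universe)
        oracle = _hypergeom_upper_tail(result.k, N, K, n)
        assert result.p_value == pytest.approx(oracle, abs=1e-12)


def test_enrichment_errors():
    with pytest.raises(InputError, match="no 3'UTR sites"):
        mirna_target_enrichment([], [("chr1", 1, 10, "m")], {"chr1": [(1, 100)]})


def test_enrichment_multi_mirna_ranking():
    """A site in targets of two miRNAs counts once for k but once per miRNA;
    the edited-target total across miRNAs can therefore exceed k."""
    universe = {"chr1": [(1, 100)]}
    targets = [("chr1", 10, 30, "miR-2"), ("chr1", 20, 40, "miR-1")]
    sites = [_site(25), _site(35)]
    result, ranking = mirna_target_enrichment(sites, targets, universe)
    assert result.k == 2
    assert ranking["edited_targets"].sum() >= result.k
    # ties broken lexicographically
    assert list(ranking["mirna"]) == ["miR-1", "miR-2"]


# ---------------------------------------------------------------------------
# codon recoding
# ---------------------------------------------------------------------------


def _toy_genome(seq, chrom="chr1"):
    return {chrom: seq}


def test_recoding_known_codon_changes():
    # CDS: CAG GAA -> codon 1 CAG (Q), codon 2 GAA (E)
    genome = _toy_genome("TTTTCAGGAATTTT")
    tx = TranscriptModel("TX0", "G0", "chr1", "+", exons=((5, 10),),
                         cds=((5, 10),), biotype="coding")
    # A-to-G at codon position 2 of CAG: CGG, Q->R, non-synonymous
    calls = call_recoding([_site(6, region="CDS")], [tx], genome)
    assert calls[0].codon_before == "CAG" and calls[0].codon_after == "CGG"
    assert (calls[0].aa_before, calls[0].aa_after) == ("Q", "R")
    assert calls[0].effect == "non-synonymous"
    # A-to-G at position 3 of GAA: GAG, E->E, synonymous wobble
    calls = call_recoding([_site(10, region="CDS")], [tx], genome)
    assert calls[0].codon_before == "GAA" and calls[0].codon_after == "GAG"
    assert calls[0].effect == "synonymous"


def test_recoding_exhaustive_sweep_matches_translation_oracle():
    """Every A position of a toy 3-codon CDS, edited A-to-G, matches an
    independent whole-sequence translate-and-compare oracle."""
    cds_seq = "AAAGATACA"  # K D T
    genome = _toy_genome("TT" + cds_seq + "TT")
    tx = TranscriptModel("TX0", "G0", "chr1", "+", exons=((3, 11),),
                         cds=((3, 11),), biotype="coding")
    for i, base in enumerate(cds_seq):
        if base != "A":
            continue
        pos = 3 + i
        (call,) = call_recoding([_site(pos, region="CDS")], [tx], genome)
        mutated = cds_seq[:i] + "G" + cds_seq[i + 1 :]
        oracle_effect = (
            "synonymous"
            if str(Seq(cds_seq).translate()) == str(Seq(mutated).translate())
            else "non-synonymous"
        )
        assert call.effect == oracle_effect, f"position {pos}"
        assert call.codon_before == cds_seq[(i // 3) * 3 : (i // 3) * 3 + 3]


def test_recoding_minus_strand_and_spliced_codon():
    """On a minus-strand transcript the CDS is read on the reverse
    complement; a codon spanning an exon junction is assembled from spliced
    coordinates."""
    # genomic: exon2=(10,14), exon1=(18,21) on minus strand
    #          CDS transcribed 5'->3' = revcomp(genome[18..21]) + revcomp(genome[10..14])
    genome = {"chr1": "N" * 9 + "TCCAT" + "NNN" + "CATG" + "N" * 5}
    tx = TranscriptModel("TX0", "G0", "chr1", "-", exons=((10, 14), (18, 21)),
                         cds=((10, 14), (18, 21)), biotype="coding")
    cds_seq = tx.cds_sequence(genome)
    assert len(cds_seq) == 9
    # pick a genomic T whose transcribed base is A
    pos = 14  # genome T -> transcribed A (first CDS base on minus strand)
    assert genome["chr1"][pos - 1] == "T"
    (call,) = call_recoding(
        [_site(pos, region="CDS", ref="T", alt="C", strand="-")], [tx], genome
    )
    idx = tx.cds_index_of(pos)
    mutated = cds_seq[:idx] + "G" + cds_seq[idx + 1 :]
    oracle = (
        "synonymous"
        if str(Seq(cds_seq).translate()) == str(Seq(mutated).translate())
        else "non-synonymous"
    )
    assert call.codon_after == mutated[(idx // 3) * 3 : (idx // 3) * 3 + 3]
    assert call.effect == oracle


def test_recoding_flags_cds_not_divisible_by_three(caplog):
    genome = _toy_genome("TTTTCAGGATTTT")
    tx = TranscriptModel("TX0", "G0", "chr1", "+", exons=((5, 9),),
                         cds=((5, 9),), biotype="coding")
    calls = call_recoding([_site(7, region="CDS")], [tx], genome)
    assert calls == []


def test_recoding_joins_damaging_labels():
    genome = _toy_genome("TTTTCAGGAATTTT")
    tx = TranscriptModel("TX0", "G0", "chr1", "+", exons=((5, 10),),
                         cds=((5, 10),), biotype="coding")
    table = {("chr1", 6): "damaging"}
    (call,) = call_recoding([_site(6, region="CDS")], [tx], genome, table)
    assert call.damaging_label == "damaging"


def test_recoding_on_synthetic_truth(small_run):
    """Recoding effects for recovered CDS sites equal the effects recorded
    when the events were planted."""
    truth = small_run.truth
    expected = {
        s.key: s.recoding_effect for s in truth.planted_sites if s.region == "CDS"
    }
    cds_sites = [a for a in small_run.annotated if a.region == "CDS"]
    calls = call_recoding(cds_sites, truth.transcripts, truth.genome)
    assert calls, "expected at least one recovered CDS site"
    for c in calls:
        assert c.effect == expected[(c.chrom, c.pos, c.ref, c.alt)]


# ---------------------------------------------------------------------------
# expression change (Kolmogorov-Smirnov)
# ---------------------------------------------------------------------------


def _expression_frame(values_by_tid):
    rows = []
    for tid, (fpkm_t, fpkm_n) in values_by_tid.items():
        rows.append({"transcript_id": tid, "sample": "PT", "fpkm": fpkm_t})
        rows.append({"transcript_id": tid, "sample": "NL", "fpkm": fpkm_n})
    return pd.DataFrame(rows)


def test_ks_identical_to_background_is_null():
    expr = _expression_frame({f"T{i}": (i + 1.0, 2.0) for i in range(20)})
    result = expression_change_test(
        {"CDS": [f"T{i}" for i in range(20)]}, expr, "PT", "NL"
    )
    row = result.iloc[0]
    assert row["D"] == 0.0
    assert row["p_value"] == pytest.approx(1.0)


def _brute_force_ks(a, b):
    grid = np.sort(np.concatenate([a, b]))
    ecdf = lambda x, pts: np.searchsorted(np.sort(x), pts, side="right") / len(x)
    return np.max(np.abs(ecdf(a, grid) - ecdf(b, grid)))


def test_ks_statistic_matches_ecdf_supremum_oracle():
    rng = np.random.default_rng(8)
    values = {f"T{i}": (float(v), 1.0) for i, v in enumerate(rng.lognormal(0, 1, 60))}
    expr = _expression_frame(values)
    shifted = [f"T{i}" for i in range(15)]
    result = expression_change_test({"CDS": shifted}, expr, "PT", "NL")
    changes = log2_expression_change(expr, "PT", "NL")
    a = changes.loc[shifted].to_numpy()
    b = changes.to_numpy()
    assert result.iloc[0]["D"] == pytest.approx(_brute_force_ks(a, b), abs=1e-12)
    assert result.iloc[0]["n"] == 15


def test_ks_small_category_is_skipped():
    expr = _expression_frame({f"T{i}": (1.0, 1.0) for i in range(5)})
    result = expression_change_test({"CDS": ["T0"]}, expr, "PT", "NL")
    assert bool(result.iloc[0]["skipped"])
    assert np.isnan(result.iloc[0]["D"])


def test_transcripts_edited_in_normal_liver_are_excluded():
    from editomescan.pipeline import _expression_categories

    sites = [
        _site(10, region="CDS", tx="T_tumor", presence={"PT", "IM"}),
        _site(20, region="CDS", tx="T_both", presence={"NL", "PT"}),
        _site(30, region="UTR5", tx="T_other", presence={"IM"}),
    ]
    categories = _expression_categories(sites, tumor="PT", normal="NL",
                                        target_keys=set())
    assert categories["CDS"] == {"T_tumor"}
    assert all("T_both" not in v for v in categories.values())


# ---------------------------------------------------------------------------
# damaging gene lists
# ---------------------------------------------------------------------------


def test_damaging_gene_lists_presence_semantics():
    genome = _toy_genome("TTTTCAGGAATTTT")
    tx = TranscriptModel("TX0", "G0", "chr1", "+", exons=((5, 10),),
                         cds=((5, 10),), biotype="coding")
    (call,) = call_recoding(
        [_site(6, region="CDS")], [tx], genome, {("chr1", 6): "damaging"}
    )
    presence = {("chr1", 6, "A", "G", "+"): ["PT", "IM"]}
    lists = damaging_gene_lists([call], presence)
    assert lists == {"IM": ["G_TX0"], "PT": ["G_TX0"]}
    # no damaging calls -> empty lists
    (syn_call,) = call_recoding(
        [_site(10, region="CDS")], [tx], genome, {("chr1", 10): "damaging"}
    )
    assert damaging_gene_lists([syn_call], presence) == {}
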