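"""Refined PVS1: observed CDS construction, NMD prediction, decision tree."""

import pytest

from acmghl.config import EngineConfig
from acmghl.core import (
    ConsequenceKind,
    CriterionState,
    GenomicVariant,
    Strength,
    TranscriptModel,
)
from acmghl.pvs1 import (
    NMDReason,
    ObservedCDS,
    build_observed_cds,
    evaluate_pvs1,
    evaluate_start_loss,
    locate_ptc,
    predict_nmd,
    reference_cds_segments,
    revcomp,
)
from acmghl.resources import Genome, ResourceBundle
from acmghl.synthetic import GenePlan, _build_gene
import random


# ---------------------------------------------------------------------------
# observed coding sequence
# ---------------------------------------------------------------------------


def test_observed_cds_snv_changes_single_codon(fixture_set, bundle):
    gene = fixture_set.genes["TOYA"]
    t = gene.transcript
    v = gene.snv_at_cds(210, "T", None)  # planted CAA -> TAA
    ref = reference_cds_segments(t, bundle.genome).sequence
    obs = build_observed_cds(t, v, bundle.genome).sequence
    assert len(ref) == len(obs)
    diffs = [i for i, (x, y) in enumerate(zip(ref, obs)) if x != y]
    assert diffs == [210]
    assert obs[210:213] == "TAA"


def test_observed_cds_deletion_shifts_downstream(fixture_set, bundle):
    gene = fixture_set.genes["TOYA"]
    t = gene.transcript
    v = gene.deletion_at_cds(150, 1, None)
    ref = reference_cds_segments(t, bundle.genome).sequence
    obs = build_observed_cds(t, v, bundle.genome).sequence
    assert len(obs) == len(ref) - 1
    assert obs == ref[:150] + ref[151:]


def test_observed_cds_splice_donor_skips_adjacent_exon(fixture_set, bundle):
    gene = fixture_set.genes["TOYA"]
    t = gene.transcript
    donor = t.exons[1][1]  # first intron base after exon 2
    v = GenomicVariant("chr1", donor, fixture_set.genome_seqs["chr1"][donor], "T")
    obs = build_observed_cds(t, v, bundle.genome)
    lens = gene.exon_coding_lens()
    assert [len(s) for _, s in obs.segments] == [lens[0], lens[2], lens[3]]
    assert obs.sequence == gene.coding[:lens[0]] + gene.coding[lens[0] + lens[1]:]


def test_observed_cds_requires_cds_or_splice_overlap(fixture_set, bundle):
    t = fixture_set.genes["TOYA"].transcript
    # deep intronic position, outside both canonical windows
    gpos = t.exons[0][1] + 20
    v = GenomicVariant("chr1", gpos, fixture_set.genome_seqs["chr1"][gpos], "A"
                       if fixture_set.genome_seqs["chr1"][gpos] != "A" else "C")
    with pytest.raises(ValueError, match="not applicable"):
        build_observed_cds(t, v, bundle.genome)


# ---------------------------------------------------------------------------
# PTC location and NMD rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ATGTAACCC", 3),
        ("ATG" + "AAA" * 5, None),
        # stops in frame at codons 7 and 12: the 5'-closest wins
        ("ATG" + "GGC" * 6 + "TGA" + "GGC" * 4 + "TAA", 21),
        # out-of-frame TAA is invisible
        ("ATGATAAGC" + "TAG", 9),
    ],
)
def test_locate_ptc_scans_in_frame(seq, expected):
    assert locate_ptc(seq) == expected


def _obs(lens):
    return ObservedCDS(tuple((k, "A" * n) for k, n in enumerate(lens)))


def test_nmd_escape_reasons_in_quoted_order():
    # PTC 30 bases before the 3' end of the penultimate exon
    out = predict_nmd(_obs([250, 100, 60]), 320)
    assert (out.occurs, out.reason) == (False, NMDReason.PENULTIMATE_EXON_LAST50)
    # PTC 150 bases downstream of the start codon
    out = predict_nmd(_obs([250, 100, 60]), 150)
    assert (out.occurs, out.reason) == (False, NMDReason.WITHIN_200BP_OF_START)
    # intronless transcript
    out = predict_nmd(_obs([400]), 300)
    assert (out.occurs, out.reason) == (False, NMDReason.INTRONLESS)
    # none of the three conditions: NMD occurs
    out = predict_nmd(_obs([250, 100, 80, 60]), 260)
    assert (out.occurs, out.reason) == (True, NMDReason.NMD_PREDICTED)


def test_nmd_last_exon_escape_is_opt_in():
    obs = _obs([250, 100, 60])
    ptc = 360  # inside the last exon, > 200, outside the penultimate window
    assert predict_nmd(obs, ptc).occurs
    out = predict_nmd(obs, ptc, last_exon_escape=True)
    assert (out.occurs, out.reason) == (False, NMDReason.LAST_EXON)


def test_nmd_boundary_of_penultimate_window():
    obs = _obs([250, 100, 60])
    # exactly 50 bases before the penultimate exon end: escapes
    assert not predict_nmd(obs, 300).occurs
    # 51 bases before: NMD occurs
    assert predict_nmd(obs, 299).occurs


# ---------------------------------------------------------------------------
# decision tree branches
# ---------------------------------------------------------------------------


def test_pvs1_very_strong_requires_phenotype_relevant_overlap(fixture_set, bundle):
    gene = fixture_set.genes["TOYA"]
    v = gene.snv_at_cds(228, "T", None)
    res = evaluate_pvs1(v, ConsequenceKind.STOP_GAINED, gene.transcript, bundle)
    assert res.triggered and res.criterion.effective_strength is Strength.VERY_STRONG

    # the same branch on a gene outside the phenotype-relevant set fails
    gene_e = fixture_set.genes["TOYE"]
    v21 = next(p for p in fixture_set.panel if p.vid == "v21").variant
    res = evaluate_pvs1(v21, ConsequenceKind.FRAMESHIFT, gene_e.transcript, bundle)
    assert not res.triggered


def test_pvs1_intronless_escape_grades_by_truncation(fixture_set, bundle):
    gene = fixture_set.genes["TOYC"]
    big = evaluate_pvs1(
        gene.snv_at_cds(210, "T", None), ConsequenceKind.STOP_GAINED,
        gene.transcript, bundle,
    )
    small = evaluate_pvs1(
        gene.snv_at_cds(285, "T", None), ConsequenceKind.STOP_GAINED,
        gene.transcript, bundle,
    )
    assert big.criterion.effective_strength is Strength.STRONG
    assert small.criterion.effective_strength is Strength.MODERATE


def test_pvs1_domain_branch_grades_by_criticality(fixture_set, bundle):
    gene = fixture_set.genes["TOYD"]
    critical = evaluate_pvs1(
        gene.snv_at_cds(225, "T", None), ConsequenceKind.STOP_GAINED,
        gene.transcript, bundle,
    )
    ordinary = evaluate_pvs1(
        gene.snv_at_cds(252, "T", None), ConsequenceKind.STOP_GAINED,
        gene.transcript, bundle,
    )
    assert critical.criterion.effective_strength is Strength.STRONG
    assert ordinary.criterion.effective_strength is Strength.MODERATE


def test_pvs1_not_applicable_for_non_lof(fixture_set, bundle):
    gene = fixture_set.genes["TOYB"]
    v = gene.snv_at_cds(180, "T", None)
    res = evaluate_pvs1(v, ConsequenceKind.MISSENSE, gene.transcript, bundle)
    assert res.state is CriterionState.NOT_APPLICABLE


def test_pvs1_strength_monotone_in_phenotype_relevance(fixture_set, bundle):
    """Dropping phenotype relevance can never raise the PVS1 strength."""
    order = {CriterionState.NOT_APPLICABLE: -2, CriterionState.NOT_TRIGGERED: -1}

    def level(res):
        return int(res.criterion.effective_strength) if res.triggered \
            else order[res.state]

    gene = fixture_set.genes["TOYA"]
    stripped_t = TranscriptModel(
        gene.transcript.transcript_id, gene.transcript.gene_symbol, "chr1",
        gene.transcript.strand, gene.transcript.exons,
        gene.transcript.cds_start, gene.transcript.cds_end,
        phenotype_relevant=False,
        clinically_significant_exons=gene.transcript.clinically_significant_exons,
    )
    stripped = ResourceBundle(
        genome=bundle.genome,
        transcripts={stripped_t.transcript_id: stripped_t},
        clinvar=bundle.clinvar,
        tracks=bundle.tracks,
    )
    for off in (120, 210, 228):
        v = gene.snv_at_cds(off, "T", None)
        full = evaluate_pvs1(v, ConsequenceKind.STOP_GAINED, gene.transcript, bundle)
        less = evaluate_pvs1(v, ConsequenceKind.STOP_GAINED, stripped_t, stripped)
        assert level(less) <= level(full)


# ---------------------------------------------------------------------------
# start-loss branch
# ---------------------------------------------------------------------------


def test_start_loss_clinvar_entry_decides_strength(fixture_set, bundle):
    f_gene = fixture_set.genes["TOYF"]
    res = evaluate_start_loss(
        f_gene.snv_at_cds(1, "C", None), f_gene.transcript, bundle
    )
    assert res.triggered and res.criterion.effective_strength is Strength.MODERATE

    g_gene = fixture_set.genes["TOYG"]
    res = evaluate_start_loss(
        g_gene.snv_at_cds(1, "C", None), g_gene.transcript, bundle
    )
    assert res.triggered and res.criterion.effective_strength is Strength.SUPPORTING


def test_start_loss_without_rescue_atg_is_supporting():
    rng = random.Random(3)
    gene = _build_gene(rng, GenePlan("NORESCUE", "+", (300,)), 100)
    seqs = {"chr1": "A" * 100 + gene.region_seq_plus + "A" * 50}
    b = ResourceBundle(
        genome=Genome(seqs),
        transcripts={gene.transcript.transcript_id: gene.transcript},
    )
    res = evaluate_start_loss(gene.snv_at_cds(1, "C", None), gene.transcript, b)
    assert res.triggered
    assert res.criterion.effective_strength is Strength.SUPPORTING
    assert "no rescue start" in res.comment


def test_start_loss_alternative_start_blocks_trigger(fixture_set, bundle):
    gene = fixture_set.genes["TOYF"]
    t = gene.transcript
    alt_t = TranscriptModel(
        "TOYF-T2", t.gene_symbol, t.chrom, t.strand, t.exons,
        t.cds_start + 9, t.cds_end, phenotype_relevant=False,
    )
    b = ResourceBundle(
        genome=bundle.genome,
        transcripts={t.transcript_id: t, alt_t.transcript_id: alt_t},
        clinvar=bundle.clinvar,
    )
    res = evaluate_start_loss(gene.snv_at_cds(1, "C", None), t, b)
    assert not res.triggered
    assert "alternative start" in res.comment


# ---------------------------------------------------------------------------
# strand symmetry
# ---------------------------------------------------------------------------


def test_strand_mirror_gives_identical_nmd_and_pvs1():
    """A minus-strand mirror of a plus-strand gene behaves identically."""
    plan_kwargs = dict(
        exon_coding_lens=(150, 120, 90), phenotype_relevant=True,
        planted_codons={75: "CAA", 84: "CAA", 40: "CAA", 95: "CAA"},
    )
    # escape <=200bp, escape in penultimate window (x2), NMD in last exon
    for off in (120, 225, 252, 285):
        outcomes = []
        for strand in "+-":
            rng = random.Random(11)  # same filler for both orientations
            gene = _build_gene(
                rng, GenePlan("MIR", strand, **plan_kwargs), 100
            )
            seqs = {"chr1": "C" * 100 + gene.region_seq_plus + "C" * 50}
            b = ResourceBundle(
                genome=Genome(seqs),
                transcripts={gene.transcript.transcript_id: gene.transcript},
            )
            v = gene.snv_at_cds(off, "T", None)
            obs = build_observed_cds(gene.transcript, v, b.genome)
            ptc = locate_ptc(obs.sequence)
            nmd = predict_nmd(obs, ptc) if ptc is not None else None
            res = evaluate_pvs1(
                v, ConsequenceKind.STOP_GAINED, gene.transcript, b
            )
            outcomes.append(
                (
                    obs.sequence, ptc,
                    None if nmd is None else (nmd.occurs, nmd.reason),
                    res.state,
                    res.criterion.effective_strength if res.triggered else None,
                )
            )
        assert outcomes[0] == outcomes[1], f"offset {off}"


def test_locate_ptc_idempotent_under_retranslation(fixture_set, bundle):
    """Truncating at the PTC and re-scanning returns the same stop."""
    gene = fixture_set.genes["TOYA"]
    v = gene.snv_at_cds(210, "T", None)
    obs = build_observed_cds(gene.transcript, v, bundle.genome).sequence
    ptc = locate_ptc(obs)
    assert ptc is not None
    assert locate_ptc(obs[: ptc + 3]) == ptc
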