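"""PM4 / BP3: protein-length change and repeat-region criteria."""

import pytest

from acmghl.consequence import classify_consequence
from acmghl.core import (
    ConsequenceKind,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    GenomicVariant,
    Strength,
)
from acmghl.criteria_regions import (
    evaluate_bp3,
    evaluate_pm4,
    protein_length_change,
)
from acmghl.pvs1 import evaluate_pvs1
from acmghl.synthetic import GenePlan, _build_gene
from acmghl.resources import Genome, ResourceBundle
import random


def _pvs1_silent():
    return CriterionResult(
        CriterionId(Criterion.PVS1), CriterionState.NOT_TRIGGERED, "no PTC"
    )


def test_inframe_deletion_fraction(fixture_set, bundle):
    gene = fixture_set.genes["TOYE"]  # 119-residue reference protein
    v = gene.deletion_at_cds(30, 45, None)  # 15 codons
    change, warning = protein_length_change(gene.transcript, v, bundle)
    assert change == pytest.approx(15 / 119)
    assert warning is None


def test_inframe_duplication_fraction(fixture_set, bundle):
    gene = fixture_set.genes["TOYE"]
    anchor = gene.cds_to_g(30) - 1
    seq = fixture_set.genome_seqs["chr1"]
    base = seq[anchor]
    ins = seq[anchor + 1 : anchor + 10]  # duplicate the next 3 codons
    v = GenomicVariant("chr1", anchor, base, base + ins)
    change, _ = protein_length_change(gene.transcript, v, bundle)
    assert change == pytest.approx(3 / 119)


def test_stop_lost_reads_into_utr(fixture_set, bundle):
    gene = fixture_set.genes["TOYE"]  # 3' UTR stop planted 40 codons in
    stop_off = len(gene.coding) - 3
    v = gene.snv_at_cds(stop_off, "G", None)
    change, warning = protein_length_change(gene.transcript, v, bundle)
    assert change == pytest.approx(41 / 119)
    assert warning is None


def test_stop_lost_without_downstream_stop_warns():
    rng = random.Random(5)
    # filler codons never contain stops, so the UTR has no rescue stop
    gene = _build_gene(rng, GenePlan("NOSTOP", "+", (150,), utr3=90), 100)
    seqs = {"chr1": "A" * 100 + gene.region_seq_plus + "A" * 50}
    b = ResourceBundle(
        genome=Genome(seqs),
        transcripts={gene.transcript.transcript_id: gene.transcript},
    )
    v = gene.snv_at_cds(147, "G", None)
    change, warning = protein_length_change(gene.transcript, v, b)
    assert warning is not None and "transcript end" in warning
    assert change > 0.10


def test_synonymous_edit_changes_nothing(fixture_set, bundle):
    """Degenerate guard: a length-preserving, stop-preserving edit is 0."""
    gene = fixture_set.genes["TOYE"]
    from Bio.Seq import Seq

    for codon_idx in range(2, 40):
        codon = gene.coding[3 * codon_idx : 3 * codon_idx + 3]
        for alt in "ACGT":
            if alt == codon[2]:
                continue
            mutated = codon[:2] + alt
            if str(Seq(mutated).translate()) == str(Seq(codon).translate()):
                v = gene.snv_at_cds(3 * codon_idx + 2, alt, None)
                change, _ = protein_length_change(gene.transcript, v, bundle)
                assert change == 0.0
                return
    pytest.fail("no synonymous third-base edit found in 38 codons")


def test_pm4_requires_all_three_conditions(fixture_set, bundle):
    gene = fixture_set.genes["TOYE"]
    t = gene.transcript
    big = gene.deletion_at_cds(30, 45, None)
    cons = classify_consequence(big, t, bundle.genome)
    assert cons.kind is ConsequenceKind.INFRAME_DELETION
    assert evaluate_pm4(big, cons, t, bundle, _pvs1_silent()).triggered

    # same deletion, but PVS1 already fired at some strength
    pvs1_hit = CriterionResult(
        CriterionId(Criterion.PVS1, Strength.SUPPORTING),
        CriterionState.TRIGGERED, "hit",
    )
    res = evaluate_pm4(big, cons, t, bundle, pvs1_hit)
    assert not res.triggered and "withheld" in res.comment

    small = gene.deletion_at_cds(30, 9, None)
    cons_small = classify_consequence(small, t, bundle.genome)
    assert not evaluate_pm4(small, cons_small, t, bundle, _pvs1_silent()).triggered

    repeat_del = gene.deletion_at_cds(165, 45, None)
    cons_rep = classify_consequence(repeat_del, t, bundle.genome)
    res = evaluate_pm4(repeat_del, cons_rep, t, bundle, _pvs1_silent())
    assert not res.triggered and "repeat" in res.comment


def test_bp3_inside_and_outside_repeat(fixture_set, bundle):
    gene = fixture_set.genes["TOYE"]
    t = gene.transcript
    inside = gene.deletion_at_cds(165, 45, None)
    cons = classify_consequence(inside, t, bundle.genome)
    assert evaluate_bp3(inside, cons, t, bundle).triggered

    outside = gene.deletion_at_cds(30, 45, None)
    cons_out = classify_consequence(outside, t, bundle.genome)
    assert not evaluate_bp3(outside, cons_out, t, bundle).triggered

    # missense: precondition fails
    geneb = fixture_set.genes["TOYB"]
    mis = geneb.snv_at_cds(180, "T", None)
    cons_mis = classify_consequence(mis, geneb.transcript, bundle.genome)
    res = evaluate_bp3(mis, cons_mis, geneb.transcript, bundle)
    assert res.state is CriterionState.NOT_APPLICABLE


def test_bp3_agrees_with_naive_interval_oracle(fixture_set, bundle):
    repeat_ivs = fixture_set.tracks["repeat_no_domain"]
    for pv in fixture_set.panel:
        gene = next(
            g for g in fixture_set.genes.values()
            if g.transcript.exons[0][0] <= pv.variant.pos < g.transcript.exons[-1][1]
        )
        cons = classify_consequence(pv.variant, gene.transcript, bundle.genome)
        res = evaluate_bp3(pv.variant, cons, gene.transcript, bundle)
        if res.state is CriterionState.NOT_APPLICABLE:
            continue
        iv = cons.affected_cds_interval
        naive = iv is not None and any(
            s < iv[1] and e > iv[0] for s, e, _ in repeat_ivs
        )
        assert res.triggered == naive, pv.vid


def test_pm4_and_pvs1_never_cotrigger_on_panel(fixture_set, bundle):
    from acmghl.classify import classify_variant

    for pv in fixture_set.panel:
        cv = classify_variant(pv.variant, bundle)
        pm4 = cv.result_for(Criterion.PM4)
        pvs1 = cv.result_for(Criterion.PVS1)
        assert not (pm4.triggered and pvs1.triggered), pv.vid
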