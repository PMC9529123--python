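"""PS1 / PM5 / PM1: curated-variant and critical-region criteria."""

import pytest

from acmghl.config import EngineConfig
from acmghl.consequence import classify_consequence
from acmghl.core import ConsequenceKind, CriterionState, GenomicVariant, Strength
from acmghl.criteria_clinvar import evaluate_pm1, evaluate_ps1_pm5


def _missense(fixture_set, bundle, gene_name, cds_off, alt_t):
    gene = fixture_set.genes[gene_name]
    v = gene.snv_at_cds(cds_off, alt_t, None)
    cons = classify_consequence(v, gene.transcript, bundle.genome)
    assert cons.kind is ConsequenceKind.MISSENSE
    return v, cons, gene.transcript


def test_ps1_identical_change_beats_pm5(fixture_set, bundle):
    _, cons, t = _missense(fixture_set, bundle, "TOYB", 100, "T")
    ps1, pm5 = evaluate_ps1_pm5(cons, t, bundle)
    assert ps1.triggered and not pm5.triggered


def test_pm5_strong_needs_two_distinct_residues(fixture_set, bundle):
    _, cons, t = _missense(fixture_set, bundle, "TOYB", 120, "G")
    ps1, pm5 = evaluate_ps1_pm5(cons, t, bundle)
    assert not ps1.triggered
    assert pm5.triggered and pm5.criterion.effective_strength is Strength.MODERATE

    _, cons, t = _missense(fixture_set, bundle, "TOYB", 150, "A")
    ps1, pm5 = evaluate_ps1_pm5(cons, t, bundle)
    assert not ps1.triggered
    assert pm5.triggered and pm5.criterion.effective_strength is Strength.STRONG


def _any_missense_at(fixture_set, bundle, gene_name, cds_off):
    """First alternate base at a CDS offset that yields a missense call."""
    gene = fixture_set.genes[gene_name]
    gpos = gene.cds_to_g(cds_off)
    ref = fixture_set.genome_seqs["chr1"][gpos]
    for alt in "ACGT":
        if alt == ref:
            continue
        v = GenomicVariant("chr1", gpos, ref, alt)
        cons = classify_consequence(v, gene.transcript, bundle.genome)
        if cons.kind is ConsequenceKind.MISSENSE:
            return v, cons, gene.transcript
    raise AssertionError("no missense substitution exists at this offset")


def test_benign_only_records_trigger_neither(fixture_set, bundle):
    """Codon 56 holds only a benign curated entry: PS1 and PM5 both stay off."""
    _, cons, t = _any_missense_at(fixture_set, bundle, "TOYB", 168)
    ps1, pm5 = evaluate_ps1_pm5(cons, t, bundle)
    assert not ps1.triggered and not pm5.triggered


def test_non_missense_not_applicable(fixture_set, bundle):
    gene = fixture_set.genes["TOYA"]
    v = gene.snv_at_cds(210, "T", None)
    cons = classify_consequence(v, gene.transcript, bundle.genome)
    ps1, pm5 = evaluate_ps1_pm5(cons, gene.transcript, bundle)
    assert ps1.state is CriterionState.NOT_APPLICABLE
    assert pm5.state is CriterionState.NOT_APPLICABLE


def test_ps1_pm5_mutual_exclusion_on_panel(fixture_set, bundle):
    for pv in fixture_set.panel:
        gene = next(
            g for g in fixture_set.genes.values()
            if g.transcript.chrom == pv.variant.chrom
            and g.transcript.exons[0][0] <= pv.variant.pos < g.transcript.exons[-1][1]
        )
        cons = classify_consequence(pv.variant, gene.transcript, bundle.genome)
        if cons.kind is not ConsequenceKind.MISSENSE:
            continue
        ps1, pm5 = evaluate_ps1_pm5(cons, gene.transcript, bundle)
        assert not (ps1.triggered and pm5.triggered), pv.vid


def test_raising_min_stars_is_monotone(fixture_set, bundle):
    """A stricter review-star floor can only switch results off."""
    for off, alt in ((100, "T"), (120, "G"), (150, "A")):
        _, cons, t = _missense(fixture_set, bundle, "TOYB", off, alt)
        for lo, hi in ((0, 1), (1, 2), (2, 3)):
            loose = evaluate_ps1_pm5(cons, t, bundle, EngineConfig(min_stars=lo))
            strict = evaluate_ps1_pm5(cons, t, bundle, EngineConfig(min_stars=hi))
            for l_res, s_res in zip(loose, strict):
                if s_res.triggered:
                    assert l_res.triggered


def test_pm1_boundary(fixture_set, bundle):
    region = next(
        (s, e) for s, e, label in fixture_set.tracks["critical_region_no_benign"]
        if label == "TOYB_motif"
    )
    gene = fixture_set.genes["TOYB"]
    inside = gene.snv_at_cds(60, "A", None)
    cons = classify_consequence(inside, gene.transcript, bundle.genome)
    assert evaluate_pm1(inside, cons, gene.transcript, bundle).triggered

    # one base past the region end: not triggered
    gpos = region[1]
    ref = fixture_set.genome_seqs["chr1"][gpos]
    outside = GenomicVariant("chr1", gpos, ref, "A" if ref != "A" else "C")
    cons_out = classify_consequence(outside, gene.transcript, bundle.genome)
    res = evaluate_pm1(outside, cons_out, gene.transcript, bundle)
    assert not res.triggered


def test_pm1_ignores_regions_voided_by_benign_entries(fixture_set, bundle):
    """A critical region holding a benign record is absent from the
    benign-free track, so PM1 must not fire inside it."""
    labels = {l for _, _, l in fixture_set.tracks["critical_region_no_benign"]}
    assert "TOYB_benign_motif" not in labels  # subtraction oracle
    v, cons, t = _any_missense_at(fixture_set, bundle, "TOYB", 168)
    in_full_track = any(
        s <= v.pos < e
        for s, e, _ in fixture_set.tracks["critical_region"]
    )
    assert in_full_track  # the position is critical, just not benign-free
    res = evaluate_pm1(v, cons, t, bundle)
    assert not res.triggered
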