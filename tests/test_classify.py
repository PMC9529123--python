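"""Criteria combination, posterior probability and VUS refinement."""

import itertools

import pytest

from acmghl.classify import combine_criteria, compute_posterior, refine_vus
from acmghl.config import PosteriorParams, RefinementThresholds
from acmghl.core import (
    ACMGClass,
    BroaderClass,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    EvidenceSet,
    Strength,
    evidence_set_from_results,
    to_broader,
)
from acmghl.resources import InheritanceMode


def _hit(base, strength=None):
    return CriterionResult(
        CriterionId(base, strength), CriterionState.TRIGGERED, "x"
    )


def _ev(*pairs):
    """EvidenceSet from (direction, strength, count) triples."""
    from collections import Counter

    c = Counter()
    for direction, strength, n in pairs:
        c[(direction, strength)] = n
    return EvidenceSet.from_counter(c)


# ---------------------------------------------------------------------------
# posterior probability
# ---------------------------------------------------------------------------


def test_posterior_moderate_plus_supporting_matches_threshold():
    ev = _ev(("pathogenic", Strength.MODERATE, 1),
             ("pathogenic", Strength.SUPPORTING, 1))
    assert round(compute_posterior(ev), 5) == 0.49988


def test_posterior_single_benign_supporting_matches_threshold():
    ev = _ev(("benign", Strength.SUPPORTING, 1))
    assert round(compute_posterior(ev), 5) == 0.05072


def test_posterior_of_empty_evidence_is_prior():
    assert compute_posterior(_ev()) == pytest.approx(0.1)
    assert compute_posterior(_ev(), PosteriorParams(prior=0.25)) == pytest.approx(0.25)


def test_posterior_monotone_in_added_evidence():
    """Adding pathogenic evidence raises, adding benign lowers, for every
    evidence multiset of up to four criteria."""
    strengths = [Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG,
                 Strength.VERY_STRONG]
    atoms = [("pathogenic", s) for s in strengths] + \
            [("benign", s) for s in strengths] + [("benign", Strength.STAND_ALONE)]
    for k in range(0, 4):
        for combo in itertools.combinations_with_replacement(atoms, k):
            from collections import Counter

            base = Counter(combo)
            p0 = compute_posterior(EvidenceSet.from_counter(base))
            for direction, strength in atoms:
                bigger = Counter(base)
                bigger[(direction, strength)] += 1
                p1 = compute_posterior(EvidenceSet.from_counter(bigger))
                if direction == "pathogenic":
                    assert p1 > p0
                else:
                    assert p1 < p0


# ---------------------------------------------------------------------------
# combining table
# ---------------------------------------------------------------------------


def test_no_evidence_defaults_to_vus():
    assert combine_criteria([]) is ACMGClass.VUS


def test_hl_refinement_pvs1_pm2_ar_is_likely_pathogenic():
    results = [_hit(Criterion.PVS1, Strength.VERY_STRONG),
               _hit(Criterion.PM2, Strength.SUPPORTING)]
    assert combine_criteria(results, InheritanceMode.AR) is ACMGClass.LIKELY_PATHOGENIC
    # outside autosomal-recessive genes the pair is insufficient
    assert combine_criteria(results, InheritanceMode.AD) is ACMGClass.VUS
    assert combine_criteria(results, InheritanceMode.UNKNOWN) is ACMGClass.VUS


def test_hl_refinement_bs1_alone_is_likely_benign():
    assert combine_criteria(
        [_hit(Criterion.BS1, Strength.SUPPORTING)]
    ) is ACMGClass.LIKELY_BENIGN
    # with a pathogenic criterion present the refinement is off
    res = combine_criteria(
        [_hit(Criterion.BS1, Strength.SUPPORTING), _hit(Criterion.PM1)]
    )
    assert res is ACMGClass.VUS


def test_standard_combinations():
    assert combine_criteria(
        [_hit(Criterion.PVS1, Strength.VERY_STRONG), _hit(Criterion.PS1)]
    ) is ACMGClass.PATHOGENIC
    assert combine_criteria(
        [_hit(Criterion.PVS1, Strength.VERY_STRONG), _hit(Criterion.PM1)]
    ) is ACMGClass.LIKELY_PATHOGENIC
    assert combine_criteria(
        [_hit(Criterion.PS1), _hit(Criterion.PM1)]
    ) is ACMGClass.LIKELY_PATHOGENIC
    assert combine_criteria([_hit(Criterion.BA1)]) is ACMGClass.BENIGN
    assert combine_criteria(
        [_hit(Criterion.BP4), _hit(Criterion.BP7)]
    ) is ACMGClass.LIKELY_BENIGN


def test_conflicting_evidence_yields_vus():
    res = combine_criteria(
        [_hit(Criterion.PVS1, Strength.VERY_STRONG), _hit(Criterion.PS1),
         _hit(Criterion.BA1)]
    )
    assert res is ACMGClass.VUS


def test_duplicate_base_criterion_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        combine_criteria([_hit(Criterion.PM1), _hit(Criterion.PM1)])


# ---------------------------------------------------------------------------
# VUS refinement (posterior thresholds)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "acmg, posterior, expected",
    [
        (ACMGClass.VUS, 0.60, BroaderClass.PATHOGENIC),
        (ACMGClass.VUS, 0.49988, BroaderClass.PATHOGENIC),  # inclusive bound
        (ACMGClass.VUS, 0.49987, BroaderClass.VUS),
        (ACMGClass.VUS, 0.05072, BroaderClass.BENIGN),      # inclusive bound
        (ACMGClass.VUS, 0.05073, BroaderClass.VUS),
        (ACMGClass.VUS, 0.1, BroaderClass.VUS),
        (ACMGClass.LIKELY_BENIGN, 0.99, BroaderClass.BENIGN),   # passthrough
        (ACMGClass.PATHOGENIC, 0.01, BroaderClass.PATHOGENIC),  # passthrough
    ],
)
def test_refine_vus(acmg, posterior, expected):
    assert refine_vus(acmg, posterior) is expected


def test_refine_vus_idempotent_at_broader_level():
    back = {
        BroaderClass.BENIGN: ACMGClass.BENIGN,
        BroaderClass.VUS: ACMGClass.VUS,
        BroaderClass.PATHOGENIC: ACMGClass.PATHOGENIC,
    }
    for acmg in ACMGClass:
        for posterior in (0.0, 0.05072, 0.2, 0.49988, 0.9):
            once = refine_vus(acmg, posterior)
            twice = refine_vus(back[once], posterior)
            assert twice is once


def test_refine_vus_rejects_invalid_posterior():
    with pytest.raises(ValueError):
        refine_vus(ACMGClass.VUS, 1.5)


def test_custom_refinement_thresholds_respected():
    th = RefinementThresholds(pathogenic_cut=0.9, benign_cut=0.01)
    assert refine_vus(ACMGClass.VUS, 0.6, th) is BroaderClass.VUS
    assert refine_vus(ACMGClass.VUS, 0.95, th) is BroaderClass.PATHOGENIC
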