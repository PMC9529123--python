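"""In-silico prediction criteria: PP3, BP4, BP7.

Aggregates externally computed conservation (phyloP-style), missense
pathogenicity (REVEL/CADD-style) and splicing (MaxEntScan/dbscSNV-style)
scores.  Missense variants use the pathogenicity+conservation conjunction;
variants without immediate amino-acid impact (excluding canonical splice
sites) use the splicing+conservation conjunction, with BP7 reserved for
synonymous variants.  Missing required scores leave the affected criterion
not_triggered with an "insufficient scores" comment.
"""

from __future__ import annotations

from typing import Optional, Tuple

from .config import ScoreThresholds
from .core import (
    ConsequenceKind,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    VariantConsequence,
)
from .resources import InSilicoScores

__all__ = ["evaluate_insilico", "splice_effect_verdict"]

_CANONICAL_SPLICE = frozenset(
    {ConsequenceKind.SPLICE_ACCEPTOR, ConsequenceKind.SPLICE_DONOR}
)
_NO_AA_IMPACT = frozenset(
    {ConsequenceKind.SYNONYMOUS, ConsequenceKind.INTRONIC, ConsequenceKind.OTHER}
)


def splice_effect_verdict(
    scores: InSilicoScores, th: ScoreThresholds
) -> Optional[bool]:
    """Three-valued splice-effect call: True/False, or None if no score.

    An effect is called when a dbscSNV-style probability reaches its cutoff
    or the MaxEntScan-style score changes by at least the relative-delta
    cutoff; "no effect" requires every available splice score to stay below
    its cutoff; with no splice scores at all there is no prediction.
    """
    votes = []
    for prob in (scores.splice_ada, scores.splice_rf):
        if prob is not None:
            votes.append(prob >= th.splice_prob)
    if scores.splice_ref is not None and scores.splice_alt is not None:
        if scores.splice_ref != 0:
            rel = abs(scores.splice_alt - scores.splice_ref) / abs(scores.splice_ref)
            votes.append(rel >= th.splice_delta)
        else:
            votes.append(scores.splice_alt != 0)
    if not votes:
        return None
    return any(votes)


def _result(
    criterion: Criterion, state: CriterionState, comment: str = ""
) -> CriterionResult:
    return CriterionResult(CriterionId(criterion), state, comment)


def evaluate_insilico(
    consequence: VariantConsequence,
    scores: InSilicoScores,
    th: Optional[ScoreThresholds] = None,
) -> Tuple[CriterionResult, CriterionResult, CriterionResult]:
    """Evaluate (PP3, BP4, BP7) for one consequence."""
    th = th or ScoreThresholds()
    kind = consequence.kind

    if kind in _CANONICAL_SPLICE:
        na = CriterionState.NOT_APPLICABLE
        return _result(Criterion.PP3, na), _result(Criterion.BP4, na), _result(
            Criterion.BP7, na
        )

    if kind is ConsequenceKind.MISSENSE:
        return _evaluate_missense(scores, th)

    if kind in _NO_AA_IMPACT:
        return _evaluate_splice_screen(kind, scores, th)

    na = CriterionState.NOT_APPLICABLE
    return _result(Criterion.PP3, na), _result(Criterion.BP4, na), _result(
        Criterion.BP7, na
    )


def _evaluate_missense(scores: InSilicoScores, th: ScoreThresholds):
    bp7 = _result(Criterion.BP7, CriterionState.NOT_APPLICABLE)

    have_pred = scores.revel is not None or scores.cadd is not None
    have_cons = scores.phylop is not None
    pathogenic_pred = (
        scores.revel is not None and scores.revel >= th.revel_pathogenic
    ) or (scores.cadd is not None and scores.cadd >= th.cadd_pathogenic)
    conserved = have_cons and scores.phylop >= th.phylop_conserved

    if not (have_pred and have_cons):
        pp3 = _result(
            Criterion.PP3, CriterionState.NOT_TRIGGERED, "insufficient scores"
        )
    elif pathogenic_pred and conserved:
        pp3 = _result(
            Criterion.PP3,
            CriterionState.TRIGGERED,
            f"pathogenicity predicted (REVEL={scores.revel}, CADD="
            f"{scores.cadd}) with high conservation (phyloP={scores.phylop})",
        )
    else:
        pp3 = _result(
            Criterion.PP3,
            CriterionState.NOT_TRIGGERED,
            "pathogenicity prediction and conservation not both high",
        )

    # benign arm: both predictors low (REVEL required), low conservation,
    # and an explicit no-splice-effect prediction
    low_pred = (
        scores.revel is not None
        and scores.revel <= th.revel_benign
        and (scores.cadd is None or scores.cadd <= th.cadd_benign)
    )
    low_cons = have_cons and scores.phylop < th.phylop_nonconserved
    splice = splice_effect_verdict(scores, th)
    if scores.revel is None or not have_cons or splice is None:
        bp4 = _result(
            Criterion.BP4, CriterionState.NOT_TRIGGERED, "insufficient scores"
        )
    elif low_pred and low_cons and splice is False:
        bp4 = _result(
            Criterion.BP4,
            CriterionState.TRIGGERED,
            f"low pathogenicity prediction (REVEL={scores.revel}), low "
            f"conservation (phyloP={scores.phylop}), no predicted splice "
            "effect",
        )
    else:
        bp4 = _result(
            Criterion.BP4,
            CriterionState.NOT_TRIGGERED,
            "benign conjunction not satisfied",
        )
    return pp3, bp4, bp7


def _evaluate_splice_screen(
    kind: ConsequenceKind, scores: InSilicoScores, th: ScoreThresholds
):
    splice = splice_effect_verdict(scores, th)
    have_cons = scores.phylop is not None
    conserved = have_cons and scores.phylop >= th.phylop_conserved
    low_cons = have_cons and scores.phylop < th.phylop_nonconserved

    if splice is None or not have_cons:
        pp3 = _result(
            Criterion.PP3, CriterionState.NOT_TRIGGERED, "insufficient scores"
        )
    elif splice and conserved:
        pp3 = _result(
            Criterion.PP3,
            CriterionState.TRIGGERED,
            f"splice effect predicted at a conserved position "
            f"(phyloP={scores.phylop})",
        )
    else:
        pp3 = _result(
            Criterion.PP3,
            CriterionState.NOT_TRIGGERED,
            "no conserved predicted splice effect",
        )

    quiet = splice is False and low_cons
    if kind is ConsequenceKind.SYNONYMOUS:
        if splice is None or not have_cons:
            bp7 = _result(
                Criterion.BP7, CriterionState.NOT_TRIGGERED, "insufficient scores"
            )
        elif quiet:
            bp7 = _result(
                Criterion.BP7,
                CriterionState.TRIGGERED,
                "synonymous variant: no predicted splice effect and low "
                f"conservation (phyloP={scores.phylop})",
            )
        else:
            bp7 = _result(
                Criterion.BP7,
                CriterionState.NOT_TRIGGERED,
                "splice effect or conservation not excluded",
            )
        bp4 = _result(
            Criterion.BP4,
            CriterionState.NOT_TRIGGERED,
            "BP7 covers synonymous variants",
        )
    else:
        bp7 = _result(Criterion.BP7, CriterionState.NOT_APPLICABLE)
        if splice is None or not have_cons:
            bp4 = _result(
                Criterion.BP4, CriterionState.NOT_TRIGGERED, "insufficient scores"
            )
        elif quiet:
            bp4 = _result(
                Criterion.BP4,
                CriterionState.TRIGGERED,
                "no predicted splice effect and low conservation "
                f"(phyloP={scores.phylop})",
            )
        else:
            bp4 = _result(
                Criterion.BP4,
                CriterionState.NOT_TRIGGERED,
                "splice effect or conservation not excluded",
            )
    return pp3, bp4, bp7
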