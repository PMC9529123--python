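"""Criteria combination, posterior pathogenicity probability, and VUS
refinement.

The five-tier class is derived from the standard ACMG/AMP combining table
(committed below as an explicit pattern table) plus two hearing-loss
refinements: PVS1 with PM2 (Supporting) yields likely_pathogenic for
autosomal-recessive genes, and BS1 without any pathogenic criterion yields
likely_benign.  The posterior follows the Bayesian point framework: each
triggered criterion contributes a fractional exponent of the very-strong
odds of pathogenicity (supporting 1/8, moderate 1/4, strong 1/2,
very-strong 1; benign evidence negated, stand-alone benign -1), and

    posterior = O * prior / ((O - 1) * prior + 1),   O = odds_pvst ** x.

VUS calls are afterwards re-classified at the posterior thresholds printed
for the implemented-criteria subset (>= 0.49988 -> Pathogenic,
<= 0.05072 -> Benign); non-VUS classes pass through unchanged.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .config import EngineConfig, PosteriorParams, RefinementThresholds
from .consequence import annotate_variant
from .core import (
    ACMGClass,
    BroaderClass,
    ClassifiedVariant,
    ConsequenceKind,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    EvidenceSet,
    GenomicVariant,
    Strength,
    VariantConsequence,
    evidence_set_from_results,
    to_broader,
)
from .criteria_clinvar import evaluate_pm1, evaluate_ps1_pm5
from .criteria_population import evaluate_population, resolve_mode_thresholds
from .criteria_regions import evaluate_bp3, evaluate_pm4
from .criteria_scores import evaluate_insilico
from .pvs1 import evaluate_pvs1
from .resources import InheritanceMode, ResourceBundle

__all__ = [
    "ALL_CRITERIA",
    "PATHOGENIC_RULES",
    "LIKELY_PATHOGENIC_RULES",
    "BENIGN_RULES",
    "LIKELY_BENIGN_RULES",
    "combine_criteria",
    "compute_posterior",
    "refine_vus",
    "classify_variant",
]

#: the full criterion schema the engine evaluates
ALL_CRITERIA: Tuple[Criterion, ...] = tuple(Criterion)

# ---------------------------------------------------------------------------
# combining table: minimum evidence counts per class
# keys: pvs = pathogenic very strong, ps = strong, pm = moderate,
#       pp = supporting, ba = stand-alone benign, bs = strong benign,
#       bp = supporting benign
# ---------------------------------------------------------------------------

PATHOGENIC_RULES: Tuple[Dict[str, int], ...] = (
    {"pvs": 1, "ps": 1},
    {"pvs": 1, "pm": 2},
    {"pvs": 1, "pm": 1, "pp": 1},
    {"pvs": 1, "pp": 2},
    {"ps": 2},
    {"ps": 1, "pm": 3},
    {"ps": 1, "pm": 2, "pp": 2},
    {"ps": 1, "pm": 1, "pp": 4},
)
LIKELY_PATHOGENIC_RULES: Tuple[Dict[str, int], ...] = (
    {"pvs": 1, "pm": 1},
    {"ps": 1, "pm": 1},
    {"ps": 1, "pp": 2},
    {"pm": 3},
    {"pm": 2, "pp": 2},
    {"pm": 1, "pp": 4},
)
BENIGN_RULES: Tuple[Dict[str, int], ...] = (
    {"ba": 1},
    {"bs": 2},
)
LIKELY_BENIGN_RULES: Tuple[Dict[str, int], ...] = (
    {"bs": 1, "bp": 1},
    {"bp": 2},
)

_COUNT_KEY = {
    ("pathogenic", Strength.VERY_STRONG): "pvs",
    ("pathogenic", Strength.STRONG): "ps",
    ("pathogenic", Strength.MODERATE): "pm",
    ("pathogenic", Strength.SUPPORTING): "pp",
    ("benign", Strength.STAND_ALONE): "ba",
    ("benign", Strength.STRONG): "bs",
    ("benign", Strength.SUPPORTING): "bp",
    ("benign", Strength.MODERATE): "bp",  # no moderate benign rules exist;
    # a hypothetical moderate benign criterion counts as supporting
}


def _evidence_counts(results: Sequence[CriterionResult]) -> Dict[str, int]:
    counts = {k: 0 for k in ("pvs", "ps", "pm", "pp", "ba", "bs", "bp")}
    seen = set()
    for r in results:
        if not r.triggered:
            continue
        if r.criterion.base in seen:
            raise ValueError(
                f"duplicate triggered entries for {r.criterion.base.value}"
            )
        seen.add(r.criterion.base)
        key = _COUNT_KEY[(r.criterion.direction, r.criterion.effective_strength)]
        counts[key] += 1
    return counts


def _matches(counts: Dict[str, int], rule: Dict[str, int]) -> bool:
    return all(counts.get(k, 0) >= n for k, n in rule.items())


def combine_criteria(
    results: Sequence[CriterionResult],
    gene_mode: InheritanceMode = InheritanceMode.UNKNOWN,
) -> ACMGClass:
    """Combine triggered criteria into the five-tier class.

    Applies the committed combining table; evidence satisfying both a
    pathogenic and a benign pattern is conflicting and yields VUS, and no
    evidence at all yields VUS.  Hearing-loss refinements: (i) PVS1 +
    PM2 (Supporting) in an autosomal-recessive gene upgrades to likely
    pathogenic; (ii) BS1 without any pathogenic criterion yields at least
    likely benign.
    """
    counts = _evidence_counts(results)
    triggered = {r.criterion.base for r in results if r.triggered}

    path_class: Optional[ACMGClass] = None
    if any(_matches(counts, rule) for rule in PATHOGENIC_RULES):
        path_class = ACMGClass.PATHOGENIC
    elif any(_matches(counts, rule) for rule in LIKELY_PATHOGENIC_RULES):
        path_class = ACMGClass.LIKELY_PATHOGENIC

    benign_class: Optional[ACMGClass] = None
    if any(_matches(counts, rule) for rule in BENIGN_RULES):
        benign_class = ACMGClass.BENIGN
    elif any(_matches(counts, rule) for rule in LIKELY_BENIGN_RULES):
        benign_class = ACMGClass.LIKELY_BENIGN

    if path_class and benign_class:
        return ACMGClass.VUS
    if path_class:
        return path_class
    if benign_class is None:
        # hearing-loss refinement (ii): BS1 alone suffices for likely benign
        if Criterion.BS1 in triggered and not any(
            c.direction == "pathogenic" for c in triggered
        ):
            return ACMGClass.LIKELY_BENIGN
    if benign_class:
        return benign_class

    # hearing-loss refinement (i): PVS1 + PM2 (Supporting), AR gene
    if (
        gene_mode is InheritanceMode.AR
        and Criterion.PM2 in triggered
        and any(
            r.triggered
            and r.criterion.base is Criterion.PVS1
            and r.criterion.effective_strength is Strength.VERY_STRONG
            for r in results
        )
    ):
        return ACMGClass.LIKELY_PATHOGENIC

    return ACMGClass.VUS


# ---------------------------------------------------------------------------
# posterior probability
# ---------------------------------------------------------------------------

_WEIGHT_ATTR = {
    Strength.SUPPORTING: "w_supporting",
    Strength.MODERATE: "w_moderate",
    Strength.STRONG: "w_strong",
    Strength.VERY_STRONG: "w_very_strong",
    Strength.STAND_ALONE: "w_stand_alone",
}


def compute_posterior(
    ev: EvidenceSet, params: Optional[PosteriorParams] = None
) -> float:
    """Posterior pathogenicity probability of an evidence multiset."""
    params = params or PosteriorParams()
    x = 0.0
    for (direction, strength), n in ev.counts:
        w = getattr(params, _WEIGHT_ATTR[strength])
        x += n * w if direction == "pathogenic" else -n * w
    odds = params.odds_pvst**x
    return (odds * params.prior) / ((odds - 1.0) * params.prior + 1.0)


def refine_vus(
    acmg_class: ACMGClass,
    posterior: float,
    th: Optional[RefinementThresholds] = None,
) -> BroaderClass:
    """Posterior-based refinement of VUS calls (non-VUS pass through)."""
    th = th or RefinementThresholds()
    if not (0.0 <= posterior <= 1.0):
        raise ValueError(f"posterior {posterior} outside [0, 1]")
    if acmg_class is not ACMGClass.VUS:
        return to_broader(acmg_class)
    if posterior >= th.pathogenic_cut:
        return BroaderClass.PATHOGENIC
    if posterior <= th.benign_cut:
        return BroaderClass.BENIGN
    return BroaderClass.VUS


# ---------------------------------------------------------------------------
# per-variant engine
# ---------------------------------------------------------------------------

_DECISIVENESS = {
    CriterionState.TRIGGERED: 2,
    CriterionState.NOT_TRIGGERED: 1,
    CriterionState.NOT_APPLICABLE: 0,
}


def _pick(results: List[CriterionResult]) -> CriterionResult:
    """Variant-level outcome for one criterion over several transcripts.

    Prefers triggered outcomes (at the highest strength for pathogenic
    criteria), then not_triggered, then not_applicable; comments name the
    deciding transcript where the evaluator recorded one.
    """
    def rank(r: CriterionResult):
        strength = int(r.criterion.effective_strength) if r.triggered else 0
        return (_DECISIVENESS[r.state], strength)

    return max(results, key=rank)


def _evaluate_transcript(
    v: GenomicVariant,
    cons: VariantConsequence,
    bundle: ResourceBundle,
    config: EngineConfig,
) -> List[CriterionResult]:
    t = bundle.transcripts[cons.transcript_id]
    pvs1 = evaluate_pvs1(v, cons.kind, t, bundle, config)
    ps1, pm5 = evaluate_ps1_pm5(cons, t, bundle, config)
    pm1 = evaluate_pm1(v, cons, t, bundle)
    pm4 = evaluate_pm4(v, cons, t, bundle, pvs1, config)
    bp3 = evaluate_bp3(v, cons, t, bundle)
    pp3, bp4, bp7 = evaluate_insilico(cons, bundle.query_scores(v), config.scores)
    return [pvs1, ps1, pm1, pm4, pm5, pp3, bp3, bp4, bp7]


def classify_variant(
    v: GenomicVariant,
    bundle: ResourceBundle,
    config: Optional[EngineConfig] = None,
    consequences: Optional[List[VariantConsequence]] = None,
) -> ClassifiedVariant:
    """Run the full evaluation for one normalised variant."""
    config = config or EngineConfig()
    if consequences is None:
        consequences = annotate_variant(v, bundle)
    warnings: List[str] = []

    per_transcript: List[List[CriterionResult]] = [
        _evaluate_transcript(v, cons, bundle, config) for cons in consequences
    ]

    per_criterion: Dict[Criterion, List[CriterionResult]] = {c: [] for c in ALL_CRITERIA}
    for results in per_transcript:
        for r in results:
            per_criterion[r.criterion.base].append(r)

    merged: List[CriterionResult] = []
    for c in (
        Criterion.PVS1,
        Criterion.PS1,
        Criterion.PM1,
        Criterion.PM4,
        Criterion.PM5,
        Criterion.PP3,
        Criterion.BP3,
        Criterion.BP4,
        Criterion.BP7,
    ):
        pool = per_criterion[c]
        if pool:
            merged.append(_pick(pool))
        else:
            merged.append(
                CriterionResult(CriterionId(c), CriterionState.NOT_APPLICABLE)
            )

    # population criteria: once per variant, against the reporting gene
    reporting_transcript = consequences[0].transcript_id if consequences else None
    gene_symbol = (
        bundle.transcripts[reporting_transcript].gene_symbol
        if reporting_transcript
        else ""
    )
    cutoffs = resolve_mode_thresholds(gene_symbol, bundle.inheritance, config.af)
    if cutoffs.warning:
        warnings.append(
            f"{gene_symbol}: mitochondrial gene; ACMG criteria are validated "
            "only for Mendelian disorders"
        )
    pm2, ba1, bs1 = evaluate_population(
        v,
        bundle.query_af(v),
        cutoffs,
        excluded_high_af=bundle.is_excluded_high_af(v),
        config=config,
    )
    merged.extend([pm2, ba1, bs1])

    order = {c: i for i, c in enumerate(ALL_CRITERIA)}
    merged.sort(key=lambda r: order[r.criterion.base])

    acmg_class = combine_criteria(merged, cutoffs.mode)
    posterior = compute_posterior(evidence_set_from_results(merged), config.posterior)
    refined = refine_vus(acmg_class, posterior, config.refinement)

    return ClassifiedVariant(
        variant=v,
        consequences=tuple(consequences),
        results=tuple(merged),
        acmg_class=acmg_class,
        posterior=posterior,
        refined_broader_class=refined,
        reporting_transcript=reporting_transcript,
        warnings=tuple(warnings),
    )
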