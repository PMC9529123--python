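"""Population allele-frequency criteria: PM2 (Supporting), BA1, BS1
(Supporting).

Thresholds are inheritance-mode specific: autosomal dominant and recessive
carry their own cutoffs, X-linked genes adopt the dominant cutoffs, and
genes with unknown mode take the strictest of the two (the value that
minimises activation).  Mitochondrial genes are treated like unknown with
an extra warning, since the criteria are validated only for Mendelian
disorders.  A criterion fires when any subpopulation's frequency or the
median frequency across subpopulations crosses its cutoff; known pathogenic
high-frequency variants are exempt from BA1/BS1.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .config import AFThresholds, EngineConfig
from .core import (
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    GenomicVariant,
    Strength,
)
from .resources import AFRecord, InheritanceMode

__all__ = [
    "EffectiveCutoffs",
    "evaluate_population",
    "median_af",
    "resolve_mode_thresholds",
]


def median_af(values) -> float:
    """Median allele frequency over the present subpopulations.

    Standard even/odd median: the middle value, or the mean of the two
    middle values for an even count.
    """
    values = list(values)
    if not values:
        raise ValueError("median of no subpopulations")
    return float(statistics.median(values))


@dataclass(frozen=True)
class EffectiveCutoffs:
    """Per-criterion cutoffs after inheritance-mode resolution."""

    ba1: float
    bs1: float
    pm2: float
    mode: InheritanceMode
    warning: bool = False  # mitochondrial gene: criteria not validated


def resolve_mode_thresholds(
    gene_symbol: str,
    inheritance: Dict[str, InheritanceMode],
    th: Optional[AFThresholds] = None,
) -> EffectiveCutoffs:
    """Effective AF cutoffs for one gene.

    Unknown mode takes the strictest threshold per criterion: the minimum
    of AD/AR for PM2's rarity test, the maximum for BA1/BS1's commonness
    tests.
    """
    th = th or AFThresholds()
    mode = inheritance.get(gene_symbol, InheritanceMode.UNKNOWN)
    if mode in (InheritanceMode.AD, InheritanceMode.XL):
        c = th.for_mode("ad")
        return EffectiveCutoffs(c["ba1"], c["bs1"], c["pm2"], mode)
    if mode is InheritanceMode.AR:
        c = th.for_mode("ar")
        return EffectiveCutoffs(c["ba1"], c["bs1"], c["pm2"], mode)
    ad, ar = th.for_mode("ad"), th.for_mode("ar")
    return EffectiveCutoffs(
        ba1=max(ad["ba1"], ar["ba1"]),
        bs1=max(ad["bs1"], ar["bs1"]),
        pm2=min(ad["pm2"], ar["pm2"]),
        mode=mode,
        warning=mode is InheritanceMode.MT,
    )


def evaluate_population(
    v: GenomicVariant,
    af: Optional[AFRecord],
    cutoffs: EffectiveCutoffs,
    excluded_high_af: bool = False,
    config: Optional[EngineConfig] = None,
) -> Tuple[CriterionResult, CriterionResult, CriterionResult]:
    """Evaluate (PM2, BA1, BS1) for one variant.

    ``af`` is None when the variant is unobserved in the frequency
    resource, which counts as frequency zero everywhere (hence PM2).
    """
    config = config or EngineConfig()
    pm2_strength = Strength.SUPPORTING if config.pm2_supporting else None
    bs1_strength = Strength.SUPPORTING if config.bs1_supporting else None

    if af is None:
        pm2 = CriterionResult(
            CriterionId(Criterion.PM2, pm2_strength),
            CriterionState.TRIGGERED,
            "variant absent from the population frequency resource",
        )
        ba1 = CriterionResult(
            CriterionId(Criterion.BA1),
            CriterionState.NOT_TRIGGERED,
            "variant absent from the population frequency resource",
        )
        bs1 = CriterionResult(
            CriterionId(Criterion.BS1, bs1_strength),
            CriterionState.NOT_TRIGGERED,
            "variant absent from the population frequency resource",
        )
        return pm2, ba1, bs1

    subpops = dict(sorted(af.af_by_subpopulation.items()))
    values = dict(subpops)
    values["median"] = median_af(subpops.values())
    top_name, top_af = max(values.items(), key=lambda kv: (kv[1], kv[0]))

    def _commonness(criterion, cutoff, strength=None):
        if excluded_high_af:
            return CriterionResult(
                CriterionId(criterion, strength),
                CriterionState.NOT_TRIGGERED,
                "known pathogenic high-AF exclusion",
            )
        if top_af >= cutoff:
            return CriterionResult(
                CriterionId(criterion, strength),
                CriterionState.TRIGGERED,
                f"{top_name} AF {top_af:g} >= {criterion.value} cutoff "
                f"{cutoff:g} ({cutoffs.mode.value} mode)",
            )
        return CriterionResult(
            CriterionId(criterion, strength),
            CriterionState.NOT_TRIGGERED,
            f"maximal AF {top_af:g} ({top_name}) below cutoff {cutoff:g}",
        )

    ba1 = _commonness(Criterion.BA1, cutoffs.ba1)
    if ba1.triggered:
        bs1 = CriterionResult(
            CriterionId(Criterion.BS1, bs1_strength),
            CriterionState.NOT_TRIGGERED,
            "BA1 already triggered (stand-alone dominates)",
        )
    else:
        bs1 = _commonness(Criterion.BS1, cutoffs.bs1, bs1_strength)

    if all(x <= cutoffs.pm2 for x in subpops.values()):
        pm2 = CriterionResult(
            CriterionId(Criterion.PM2, pm2_strength),
            CriterionState.TRIGGERED,
            f"all subpopulation AFs <= PM2 cutoff {cutoffs.pm2:g} "
            f"({cutoffs.mode.value} mode)",
        )
    else:
        pm2 = CriterionResult(
            CriterionId(Criterion.PM2, pm2_strength),
            CriterionState.NOT_TRIGGERED,
            f"{top_name} AF {top_af:g} exceeds PM2 cutoff {cutoffs.pm2:g}",
        )
    return pm2, ba1, bs1
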