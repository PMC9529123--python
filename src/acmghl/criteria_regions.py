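"""Protein-length and repeat-region criteria: PM4 and BP3.

PM4 fires for in-frame deletions/duplications and stop-loss variants that
escape PVS1, lie outside repeat regions and change the protein length by
more than 10%.  BP3 fires when the variant-affected coding region overlaps
a repeat region with no overlapping protein domain.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

from .config import EngineConfig
from .core import (
    ConsequenceKind,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    GenomicVariant,
    TranscriptModel,
    VariantConsequence,
)
from .pvs1 import STOP_CODONS, build_observed_cds, locate_ptc, revcomp
from .resources import ResourceBundle

logger = logging.getLogger(__name__)

__all__ = ["protein_length_change", "evaluate_pm4", "evaluate_bp3"]

PM4_KINDS = frozenset(
    {
        ConsequenceKind.INFRAME_DELETION,
        ConsequenceKind.INFRAME_DUPLICATION,
        ConsequenceKind.STOP_LOST,
    }
)
BP3_KINDS = frozenset(
    {
        ConsequenceKind.INFRAME_DELETION,
        ConsequenceKind.INFRAME_DUPLICATION,
        ConsequenceKind.STOP_GAINED,
    }
)


def _three_prime_flank(t: TranscriptModel, genome) -> str:
    """Exonic sequence 3' of the stop codon, in transcript orientation."""
    pieces = []
    for s, e in t.exons:
        if t.strand == "+":
            fs, fe = max(s, t.cds_end), e
        else:
            fs, fe = s, min(e, t.cds_start)
        if fs < fe:
            pieces.append(genome.seq(t.chrom, fs, fe))
    if t.strand == "-":
        pieces = [revcomp(p) for p in reversed(pieces)]
    return "".join(pieces)


def protein_length_change(
    t: TranscriptModel,
    v: GenomicVariant,
    bundle: ResourceBundle,
    config: Optional[EngineConfig] = None,
) -> Tuple[float, Optional[str]]:
    """Fractional change of the observed protein length vs. the reference.

    The observed length runs to the first in-frame stop of the mutated
    coding sequence; a lost terminal stop extends translation into the
    3' UTR until the next in-frame stop (to the transcript end, with a
    warning, if none exists).  Returns ``(fraction, warning-or-None)``.
    """
    config = config or EngineConfig()
    observed = build_observed_cds(t, v, bundle.genome, config.splice_model)
    ref_len = t.cds_length // 3 - 1
    if ref_len <= 0:
        return 0.0, "reference protein empty"
    seq = observed.sequence
    stop = locate_ptc(seq)
    warning = None
    if stop is None:
        flank = _three_prime_flank(t, bundle.genome)
        tail_frame = len(seq) % 3
        extended = seq + flank
        stop = None
        for off in range(0, len(extended) - 2, 3):
            if extended[off : off + 3] in STOP_CODONS:
                stop = off
                break
        if stop is None:
            stop = (len(extended) // 3) * 3
            warning = (
                f"{t.transcript_id}: no in-frame stop downstream of lost "
                "terminator; extension taken to the transcript end"
            )
            logger.warning(warning)
        if tail_frame:
            # partial final codon of the CDS completes in the UTR flank
            pass
    obs_len = stop // 3
    return abs(obs_len - ref_len) / ref_len, warning


def evaluate_pm4(
    v: GenomicVariant,
    consequence: VariantConsequence,
    t: TranscriptModel,
    bundle: ResourceBundle,
    pvs1_result: CriterionResult,
    config: Optional[EngineConfig] = None,
) -> CriterionResult:
    """PM4: protein-length change > 10% outside repeats, PVS1 silent."""
    if consequence.kind not in PM4_KINDS:
        return CriterionResult(
            CriterionId(Criterion.PM4), CriterionState.NOT_APPLICABLE
        )
    if pvs1_result.triggered:
        return CriterionResult(
            CriterionId(Criterion.PM4),
            CriterionState.NOT_TRIGGERED,
            f"PVS1 already triggered at {pvs1_result.criterion.label}; "
            "PM4 withheld",
        )
    interval = consequence.affected_cds_interval
    if interval is not None:
        repeats = bundle.query_track("repeat_no_domain", v.chrom, *interval)
        if repeats:
            return CriterionResult(
                CriterionId(Criterion.PM4),
                CriterionState.NOT_TRIGGERED,
                f"variant affects repeat region {repeats[0][2]!r}",
            )
    change, warning = protein_length_change(t, v, bundle, config)
    if change > 0.10:
        return CriterionResult(
            CriterionId(Criterion.PM4),
            CriterionState.TRIGGERED,
            f"{t.transcript_id}: protein length changes by {change:.1%} "
            "(>10%) outside repeat regions"
            + (f"; {warning}" if warning else ""),
        )
    return CriterionResult(
        CriterionId(Criterion.PM4),
        CriterionState.NOT_TRIGGERED,
        f"{t.transcript_id}: protein length changes by {change:.1%} (<=10%)",
    )


def evaluate_bp3(
    v: GenomicVariant,
    consequence: VariantConsequence,
    t: TranscriptModel,
    bundle: ResourceBundle,
) -> CriterionResult:
    """BP3: affected coding region inside a repeat without known function."""
    if consequence.kind not in BP3_KINDS:
        return CriterionResult(
            CriterionId(Criterion.BP3), CriterionState.NOT_APPLICABLE
        )
    interval = consequence.affected_cds_interval
    hits = (
        bundle.query_track("repeat_no_domain", v.chrom, *interval)
        if interval is not None
        else []
    )
    if hits:
        return CriterionResult(
            CriterionId(Criterion.BP3),
            CriterionState.TRIGGERED,
            f"affected coding region overlaps functionless repeat "
            f"{hits[0][2]!r}",
        )
    return CriterionResult(
        CriterionId(Criterion.BP3),
        CriterionState.NOT_TRIGGERED,
        "affected coding region overlaps no functionless repeat",
    )
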