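"""ClinVar- and region-lookup criteria: PS1, PM5 (with strong form), PM1.

PS1/PM5 compare the observed missense change against curated entries at the
same codon: the codon's genomic positions are computed strand-aware and
exon-junction-aware, curated missense records at those positions are
filtered by gene strand and review stars, and the amino-acid changes are
compared.  PM1 tests membership in critical protein regions that carry no
benign curated entry.
"""

from __future__ import annotations

from typing import Optional, Tuple

from .config import EngineConfig
from .core import (
    ConsequenceKind,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    GenomicVariant,
    Strength,
    TranscriptModel,
    VariantConsequence,
)
from .hgvs import parse_protein_change
from .resources import ClinVarSignificance, ResourceBundle

__all__ = ["evaluate_ps1_pm5", "evaluate_pm1"]


def evaluate_ps1_pm5(
    consequence: VariantConsequence,
    t: TranscriptModel,
    bundle: ResourceBundle,
    config: Optional[EngineConfig] = None,
) -> Tuple[CriterionResult, CriterionResult]:
    """Evaluate PS1 and PM5 for one missense consequence.

    PS1 fires on an identical amino-acid change already curated pathogenic;
    PM5 fires on a *different* pathogenic change at the same codon, at
    strong strength when two or more distinct such changes exist.  The two
    criteria are mutually exclusive by construction.
    """
    config = config or EngineConfig()
    na = lambda c: CriterionResult(CriterionId(c), CriterionState.NOT_APPLICABLE)
    if consequence.kind is not ConsequenceKind.MISSENSE:
        return na(Criterion.PS1), na(Criterion.PM5)
    codon = consequence.affected_codon_index
    observed = parse_protein_change(consequence.hgvs_p)
    if codon is None or observed is None:
        return na(Criterion.PS1), na(Criterion.PM5)
    obs_alt = observed[2]

    records = bundle.query_clinvar_codon(t, codon, min_stars=config.min_stars)
    pathogenic_sig = {ClinVarSignificance.PATHOGENIC}
    if config.ps1_include_likely:
        pathogenic_sig.add(ClinVarSignificance.LIKELY_PATHOGENIC)

    same, different = [], []
    for rec in records:
        if rec.significance not in pathogenic_sig:
            continue
        parsed = rec.protein_change
        if parsed is None:
            continue
        (same if parsed[2] == obs_alt else different).append(rec)

    residue = codon + 1
    if same:
        ps1 = CriterionResult(
            CriterionId(Criterion.PS1),
            CriterionState.TRIGGERED,
            f"{t.transcript_id}: pathogenic curated variant with identical "
            f"amino-acid change {consequence.hgvs_p} at codon {residue} "
            f"({len(same)} record(s), >= {config.min_stars} star(s))",
        )
        pm5 = CriterionResult(
            CriterionId(Criterion.PM5),
            CriterionState.NOT_TRIGGERED,
            "identical amino-acid change known pathogenic (PS1 applies)",
        )
        return ps1, pm5

    ps1 = CriterionResult(
        CriterionId(Criterion.PS1),
        CriterionState.NOT_TRIGGERED,
        f"{t.transcript_id}: no pathogenic curated variant reproduces "
        f"{consequence.hgvs_p or 'the observed change'}",
    )
    if not different:
        return ps1, CriterionResult(
            CriterionId(Criterion.PM5),
            CriterionState.NOT_TRIGGERED,
            f"{t.transcript_id}: no pathogenic curated missense at codon {residue}",
        )

    if config.pm5_count_residues:
        multiplicity = len({rec.protein_change[2] for rec in different})
    else:
        multiplicity = len({(rec.pos, rec.ref, rec.alt) for rec in different})
    strength = Strength.STRONG if multiplicity >= 2 else Strength.MODERATE
    pm5 = CriterionResult(
        CriterionId(Criterion.PM5, strength),
        CriterionState.TRIGGERED,
        f"{t.transcript_id}: {multiplicity} distinct pathogenic change(s) at "
        f"codon {residue} different from {consequence.hgvs_p}"
        + (" (applied as strong evidence)" if strength is Strength.STRONG else ""),
    )
    return ps1, pm5


def evaluate_pm1(
    v: GenomicVariant,
    consequence: VariantConsequence,
    t: TranscriptModel,
    bundle: ResourceBundle,
) -> CriterionResult:
    """PM1: variant falls in a critical protein region free of benign
    curated entries (track also carries the expert-panel domains/motifs)."""
    if consequence.affected_cds_interval is None:
        return CriterionResult(
            CriterionId(Criterion.PM1), CriterionState.NOT_APPLICABLE
        )
    hits = bundle.query_track(
        "critical_region_no_benign", v.chrom, v.pos, max(v.end, v.pos + 1)
    )
    if hits:
        return CriterionResult(
            CriterionId(Criterion.PM1),
            CriterionState.TRIGGERED,
            f"variant lies in benign-free critical region {hits[0][2]!r}",
        )
    return CriterionResult(
        CriterionId(Criterion.PM1),
        CriterionState.NOT_TRIGGERED,
        "variant overlaps no benign-free critical region",
    )
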