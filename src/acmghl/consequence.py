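"""Minimal per-transcript consequence annotation over provided transcript
models.

This replaces an external annotation pipeline for offline use: given a
normalised variant, a transcript model and the reference genome, it
determines the functional consequence kind, simple HGVS-style c./p. names,
the variant-affected coding region and the first affected codon.
"""

from __future__ import annotations

import logging
from typing import List, Optional

from Bio.Seq import Seq

from . import hgvs
from .core import (
    ConsequenceKind,
    GenomicVariant,
    TranscriptModel,
    VariantConsequence,
)
from .pvs1 import (
    build_observed_cds,
    reference_cds_segments,
    splice_site_disruption,
)
from .resources import Genome, ResourceBundle

logger = logging.getLogger(__name__)

__all__ = ["classify_consequence", "annotate_variant"]


def _translate_codon(codon: str) -> str:
    return "*" if len(codon) < 3 else str(Seq(codon).translate())


def _first_changed_cds_offset(t: TranscriptModel, v: GenomicVariant) -> Optional[int]:
    """Smallest CDS offset touched by the variant's changed bases.

    For anchored indels the anchor base is unchanged; for SNVs the single
    position is used.
    """
    if v.is_snv:
        return t.genomic_to_cds(v.pos)
    changed = range(v.pos + 1, v.end) if v.ref[0] == v.alt[0] else range(v.pos, v.end)
    if not changed:  # pure insertion: attribute to the base after the anchor
        changed = range(v.pos, v.pos + 1)
    offsets = [t.genomic_to_cds(p) for p in changed]
    offsets = [o for o in offsets if o is not None]
    return min(offsets) if offsets else None


def classify_consequence(
    v: GenomicVariant, t: TranscriptModel, genome: Genome
) -> VariantConsequence:
    """Classify one variant against one transcript."""
    # canonical splice sites take precedence over exonic annotation
    splice = splice_site_disruption(t, v)
    if splice is not None:
        kind, skipped = splice
        interval = None
        for i, gs, ge in t.coding_intervals():
            if i == skipped:
                interval = (gs, ge)
        return VariantConsequence(
            variant=v,
            transcript_id=t.transcript_id,
            kind=kind,
            hgvs_c=f"c.{kind.value}_exon{skipped + 1}",
            affected_cds_interval=interval,
        )

    in_transcript = t.exons[0][0] <= v.pos and v.end <= t.exons[-1][1]
    overlaps_exon = any(v.pos < e and v.end > s for s, e in t.exons)
    if not overlaps_exon:
        return VariantConsequence(
            v, t.transcript_id,
            ConsequenceKind.INTRONIC if in_transcript else ConsequenceKind.OTHER,
        )

    cds_overlap = (max(v.pos, t.cds_start), min(v.end, t.cds_end))
    if cds_overlap[0] >= cds_overlap[1]:
        return VariantConsequence(v, t.transcript_id, ConsequenceKind.OTHER)

    try:
        observed = build_observed_cds(t, v, genome)
    except ValueError as exc:
        logger.warning("%s on %s: %s", v, t.transcript_id, exc)
        return VariantConsequence(v, t.transcript_id, ConsequenceKind.OTHER)

    ref_seq = reference_cds_segments(t, genome).sequence
    obs_seq = observed.sequence
    off = _first_changed_cds_offset(t, v)
    if off is None:
        off = t.genomic_to_cds(cds_overlap[0]) or 0
    codon_index = off // 3
    dlen = len(v.alt) - len(v.ref)

    if dlen % 3 != 0:
        kind = ConsequenceKind.FRAMESHIFT
        ref_aa = _translate_codon(ref_seq[3 * codon_index : 3 * codon_index + 3])
        hgvs_p = f"p.{hgvs.protein_change(ref_aa, codon_index + 1, ref_aa)[2:5]}{codon_index + 1}fs"
    elif dlen < 0:
        kind = ConsequenceKind.INFRAME_DELETION
        hgvs_p = ""
    elif dlen > 0:
        kind = ConsequenceKind.INFRAME_DUPLICATION
        hgvs_p = ""
    else:
        ref_codon = ref_seq[3 * codon_index : 3 * codon_index + 3]
        alt_codon = obs_seq[3 * codon_index : 3 * codon_index + 3]
        ref_aa, alt_aa = _translate_codon(ref_codon), _translate_codon(alt_codon)
        if codon_index == 0 and alt_codon != "ATG":
            kind = ConsequenceKind.START_LOSS
            hgvs_p = "p.Met1?"
        elif ref_aa == alt_aa:
            kind = ConsequenceKind.SYNONYMOUS
            hgvs_p = hgvs.protein_change(ref_aa, codon_index + 1, alt_aa)
        elif alt_aa == "*":
            kind = ConsequenceKind.STOP_GAINED
            hgvs_p = hgvs.protein_change(ref_aa, codon_index + 1, "*")
        elif ref_aa == "*":
            kind = ConsequenceKind.STOP_LOST
            hgvs_p = hgvs.protein_change("*", codon_index + 1, alt_aa)
        else:
            kind = ConsequenceKind.MISSENSE
            hgvs_p = hgvs.protein_change(ref_aa, codon_index + 1, alt_aa)

    return VariantConsequence(
        variant=v,
        transcript_id=t.transcript_id,
        kind=kind,
        hgvs_c=hgvs.coding_change(off + 1, v.ref, v.alt),
        hgvs_p=hgvs_p,
        affected_cds_interval=cds_overlap,
        affected_codon_index=codon_index,
    )


def annotate_variant(
    v: GenomicVariant, bundle: ResourceBundle
) -> List[VariantConsequence]:
    """Consequences of one variant against every overlapping transcript.

    Ordered deterministically: phenotype-relevant transcripts first, then
    lexicographically by transcript id.
    """
    hits = bundle.transcripts_overlapping(v.chrom, v.pos, v.end)
    hits.sort(key=lambda t: (not t.phenotype_relevant, t.transcript_id))
    return [classify_consequence(v, t, bundle.genome) for t in hits]
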