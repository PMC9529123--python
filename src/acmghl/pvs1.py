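"""Refined PVS1: observed coding sequence, NMD prediction, decision tree.

The loss-of-function criterion PVS1 is evaluated per (variant, transcript)
in four stages:

1. Build the *observed* coding sequence per exon by applying the variant to
   the reference CDS.  Canonical splice acceptor/donor disruption is
   modelled as skipping the adjacent exon (configurable to intron
   retention).
2. Locate the 5'-closest in-frame stop codon of the observed sequence; if
   it is not the final codon, it is a premature termination codon (PTC).
3. Predict whether the transcript escapes nonsense-mediated decay (NMD).
   The sequence escapes if the PTC lies within the last 50 bases of the
   penultimate exon, at most 200 bases downstream of the start codon, or
   the transcript is intronless; otherwise NMD is predicted to occur.
4. Walk the refined PVS1 decision tree: NMD degrading a phenotype-relevant
   transcript is very-strong evidence; NMD-escaping truncations are graded
   by protein-domain criticality or, failing that, by clinically
   significant exon membership and the fraction of protein removed.

Start-loss variants take a separate branch that searches for an in-frame
rescue start codon within 200 bases and consults the clinical-variant
table over the skipped region.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .config import EngineConfig
from .core import (
    ConsequenceKind,
    Criterion,
    CriterionId,
    CriterionResult,
    CriterionState,
    GenomicVariant,
    LOF_KINDS,
    Strength,
    TranscriptModel,
)
from .resources import ClinVarSignificance, Genome, ResourceBundle

logger = logging.getLogger(__name__)

__all__ = [
    "NMDOutcome",
    "NMDReason",
    "ObservedCDS",
    "build_observed_cds",
    "evaluate_pvs1",
    "evaluate_start_loss",
    "locate_ptc",
    "predict_nmd",
    "reference_cds_segments",
    "splice_site_disruption",
]

_RC = str.maketrans("ACGT", "TGCA")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: escape windows of the NMD rule (bases)
PENULTIMATE_EXON_WINDOW = 50
START_PROXIMAL_WINDOW = 200
#: search range for an in-frame rescue start codon after start loss (bases)
RESCUE_START_WINDOW = 200


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class NMDReason(str, enum.Enum):
    PENULTIMATE_EXON_LAST50 = "penultimate_exon_last50"
    WITHIN_200BP_OF_START = "within_200bp_of_start"
    INTRONLESS = "intronless"
    LAST_EXON = "last_exon"  # only with the optional last-exon escape clause
    NMD_PREDICTED = "nmd_predicted"
    NO_PTC = "no_ptc"


@dataclass(frozen=True)
class NMDOutcome:
    occurs: bool
    ptc_position: Optional[int]  # CDS offset of the PTC's first base
    reason: NMDReason

    def __post_init__(self) -> None:
        escape = {
            NMDReason.PENULTIMATE_EXON_LAST50,
            NMDReason.WITHIN_200BP_OF_START,
            NMDReason.INTRONLESS,
            NMDReason.LAST_EXON,
            NMDReason.NO_PTC,
        }
        if self.occurs == (self.reason in escape):
            raise ValueError("occurs flag inconsistent with reason")
        if self.reason is not NMDReason.NO_PTC and self.ptc_position is None:
            raise ValueError("ptc_position required unless reason=no_ptc")


@dataclass(frozen=True)
class ObservedCDS:
    """Mutated coding sequence partitioned per (observed) exon.

    ``segments`` hold ``(source_exon_index, sequence)`` in 5'->3'
    transcript order with sequences already oriented to the coding strand.
    An index of -1 marks a retained intron.
    """

    segments: tuple

    @property
    def sequence(self) -> str:
        return "".join(s for _, s in self.segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def locate(self, cds_offset: int) -> Tuple[int, int]:
        """Map a CDS offset to (segment ordinal, offset within segment)."""
        off = cds_offset
        for k, (_, seq) in enumerate(self.segments):
            if off < len(seq):
                return k, off
            off -= len(seq)
        raise ValueError(f"offset {cds_offset} beyond observed CDS")


# ---------------------------------------------------------------------------
# observed-CDS construction
# ---------------------------------------------------------------------------


def splice_site_disruption(
    t: TranscriptModel, v: GenomicVariant
) -> Optional[Tuple[ConsequenceKind, int]]:
    """Detect canonical (+/-2) splice-site disruption.

    Returns ``(kind, skipped_genomic_exon_index)`` or None.  The exon on
    the transcript-5' side of the intron is skipped for donor loss, the
    3'-side exon for acceptor loss.
    """
    for i in range(len(t.exons) - 1):
        gap_start, gap_end = t.exons[i][1], t.exons[i + 1][0]
        five = (gap_start, gap_start + 2)  # genomic-left edge of the intron
        three = (gap_end - 2, gap_end)
        for window, genomic_left in ((five, True), (three, False)):
            if v.pos < window[1] and v.end > window[0]:
                if t.strand == "+":
                    kind = (
                        ConsequenceKind.SPLICE_DONOR
                        if genomic_left
                        else ConsequenceKind.SPLICE_ACCEPTOR
                    )
                    skipped = i if genomic_left else i + 1
                else:
                    kind = (
                        ConsequenceKind.SPLICE_ACCEPTOR
                        if genomic_left
                        else ConsequenceKind.SPLICE_DONOR
                    )
                    skipped = i + 1 if genomic_left else i
                return kind, skipped
    return None


def reference_cds_segments(t: TranscriptModel, genome: Genome) -> ObservedCDS:
    """Reference coding sequence per exon, oriented 5'->3'."""
    pieces = []
    for i, gs, ge in t.coding_intervals():
        pieces.append((i, genome.seq(t.chrom, gs, ge)))
    if t.strand == "-":
        pieces = [(i, revcomp(s)) for i, s in reversed(pieces)]
    return ObservedCDS(tuple(pieces))


def build_observed_cds(
    t: TranscriptModel,
    v: GenomicVariant,
    genome: Genome,
    splice_model: str = "skip",
) -> ObservedCDS:
    """Apply the variant to the transcript's CDS, per exon.

    Raises ``ValueError`` when the variant neither lies in the CDS nor
    disrupts a canonical splice site (PVS1 not applicable).
    """
    splice = splice_site_disruption(t, v)
    coding = t.coding_intervals()
    if splice is not None:
        _, skipped = splice
        if splice_model == "skip":
            pieces = [
                (i, genome.seq(t.chrom, gs, ge))
                for i, gs, ge in coding
                if i != skipped
            ]
        else:  # intron retention: splice in the intron downstream of 5' exon
            pieces = []
            for k, (i, gs, ge) in enumerate(coding):
                pieces.append((i, genome.seq(t.chrom, gs, ge)))
                if k + 1 < len(coding):
                    nxt = coding[k + 1]
                    gap = (t.exons[i][1], t.exons[nxt[0]][0])
                    touches = (
                        i == skipped if (t.strand == "+") else nxt[0] == skipped
                    )
                    if touches:
                        pieces.append((-1, genome.seq(t.chrom, *gap)))
        if t.strand == "-":
            pieces = [(i, revcomp(s)) for i, s in reversed(pieces)]
        return ObservedCDS(tuple(pieces))

    # exonic edit: the reference span must fall inside one coding segment
    hit = None
    for i, gs, ge in coding:
        if gs <= v.pos and v.end <= ge:
            hit = (i, gs, ge)
            break
    if hit is None:
        overlaps = any(v.pos < ge and v.end > gs for _, gs, ge in coding)
        if overlaps:
            raise ValueError(
                f"variant {v} straddles a coding-segment boundary of "
                f"{t.transcript_id}; unsupported"
            )
        raise ValueError(
            f"PVS1 not applicable: variant {v} outside the CDS of "
            f"{t.transcript_id} and not at a canonical splice site"
        )
    pieces = []
    for i, gs, ge in coding:
        seq = genome.seq(t.chrom, gs, ge)
        if i == hit[0]:
            seq = seq[: v.pos - gs] + v.alt + seq[v.end - gs :]
        pieces.append((i, seq))
    if t.strand == "-":
        pieces = [(i, revcomp(s)) for i, s in reversed(pieces)]
    return ObservedCDS(tuple(pieces))


# ---------------------------------------------------------------------------
# PTC location and NMD prediction
# ---------------------------------------------------------------------------


def locate_ptc(sequence: str) -> Optional[int]:
    """CDS offset of the first base of the 5'-closest in-frame stop codon."""
    if len(sequence) < 3:
        raise ValueError("observed CDS shorter than one codon")
    for off in range(0, len(sequence) - 2, 3):
        if sequence[off : off + 3] in STOP_CODONS:
            return off
    return None


def is_premature(observed: ObservedCDS, ptc: Optional[int]) -> bool:
    """A stop is premature unless it is the final complete codon."""
    if ptc is None:
        return False
    seq_len = len(observed.sequence)
    last_codon_offset = (seq_len // 3 - 1) * 3
    return ptc != last_codon_offset


def predict_nmd(
    observed: ObservedCDS, ptc: int, last_exon_escape: bool = False
) -> NMDOutcome:
    """Apply the NMD escape rule to a located PTC.

    Escape conditions, checked in order: PTC within the 50 last bases of
    the penultimate exon; PTC at most 200 bases downstream of the start
    codon; intronless transcript.  ``last_exon_escape`` appends the
    optional "PTC in the last exon" clause.
    """
    seg, off = observed.locate(ptc)
    if observed.n_segments >= 2 and seg == observed.n_segments - 2:
        seg_len = len(observed.segments[seg][1])
        if seg_len - off <= PENULTIMATE_EXON_WINDOW:
            return NMDOutcome(False, ptc, NMDReason.PENULTIMATE_EXON_LAST50)
    if ptc <= START_PROXIMAL_WINDOW:
        return NMDOutcome(False, ptc, NMDReason.WITHIN_200BP_OF_START)
    if observed.n_segments == 1:
        return NMDOutcome(False, ptc, NMDReason.INTRONLESS)
    if last_exon_escape and seg == observed.n_segments - 1:
        return NMDOutcome(False, ptc, NMDReason.LAST_EXON)
    return NMDOutcome(True, ptc, NMDReason.NMD_PREDICTED)


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------


def _affected_interval(
    t: TranscriptModel, v: GenomicVariant
) -> Optional[Tuple[int, int]]:
    """Variant-affected coding region: ref span (or skipped exon) within CDS."""
    splice = splice_site_disruption(t, v)
    if splice is not None:
        _, skipped = splice
        for i, gs, ge in t.coding_intervals():
            if i == skipped:
                return (gs, ge)
        return None
    start = max(v.pos, t.cds_start)
    end = min(v.end, t.cds_end)
    return (start, end) if start < end else None


def _intersects_phenotype_relevant(
    bundle: ResourceBundle, chrom: str, interval: Tuple[int, int]
) -> Optional[str]:
    """Id of a phenotype-relevant transcript whose CDS overlaps the region."""
    for t in sorted(bundle.transcripts.values(), key=lambda t: t.transcript_id):
        if not t.phenotype_relevant or t.chrom != chrom:
            continue
        for _, gs, ge in t.coding_intervals():
            if gs < interval[1] and ge > interval[0]:
                return t.transcript_id
    return None


def evaluate_pvs1(
    v: GenomicVariant,
    consequence_kind: ConsequenceKind,
    t: TranscriptModel,
    bundle: ResourceBundle,
    config: Optional[EngineConfig] = None,
) -> CriterionResult:
    """Refined PVS1 decision tree for one (variant, transcript) pair."""
    config = config or EngineConfig()
    if consequence_kind not in LOF_KINDS:
        return CriterionResult(
            CriterionId(Criterion.PVS1), CriterionState.NOT_APPLICABLE
        )
    if consequence_kind is ConsequenceKind.START_LOSS:
        return evaluate_start_loss(v, t, bundle, config)

    try:
        observed = build_observed_cds(t, v, bundle.genome, config.splice_model)
    except ValueError as exc:
        return CriterionResult(
            CriterionId(Criterion.PVS1), CriterionState.NOT_TRIGGERED, str(exc)
        )
    ptc = locate_ptc(observed.sequence)
    if not is_premature(observed, ptc):
        return CriterionResult(
            CriterionId(Criterion.PVS1),
            CriterionState.NOT_TRIGGERED,
            f"{t.transcript_id}: observed coding sequence carries no premature "
            "termination codon",
        )

    nmd = predict_nmd(observed, ptc, config.nmd_last_exon_escape)
    interval = _affected_interval(t, v)
    if interval is None:
        return CriterionResult(
            CriterionId(Criterion.PVS1),
            CriterionState.NOT_TRIGGERED,
            f"{t.transcript_id}: variant-affected coding region is empty",
        )

    if nmd.occurs:
        hit = _intersects_phenotype_relevant(bundle, t.chrom, interval)
        if hit is not None:
            return CriterionResult(
                CriterionId(Criterion.PVS1, Strength.VERY_STRONG),
                CriterionState.TRIGGERED,
                f"{t.transcript_id}: NMD predicted (PTC at CDS offset "
                f"{ptc}); affected region intersects phenotype-relevant "
                f"transcript {hit}",
            )
        return CriterionResult(
            CriterionId(Criterion.PVS1),
            CriterionState.NOT_TRIGGERED,
            f"{t.transcript_id}: NMD predicted but affected region "
            "intersects no phenotype-relevant transcript",
        )

    # NMD escape: grade the surviving truncated protein
    domain_hits = bundle.query_track("protein_domain", t.chrom, *interval)
    if domain_hits:
        critical = bundle.query_track("critical_region", t.chrom, *interval)
        if critical:
            label = critical[0][2]
            return CriterionResult(
                CriterionId(Criterion.PVS1, Strength.STRONG),
                CriterionState.TRIGGERED,
                f"{t.transcript_id}: NMD escape ({nmd.reason.value}); "
                f"truncated region lies in critical domain {label!r}",
            )
        return CriterionResult(
            CriterionId(Criterion.PVS1, Strength.MODERATE),
            CriterionState.TRIGGERED,
            f"{t.transcript_id}: NMD escape ({nmd.reason.value}); truncated "
            f"region lies in protein domain {domain_hits[0][2]!r} not marked "
            "critical",
        )

    exon_hits = bundle.query_track("clinically_significant_exon", t.chrom, *interval)
    if exon_hits and _intersects_phenotype_relevant(bundle, t.chrom, interval):
        ref_len = t.cds_length // 3 - 1  # residues, excluding the stop
        retained = ptc // 3
        removed_fraction = (ref_len - retained) / ref_len if ref_len > 0 else 0.0
        if removed_fraction > 0.10:
            return CriterionResult(
                CriterionId(Criterion.PVS1, Strength.STRONG),
                CriterionState.TRIGGERED,
                f"{t.transcript_id}: NMD escape ({nmd.reason.value}); "
                f"clinically significant exon; PTC removes "
                f"{removed_fraction:.1%} (>10%) of the reference protein",
            )
        return CriterionResult(
            CriterionId(Criterion.PVS1, Strength.MODERATE),
            CriterionState.TRIGGERED,
            f"{t.transcript_id}: NMD escape ({nmd.reason.value}); clinically "
            f"significant exon; PTC removes {removed_fraction:.1%} "
            "(<=10%) of the reference protein",
        )

    return CriterionResult(
        CriterionId(Criterion.PVS1),
        CriterionState.NOT_TRIGGERED,
        f"{t.transcript_id}: NMD escape ({nmd.reason.value}); truncated "
        "region in no protein domain and no clinically significant exon of "
        "a phenotype-relevant transcript",
    )


def evaluate_start_loss(
    v: GenomicVariant,
    t: TranscriptModel,
    bundle: ResourceBundle,
    config: Optional[EngineConfig] = None,
) -> CriterionResult:
    """Start-loss branch of PVS1.

    If another transcript of the gene provides a different start codon the
    criterion is left not_triggered (the alternative start may rescue
    translation).  Otherwise the nearest in-frame ATG within 200 bases
    downstream is sought; a pathogenic clinical-variant entry between the
    lost and the rescue start upgrades the evidence to moderate, else it
    stays supporting.
    """
    config = config or EngineConfig()
    own_start = t.cds_to_genomic(0)
    for other in bundle.transcripts_for_gene(t.gene_symbol):
        if other.transcript_id == t.transcript_id:
            continue
        if other.cds_to_genomic(0) != own_start:
            return CriterionResult(
                CriterionId(Criterion.PVS1),
                CriterionState.NOT_TRIGGERED,
                f"{t.transcript_id}: start lost but transcript "
                f"{other.transcript_id} provides an alternative start codon",
            )

    ref = reference_cds_segments(t, bundle.genome).sequence
    rescue_offset = None
    for off in range(3, min(RESCUE_START_WINDOW, len(ref) - 2) + 1, 3):
        if ref[off : off + 3] == "ATG":
            rescue_offset = off
            break
    if rescue_offset is None:
        return CriterionResult(
            CriterionId(Criterion.PVS1, Strength.SUPPORTING),
            CriterionState.TRIGGERED,
            f"{t.transcript_id}: start lost; no rescue start found within "
            f"{RESCUE_START_WINDOW} bases downstream",
        )

    gpositions = [t.cds_to_genomic(off) for off in range(0, rescue_offset)]
    lo, hi = min(gpositions), max(gpositions) + 1
    pathogenic = bundle.query_clinvar_range(
        t.chrom,
        lo,
        hi,
        significance_filter={ClinVarSignificance.PATHOGENIC},
        min_stars=config.min_stars,
    )
    if pathogenic:
        return CriterionResult(
            CriterionId(Criterion.PVS1, Strength.MODERATE),
            CriterionState.TRIGGERED,
            f"{t.transcript_id}: start lost; rescue start at CDS offset "
            f"{rescue_offset}; {len(pathogenic)} pathogenic clinical "
            "entr(y/ies) in the skipped region",
        )
    return CriterionResult(
        CriterionId(Criterion.PVS1, Strength.SUPPORTING),
        CriterionState.TRIGGERED,
        f"{t.transcript_id}: start lost; rescue start at CDS offset "
        f"{rescue_offset}; no pathogenic clinical entry in the skipped region",
    )
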