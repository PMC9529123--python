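"""Core domain types shared by every criterion evaluator and the classifier.

Conventions
-----------
* All internal genomic coordinates are 0-based, half-open.  VCF input/output
  converts at the boundary (VCF is 1-based).
* A :class:`TranscriptModel` stores exons in ascending genomic order
  regardless of strand; transcript-orientation logic (5'->3') is handled by
  the coordinate-mapping helpers.
* Criterion identifiers combine a base rule (PVS1 ... BP7) with a strength
  modifier; ``Strength.DEFAULT`` means "the strength implied by the rule
  name" (PS -> strong, PM -> moderate, ...).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "ACMGClass",
    "BroaderClass",
    "ConsequenceKind",
    "Criterion",
    "CriterionId",
    "CriterionResult",
    "CriterionState",
    "ClassifiedVariant",
    "EvidenceSet",
    "GenomicVariant",
    "Strength",
    "TranscriptModel",
    "VariantConsequence",
    "evidence_set_from_results",
    "to_broader",
]

_VALID_BASES = frozenset("ACGT")


class Criterion(str, enum.Enum):
    """The 12 automatable ACMG/AMP rules specialised for hearing loss."""

    PVS1 = "PVS1"
    PS1 = "PS1"
    PM1 = "PM1"
    PM2 = "PM2"
    PM4 = "PM4"
    PM5 = "PM5"
    PP3 = "PP3"
    BA1 = "BA1"
    BS1 = "BS1"
    BP3 = "BP3"
    BP4 = "BP4"
    BP7 = "BP7"

    @property
    def direction(self) -> str:
        """'pathogenic' for P* rules, 'benign' for B* rules."""
        return "pathogenic" if self.value.startswith("P") else "benign"

    @property
    def default_strength(self) -> "Strength":
        prefix = self.value[:-1] if self.value[-1].isdigit() else self.value
        return _DEFAULT_STRENGTH[prefix]


class Strength(enum.IntEnum):
    """Evidence strength; the integer order is weakest -> strongest."""

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5


_DEFAULT_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}

# Strength modifiers each rule may legally carry (beyond its default).
_ALLOWED_MODIFIED = {
    Criterion.PVS1: {
        Strength.VERY_STRONG,
        Strength.STRONG,
        Strength.MODERATE,
        Strength.SUPPORTING,
    },
    Criterion.PM5: {Strength.MODERATE, Strength.STRONG},
    Criterion.PM2: {Strength.MODERATE, Strength.SUPPORTING},
    Criterion.BS1: {Strength.STRONG, Strength.SUPPORTING},
}


@dataclass(frozen=True)
class CriterionId:
    """A base rule together with the strength it is applied at."""

    base: Criterion
    strength: Optional[Strength] = None  # None == default for the rule

    def __post_init__(self) -> None:
        if self.strength is not None:
            allowed = _ALLOWED_MODIFIED.get(self.base, {self.base.default_strength})
            if self.strength not in allowed:
                raise ValueError(
                    f"{self.base.value} cannot be applied at strength "
                    f"{self.strength.name}"
                )

    @property
    def effective_strength(self) -> Strength:
        return self.strength if self.strength is not None else self.base.default_strength

    @property
    def direction(self) -> str:
        return self.base.direction

    @property
    def label(self) -> str:
        if self.strength is None or self.strength == self.base.default_strength:
            return self.base.value
        return f"{self.base.value}_{self.strength.name.title().replace('_', '')}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


class CriterionState(str, enum.Enum):
    TRIGGERED = "triggered"
    NOT_TRIGGERED = "not_triggered"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of evaluating one rule, with an explanatory comment."""

    criterion: CriterionId
    state: CriterionState
    comment: str = ""

    def __post_init__(self) -> None:
        if self.state is not CriterionState.NOT_APPLICABLE and not self.comment:
            raise ValueError(
                f"{self.criterion.label}: comment required for state {self.state.value}"
            )

    @property
    def triggered(self) -> bool:
        return self.state is CriterionState.TRIGGERED


@dataclass(frozen=True)
class GenomicVariant:
    """A normalised biallelic small variant (SNV or indel).

    ``pos`` is the 0-based position of the first reference base.  Use
    :meth:`from_vcf` when converting from 1-based VCF records.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @classmethod
    def from_vcf(
        cls, chrom: str, pos1: int, ref: str, alt: str, id: Optional[str] = None
    ) -> "GenomicVariant":
        return cls(chrom, pos1 - 1, ref.upper(), alt.upper(), id)

    @property
    def pos1(self) -> int:
        """1-based position for VCF-facing output."""
        return self.pos + 1

    @property
    def end(self) -> int:
        """0-based end of the reference span (half-open)."""
        return self.pos + len(self.ref)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos1}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order; ``cds_start``/``cds_end`` are genomic bounds of the coding
    sequence.  ``clinically_significant_exons`` holds 0-based indices into
    ``exons`` (genomic order).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    phenotype_relevant: bool = False
    clinically_significant_exons: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = -1
        for start, end in exons:
            if start >= end:
                raise ValueError(f"invalid exon interval [{start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if not (self.cds_start < self.cds_end):
            raise ValueError("cds_start must be < cds_end")
        if not any(s <= self.cds_start < e for s, e in exons):
            raise ValueError("cds_start outside exons")
        if not any(s < self.cds_end <= e for s, e in exons):
            raise ValueError("cds_end outside exons")
        object.__setattr__(
            self, "clinically_significant_exons", frozenset(self.clinically_significant_exons)
        )

    # -- derived structure -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_intronless(self) -> bool:
        return len(self.exons) == 1

    def coding_intervals(self) -> list:
        """Per-exon genomic coding intervals, ascending genomic order.

        Returns ``[(exon_index, start, end), ...]`` with empty pieces
        omitted.
        """
        out = []
        for i, (s, e) in enumerate(self.exons):
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((i, cs, ce))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for _, s, e in self.coding_intervals())

    def coding_intervals_5p(self) -> list:
        """Coding intervals ordered 5'->3' in transcript orientation."""
        ivs = self.coding_intervals()
        return ivs if self.strand == "+" else list(reversed(ivs))

    # -- coordinate mapping ------------------------------------------------

    def genomic_to_cds(self, gpos: int) -> Optional[int]:
        """Map a genomic position to its 0-based CDS offset, or None."""
        offset = 0
        for _, s, e in self.coding_intervals_5p():
            if s <= gpos < e:
                return offset + (gpos - s if self.strand == "+" else e - 1 - gpos)
            offset += e - s
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        """Map a 0-based CDS offset to its genomic position."""
        if cpos < 0:
            raise ValueError("negative CDS offset")
        offset = 0
        for _, s, e in self.coding_intervals_5p():
            width = e - s
            if cpos < offset + width:
                rel = cpos - offset
                return s + rel if self.strand == "+" else e - 1 - rel
            offset += width
        raise ValueError(f"CDS offset {cpos} beyond CDS length {offset}")

    def codon_genomic_positions(self, codon_index: int) -> list:
        """Genomic positions of the three bases of a codon (0-based index).

        The positions are returned 5'->3'; a codon spanning an exon
        junction yields non-contiguous positions.
        """
        if codon_index < 0 or 3 * codon_index + 2 >= self.cds_length:
            raise ValueError(
                f"codon {codon_index} outside CDS of {self.transcript_id}"
            )
        return [self.cds_to_genomic(3 * codon_index + k) for k in range(3)]


class ConsequenceKind(str, enum.Enum):
    START_LOSS = "start_loss"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    FRAMESHIFT = "frameshift"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_DUPLICATION = "inframe_duplication"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


#: Kinds eligible for loss-of-function (PVS1) assessment.
LOF_KINDS = frozenset(
    {
        ConsequenceKind.START_LOSS,
        ConsequenceKind.STOP_GAINED,
        ConsequenceKind.STOP_LOST,
        ConsequenceKind.FRAMESHIFT,
        ConsequenceKind.INFRAME_DELETION,
        ConsequenceKind.INFRAME_DUPLICATION,
        ConsequenceKind.SPLICE_ACCEPTOR,
        ConsequenceKind.SPLICE_DONOR,
    }
)


@dataclass(frozen=True)
class VariantConsequence:
    """Per-transcript functional effect of one variant."""

    variant: GenomicVariant
    transcript_id: str
    kind: ConsequenceKind
    hgvs_c: str = ""
    hgvs_p: str = ""
    #: genomic interval (0-based half-open) of the variant-affected coding
    #: region; None for non-coding consequences
    affected_cds_interval: Optional[tuple] = None
    #: 0-based index of the first affected codon, where defined
    affected_codon_index: Optional[int] = None


class ACMGClass(str, enum.Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "VUS"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"


class BroaderClass(str, enum.Enum):
    BENIGN = "Benign"
    VUS = "VUS"
    PATHOGENIC = "Pathogenic"


_BROADER = {
    ACMGClass.BENIGN: BroaderClass.BENIGN,
    ACMGClass.LIKELY_BENIGN: BroaderClass.BENIGN,
    ACMGClass.VUS: BroaderClass.VUS,
    ACMGClass.LIKELY_PATHOGENIC: BroaderClass.PATHOGENIC,
    ACMGClass.PATHOGENIC: BroaderClass.PATHOGENIC,
}


def to_broader(c: ACMGClass) -> BroaderClass:
    """Collapse the five-tier class into Benign / VUS / Pathogenic."""
    return _BROADER[c]


@dataclass(frozen=True)
class EvidenceSet:
    """Multiset of triggered evidence keyed by (direction, strength)."""

    counts: tuple = ()  # tuple of ((direction, Strength), count), canonical order

    @classmethod
    def from_counter(cls, counter: Counter) -> "EvidenceSet":
        items = tuple(
            sorted(
                ((k, v) for k, v in counter.items() if v > 0),
                key=lambda kv: (kv[0][0], int(kv[0][1])),
            )
        )
        return cls(items)

    def count(self, direction: str, strength: Strength) -> int:
        return dict(self.counts).get((direction, strength), 0)

    def total(self, direction: str) -> int:
        return sum(v for (d, _), v in self.counts if d == direction)

    def __bool__(self) -> bool:
        return bool(self.counts)


def evidence_set_from_results(results: Sequence[CriterionResult]) -> EvidenceSet:
    """Count triggered criteria at their (possibly modified) strengths.

    Raises ``ValueError`` on duplicate triggered entries for one base rule.
    """
    seen = set()
    counter: Counter = Counter()
    for r in results:
        if not r.triggered:
            continue
        if r.criterion.base in seen:
            raise ValueError(f"duplicate triggered entries for {r.criterion.base.value}")
        seen.add(r.criterion.base)
        counter[(r.criterion.direction, r.criterion.effective_strength)] += 1
    return EvidenceSet.from_counter(counter)


@dataclass(frozen=True)
class ClassifiedVariant:
    """Final per-variant record: consequences, criteria, class, posterior."""

    variant: GenomicVariant
    consequences: tuple
    results: tuple
    acmg_class: ACMGClass
    posterior: float
    refined_broader_class: BroaderClass
    reporting_transcript: Optional[str] = None
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")

    def result_for(self, base: Criterion) -> Optional[CriterionResult]:
        for r in self.results:
            if r.criterion.base is base:
                return r
        return None
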