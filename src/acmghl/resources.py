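"""Local flat-file annotation resources and their indexed queries.

The engine runs fully offline: the clinical-variant table (a mini ClinVar
subset), per-subpopulation allele frequencies, region tracks, the
gene-to-inheritance-mode map and per-variant in-silico scores are all plain
TSV/BED files whose dialects are documented below, loaded once into indexed
in-memory structures.

File dialects
-------------
transcripts.tsv
    ``transcript_id  gene_symbol  chrom  strand  exon_starts  exon_ends
    cds_start  cds_end  phenotype_relevant  clin_sig_exons`` --
    coordinates 0-based half-open; exon lists comma-separated;
    ``clin_sig_exons`` comma-separated 0-based exon indices (may be empty).
clinvar.tsv
    ``chrom  pos  ref  alt  significance  review_stars  hgvs_p  gene_strand``
    with ``pos`` 1-based (VCF convention).
af.tsv
    ``chrom  pos  ref  alt`` plus one column per subpopulation holding
    allele fractions; empty cells mean "not observed in that subpopulation".
tracks (BED4)
    ``chrom  start  end  name`` with ``name`` = ``label`` or
    ``label|gene_symbol``.
inheritance.tsv
    ``gene_symbol  mode`` with mode in {AD, AR, XL, MT, unknown}.
scores.tsv
    ``chrom  pos  ref  alt  revel  cadd  phylop  splice_ref  splice_alt
    splice_ada  splice_rf`` (empty cells = score unavailable).
exclusion.tsv
    ``chrom  pos  ref  alt`` -- known pathogenic high-AF variants exempt
    from BA1/BS1.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml
from intervaltree import IntervalTree

from .core import GenomicVariant, TranscriptModel
from .hgvs import is_missense_change, parse_protein_change

logger = logging.getLogger(__name__)

__all__ = [
    "AFRecord",
    "ClinVarRecord",
    "ClinVarSignificance",
    "Genome",
    "InSilicoScores",
    "InheritanceMode",
    "ResourceBundle",
    "ResourceError",
    "TRACK_NAMES",
    "load_resources",
    "load_transcripts",
]

TRACK_NAMES = (
    "critical_region",
    "critical_region_no_benign",
    "repeat_no_domain",
    "protein_domain",
    "clinically_significant_exon",
)

#: resource -> criteria that become unusable without it
_MANDATORY = {
    "clinvar": "PS1, PM5 and the PVS1 start-loss branch",
    "af": "PM2, BA1 and BS1",
    "scores": "PP3, BP4 and BP7",
    "critical_region_no_benign": "PM1",
    "repeat_no_domain": "PM4 and BP3",
    "protein_domain": "the PVS1 NMD-escape domain branch",
    "clinically_significant_exon": "the PVS1 NMD-escape exon branch",
}


class ResourceError(RuntimeError):
    """A mandatory annotation resource is missing or unreadable."""


class ClinVarSignificance(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "VUS"
    OTHER = "other"


class InheritanceMode(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"
    MT = "MT"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ClinVarRecord:
    """One curated variant assertion (position 0-based internally)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    significance: ClinVarSignificance
    review_stars: int
    hgvs_p: str = ""
    strand_of_gene: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.review_stars <= 4):
            raise ValueError(f"review_stars {self.review_stars} outside [0, 4]")
        if self.strand_of_gene not in ("+", "-"):
            raise ValueError("strand_of_gene must be + or -")

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    @property
    def is_missense(self) -> bool:
        return is_missense_change(self.hgvs_p)

    @property
    def protein_change(self):
        return parse_protein_change(self.hgvs_p)


@dataclass(frozen=True)
class AFRecord:
    """Allele frequencies of one variant across named subpopulations."""

    key: tuple
    af_by_subpopulation: dict

    def __post_init__(self) -> None:
        if not self.af_by_subpopulation:
            raise ValueError("need at least one subpopulation")
        for name, af in self.af_by_subpopulation.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"AF {af} for {name} outside [0, 1]")


@dataclass(frozen=True)
class InSilicoScores:
    """Pre-computed predictor scores for one variant (all optional)."""

    revel: Optional[float] = None
    cadd: Optional[float] = None
    phylop: Optional[float] = None
    splice_ref: Optional[float] = None
    splice_alt: Optional[float] = None
    splice_ada: Optional[float] = None
    splice_rf: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("splice_ada", "splice_rf"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1]")


class Genome:
    """Reference sequence access (pyfaidx-backed or in-memory dict)."""

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = {k: v.upper() for k, v in source.items()}
            self._fasta = None
        else:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._seqs = None

    def seq(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, uppercase, plus strand."""
        if start < 0 or end < start:
            raise ValueError(f"invalid interval [{start}, {end})")
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()

    def __contains__(self, chrom: str) -> bool:
        if self._seqs is not None:
            return chrom in self._seqs
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])


def _read_rows(path: Path) -> Tuple[List[str], List[Tuple[int, List[str]]]]:
    """Read a header-bearing TSV; returns (header, [(lineno, fields), ...])."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return [], []
    header = lines[0].rstrip("\n").split("\t")
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        rows.append((i, line.split("\t")))
    return header, rows


def load_transcripts(path) -> Dict[str, TranscriptModel]:
    header, rows = _read_rows(Path(path))
    idx = {name: k for k, name in enumerate(header)}
    out: Dict[str, TranscriptModel] = {}
    for lineno, f in rows:
        try:
            starts = [int(x) for x in f[idx["exon_starts"]].split(",") if x]
            ends = [int(x) for x in f[idx["exon_ends"]].split(",") if x]
            cse_raw = f[idx["clin_sig_exons"]] if "clin_sig_exons" in idx else ""
            t = TranscriptModel(
                transcript_id=f[idx["transcript_id"]],
                gene_symbol=f[idx["gene_symbol"]],
                chrom=f[idx["chrom"]],
                strand=f[idx["strand"]],
                exons=tuple(zip(starts, ends)),
                cds_start=int(f[idx["cds_start"]]),
                cds_end=int(f[idx["cds_end"]]),
                phenotype_relevant=f[idx["phenotype_relevant"]] in ("1", "true", "True"),
                clinically_significant_exons=frozenset(
                    int(x) for x in cse_raw.split(",") if x
                ),
            )
        except (KeyError, ValueError, IndexError) as exc:
            logger.warning("%s row %d rejected: %s", path, lineno, exc)
            continue
        out[t.transcript_id] = t
    return out


def _load_clinvar(path) -> List[ClinVarRecord]:
    header, rows = _read_rows(Path(path))
    idx = {name: k for k, name in enumerate(header)}
    out = []
    for lineno, f in rows:
        try:
            out.append(
                ClinVarRecord(
                    chrom=f[idx["chrom"]],
                    pos=int(f[idx["pos"]]) - 1,
                    ref=f[idx["ref"]].upper(),
                    alt=f[idx["alt"]].upper(),
                    significance=ClinVarSignificance(f[idx["significance"]]),
                    review_stars=int(f[idx["review_stars"]]),
                    hgvs_p=f[idx["hgvs_p"]] if "hgvs_p" in idx else "",
                    strand_of_gene=f[idx["gene_strand"]] if "gene_strand" in idx else "+",
                )
            )
        except (KeyError, ValueError, IndexError) as exc:
            logger.warning("%s row %d rejected: %s", path, lineno, exc)
    return out


def _load_keyed_floats(path, key_cols=("chrom", "pos", "ref", "alt")):
    """Generic loader: variant key columns + named float columns."""
    header, rows = _read_rows(Path(path))
    idx = {name: k for k, name in enumerate(header)}
    value_cols = [c for c in header if c not in key_cols]
    out = {}
    for lineno, f in rows:
        try:
            key = (f[idx["chrom"]], int(f[idx["pos"]]) - 1, f[idx["ref"]].upper(),
                   f[idx["alt"]].upper())
            values = {}
            for c in value_cols:
                cell = f[idx[c]] if idx[c] < len(f) else ""
                if cell != "":
                    values[c] = float(cell)
            out[key] = values
        except (KeyError, ValueError, IndexError) as exc:
            logger.warning("%s row %d rejected: %s", path, lineno, exc)
    return out


def _load_bed_track(path) -> Dict[str, IntervalTree]:
    """BED4 -> per-chromosome interval tree carrying the name field."""
    trees: Dict[str, IntervalTree] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            label = f[3] if len(f) > 3 else ""
            if start >= end:
                raise ValueError(f"start {start} >= end {end}")
        except (ValueError, IndexError) as exc:
            logger.warning("%s row %d rejected: %s", path, lineno, exc)
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end, label)
    return trees


@dataclass
class ResourceBundle:
    """All annotation resources, indexed and ready for per-variant queries."""

    genome: Genome
    transcripts: Dict[str, TranscriptModel]
    clinvar: List[ClinVarRecord] = field(default_factory=list)
    af: Dict[tuple, AFRecord] = field(default_factory=dict)
    tracks: Dict[str, Dict[str, IntervalTree]] = field(default_factory=dict)
    inheritance: Dict[str, InheritanceMode] = field(default_factory=dict)
    scores: Dict[tuple, InSilicoScores] = field(default_factory=dict)
    exclusion: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self._clinvar_index: Dict[str, IntervalTree] = {}
        for rec in self.clinvar:
            self._clinvar_index.setdefault(rec.chrom, IntervalTree()).addi(
                rec.pos, rec.end, rec
            )

    # -- queries -----------------------------------------------------------

    def transcripts_for_gene(self, gene_symbol: str) -> List[TranscriptModel]:
        return sorted(
            (t for t in self.transcripts.values() if t.gene_symbol == gene_symbol),
            key=lambda t: (not t.phenotype_relevant, t.transcript_id),
        )

    def transcripts_overlapping(self, chrom: str, start: int, end: int):
        return [
            t
            for t in self.transcripts.values()
            if t.chrom == chrom and t.exons[0][0] < end and t.exons[-1][1] > start
        ]

    def query_clinvar_range(
        self,
        chrom: str,
        start: int,
        end: int,
        significance_filter: Optional[Iterable[ClinVarSignificance]] = None,
        min_stars: int = 0,
    ) -> List[ClinVarRecord]:
        """Records whose reference span overlaps [start, end) on chrom."""
        if end <= start:
            return []
        tree = self._clinvar_index.get(chrom)
        if tree is None:
            return []
        wanted = set(significance_filter) if significance_filter else None
        hits = [iv.data for iv in tree.overlap(start, end)]
        out = [
            r
            for r in hits
            if r.review_stars >= min_stars
            and (wanted is None or r.significance in wanted)
        ]
        return sorted(out, key=lambda r: (r.pos, r.ref, r.alt))

    def query_clinvar_codon(
        self, t: TranscriptModel, codon_index: int, min_stars: int = 1
    ) -> List[ClinVarRecord]:
        """Missense records at the codon's (possibly exon-split) genomic
        positions, filtered to the gene's strand and a review-star floor.
        """
        positions = t.codon_genomic_positions(codon_index)  # raises if outside CDS
        out = []
        seen = set()
        for gpos in positions:
            tree = self._clinvar_index.get(t.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(gpos, gpos + 1):
                rec = iv.data
                rid = (rec.pos, rec.ref, rec.alt, rec.hgvs_p)
                if rid in seen:
                    continue
                if rec.strand_of_gene != t.strand:
                    continue
                if rec.review_stars < min_stars:
                    continue
                if not rec.is_missense:
                    continue
                seen.add(rid)
                out.append(rec)
        return sorted(out, key=lambda r: (r.pos, r.ref, r.alt))

    def query_af(self, v: GenomicVariant) -> Optional[AFRecord]:
        return self.af.get(v.key)

    def query_scores(self, v: GenomicVariant) -> InSilicoScores:
        values = self.scores.get(v.key)
        return values if values is not None else InSilicoScores()

    def query_track(
        self, name: str, chrom: str, start: int, end: int
    ) -> List[Tuple[int, int, str]]:
        """Track intervals overlapping [start, end); [] if track absent."""
        if name not in TRACK_NAMES:
            raise ValueError(f"unknown track {name!r}")
        trees = self.tracks.get(name, {})
        tree = trees.get(chrom)
        if tree is None or end <= start:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))

    def inheritance_mode(self, gene_symbol: str) -> InheritanceMode:
        return self.inheritance.get(gene_symbol, InheritanceMode.UNKNOWN)

    def is_excluded_high_af(self, v: GenomicVariant) -> bool:
        return v.key in self.exclusion


def load_resources(config) -> ResourceBundle:
    """Load a :class:`ResourceBundle` from a YAML config or a path dict.

    The config maps resource names to file paths::

        genome: toy_genome.fa
        transcripts: transcripts.tsv
        clinvar: clinvar.tsv
        af: af.tsv
        inheritance: inheritance.tsv
        scores: scores.tsv
        exclusion: exclusion.tsv
        tracks:
          critical_region_no_benign: pm1.bed
          ...

    Missing mandatory files raise :class:`ResourceError` naming the criteria
    that would become not_applicable; ``inheritance`` and ``exclusion`` are
    optional.
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        raw = yaml.safe_load(Path(config).read_text()) or {}
        paths = {
            k: (
                {n: base / p for n, p in v.items()}
                if isinstance(v, dict)
                else base / v
            )
            for k, v in raw.items()
        }
    else:
        paths = dict(config)

    def _require(name: str) -> Path:
        p = paths.get(name) if name != "tracks" else None
        if p is None or not Path(p).exists():
            hint = _MANDATORY.get(name, name)
            raise ResourceError(
                f"missing mandatory resource {name!r}; without it {hint} "
                "cannot be evaluated (would be not_applicable)"
            )
        return Path(p)

    for must in ("genome", "transcripts", "clinvar", "af", "scores"):
        _require(must)

    track_paths = paths.get("tracks", {})
    tracks: Dict[str, Dict[str, IntervalTree]] = {}
    for name in TRACK_NAMES:
        p = track_paths.get(name)
        if p is None or not Path(p).exists():
            if name in _MANDATORY:
                raise ResourceError(
                    f"missing mandatory track {name!r}; without it "
                    f"{_MANDATORY[name]} cannot be evaluated (would be "
                    "not_applicable)"
                )
            tracks[name] = {}
        else:
            tracks[name] = _load_bed_track(p)

    inheritance: Dict[str, InheritanceMode] = {}
    inh_path = paths.get("inheritance")
    if inh_path is not None and Path(inh_path).exists():
        header, rows = _read_rows(Path(inh_path))
        idx = {name: k for k, name in enumerate(header)}
        for lineno, f in rows:
            try:
                inheritance[f[idx["gene_symbol"]]] = InheritanceMode(f[idx["mode"]])
            except (KeyError, ValueError, IndexError) as exc:
                logger.warning("%s row %d rejected: %s", inh_path, lineno, exc)

    exclusion: set = set()
    excl_path = paths.get("exclusion")
    if excl_path is not None and Path(excl_path).exists():
        header, rows = _read_rows(Path(excl_path))
        idx = {name: k for k, name in enumerate(header)}
        for lineno, f in rows:
            try:
                exclusion.add(
                    (f[idx["chrom"]], int(f[idx["pos"]]) - 1,
                     f[idx["ref"]].upper(), f[idx["alt"]].upper())
                )
            except (KeyError, ValueError, IndexError) as exc:
                logger.warning("%s row %d rejected: %s", excl_path, lineno, exc)

    af = {
        key: AFRecord(key=key, af_by_subpopulation=vals)
        for key, vals in _load_keyed_floats(paths["af"]).items()
        if vals
    }
    score_fields = InSilicoScores.__dataclass_fields__
    scores = {
        key: InSilicoScores(**{k: v for k, v in vals.items() if k in score_fields})
        for key, vals in _load_keyed_floats(paths["scores"]).items()
    }

    return ResourceBundle(
        genome=Genome(paths["genome"]),
        transcripts=load_transcripts(paths["transcripts"]),
        clinvar=_load_clinvar(paths["clinvar"]),
        af=af,
        tracks=tracks,
        inheritance=inheritance,
        scores=scores,
        exclusion=exclusion,
    )
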