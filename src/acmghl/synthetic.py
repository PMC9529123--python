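"""Seedable synthetic fixtures: toy genome, transcripts, annotation
resources and a variant panel with independently derived expected outcomes.

The generator designs each gene in transcript space (5' UTR, coding exons
with planted codons at planned positions, GT..AG introns, 3' UTR), places
it on a toy chromosome (reverse-complemented for minus-strand genes), and
derives every variant's expected criterion states, class and posterior by
straight-line bookkeeping on its own data structures -- string edits,
interval comparisons and the closed-form posterior -- never by calling the
classification engine.  The resulting panel is the end-to-end golden
standard for the engine.

The default panel covers: PVS1 very-strong (NMD + phenotype-relevant
transcript) and its negative branch, every NMD-escape reason, the
NMD-escape domain/critical-domain and clinically-significant-exon (> / <=
10% truncation) branches, start-loss with and without a pathogenic rescue
entry, PS1 at an exon-junction codon, PM5 at one and at two distinct
residues, PM1, PM4 above/below 10% and repeat-blocked, BP3, PP3 (missense
and splice arms), BP4, BP7, PM2 (absence), BA1, the BA1/BS1 exclusion
list, and BS1.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .core import GenomicVariant, TranscriptModel
from .resources import (
    AFRecord,
    ClinVarRecord,
    ClinVarSignificance,
    Genome,
    InSilicoScores,
    InheritanceMode,
    ResourceBundle,
)
from intervaltree import IntervalTree

__all__ = ["FixtureSet", "PanelVariant", "make_fixture_set", "CHROM"]

CHROM = "chr1"
_RC = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
#: codons never produced by the filler (stops, start, and NMD-test codons)
_FILLER_EXCLUDE = set(_STOPS) | {"ATG"}

# posterior weights of the Bayesian point framework (independent copy for
# the generator's own bookkeeping)
_W = {"pvs": 1.0, "ps": 0.5, "pm": 0.25, "pp": 0.125, "ba": 1.0, "bs": 0.5,
      "bp": 0.125}

# hearing-loss AF cutoffs used when building the fixture frequencies
_AF_CUT = {
    "AD": {"ba1": 0.001, "bs1": 0.0002, "pm2": 0.00002},
    "AR": {"ba1": 0.005, "bs1": 0.003, "pm2": 0.00007},
}

#: moderate frequencies that trigger nothing in either mode
_AF_NEUTRAL = {"NFE": 1e-4, "AFR": 5e-5, "EAS": 8e-5}
_AF_COMMON = {"NFE": 0.02, "AFR": 0.01, "EAS": 0.015}
_AF_BS1 = {"NFE": 5e-4, "AFR": 3e-4, "EAS": 2e-4}


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _filler_codons(rng: random.Random, n: int) -> List[str]:
    out = []
    while len(out) < n:
        c = "".join(rng.choice(_BASES) for _ in range(3))
        if c not in _FILLER_EXCLUDE:
            out.append(c)
    return out


def _filler_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------


@dataclass
class GenePlan:
    name: str
    strand: str
    exon_coding_lens: Tuple[int, ...]
    phenotype_relevant: bool = True
    mode: Optional[str] = None  # inheritance; None -> absent from map
    clin_sig_exons: Tuple[int, ...] = ()  # transcript-order exon indices
    planted_codons: Dict[int, str] = field(default_factory=dict)
    utr3_stop_at_codon: Optional[int] = None  # in-frame stop in the 3' UTR
    utr5: int = 30
    utr3: int = 150
    intron_len: int = 60


@dataclass
class BuiltGene:
    """One placed gene with generator-owned coordinate bookkeeping."""

    plan: GenePlan
    region_start: int
    region_seq_plus: str  # as written into the genome
    region_seq_t: str  # transcript orientation
    coding: str  # transcript-space coding sequence
    coding_t_ranges: List[Tuple[int, int]]  # per exon, transcript-space
    exon_t_ranges: List[Tuple[int, int]]
    transcript: TranscriptModel

    # -- transcript-space <-> genomic arithmetic (independent of the
    #    TranscriptModel coordinate helpers) -------------------------------

    def t_to_g(self, tpos: int) -> int:
        if self.plan.strand == "+":
            return self.region_start + tpos
        return self.region_start + len(self.region_seq_t) - 1 - tpos

    def cds_to_t(self, off: int) -> int:
        rem = off
        for ts, te in self.coding_t_ranges:
            if rem < te - ts:
                return ts + rem
            rem -= te - ts
        raise ValueError(f"CDS offset {off} outside coding ranges")

    def cds_to_g(self, off: int) -> int:
        return self.t_to_g(self.cds_to_t(off))

    def g_to_cds(self, g: int) -> Optional[int]:
        for off in range(len(self.coding)):
            if self.cds_to_g(off) == g:
                return off
        return None

    def exon_coding_lens(self) -> List[int]:
        return [te - ts for ts, te in self.coding_t_ranges]

    # -- variant constructors ---------------------------------------------

    def snv_at_cds(self, off: int, alt_t: str, vid: str) -> GenomicVariant:
        g = self.cds_to_g(off)
        ref = self.region_seq_plus[g - self.region_start]
        alt = alt_t if self.plan.strand == "+" else _rc(alt_t)
        return GenomicVariant(CHROM, g, ref, alt, vid)

    def snv_at_t(self, tpos: int, alt_t: str, vid: str) -> GenomicVariant:
        g = self.t_to_g(tpos)
        ref = self.region_seq_plus[g - self.region_start]
        alt = alt_t if self.plan.strand == "+" else _rc(alt_t)
        return GenomicVariant(CHROM, g, ref, alt, vid)

    def deletion_at_cds(self, off: int, length: int, vid: str) -> GenomicVariant:
        """Anchored deletion of `length` bases starting at CDS offset
        ``off`` (plus-strand genes only)."""
        assert self.plan.strand == "+"
        g_anchor = self.cds_to_g(off) - 1
        s = self.region_seq_plus
        i = g_anchor - self.region_start
        return GenomicVariant(CHROM, g_anchor, s[i : i + 1 + length], s[i], vid)


def _build_gene(rng: random.Random, plan: GenePlan, region_start: int) -> BuiltGene:
    total_coding = sum(plan.exon_coding_lens)
    assert total_coding % 3 == 0
    n_codons = total_coding // 3
    codons = ["ATG"] + _filler_codons(rng, n_codons - 2) + ["TAA"]
    for idx, codon in plan.planted_codons.items():
        codons[idx] = codon
    coding = "".join(codons)

    utr5 = _filler_seq(rng, plan.utr5)
    utr3_codons = _filler_codons(rng, plan.utr3 // 3 + 1)
    if plan.utr3_stop_at_codon is not None:
        utr3_codons[plan.utr3_stop_at_codon] = "TAA"
    utr3 = "".join(utr3_codons)[: plan.utr3]

    # assemble transcript-space region and record exon/coding ranges
    pieces: List[str] = []
    exon_t_ranges: List[Tuple[int, int]] = []
    coding_t_ranges: List[Tuple[int, int]] = []
    cursor = 0
    coding_cursor = 0
    n_exons = len(plan.exon_coding_lens)
    for k, clen in enumerate(plan.exon_coding_lens):
        exon_seq = coding[coding_cursor : coding_cursor + clen]
        prefix = utr5 if k == 0 else ""
        suffix = utr3 if k == n_exons - 1 else ""
        full = prefix + exon_seq + suffix
        exon_t_ranges.append((cursor, cursor + len(full)))
        coding_t_ranges.append(
            (cursor + len(prefix), cursor + len(prefix) + clen)
        )
        pieces.append(full)
        cursor += len(full)
        coding_cursor += clen
        if k < n_exons - 1:
            intron = "GT" + _filler_seq(rng, plan.intron_len - 4) + "AG"
            pieces.append(intron)
            cursor += len(intron)
    region_t = "".join(pieces)
    region_plus = region_t if plan.strand == "+" else _rc(region_t)

    L = len(region_t)

    def flip(iv: Tuple[int, int]) -> Tuple[int, int]:
        ts, te = iv
        if plan.strand == "+":
            return (region_start + ts, region_start + te)
        return (region_start + L - te, region_start + L - ts)

    g_exons = sorted(flip(iv) for iv in exon_t_ranges)
    cds_t = (coding_t_ranges[0][0], coding_t_ranges[-1][1])
    g_cds = flip(cds_t)
    # clinically significant exon indices in genomic (ascending) order
    if plan.strand == "+":
        cse = frozenset(plan.clin_sig_exons)
    else:
        cse = frozenset(n_exons - 1 - i for i in plan.clin_sig_exons)

    transcript = TranscriptModel(
        transcript_id=f"{plan.name}-T1",
        gene_symbol=plan.name,
        chrom=CHROM,
        strand=plan.strand,
        exons=tuple(g_exons),
        cds_start=g_cds[0],
        cds_end=g_cds[1],
        phenotype_relevant=plan.phenotype_relevant,
        clinically_significant_exons=cse,
    )
    return BuiltGene(
        plan=plan,
        region_start=region_start,
        region_seq_plus=region_plus,
        region_seq_t=region_t,
        coding=coding,
        coding_t_ranges=coding_t_ranges,
        exon_t_ranges=exon_t_ranges,
        transcript=transcript,
    )


# ---------------------------------------------------------------------------
# independent expected-outcome bookkeeping
# ---------------------------------------------------------------------------

CRITERIA = ("PVS1", "PS1", "PM1", "PM2", "PM4", "PM5", "PP3", "BA1", "BS1",
            "BP3", "BP4", "BP7")

NA = "not_applicable"
NT = "not_triggered"


def _posterior(x: float, prior: float = 0.1, odds: float = 350.0) -> float:
    o = odds**x
    return (o * prior) / ((o - 1.0) * prior + 1.0)


def _combine(
    strengths: List[str],
    mode: Optional[str],
    pm2_triggered: bool = False,
    bs1_triggered: bool = False,
) -> str:
    """Straight-line re-statement of the combining rules on triggered
    strengths (keys as in ``_W``), with the two hearing-loss refinements."""
    n = {k: strengths.count(k) for k in _W}
    pathogenic = (
        (n["pvs"] >= 1 and (n["ps"] >= 1 or n["pm"] >= 2
                            or (n["pm"] >= 1 and n["pp"] >= 1) or n["pp"] >= 2))
        or n["ps"] >= 2
        or (n["ps"] >= 1 and (n["pm"] >= 3 or (n["pm"] >= 2 and n["pp"] >= 2)
                              or (n["pm"] >= 1 and n["pp"] >= 4)))
    )
    likely_pathogenic = (
        (n["pvs"] >= 1 and n["pm"] >= 1)
        or (n["ps"] >= 1 and n["pm"] >= 1)
        or (n["ps"] >= 1 and n["pp"] >= 2)
        or n["pm"] >= 3
        or (n["pm"] >= 2 and n["pp"] >= 2)
        or (n["pm"] >= 1 and n["pp"] >= 4)
    )
    benign = n["ba"] >= 1 or n["bs"] >= 2
    likely_benign = (n["bs"] >= 1 and n["bp"] >= 1) or n["bp"] >= 2
    has_path = any(n[k] for k in ("pvs", "ps", "pm", "pp"))
    has_ben = any(n[k] for k in ("ba", "bs", "bp"))

    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return "VUS"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    # HL refinement (ii): BS1 without any pathogenic criterion
    if likely_benign or (bs1_triggered and not has_path):
        return "likely_benign"
    # HL refinement (i): PVS1 + PM2 (Supporting), AR gene
    if mode == "AR" and n["pvs"] >= 1 and pm2_triggered:
        return "likely_pathogenic"
    return "VUS"


def _refine(acmg_class: str, posterior: float) -> str:
    if acmg_class in ("benign", "likely_benign"):
        return "Benign"
    if acmg_class in ("pathogenic", "likely_pathogenic"):
        return "Pathogenic"
    if posterior >= 0.49988:
        return "Pathogenic"
    if posterior <= 0.05072:
        return "Benign"
    return "VUS"


@dataclass
class PanelVariant:
    vid: str
    variant: GenomicVariant
    description: str
    expected_states: Dict[str, str]
    expected_class: str
    expected_posterior: float
    expected_refined: str


def _baseline_states(kind: str) -> Dict[str, str]:
    """Engine-schema baseline: which criteria are applicable per kind."""
    s = {c: NA for c in CRITERIA}
    s["PM2"] = NT
    s["BA1"] = NT
    s["BS1"] = NT
    lof = {"stop_gained", "stop_lost", "frameshift", "inframe_deletion",
           "inframe_duplication", "splice_acceptor", "splice_donor",
           "start_loss"}
    if kind in lof:
        s["PVS1"] = NT
    if kind == "missense":
        s["PS1"] = NT
        s["PM5"] = NT
        s["PP3"] = NT
        s["BP4"] = NT
    if kind in ("synonymous", "intronic", "other"):
        s["PP3"] = NT
        s["BP4"] = NT
        if kind == "synonymous":
            s["BP7"] = NT
    if kind in ("inframe_deletion", "inframe_duplication", "stop_lost"):
        s["PM4"] = NT
    if kind in ("inframe_deletion", "inframe_duplication", "stop_gained"):
        s["BP3"] = NT
    # PM1 is applicable whenever the variant maps into a CDS or skips an exon
    if kind not in ("intronic", "other"):
        s["PM1"] = NT
    return s


def _strength_key(label: str) -> str:
    """Map a triggered-state label to its posterior-weight key."""
    table = {
        "PVS1": "pvs", "PVS1_Strong": "ps", "PVS1_Moderate": "pm",
        "PVS1_Supporting": "pp",
        "PS1": "ps", "PM1": "pm", "PM4": "pm", "PM5": "pm",
        "PM5_Strong": "ps", "PM2_Supporting": "pp", "PM2": "pm",
        "PP3": "pp", "BA1": "ba", "BS1": "bs", "BS1_Supporting": "bp",
        "BP3": "bp", "BP4": "bp", "BP7": "bp",
    }
    return table[label]


# ---------------------------------------------------------------------------
# generator-side evaluation of designed loss-of-function variants
# ---------------------------------------------------------------------------


def _observed_coding(gene: BuiltGene, v: GenomicVariant,
                     skip_exon: Optional[int] = None):
    """(sequence, per-exon lengths) of the mutated CDS, transcript space.

    ``skip_exon`` (transcript-order index) models exon skipping for splice
    variants; otherwise the edit must be contained in one coding exon.
    """
    lens = gene.exon_coding_lens()
    if skip_exon is not None:
        seqs = []
        off = 0
        for k, clen in enumerate(lens):
            if k != skip_exon:
                seqs.append(gene.coding[off : off + clen])
            off += clen
        return "".join(seqs), [l for k, l in enumerate(lens) if k != skip_exon]
    # orient the edit into transcript space
    if gene.plan.strand == "+":
        g_lo = v.pos
        ref_t, alt_t = v.ref, v.alt
    else:
        g_lo = v.pos  # genomic span start
        ref_t, alt_t = _rc(v.ref), _rc(v.alt)
    # locate the CDS offset of the transcript-5'-most reference base
    span = [gene.g_to_cds(g) for g in range(v.pos, v.end)]
    span = [o for o in span if o is not None]
    o_lo = min(span)
    seq = gene.coding[:o_lo] + alt_t + gene.coding[o_lo + len(v.ref) :]
    # per-exon lengths after the edit: the containing exon absorbs dlen
    dlen = len(v.alt) - len(v.ref)
    new_lens = list(lens)
    acc = 0
    for k, clen in enumerate(lens):
        if acc <= o_lo < acc + clen:
            new_lens[k] = clen + dlen
            break
        acc += clen
    return seq, new_lens


def _first_stop(seq: str) -> Optional[int]:
    for off in range(0, len(seq) - 2, 3):
        if seq[off : off + 3] in _STOPS:
            return off
    return None


def _nmd_escape(ptc: int, exon_lens: List[int]) -> Optional[str]:
    """Reason string if the PTC escapes NMD, else None (NMD occurs)."""
    if len(exon_lens) >= 2:
        pen_start = sum(exon_lens[:-2])
        pen_end = sum(exon_lens[:-1])
        if pen_start <= ptc < pen_end and pen_end - ptc <= 50:
            return "penultimate_exon_last50"
    if ptc <= 200:
        return "within_200bp_of_start"
    if len(exon_lens) == 1:
        return "intronless"
    return None


def _expected_pvs1_truncating(
    gene: BuiltGene,
    v: GenomicVariant,
    tracks: Dict[str, List[Tuple[int, int, str]]],
    any_phenotype_relevant_overlap: bool,
    skip_exon: Optional[int] = None,
) -> str:
    """Straight-line refined-PVS1 outcome for a PTC-producing variant."""
    seq, lens = _observed_coding(gene, v, skip_exon)
    ptc = _first_stop(seq)
    last_complete = (len(seq) // 3 - 1) * 3
    if ptc is None or ptc == last_complete:
        return NT
    escape = _nmd_escape(ptc, lens)
    if escape is None:  # NMD occurs
        return "PVS1" if any_phenotype_relevant_overlap else NT
    # variant-affected genomic interval
    if skip_exon is not None:
        lens_ref = gene.exon_coding_lens()
        lo = sum(lens_ref[:skip_exon])
        hi = lo + lens_ref[skip_exon]
        gpos = [gene.cds_to_g(o) for o in (lo, hi - 1)]
        interval = (min(gpos), max(gpos) + 1)
    else:
        interval = (v.pos, v.end)

    def overlaps(track: str) -> bool:
        return any(s < interval[1] and e > interval[0]
                   for s, e, _ in tracks.get(track, []))

    if overlaps("protein_domain"):
        return "PVS1_Strong" if overlaps("critical_region") else "PVS1_Moderate"
    if overlaps("clinically_significant_exon") and any_phenotype_relevant_overlap:
        ref_len = len(gene.coding) // 3 - 1
        removed = (ref_len - ptc // 3) / ref_len
        return "PVS1_Strong" if removed > 0.10 else "PVS1_Moderate"
    return NT


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------


@dataclass
class FixtureSet:
    seed: int
    genome_seqs: Dict[str, str]
    genes: Dict[str, BuiltGene]
    clinvar: List[ClinVarRecord]
    af: Dict[tuple, Dict[str, float]]
    scores: Dict[tuple, Dict[str, float]]
    tracks: Dict[str, List[Tuple[int, int, str]]]
    inheritance: Dict[str, str]
    exclusion: List[tuple]
    panel: List[PanelVariant]

    # -- in-memory bundle --------------------------------------------------

    def bundle(self) -> ResourceBundle:
        tracks = {
            name: {CHROM: IntervalTree()}
            for name in self.tracks
        }
        for name, ivs in self.tracks.items():
            for s, e, label in ivs:
                tracks[name][CHROM].addi(s, e, label)
        return ResourceBundle(
            genome=Genome(self.genome_seqs),
            transcripts={g.transcript.transcript_id: g.transcript
                         for g in self.genes.values()},
            clinvar=list(self.clinvar),
            af={k: AFRecord(key=k, af_by_subpopulation=v)
                for k, v in self.af.items()},
            tracks=tracks,
            inheritance={g: InheritanceMode(m)
                         for g, m in self.inheritance.items()},
            scores={k: InSilicoScores(**v) for k, v in self.scores.items()},
            exclusion=set(self.exclusion),
        )

    # -- file emission -----------------------------------------------------

    def write(self, outdir) -> Path:
        """Write all resource files, the panel VCF, the expected-outcome
        table and a resources.yaml; returns the config path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        with open(out / "toy_genome.fa", "w") as fh:
            for chrom, seq in self.genome_seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

        with open(out / "transcripts.tsv", "w") as fh:
            fh.write(
                "transcript_id\tgene_symbol\tchrom\tstrand\texon_starts\t"
                "exon_ends\tcds_start\tcds_end\tphenotype_relevant\t"
                "clin_sig_exons\n"
            )
            for g in self.genes.values():
                t = g.transcript
                fh.write(
                    "\t".join(
                        [
                            t.transcript_id, t.gene_symbol, t.chrom, t.strand,
                            ",".join(str(s) for s, _ in t.exons),
                            ",".join(str(e) for _, e in t.exons),
                            str(t.cds_start), str(t.cds_end),
                            "1" if t.phenotype_relevant else "0",
                            ",".join(
                                str(i)
                                for i in sorted(t.clinically_significant_exons)
                            ),
                        ]
                    )
                    + "\n"
                )

        with open(out / "clinvar.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tsignificance\treview_stars\t"
                     "hgvs_p\tgene_strand\n")
            for r in self.clinvar:
                fh.write(
                    f"{r.chrom}\t{r.pos + 1}\t{r.ref}\t{r.alt}\t"
                    f"{r.significance.value}\t{r.review_stars}\t{r.hgvs_p}\t"
                    f"{r.strand_of_gene}\n"
                )

        subpops = sorted({s for v in self.af.values() for s in v})
        with open(out / "af.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\t" + "\t".join(subpops) + "\n")
            for (chrom, pos, ref, alt), vals in sorted(self.af.items()):
                cells = [f"{vals[s]:g}" if s in vals else "" for s in subpops]
                fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t"
                         + "\t".join(cells) + "\n")

        score_cols = ["revel", "cadd", "phylop", "splice_ref", "splice_alt",
                      "splice_ada", "splice_rf"]
        with open(out / "scores.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\t" + "\t".join(score_cols) + "\n")
            for (chrom, pos, ref, alt), vals in sorted(self.scores.items()):
                cells = [f"{vals[c]:g}" if c in vals else "" for c in score_cols]
                fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t"
                         + "\t".join(cells) + "\n")

        with open(out / "inheritance.tsv", "w") as fh:
            fh.write("gene_symbol\tmode\n")
            for gene, mode in sorted(self.inheritance.items()):
                fh.write(f"{gene}\t{mode}\n")

        with open(out / "exclusion.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for chrom, pos, ref, alt in sorted(self.exclusion):
                fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\n")

        track_files = {}
        for name, ivs in self.tracks.items():
            fname = f"track_{name}.bed"
            with open(out / fname, "w") as fh:
                for s, e, label in sorted(ivs):
                    fh.write(f"{CHROM}\t{s}\t{e}\t{label}\n")
            track_files[name] = fname

        with open(out / "resources.yaml", "w") as fh:
            fh.write("genome: toy_genome.fa\n")
            fh.write("transcripts: transcripts.tsv\n")
            fh.write("clinvar: clinvar.tsv\n")
            fh.write("af: af.tsv\n")
            fh.write("scores: scores.tsv\n")
            fh.write("inheritance: inheritance.tsv\n")
            fh.write("exclusion: exclusion.tsv\n")
            fh.write("tracks:\n")
            for name, fname in sorted(track_files.items()):
                fh.write(f"  {name}: {fname}\n")

        with open(out / "panel.vcf", "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, seq in self.genome_seqs.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for pv in self.panel:
                v = pv.variant
                fh.write(f"{v.chrom}\t{v.pos1}\t{pv.vid}\t{v.ref}\t{v.alt}"
                         "\t.\t.\t.\n")

        with open(out / "expected_outcomes.tsv", "w") as fh:
            cols = (["variant_id", "chrom", "pos", "ref", "alt", "description"]
                    + [f"{c}_state" for c in CRITERIA]
                    + ["acmg_class", "posterior", "refined_class"])
            fh.write("\t".join(cols) + "\n")
            for pv in self.panel:
                v = pv.variant
                row = [pv.vid, v.chrom, str(v.pos1), v.ref, v.alt,
                       pv.description]
                row += [pv.expected_states[c] for c in CRITERIA]
                row += [pv.expected_class, f"{pv.expected_posterior:.5f}",
                        pv.expected_refined]
                fh.write("\t".join(row) + "\n")

        return out / "resources.yaml"


def make_fixture_set(seed: int = 7) -> FixtureSet:
    """Build the complete deterministic fixture set for one seed."""
    rng = random.Random(seed)

    plans = {
        "TOYA": GenePlan(
            "TOYA", "+", (120, 100, 80, 60), phenotype_relevant=True,
            mode="AR", clin_sig_exons=(1,),
            planted_codons={70: "CAA", 76: "CAA", 40: "CAA"},
        ),
        "TOYB": GenePlan(
            "TOYB", "-", (100, 80, 60), phenotype_relevant=True, mode="AD",
            planted_codons={
                33: "AGA", 40: "CTG", 50: "GGA", 20: "GAT", 60: "CGT",
                65: "ACT", 70: "CTG", 71: "CTG", 72: "CTG", 73: "CTG",
            },
        ),
        "TOYC": GenePlan(
            "TOYC", "+", (300,), phenotype_relevant=True, mode="AR",
            clin_sig_exons=(0,), planted_codons={70: "CAA", 95: "CAA"},
        ),
        "TOYD": GenePlan(
            "TOYD", "-", (150, 120, 90), phenotype_relevant=True, mode="AD",
            planted_codons={75: "CAA", 84: "CAA"},
        ),
        "TOYE": GenePlan(
            "TOYE", "+", (150, 120, 90), phenotype_relevant=False,
            mode=None, utr3_stop_at_codon=40,
        ),
        "TOYF": GenePlan(
            "TOYF", "+", (90, 60), phenotype_relevant=True, mode="AR",
            planted_codons={30: "ATG"},
        ),
        "TOYG": GenePlan(
            "TOYG", "+", (150,), phenotype_relevant=True, mode="AD",
            planted_codons={20: "ATG"},
        ),
    }

    genes: Dict[str, BuiltGene] = {}
    cursor = 200
    chrom_parts = [_filler_seq(rng, 200)]
    for name, plan in plans.items():
        g = _build_gene(rng, plan, cursor)
        genes[name] = g
        chrom_parts.append(g.region_seq_plus)
        cursor += len(g.region_seq_plus)
        gap = _filler_seq(rng, 150)
        chrom_parts.append(gap)
        cursor += len(gap)
    chrom_parts.append(_filler_seq(rng, 200))
    genome_seqs = {CHROM: "".join(chrom_parts)}

    a, b, c, d, e, f, g7 = (genes[n] for n in
                            ("TOYA", "TOYB", "TOYC", "TOYD", "TOYE", "TOYF",
                             "TOYG"))

    # left-normalise indels exactly the way the VCF reader will, so that
    # resource keys and expected outcomes refer to the canonical form
    from .io_tabular import normalize_variant

    genome_obj = Genome(genome_seqs)

    def norm(v: GenomicVariant) -> GenomicVariant:
        chrom, pos, ref, alt = normalize_variant(
            v.chrom, v.pos, v.ref, v.alt, genome_obj
        )
        return GenomicVariant(chrom, pos, ref, alt, v.id)

    # ---- region tracks ----------------------------------------------------
    def t_span(gene: BuiltGene, lo: int, hi: int) -> Tuple[int, int]:
        """Genomic interval of CDS offsets [lo, hi)."""
        gpos = [gene.cds_to_g(o) for o in (lo, hi - 1)]
        return (min(gpos), max(gpos) + 1)

    pm1_region = t_span(b, 45, 78)  # TOYB codons 15..25
    benign_region = t_span(b, 165, 175)  # critical, but holds a benign entry
    domain1 = t_span(d, 218, 240)  # critical
    domain2 = t_span(d, 244, 266)  # not critical
    repeat = t_span(e, 150, 270)  # TOYE exon 2
    critical_regions = [
        (*pm1_region, "TOYB_motif"),
        (*benign_region, "TOYB_benign_motif"),
        (*domain1, "TOYD_critical_domain"),
    ]
    clin_sig_track = []
    for gene, exon_idx in ((a, 1), (c, 0)):
        lens = gene.exon_coding_lens()
        lo = sum(lens[:exon_idx])
        clin_sig_track.append(
            (*t_span(gene, lo, lo + lens[exon_idx]),
             f"{gene.plan.name}_exon{exon_idx + 1}")
        )

    # ---- clinical-variant table ------------------------------------------
    clinvar: List[ClinVarRecord] = []

    def cv(gene, cds_off, alt_t, sig, stars, hgvs_p=""):
        g_ = gene.cds_to_g(cds_off)
        ref = genome_seqs[CHROM][g_]
        alt = alt_t if gene.plan.strand == "+" else _rc(alt_t)
        clinvar.append(
            ClinVarRecord(CHROM, g_, ref, alt, ClinVarSignificance(sig),
                          stars, hgvs_p, gene.plan.strand)
        )

    cv(b, 100, "T", "pathogenic", 1, "p.Arg34Ile")      # PS1 twin of v05
    cv(b, 121, "C", "pathogenic", 2, "p.Leu41Pro")      # PM5 x1 for v06
    cv(b, 151, "T", "pathogenic", 1, "p.Gly51Val")      # PM5 x2 for v07
    cv(b, 151, "C", "pathogenic", 2, "p.Gly51Ala")
    cv(b, 170, "A", "benign", 1, "")                    # voids benign_region
    cv(d, 230, "A", "benign", 1, "")                    # keeps the critical
    # domain out of the benign-free PM1 track (PVS1 still sees it)
    cv(f, 45, "A", "pathogenic", 1, "")  # between TOYF's lost and rescue start

    critical_no_benign = [
        iv for iv in critical_regions
        if not any(iv[0] <= r.pos < iv[1] for r in clinvar
                   if r.significance in (ClinVarSignificance.BENIGN,
                                         ClinVarSignificance.LIKELY_BENIGN))
    ]
    tracks = {
        "critical_region": critical_regions,
        "critical_region_no_benign": critical_no_benign,
        "protein_domain": [(*domain1, "TOYD_dom1"), (*domain2, "TOYD_dom2")],
        "repeat_no_domain": [(*repeat, "TOYE_repeat")],
        "clinically_significant_exon": clin_sig_track,
    }
    track_lists = {k: list(v) for k, v in tracks.items()}

    inheritance = {n: p.mode for n, p in plans.items() if p.mode}

    # ---- panel ------------------------------------------------------------
    af: Dict[tuple, Dict[str, float]] = {}
    scores: Dict[tuple, Dict[str, float]] = {}
    exclusion: List[tuple] = []
    panel: List[PanelVariant] = []

    def add(vid, variant, kind, desc, *, gene, af_profile="neutral",
            score_vals=None, excluded=False, overrides=None):
        """Register a panel variant with straight-line expected outcomes."""
        if af_profile == "neutral":
            af[variant.key] = dict(_AF_NEUTRAL)
        elif af_profile == "common":
            af[variant.key] = dict(_AF_COMMON)
        elif af_profile == "bs1":
            af[variant.key] = dict(_AF_BS1)
        elif af_profile == "absent":
            pass
        if score_vals:
            scores[variant.key] = dict(score_vals)
        if excluded:
            exclusion.append(variant.key)

        states = _baseline_states(kind)
        # population expectations from the frequencies just assigned
        mode = gene.plan.mode
        if mode in ("AD", "AR"):
            cut = _AF_CUT[mode]
        else:  # unknown: strictest per criterion
            cut = {
                "ba1": max(_AF_CUT["AD"]["ba1"], _AF_CUT["AR"]["ba1"]),
                "bs1": max(_AF_CUT["AD"]["bs1"], _AF_CUT["AR"]["bs1"]),
                "pm2": min(_AF_CUT["AD"]["pm2"], _AF_CUT["AR"]["pm2"]),
            }
        rec = af.get(variant.key)
        if rec is None:
            states["PM2"] = "PM2_Supporting"
        else:
            vals = list(rec.values()) + [statistics.median(rec.values())]
            if not excluded and max(vals) >= cut["ba1"]:
                states["BA1"] = "BA1"
            elif not excluded and max(vals) >= cut["bs1"]:
                states["BS1"] = "BS1_Supporting"
            if all(x <= cut["pm2"] for x in rec.values()):
                states["PM2"] = "PM2_Supporting"
        if overrides:
            states.update(overrides)

        triggered = [_strength_key(s) for s in states.values()
                     if s not in (NA, NT)]
        acmg = _combine(
            triggered,
            mode,
            pm2_triggered=states["PM2"] not in (NA, NT),
            bs1_triggered=states["BS1"] not in (NA, NT),
        )
        x = sum(_W[k] for k in triggered if k in ("pvs", "ps", "pm", "pp"))
        x -= sum(_W[k] for k in triggered if k in ("ba", "bs", "bp"))
        post = _posterior(x)
        panel.append(
            PanelVariant(vid, variant, desc, states, acmg, post,
                         _refine(acmg, post))
        )

    # --- TOYA: NMD / PVS1 very-strong family ------------------------------
    v = a.snv_at_cds(210, "T", "v01")  # CAA -> TAA at codon 70
    add("v01", v, "stop_gained",
        "nonsense, NMD predicted, phenotype-relevant gene, novel variant",
        gene=a, af_profile="absent",
        overrides={"PVS1": "PVS1"})
    v = a.snv_at_cds(228, "T", "v02")  # codon 76, penultimate exon, not last-50
    add("v02", v, "stop_gained",
        "nonsense, NMD predicted (PTC outside penultimate-exon window)",
        gene=a, overrides={"PVS1": "PVS1"})

    v = norm(a.deletion_at_cds(150, 1, "v03"))
    pvs1 = _expected_pvs1_truncating(a, v, track_lists, True)
    add("v03", v, "frameshift", "1-bp frameshift deletion", gene=a,
        overrides={"PVS1": pvs1})

    donor_g = a.transcript.exons[1][1]  # first intron base after exon 2
    v = GenomicVariant(CHROM, donor_g, genome_seqs[CHROM][donor_g], "T", "v04")
    pvs1 = _expected_pvs1_truncating(a, v, track_lists, True, skip_exon=1)
    add("v04", v, "splice_donor", "canonical donor disruption, exon skipped",
        gene=a, overrides={"PVS1": pvs1})

    v = a.snv_at_cds(120, "T", "v28")  # codon 40: escape (<=200 bp of start)
    add("v28", v, "stop_gained",
        "nonsense escaping NMD near the start codon; clinically significant "
        "exon, 66% of the protein removed",
        gene=a, overrides={"PVS1": "PVS1_Strong"})

    # --- TOYB: missense / population family -------------------------------
    add("v05", b.snv_at_cds(100, "T", "v05"), "missense",
        "missense at an exon-junction codon with an identical pathogenic "
        "curated change (PS1)", gene=b, overrides={"PS1": "PS1"})
    add("v06", b.snv_at_cds(120, "G", "v06"), "missense",
        "missense with one different-residue pathogenic change at the codon "
        "(PM5)", gene=b, overrides={"PM5": "PM5"})
    add("v07", b.snv_at_cds(150, "A", "v07"), "missense",
        "missense with two distinct different-residue pathogenic changes "
        "(PM5 strong)", gene=b, overrides={"PM5": "PM5_Strong"})
    add("v08", b.snv_at_cds(60, "A", "v08"), "missense",
        "missense inside a benign-free critical region (PM1)", gene=b,
        overrides={"PM1": "PM1"})
    add("v09", b.snv_at_cds(180, "T", "v09"), "missense",
        "missense with pathogenic prediction and high conservation (PP3)",
        gene=b, score_vals={"revel": 0.9, "cadd": 25.0, "phylop": 2.5},
        overrides={"PP3": "PP3"})
    add("v10", b.snv_at_cds(195, "G", "v10"), "missense",
        "missense with benign predictions, low conservation, no splice "
        "effect (BP4)", gene=b,
        score_vals={"revel": 0.05, "cadd": 5.0, "phylop": 0.0,
                    "splice_ada": 0.1, "splice_rf": 0.05},
        overrides={"BP4": "BP4"})
    add("v11", b.snv_at_cds(212, "A", "v11"), "synonymous",
        "synonymous variant common in every subpopulation (BA1)", gene=b,
        af_profile="common", overrides={})
    add("v12", b.snv_at_cds(215, "A", "v12"), "synonymous",
        "common variant on the known-pathogenic high-AF exclusion list",
        gene=b, af_profile="common", excluded=True)
    add("v13", b.snv_at_cds(218, "A", "v13"), "synonymous",
        "moderately common variant (BS1 supporting; likely benign by the "
        "hearing-loss refinement)", gene=b, af_profile="bs1")
    add("v14", b.snv_at_cds(221, "A", "v14"), "synonymous",
        "synonymous, low conservation, no splice effect (BP7)", gene=b,
        score_vals={"phylop": 0.0, "splice_ada": 0.1, "splice_rf": 0.1},
        overrides={"BP7": "BP7"})

    # intronic variants in TOYB intron 1 (non-canonical positions)
    b_gap = (b.transcript.exons[0][1], b.transcript.exons[1][0])
    for vid, shift, score_vals, overrides in (
        ("v15", 30, {"splice_ada": 0.9, "phylop": 2.0}, {"PP3": "PP3"}),
        ("v16", 40, {"splice_ada": 0.05, "splice_rf": 0.1, "phylop": 0.0},
         {"BP4": "BP4"}),
    ):
        gpos = b_gap[0] + shift
        ref = genome_seqs[CHROM][gpos]
        alt = "A" if ref != "A" else "G"
        add(vid, GenomicVariant(CHROM, gpos, ref, alt, vid), "intronic",
            "deep-ish intronic variant screened for splice impact", gene=b,
            score_vals=score_vals, overrides=overrides)

    # --- TOYC: intronless NMD escape --------------------------------------
    add("v17", c.snv_at_cds(210, "T", "v17"), "stop_gained",
        "nonsense in an intronless gene, 29% of the protein removed "
        "(PVS1 strong), novel variant", gene=c, af_profile="absent",
        overrides={"PVS1": "PVS1_Strong"})
    add("v18", c.snv_at_cds(285, "T", "v18"), "stop_gained",
        "nonsense in an intronless gene, 4% of the protein removed "
        "(PVS1 moderate)", gene=c, overrides={"PVS1": "PVS1_Moderate"})

    # --- TOYD: NMD-escape domain branches ---------------------------------
    add("v19", d.snv_at_cds(225, "T", "v19"), "stop_gained",
        "nonsense escaping NMD in a critical protein domain (PVS1 strong)",
        gene=d, overrides={"PVS1": "PVS1_Strong"})
    add("v20", d.snv_at_cds(252, "T", "v20"), "stop_gained",
        "nonsense escaping NMD in a non-critical domain (PVS1 moderate)",
        gene=d, overrides={"PVS1": "PVS1_Moderate"})

    # --- TOYE: PM4 / BP3 family (not phenotype-relevant) ------------------
    v = norm(e.deletion_at_cds(160, 1, "v21"))
    pvs1 = _expected_pvs1_truncating(e, v, track_lists, False)
    add("v21", v, "frameshift",
        "frameshift in a gene outside the phenotype-relevant set", gene=e,
        overrides={"PVS1": pvs1})
    add("v22", norm(e.deletion_at_cds(30, 45, "v22")), "inframe_deletion",
        "in-frame deletion of 15 codons (12.6% of the protein; PM4)",
        gene=e, overrides={"PM4": "PM4"})
    add("v23", norm(e.deletion_at_cds(30, 9, "v23")), "inframe_deletion",
        "in-frame deletion of 3 codons (2.5%; below the PM4 cutoff)",
        gene=e)
    add("v24", norm(e.deletion_at_cds(165, 45, "v24")), "inframe_deletion",
        "in-frame deletion inside a functionless repeat (BP3; PM4 blocked)",
        gene=e, overrides={"BP3": "BP3"})
    stop_off = len(e.coding) - 3
    add("v25", e.snv_at_cds(stop_off, "G", "v25"), "stop_lost",
        "stop-loss reading 41 codons into the 3' UTR (34%; PM4)", gene=e,
        overrides={"PM4": "PM4"})

    # --- TOYF / TOYG: start-loss branches ---------------------------------
    add("v26", f.snv_at_cds(1, "C", "v26"), "start_loss",
        "start loss with a pathogenic curated entry before the rescue "
        "start (PVS1 moderate)", gene=f,
        overrides={"PVS1": "PVS1_Moderate"})
    add("v27", g7.snv_at_cds(1, "C", "v27"), "start_loss",
        "start loss with a clean region before the rescue start "
        "(PVS1 supporting)", gene=g7,
        overrides={"PVS1": "PVS1_Supporting"})

    return FixtureSet(
        seed=seed,
        genome_seqs=genome_seqs,
        genes=genes,
        clinvar=clinvar,
        af=af,
        scores=scores,
        tracks=track_lists,
        inheritance=inheritance,
        exclusion=exclusion,
        panel=panel,
    )
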