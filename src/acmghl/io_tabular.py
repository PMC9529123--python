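"""VCF ingestion, variant normalisation, and the tabular intermediate
format.

The intermediate file is a versioned TSV (one row per normalised biallelic
variant) carrying the basic annotation an upstream annotator would provide:
gene, reporting transcript, consequence kind, HGVS-style names, allele
frequencies and in-silico scores.  ``classify_table`` extends it with
per-criterion states and comments, the five-tier class, the posterior
pathogenicity probability and the refined broader class.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
import pysam

from .classify import ALL_CRITERIA, classify_variant
from .config import EngineConfig
from .consequence import annotate_variant
from .core import GenomicVariant
from .resources import Genome, ResourceBundle

logger = logging.getLogger(__name__)

__all__ = [
    "FORMAT_VERSION",
    "annotate",
    "classify_table",
    "normalize_variant",
    "read_vcf",
    "read_table",
    "write_table",
]

FORMAT_VERSION = "acmghl-intermediate v1"


# ---------------------------------------------------------------------------
# variant normalisation
# ---------------------------------------------------------------------------


def normalize_variant(
    chrom: str, pos0: int, ref: str, alt: str, genome: Optional[Genome] = None
) -> Tuple[str, int, str, str]:
    """Trim shared context and left-align indels (0-based input/output).

    Follows the usual parsimony/left-alignment procedure: shared suffix
    bases are dropped (extending to the left with reference sequence when
    an allele would empty), then shared prefix bases are dropped.
    """
    ref, alt = ref.upper(), alt.upper()
    changed = True
    while changed:
        changed = False
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        elif (
            genome is not None
            and ref
            and alt
            and ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and ref != alt
            and pos0 > 0
        ):
            base = genome.seq(chrom, pos0 - 1, pos0)
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos0 -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return chrom, pos0, ref, alt


def read_vcf(path, genome: Optional[Genome] = None) -> List[GenomicVariant]:
    """Read a VCF, split multi-allelic records, normalise each allele."""
    out: List[GenomicVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if set(alt.upper()) - set("ACGT"):
                    logger.warning(
                        "%s:%d skipping symbolic/invalid alt %r",
                        rec.chrom, rec.pos, alt,
                    )
                    continue
                chrom, pos0, ref, a = normalize_variant(
                    rec.chrom, rec.pos - 1, rec.ref, alt, genome
                )
                out.append(GenomicVariant(chrom, pos0, ref, a, rec.id))
    return out


# ---------------------------------------------------------------------------
# intermediate table
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "id", "gene", "transcript", "consequence",
    "hgvs_c", "hgvs_p", "allele_frequencies", "scores",
]


def _format_kv(d: dict) -> str:
    return ";".join(f"{k}={v:g}" for k, v in sorted(d.items()))


def annotate(vcf_path, bundle: ResourceBundle) -> pd.DataFrame:
    """Annotate every variant of a VCF into the intermediate table."""
    rows = []
    for v in read_vcf(vcf_path, bundle.genome):
        if v.chrom not in bundle.genome:
            raise ValueError(
                f"contig {v.chrom!r} absent from the reference sequence"
            )
        consequences = annotate_variant(v, bundle)
        af = bundle.query_af(v)
        sc = bundle.scores.get(v.key)
        score_str = (
            _format_kv(
                {
                    k: val
                    for k, val in vars(sc).items()
                    if val is not None
                }
            )
            if sc is not None
            else ""
        )
        if consequences:
            lead = consequences[0]
            t = bundle.transcripts[lead.transcript_id]
            row = {
                "gene": t.gene_symbol,
                "transcript": lead.transcript_id,
                "consequence": lead.kind.value,
                "hgvs_c": lead.hgvs_c,
                "hgvs_p": lead.hgvs_p,
            }
        else:
            logger.warning("%s overlaps no transcript; annotation empty", v)
            row = {
                "gene": "", "transcript": "", "consequence": "",
                "hgvs_c": "", "hgvs_p": "",
            }
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos1,
                "ref": v.ref,
                "alt": v.alt,
                "id": v.id or "",
                **row,
                "allele_frequencies": _format_kv(af.af_by_subpopulation) if af else "",
                "scores": score_str,
            }
        )
    return pd.DataFrame(rows, columns=_BASE_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"##{FORMAT_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##acmghl-intermediate"):
            raise ValueError(f"{path}: missing intermediate-format header line")
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema violation, missing column(s) {missing}")
    return df.fillna("")


def classify_table(
    df: pd.DataFrame, bundle: ResourceBundle, config: Optional[EngineConfig] = None
) -> pd.DataFrame:
    """Extend an intermediate table with criteria, class and posterior."""
    config = config or EngineConfig()
    out_rows = []
    for _, row in df.iterrows():
        v = GenomicVariant.from_vcf(
            str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]),
            str(row.get("id", "")) or None,
        )
        cv = classify_variant(v, bundle, config)
        extra = {}
        for r in cv.results:
            base = r.criterion.base.value
            state = r.state.value
            if r.triggered:
                state = r.criterion.label  # records the applied strength
            extra[f"{base}_state"] = state
            extra[f"{base}_comment"] = r.comment
        extra["acmg_class"] = cv.acmg_class.value
        extra["posterior"] = f"{cv.posterior:.5f}"
        extra["refined_class"] = cv.refined_broader_class.value
        extra["warnings"] = "; ".join(cv.warnings)
        out_rows.append({**row.to_dict(), **extra})
    columns = list(df.columns)
    for c in ALL_CRITERIA:
        columns += [f"{c.value}_state", f"{c.value}_comment"]
    columns += ["acmg_class", "posterior", "refined_class", "warnings"]
    return pd.DataFrame(out_rows, columns=columns)
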