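"""Minimal HGVS-style naming for coding and protein changes.

Only the forms the engine emits and consumes are covered: substitutions,
deletions, duplications/insertions and frameshifts, written against a
transcript's CDS.  This is deliberately not a general HGVS parser.
"""

from __future__ import annotations

import re
from typing import Optional, Tuple

from Bio.SeqUtils import seq3

__all__ = ["protein_change", "parse_protein_change", "coding_change"]

_AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Ter",
}
_AA1_TO_3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter", "X": "Ter",
}

_P_RE = re.compile(
    r"^p\.\(?([A-Za-z*]{1,3})(\d+)([A-Za-z*]{1,3}|=)(fs.*)?\)?$"
)


def _norm_aa(token: str) -> Optional[str]:
    if token in _AA3:
        return token
    if len(token) == 1 and token.upper() in _AA1_TO_3:
        return _AA1_TO_3[token.upper()]
    t = token.capitalize()
    return t if t in _AA3 else None


def protein_change(ref_aa: str, residue_1based: int, alt_aa: str) -> str:
    """Format a simple substitution, e.g. ``p.Arg42Cys`` (1-letter input ok)."""
    r3 = _norm_aa(ref_aa) or seq3(ref_aa)
    a3 = _norm_aa(alt_aa) or seq3(alt_aa)
    return f"p.{r3}{residue_1based}{a3}"


def parse_protein_change(hgvs_p: str) -> Optional[Tuple[str, int, str]]:
    """Parse ``p.Arg42Cys``-style strings to ``(ref3, residue, alt3)``.

    Returns None for unparseable, synonymous (``=``) or frameshift forms.
    """
    if not hgvs_p:
        return None
    m = _P_RE.match(hgvs_p.strip())
    if not m:
        return None
    ref_tok, pos, alt_tok, fs = m.groups()
    if fs or alt_tok == "=":
        return None
    ref3, alt3 = _norm_aa(ref_tok), _norm_aa(alt_tok)
    if ref3 is None or alt3 is None:
        return None
    return ref3, int(pos), alt3


def is_missense_change(hgvs_p: str) -> bool:
    """True if hgvs_p denotes a single-residue substitution (not to/from Ter)."""
    parsed = parse_protein_change(hgvs_p)
    if parsed is None:
        return False
    ref3, _, alt3 = parsed
    return ref3 != alt3 and ref3 != "Ter" and alt3 != "Ter"


def coding_change(cds_pos_1based: int, ref: str, alt: str) -> str:
    """Format a CDS-level change (substitution/del/dup/ins/delins)."""
    if len(ref) == 1 and len(alt) == 1:
        return f"c.{cds_pos_1based}{ref}>{alt}"
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        start = cds_pos_1based + 1
        end = cds_pos_1based + len(ref) - 1
        return f"c.{start}_{end}del" if end > start else f"c.{start}del"
    if len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
        ins = alt[1:]
        return f"c.{cds_pos_1based}_{cds_pos_1based + 1}ins{ins}"
    end = cds_pos_1based + len(ref) - 1
    return f"c.{cds_pos_1based}_{end}delins{alt}"
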