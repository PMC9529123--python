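"""Tunable thresholds and parameters for the classification engine.

Every cutoff used by a criterion evaluator lives here so that the engine can
be re-specialised for phenotypes other than hearing loss by editing a single
YAML file.  Defaults follow the hearing-loss expert-panel specification and
the Bayesian point framework the engine's posterior is built on; all are
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "AFThresholds",
    "EngineConfig",
    "PosteriorParams",
    "RefinementThresholds",
    "ScoreThresholds",
    "load_config",
]


@dataclass(frozen=True)
class AFThresholds:
    """Allele-frequency cutoffs per inheritance mode (fractions in [0,1]).

    ``ba1``/``bs1`` are commonness cutoffs (AF at or above triggers), ``pm2``
    is a rarity cutoff (all AFs at or below triggers).  Within a mode
    ``ba1 >= bs1 >= pm2`` must hold.
    """

    ba1_ad: float = 0.001
    ba1_ar: float = 0.005
    bs1_ad: float = 0.0002
    bs1_ar: float = 0.003
    pm2_ad: float = 0.00002
    pm2_ar: float = 0.00007

    def __post_init__(self) -> None:
        for mode in ("ad", "ar"):
            ba1 = getattr(self, f"ba1_{mode}")
            bs1 = getattr(self, f"bs1_{mode}")
            pm2 = getattr(self, f"pm2_{mode}")
            if not (ba1 >= bs1 >= pm2 >= 0):
                raise ValueError(f"need ba1 >= bs1 >= pm2 >= 0 for mode {mode.upper()}")

    def for_mode(self, mode: str) -> dict:
        mode = mode.lower()
        if mode not in ("ad", "ar"):
            raise ValueError(f"no direct thresholds for mode {mode!r}")
        return {
            "ba1": getattr(self, f"ba1_{mode}"),
            "bs1": getattr(self, f"bs1_{mode}"),
            "pm2": getattr(self, f"pm2_{mode}"),
        }


@dataclass(frozen=True)
class ScoreThresholds:
    """Cutoffs for the in-silico prediction criteria (PP3/BP4/BP7)."""

    revel_pathogenic: float = 0.7
    revel_benign: float = 0.15
    cadd_pathogenic: float = 20.0
    cadd_benign: float = 10.0
    phylop_conserved: float = 1.5
    phylop_nonconserved: float = 0.1
    #: MaxEntScan-style relative change of the splice-site score
    splice_delta: float = 0.10
    #: dbscSNV-style probability cutoff for a splice effect
    splice_prob: float = 0.6

    def __post_init__(self) -> None:
        if self.revel_pathogenic < self.revel_benign:
            raise ValueError("revel_pathogenic must be >= revel_benign")
        if self.cadd_pathogenic < self.cadd_benign:
            raise ValueError("cadd_pathogenic must be >= cadd_benign")
        if self.phylop_conserved < self.phylop_nonconserved:
            raise ValueError("phylop_conserved must be >= phylop_nonconserved")
        if not (0.0 <= self.splice_prob <= 1.0):
            raise ValueError("splice_prob must be a probability")


@dataclass(frozen=True)
class PosteriorParams:
    """Parameters of the Bayesian posterior pathogenicity probability.

    ``odds_pvst`` is the odds of pathogenicity assigned to one very-strong
    pathogenic criterion; lesser strengths contribute fractional exponents
    (supporting 1/8, moderate 1/4, strong 1/2).  Benign evidence enters with
    the negated weight of its strength; stand-alone benign weighs -1.
    """

    prior: float = 0.1
    odds_pvst: float = 350.0
    w_supporting: float = 1.0 / 8.0
    w_moderate: float = 1.0 / 4.0
    w_strong: float = 1.0 / 2.0
    w_very_strong: float = 1.0
    w_stand_alone: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must lie in (0, 1)")
        if self.odds_pvst <= 1.0:
            raise ValueError("odds_pvst must exceed 1")
        if not (self.w_supporting < self.w_moderate < self.w_strong < self.w_very_strong):
            raise ValueError("strength weights must be strictly increasing")


@dataclass(frozen=True)
class RefinementThresholds:
    """Posterior cutoffs for re-classifying VUS calls (inclusive bounds)."""

    pathogenic_cut: float = 0.49988
    benign_cut: float = 0.05072

    def __post_init__(self) -> None:
        if not (0.0 < self.benign_cut < self.pathogenic_cut < 1.0):
            raise ValueError("need 0 < benign_cut < pathogenic_cut < 1")


@dataclass(frozen=True)
class EngineConfig:
    """Top-level engine configuration."""

    af: AFThresholds = field(default_factory=AFThresholds)
    scores: ScoreThresholds = field(default_factory=ScoreThresholds)
    posterior: PosteriorParams = field(default_factory=PosteriorParams)
    refinement: RefinementThresholds = field(default_factory=RefinementThresholds)
    #: minimum review stars for ClinVar records consulted by PS1/PM5/PVS1
    min_stars: int = 1
    #: add the "PTC in the last exon" clause to the NMD escape rule
    nmd_last_exon_escape: bool = False
    #: model splice acceptor/donor disruption as skipping the adjacent exon
    #: ("skip") or retaining the intron ("retain")
    splice_model: str = "skip"
    #: count likely_pathogenic ClinVar entries as pathogenic for PS1/PM5
    ps1_include_likely: bool = False
    #: count PM5 multiplicity by distinct alternate residues (True) or by
    #: distinct genomic variants (False)
    pm5_count_residues: bool = True
    #: emit PM2 at supporting strength (hearing-loss demotion)
    pm2_supporting: bool = True
    #: emit BS1 at supporting strength (hearing-loss demotion)
    bs1_supporting: bool = True

    def __post_init__(self) -> None:
        if self.min_stars < 0:
            raise ValueError("min_stars must be >= 0")
        if self.splice_model not in ("skip", "retain"):
            raise ValueError("splice_model must be 'skip' or 'retain'")


_SECTIONS = {
    "af": AFThresholds,
    "scores": ScoreThresholds,
    "posterior": PosteriorParams,
    "refinement": RefinementThresholds,
}


def load_config(path: Optional[str] = None) -> EngineConfig:
    """Build an :class:`EngineConfig` from a YAML file (defaults if None).

    The YAML mirrors the dataclass layout::

        min_stars: 1
        af: {ba1_ad: 0.001, ...}
        posterior: {prior: 0.1, odds_pvst: 350}

    Unknown keys raise ``ValueError`` with the offending name.
    """
    if path is None:
        return EngineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    kwargs = {}
    top_fields = {f.name for f in fields(EngineConfig)}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            valid = {f.name for f in fields(cls)}
            bad = set(value) - valid
            if bad:
                raise ValueError(f"unknown {key} option(s): {sorted(bad)}")
            kwargs[key] = cls(**value)
        elif key in top_fields:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config option: {key}")
    return EngineConfig(**kwargs)
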