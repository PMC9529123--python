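"""Benchmark machinery: activation-frequency log ratios and micro-averaged
classification metrics.

The activation frequency of a criterion within one broader truth class is
the fraction of that class's variants for which the criterion fires; tools
are compared to manual curation through the elementwise log10 ratio of
these frequencies.  Classification quality over the three broader classes
(Benign / VUS / Pathogenic) is summarised by one-vs-rest micro-averaged
ROC AUC and average precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .core import BroaderClass

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationProfile",
    "LogRatioMatrix",
    "activation_log_ratio",
    "micro_metrics",
    "plot_log_ratio_heatmap",
    "posterior_class_scores",
]

CLASS_ORDER: Tuple[BroaderClass, ...] = (
    BroaderClass.BENIGN,
    BroaderClass.VUS,
    BroaderClass.PATHOGENIC,
)


@dataclass(frozen=True)
class ActivationProfile:
    """Per (criterion, broader class) activation frequencies of one source."""

    source: str
    frequencies: dict  # (criterion label, BroaderClass) -> frequency

    def __post_init__(self) -> None:
        for key, f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"activation frequency {f} for {key} outside [0,1]")

    @property
    def criteria(self) -> frozenset:
        return frozenset(c for c, _ in self.frequencies)


@dataclass(frozen=True)
class LogRatioMatrix:
    """Elementwise log10(alpha_tool / alpha_manual); None where undefined."""

    tool: str
    ratios: dict  # (criterion label, BroaderClass) -> float | None

    def value(self, criterion: str, cls: BroaderClass):
        return self.ratios.get((criterion, cls))


def activation_log_ratio(
    tool: ActivationProfile, manual: ActivationProfile
) -> LogRatioMatrix:
    """Log10 activation-frequency ratio of a tool over manual curation.

    Ratios with a zero manual frequency are undefined (None); a zero tool
    frequency against a nonzero manual one yields ``-inf``, which heatmap
    rendering maps to (matrix minimum - 1).
    """
    if tool.criteria != manual.criteria:
        raise ValueError(
            "profiles cover different criteria: "
            f"{sorted(tool.criteria ^ manual.criteria)}"
        )
    ratios = {}
    for key, a_tool in tool.frequencies.items():
        a_manual = manual.frequencies.get(key)
        if a_manual is None:
            continue
        if a_manual == 0.0:
            ratios[key] = None
        elif a_tool == 0.0:
            ratios[key] = -math.inf
        else:
            ratios[key] = math.log10(a_tool / a_manual)
    return LogRatioMatrix(tool=tool.source, ratios=ratios)


def posterior_class_scores(posterior: float) -> Dict[BroaderClass, float]:
    """Per-class scores derived from the pathogenicity posterior.

    score(Pathogenic) = p, score(Benign) = 1 - p,
    score(VUS) = 1 - |2p - 1|, renormalised to sum to one.
    """
    raw = {
        BroaderClass.PATHOGENIC: posterior,
        BroaderClass.BENIGN: 1.0 - posterior,
        BroaderClass.VUS: 1.0 - abs(2.0 * posterior - 1.0),
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def plot_log_ratio_heatmap(matrices, cls, ax=None):
    """Render criteria x tools log-ratio heatmaps for one broader class.

    ``matrices`` is a list of :class:`LogRatioMatrix`.  Undefined ratios
    are masked; ``-inf`` renders as the matrix minimum minus one.
    Requires matplotlib (optional extra).
    """
    import matplotlib.pyplot as plt

    criteria = sorted({c for m in matrices for c, k in m.ratios if k is cls})
    grid = np.full((len(criteria), len(matrices)), np.nan)
    for j, m in enumerate(matrices):
        for i, crit in enumerate(criteria):
            r = m.value(crit, cls)
            if r is not None:
                grid[i, j] = r
    finite = grid[np.isfinite(grid)]
    floor = (finite.min() if finite.size else 0.0) - 1.0
    grid = np.where(np.isneginf(grid), floor, grid)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + len(matrices), 0.4 * len(criteria) + 1))
    masked = np.ma.masked_invalid(grid)
    im = ax.imshow(masked, cmap="coolwarm", aspect="auto")
    ax.set_xticks(range(len(matrices)), [m.tool for m in matrices])
    ax.set_yticks(range(len(criteria)), criteria)
    ax.set_title(f"log10 activation ratio vs manual ({cls.value})")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def micro_metrics(
    truth: Sequence[BroaderClass],
    scores: Sequence[Dict[BroaderClass, float]],
) -> Tuple[float, float]:
    """One-vs-rest micro-averaged ROC AUC and average precision.

    ``scores`` holds per-variant class scores summing to one.  Classes
    absent from the truth are skipped with a warning (their one-vs-rest
    problem is degenerate).
    """
    if len(truth) != len(scores):
        raise ValueError("truth and scores must have equal length")
    present = [c for c in CLASS_ORDER if c in set(truth)]
    skipped = [c.value for c in CLASS_ORDER if c not in set(truth)]
    if skipped:
        logger.warning("classes absent from truth, skipped: %s", skipped)
    if not present:
        raise ValueError("no class present in truth")
    y = np.array([[1 if t is c else 0 for c in present] for t in truth])
    s = np.array([[sc[c] for c in present] for sc in scores])
    roc = float(roc_auc_score(y.ravel(), s.ravel()))
    ap = float(average_precision_score(y.ravel(), s.ravel()))
    return roc, ap
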