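"""Virtual-screening enrichment metrics over labeled, scored molecule lists.

Scores are energies: lower is better.  Two early-recognition metrics are
provided: the enrichment factor at a top fraction (EF) and the adjusted
semilog ROC area (adjusted logAUC), where the x-axis is the fraction of
decoys screened (the usual DOCK convention) or, optionally, the fraction
of the whole database.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .errors import MetricError

__all__ = [
    "ScreenRecord",
    "EnrichmentReport",
    "ef_at_fraction",
    "adjusted_logauc",
    "enrichment_report",
    "RANDOM_LOGAUC_PERCENT",
]

# semilog area of the random (y = x) curve for lambda = 0.001, in percent
RANDOM_LOGAUC_PERCENT = 14.462


@dataclass(frozen=True)
class ScreenRecord:
    """One screened molecule: id, score (kcal/mol, lower = better), label."""

    mol_id: str
    score: Optional[float]
    label: Literal["active", "decoy"]
    scored: bool = True

    def __post_init__(self) -> None:
        if self.label not in ("active", "decoy"):
            raise MetricError(f"label must be 'active' or 'decoy', got {self.label!r}")
        if self.scored and (self.score is None or not math.isfinite(self.score)):
            raise MetricError(f"record {self.mol_id!r}: non-finite score")


@dataclass
class EnrichmentReport:
    adjusted_logauc: float
    ef_at_fraction: float
    fraction: float
    n_actives: int
    n_decoys: int
    n_unscored: int = 0
    lambda_min: float = 0.001
    x_axis: str = "decoys"


def _ranked(records: Sequence[ScreenRecord]) -> list[ScreenRecord]:
    """Stable sort: scored records ascending by score, unscored appended last."""
    scored = [r for r in records if r.scored]
    unscored = [r for r in records if not r.scored]
    scored.sort(key=lambda r: r.score)  # sort is stable
    return scored + unscored


def _counts(records: Sequence[ScreenRecord]) -> tuple[int, int]:
    n_act = sum(1 for r in records if r.label == "active")
    n_dec = sum(1 for r in records if r.label == "decoy")
    if n_act == 0:
        raise MetricError("no actives: enrichment metrics are undefined")
    if n_dec == 0:
        raise MetricError("no decoys: enrichment metrics are undefined")
    return n_act, n_dec


def ef_at_fraction(records: Sequence[ScreenRecord], fraction: float) -> float:
    """Enrichment factor at the given top fraction of the ranked list."""
    if not 0.0 < fraction <= 1.0:
        raise MetricError(f"fraction must be in (0, 1], got {fraction}")
    n_act, _ = _counts(records)
    ranked = _ranked(records)
    n_top = math.ceil(fraction * len(ranked))
    if (
        n_top < len(ranked)
        and ranked[n_top - 1].scored
        and ranked[n_top].scored
        and ranked[n_top - 1].score == ranked[n_top].score
    ):
        warnings.warn(
            f"score tie spans the top-{fraction:g} cutoff; ranking at the "
            "boundary follows stable input order",
            stacklevel=2,
        )
    found = sum(1 for r in ranked[:n_top] if r.label == "active")
    return (found / n_act) / fraction


def adjusted_logauc(
    records: Sequence[ScreenRecord],
    lambda_min: float = 0.001,
    x_axis: Literal["decoys", "database"] = "decoys",
) -> float:
    """Adjusted semilog ROC area, percent scale.

    Trapezoid area of the actives-found fraction against log10(x) over
    [lambda_min, 1], normalized by log10(1/lambda_min), times 100, minus
    the random-curve area (14.462% at lambda_min = 0.001).  Perfect
    ranking gives 85.538; random ranking averages about 0.
    """
    if not 0.0 < lambda_min < 1.0:
        raise MetricError(f"lambda_min must be in (0, 1), got {lambda_min}")
    n_act, n_dec = _counts(records)
    ranked = _ranked(records)
    denom = n_dec if x_axis == "decoys" else len(ranked)

    area = 0.0
    x_prev, y_prev = 0.0, 0.0
    found_act = found_dec = 0
    for i, r in enumerate(ranked):
        if r.label == "active":
            found_act += 1
        else:
            found_dec += 1
        x = (found_dec if x_axis == "decoys" else i + 1) / denom
        y = found_act / n_act
        if x > lambda_min:
            a = max(x_prev, lambda_min)
            if x > a:
                area += 0.5 * (y_prev + y) * (math.log10(x) - math.log10(a))
        x_prev, y_prev = x, y

    # random-curve reference recomputed for the actual lambda_min
    random_area = (1.0 - lambda_min) / math.log(10.0)
    norm = math.log10(1.0 / lambda_min)
    return 100.0 * area / norm - 100.0 * random_area / norm


def enrichment_report(
    records: Sequence[ScreenRecord],
    fraction: float = 0.01,
    lambda_min: float = 0.001,
    x_axis: Literal["decoys", "database"] = "decoys",
) -> EnrichmentReport:
    n_act, n_dec = _counts(records)
    return EnrichmentReport(
        adjusted_logauc=adjusted_logauc(records, lambda_min, x_axis),
        ef_at_fraction=ef_at_fraction(records, fraction),
        fraction=fraction,
        n_actives=n_act,
        n_decoys=n_dec,
        n_unscored=sum(1 for r in records if not r.scored),
        lambda_min=lambda_min,
        x_axis=x_axis,
    )
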