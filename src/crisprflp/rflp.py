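"""RFLP densitometry: from band intensities to mutagenesis efficiencies.

Each gel lane holds the digested PCR product of one embryo.  Cas9-induced
indels destroy the restriction site, so edited template resists digestion:
the fraction of signal remaining in the undigested (full-length) band
estimates the fraction of mutant alleles in that embryo.

    efficiency = undigested / (undigested + sum(digested))

which runs from 0 (no activity, complete digestion) to 1 (complete target
mutagenesis).  A ratio of 0.9 is reported as 90% efficiency.  Guides whose
aggregate efficiency exceeds 0.90 are classified as highly active (haCR) —
the pre-screen's pass threshold.

Uninjected control embryos must digest completely (efficiency near 0); a
control lane above the QC threshold indicates failed digestion, poor DNA or
gel saturation, and invalidates the guide's measurement.

Intensities are assumed background-subtracted upstream (gel image analysis
is out of scope; the toolkit starts from numbers, not pixels).  Bands that
are neither full-length amplicon nor predicted digest fragments (e.g.
heteroduplexes) may be recorded in ``other_intensities``; they are excluded
from the ratio, which is the conservative choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LaneMeasurement",
    "ActivityEstimate",
    "efficiency_from_lane",
    "validate_controls",
    "aggregate_guide",
    "activity_distribution",
    "HACR_THRESHOLD",
    "CONTROL_THRESHOLD",
]

HACR_THRESHOLD = 0.90  # aggregate efficiency must be strictly above this
CONTROL_THRESHOLD = 0.05  # max tolerated control-lane efficiency


@dataclass(frozen=True)
class LaneMeasurement:
    """Background-subtracted band intensities for one embryo's lane."""

    guide_id: str
    embryo_id: str
    is_control: bool
    undigested_intensity: float
    digested_intensities: tuple[float, ...]
    other_intensities: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        vals = (self.undigested_intensity, *self.digested_intensities,
                *self.other_intensities)
        for v in vals:
            if not math.isfinite(v):
                raise ValueError(f"lane {self.embryo_id}: non-finite intensity")
            if v < 0:
                raise ValueError(
                    f"lane {self.embryo_id}: negative intensity {v}"
                )


@dataclass(frozen=True)
class ActivityEstimate:
    """Aggregated mutagenesis efficiency for one guide."""

    guide_id: str
    per_embryo: tuple[float, ...]
    aggregate: float
    is_hacr: bool
    qc_pass: bool
    n_controls: int = 0


def efficiency_from_lane(lane: LaneMeasurement) -> float:
    """Mutagenesis efficiency of one lane: undigested / (undigested + digested).

    Clipped to [0, 1].  A lane with zero total signal is uninterpretable and
    raises (``"empty lane"``).
    """
    undig = lane.undigested_intensity
    total = undig + sum(lane.digested_intensities)
    if total <= 0:
        raise ValueError(f"empty lane: {lane.guide_id}/{lane.embryo_id}")
    return float(min(1.0, max(0.0, undig / total)))


def validate_controls(
    lanes: Iterable[LaneMeasurement],
    control_threshold: float = CONTROL_THRESHOLD,
) -> bool:
    """QC: every uninjected control lane must digest (near-)completely.

    Returns True iff every control lane's efficiency is <= the threshold
    (boundary inclusive).  No control lanes at all means the digestion
    cannot be validated: QC fails with a warning.
    """
    controls = [ln for ln in lanes if ln.is_control]
    if not controls:
        warnings.warn("no control lanes; QC fails", stacklevel=2)
        return False
    return all(efficiency_from_lane(ln) <= control_threshold for ln in controls)


def aggregate_guide(
    lanes: Sequence[LaneMeasurement],
    hacr_threshold: float = HACR_THRESHOLD,
    control_threshold: float = CONTROL_THRESHOLD,
) -> ActivityEstimate:
    """Aggregate one guide's lanes into an activity estimate.

    The aggregate is the arithmetic mean of the injected embryos' per-lane
    efficiencies; per-embryo values are kept alongside so users can
    re-aggregate.  ``is_hacr`` requires the aggregate to be strictly above
    the threshold AND control QC to pass; on QC failure the estimate is
    still emitted, with ``is_hacr`` forced false.
    """
    injected = [ln for ln in lanes if not ln.is_control]
    if not injected:
        raise ValueError("no injected lanes for guide")
    guide_ids = {ln.guide_id for ln in lanes}
    if len(guide_ids) != 1:
        raise ValueError(f"lanes from multiple guides: {sorted(guide_ids)}")
    per_embryo = tuple(efficiency_from_lane(ln) for ln in injected)
    qc = validate_controls(lanes, control_threshold)
    aggregate = float(np.mean(per_embryo))
    return ActivityEstimate(
        guide_id=guide_ids.pop(),
        per_embryo=per_embryo,
        aggregate=aggregate,
        is_hacr=bool(aggregate > hacr_threshold and qc),
        qc_pass=qc,
        n_controls=sum(1 for ln in lanes if ln.is_control),
    )


def activity_distribution(
    estimates: Sequence[ActivityEstimate] | Sequence[float],
    bin_edges: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0),
    hacr_threshold: float = HACR_THRESHOLD,
    low_threshold: float = 0.5,
) -> dict:
    """Histogram + summary of a batch of guide efficiencies.

    Accepts ActivityEstimates or raw aggregate efficiencies.  Returns bin
    counts (summing to n), the fraction classified haCR (strictly above the
    threshold) and the count/fraction below ``low_threshold`` — the two
    summaries a pre-screen campaign reports.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be ascending with >= 2 values")
    values = np.asarray(
        [e.aggregate if isinstance(e, ActivityEstimate) else float(e)
         for e in estimates],
        dtype=float,
    )
    if values.size == 0:
        return {
            "counts": np.zeros(edges.size - 1, dtype=int),
            "bin_edges": edges,
            "n": 0,
            "n_hacr": 0,
            "fraction_hacr": float("nan"),
            "n_below": 0,
            "fraction_below": float("nan"),
        }
    counts, _ = np.histogram(values, bins=edges)
    n_hacr = int(np.sum(values > hacr_threshold))
    n_below = int(np.sum(values < low_threshold))
    return {
        "counts": counts,
        "bin_edges": edges,
        "n": int(values.size),
        "n_hacr": n_hacr,
        "fraction_hacr": n_hacr / values.size,
        "n_below": n_below,
        "fraction_below": n_below / values.size,
    }
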