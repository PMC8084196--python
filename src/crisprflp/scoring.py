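"""In-silico guide activity rules and their correlation with measured activity.

Three published rule families are implemented for scoring 20-nt protospacers
(guide orientation, position -1 = PAM-proximal base):

* a positional feature count (C at -3; A at -5 and -12; G at -14 and -17),
* a guanine-enrichment / adenine-depletion score, (#G - #A) / 20,
* a generic position-weight model (single- and di-nucleotide weights plus
  GC-count terms) that accepts externally trained weight tables.

These scorers exist so users can compare predicted activity against the
efficiency actually measured in vivo by RFLP; in the F0 crispant setting
that correlation is characteristically weak, which is the argument for
empirical pre-screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WeightTable",
    "score_positional",
    "score_ga",
    "score_weighted",
    "correlate_activity",
    "correlate_position",
    "RegressionResult",
]

# (position counted back from the PAM, required base) -> one point each.
# -1 is the PAM-proximal base of the 20-mer, so position -k is index 20 - k.
POSITIONAL_FEATURES: tuple[tuple[int, str], ...] = (
    (-3, "C"),
    (-5, "A"),
    (-12, "A"),
    (-14, "G"),
    (-17, "G"),
)


def _check_protospacer(protospacer: str) -> str:
    protospacer = protospacer.upper()
    if len(protospacer) != 20:
        raise ValueError(f"protospacer must be 20 nt, got {len(protospacer)}")
    return protospacer


def score_positional(protospacer: str) -> int:
    """Count of favourable positional features present (0-5).

    One point for each of: C at -3, A at -5, A at -12, G at -14, G at -17,
    where -1 denotes the PAM-proximal base and positions count away from
    the PAM.
    """
    protospacer = _check_protospacer(protospacer)
    return sum(
        1 for pos, base in POSITIONAL_FEATURES if protospacer[20 + pos] == base
    )


def score_ga(protospacer: str) -> float:
    """Guanine-enrichment / adenine-depletion score, (#G - #A) / 20 in [-1, 1]."""
    protospacer = _check_protospacer(protospacer)
    return (protospacer.count("G") - protospacer.count("A")) / 20.0


@dataclass(frozen=True)
class WeightTable:
    """Position-specific k-mer weights plus GC-count terms.

    ``kmer_weights`` maps ``(position, kmer)`` with 1- or 2-nt kmers and
    0-based positions on a protospacer+PAM (or longer, up to 30-nt) context;
    ``gc_weights`` maps a GC count over the 20-nt protospacer to a weight.
    The shipped example table is illustrative only; externally trained
    weights in the same TSV format are accepted verbatim.
    """

    kmer_weights: Mapping[tuple[int, str], float] = field(default_factory=dict)
    gc_weights: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (pos, kmer), _ in self.kmer_weights.items():
            if not (0 <= pos <= 29):
                raise ValueError(f"weight position {pos} outside 0-29")
            if len(kmer) not in (1, 2):
                raise ValueError(f"kmer {kmer!r} must be 1 or 2 nt")


def score_weighted(protospacer: str, pam: str, table: WeightTable) -> float:
    """Sum of matched position/k-mer weights plus the GC-count term.

    The scoring context is ``protospacer + pam``; weights referencing
    positions beyond the context simply never match.  An all-zero (empty)
    table scores 0.
    """
    protospacer = _check_protospacer(protospacer)
    context = protospacer + pam.upper()
    total = 0.0
    for (pos, kmer), w in table.kmer_weights.items():
        if context[pos : pos + len(kmer)] == kmer:
            total += w
    gc = protospacer.count("G") + protospacer.count("C")
    total += table.gc_weights.get(gc, 0.0)
    return total


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def correlate_activity(
    scores: Sequence[float], efficiencies: Sequence[float]
) -> RegressionResult:
    """OLS of measured efficiency on predicted score.

    Returns slope, intercept and R^2 of the ordinary least-squares fit of
    ``efficiencies`` (each in [0, 1]) on ``scores``.  Constant scores carry
    no information: the fit degenerates to the mean with R^2 = 0 and a
    warning, matching a constant predictor.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(efficiencies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and efficiencies must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("efficiencies must lie in [0, 1]")
    if np.ptp(x) == 0:
        warnings.warn("zero variance in scores; R^2 = 0", stacklevel=2)
        return RegressionResult(0.0, float(y.mean()), 0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    )


def correlate_position(
    distances: Sequence[float], efficiencies: Sequence[float]
) -> float:
    """R^2 of efficiency against distance from the CDS start.

    Same OLS core as :func:`correlate_activity`; used to ask whether
    5'-proximal guides are systematically more active in vivo.
    """
    return correlate_activity(distances, efficiencies).r_squared
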