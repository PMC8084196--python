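"""Proportion-based phenotypic screen analysis.

The screen's per-larva readout is binary: does labelled tissue bridge the
spinal lesion site at a fixed time post-lesion?  Each perturbation arm is a
(bridged, total) count paired with same-experiment lesioned controls; arms
are compared to controls with Fisher's exact test, and effects are reported
as the arm's bridging proportion as a percentage of the control proportion.

Default baselines for simulation follow the larval lesion paradigm:
about 40% of control larvae bridge by 24 hours post-lesion (hpl) and about
80% by 48 hpl.

The two-sided Fisher p-value uses the point-probability criterion (sum the
probabilities of all tables with the observed margins whose probability does
not exceed the observed table's, with a 1 + 1e-7 relative tolerance for
floating-point ties) — the convention of mainstream statistical software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenArm",
    "bridging_proportion",
    "percent_of_control",
    "fisher_exact_2x2",
    "screen_report",
    "power_simulation",
    "DEFAULT_CONTROL_P",
]

# Control bridging baselines by hours post-lesion.
DEFAULT_CONTROL_P = {24: 0.40, 48: 0.80}

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ScreenArm:
    """Counts for one perturbation at one timepoint, with paired controls."""

    arm: str
    timepoint: int
    n_total: int
    n_bridged: int
    control_total: int
    control_bridged: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_bridged <= self.n_total):
            raise ValueError(
                f"{self.arm}: n_bridged {self.n_bridged} outside [0, {self.n_total}]"
            )
        if not (0 <= self.control_bridged <= self.control_total):
            raise ValueError(
                f"{self.arm}: control_bridged outside [0, control_total]"
            )


def bridging_proportion(arm: ScreenArm) -> float:
    """Fraction of assessed larvae with a bridged injury site."""
    if arm.n_total < 1:
        raise ValueError(f"{arm.arm}: no larvae assessed")
    return arm.n_bridged / arm.n_total


def percent_of_control(arm: ScreenArm) -> float:
    """Arm bridging proportion as a percentage of the paired control's.

    Scale-free in the counts.  Undefined when no control larva bridged.
    """
    if arm.control_total < 1:
        raise ValueError(f"{arm.arm}: no control larvae")
    ctrl = arm.control_bridged / arm.control_total
    if ctrl == 0:
        raise ValueError(f"{arm.arm}: undefined normalization (control proportion 0)")
    return 100.0 * bridging_proportion(arm) / ctrl


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Rows are outcomes (bridged / not bridged), columns are groups (arm /
    control).  Conditional on the margins, the count ``a`` is
    hypergeometric; the two-sided p sums P(table) over all tables whose
    point probability is <= that of the observed table (relative tolerance
    1 + 1e-7).  A table with any zero margin carries no information and
    returns p = 1.0 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = a + b + c + d
    if 0 in (row1, row2, col1, col2):
        warnings.warn("zero margin in 2x2 table; p = 1.0", stacklevel=2)
        return 1.0
    dist = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - row2), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return min(1.0, max(p, float(p_obs)))


def screen_report(
    arms: Sequence[ScreenArm],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-arm summary table with Fisher p-values and hit flags.

    Columns: arm, timepoint, counts, bridging proportion, percent of
    control, raw two-sided p, hit flag (raw p < alpha — the convention for
    small targeted screens reporting uncorrected per-gene tests), and a
    Benjamini-Hochberg ``q`` column when ``adjust=True`` for wider screens.
    Rows are ordered by timepoint then arm label for determinism.
    """
    rows = []
    for arm in sorted(arms, key=lambda a: (a.timepoint, a.arm)):
        if arm.control_total < 1:
            warnings.warn(f"{arm.arm}: no paired controls; skipped", stacklevel=2)
            continue
        p = fisher_exact_2x2(
            arm.n_bridged,
            arm.control_bridged,
            arm.n_total - arm.n_bridged,
            arm.control_total - arm.control_bridged,
        )
        rows.append(
            {
                "arm": arm.arm,
                "timepoint": arm.timepoint,
                "n_total": arm.n_total,
                "n_bridged": arm.n_bridged,
                "proportion": bridging_proportion(arm),
                "percent_of_control": (
                    percent_of_control(arm) if arm.control_bridged > 0 else np.nan
                ),
                "p": p,
                "hit": p < alpha,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "arm", "timepoint", "n_total", "n_bridged",
            "proportion", "percent_of_control", "p", "hit",
        ],
    )
    if adjust and len(df):
        df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df


class PowerEstimate(NamedTuple):
    power: float
    mc_se: float
    n_sims: int


def power_simulation(
    n_per_arm: int,
    p_control: float,
    effect_ratio: float,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the Fisher test for a proportional reduction.

    Simulates screens where the arm bridges at ``p_control * effect_ratio``
    and the control at ``p_control``, each with ``n_per_arm`` larvae, and
    reports the fraction with two-sided p < alpha plus its binomial
    standard error.  ``effect_ratio = 1`` is the null and recovers the test
    size (conservatively, as exact tests do).  Screens aim for power > 0.8.
    """
    if not 0.0 < effect_ratio <= 1.0:
        raise ValueError("effect_ratio must be in (0, 1]")
    p_arm = p_control * effect_ratio
    if not 0.0 <= p_arm <= 1.0 or not 0.0 <= p_control <= 1.0:
        raise ValueError("proportions must lie in [0, 1]")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    arm_hits = rng.binomial(n_per_arm, p_arm, size=n_sims)
    ctrl_hits = rng.binomial(n_per_arm, p_control, size=n_sims)
    rejections = 0
    cache: dict[tuple[int, int], float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-margin tables under the null
        for x, y in zip(arm_hits, ctrl_hits):
            key = (int(x), int(y))
            if key not in cache:
                cache[key] = fisher_exact_2x2(
                    key[0], key[1], n_per_arm - key[0], n_per_arm - key[1]
                )
            if cache[key] < alpha:
                rejections += 1
    power = rejections / n_sims
    mc_se = math.sqrt(power * (1 - power) / n_sims)
    return PowerEstimate(power=power, mc_se=mc_se, n_sims=n_sims)
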