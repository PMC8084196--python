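"""Synthetic inputs for every stage of the pipeline, with known ground truth.

Three generators mirror the three experimental layers:

* :func:`make_sequence` — a random target region with restriction-enzyme
  recognition motifs implanted so that each implant supports at least one
  RFLP-compatible guide (the implanted motifs carry an NGG on a strand, and
  enough flanking sequence for a full protospacer).
* :func:`make_gel_lanes` — per-embryo band intensities for a guide of known
  true efficiency.  Embryo-to-embryo mosaicism is beta-distributed around
  the true efficiency (bounded support; concentration configurable), and
  band densitometry noise is multiplicative lognormal, because measurement
  error scales with band intensity.  Uninjected controls are generated at
  zero efficiency.
* :func:`make_screen_counts` — binomial bridged/total counts per arm and
  timepoint, with control baselines 40% at 24 hpl and 80% at 48 hpl.

Everything is driven by an explicit seed and is bit-reproducible.  These
generators emulate the *statistical* structure the analysis assumes; they do
not simulate gel images, sequencing reads, or real repair-outcome spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enzymes import IUPAC_CODES, RestrictionEnzyme, default_catalog
from .rflp import LaneMeasurement

__all__ = [
    "FixtureConfig",
    "make_sequence",
    "make_gel_lanes",
    "make_screen_counts",
]


@dataclass
class FixtureConfig:
    """Knobs shared by the fixture generators; seed is mandatory."""

    seed: int
    length: int = 1000
    gc_content: float = 0.5
    n_implants: int = 3
    enzymes: Sequence[RestrictionEnzyme] | None = None
    # gel model
    n_injected: int = 8
    n_controls: int = 4
    noise_sigma: float = 0.1
    background: float = 0.0
    beta_concentration: float = 100.0
    # clone model
    edit_prob: float = 1.0
    frameshift_fraction: float = 2.0 / 3.0


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=p))


def _concretize(rng: np.random.Generator, motif: str) -> str:
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_CODES[b]))
        for b in motif
    )


def make_sequence(config: FixtureConfig) -> tuple[str, list[dict]]:
    """Random background sequence with enzyme motifs implanted.

    Implants are placed non-overlapping with >= 25 nt flanks, so a full
    protospacer + PAM fits around each motif.  Only PAM-compatible enzymes
    are used (their expansions contain an NGG, guaranteeing a guide whose
    cut boundary falls inside the motif).  Each implant's support for an
    RFLP-compatible guide is verified at generation time; a concretization
    that fails (or an implant collision) is retried a bounded number of
    times before erroring.

    Returns the sequence and a ground-truth list of dicts with keys
    ``enzyme``, ``start``, ``end``.
    """
    from .design import attach_rflp_sites, enumerate_protospacers
    from .enzymes import scan_motifs

    if config.length < 200:
        raise ValueError("sequence length must be >= 200")
    rng = np.random.default_rng(config.seed)
    enzymes = list(config.enzymes) if config.enzymes else [
        e for e in default_catalog() if e.pam_compatible and len(e.motif) >= 10
    ]
    if config.n_implants and not enzymes:
        raise ValueError("no PAM-compatible enzymes to implant")
    seq = _random_sequence(rng, config.length, config.gc_content)
    flank = 25
    truth: list[dict] = []
    occupied: list[tuple[int, int]] = []
    for i in range(config.n_implants):
        enz = enzymes[i % len(enzymes)]
        placed = False
        for _ in range(200):
            start = int(rng.integers(flank, config.length - flank - len(enz.motif)))
            end = start + len(enz.motif)
            if any(max(start - flank, s) < min(end + flank, e) for s, e in occupied):
                continue
            concrete = _concretize(rng, enz.motif)
            trial = seq.copy()
            trial[start:end] = list(concrete)
            # verify the implant supports an RFLP-compatible guide
            region = "".join(trial[max(0, start - flank) : end + flank])
            offset = max(0, start - flank)
            cands = attach_rflp_sites(
                enumerate_protospacers(region),
                scan_motifs(region, [enz]),
            )
            ok = any(
                c.is_rflp_compatible
                and start < offset + c.cut_boundary < end
                for c in cands
            )
            if not ok:
                continue
            seq = trial
            occupied.append((start, end))
            truth.append({"enzyme": enz.name, "start": start, "end": end})
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place implant {i + 1} ({enz.name}) after bounded retries"
            )
    truth.sort(key=lambda t: t["start"])
    return "".join(seq), truth


def make_gel_lanes(
    true_efficiency: float,
    guide_id: str = "guide1",
    n_injected: int = 8,
    n_controls: int = 4,
    noise_sigma: float = 0.1,
    background: float = 0.0,
    beta_concentration: float = 100.0,
    amplitude: float = 1000.0,
    seed: int = 0,
) -> list[LaneMeasurement]:
    """Simulate one guide's RFLP gel: injected embryos plus uninjected controls.

    Each injected embryo's mosaic fraction m_i is drawn from
    ``Beta(m * k, (1 - m) * k)`` around the true efficiency ``m`` (point
    mass at m = 0 or 1); the undigested band is proportional to m_i, and
    the digested signal (split into two fragments, 60/40) to 1 - m_i, each
    multiplied by lognormal noise ``exp(sigma * Z)`` and shifted by the
    additive ``background``.  Controls are generated at m = 0.  With zero
    noise and background the lane ratio recovers m_i exactly.
    """
    if not 0.0 <= true_efficiency <= 1.0:
        raise ValueError("true_efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def lane(embryo_id: str, m: float, is_control: bool) -> LaneMeasurement:
        if 0.0 < m < 1.0 and beta_concentration > 0:
            frac = rng.beta(m * beta_concentration, (1 - m) * beta_concentration)
        else:
            frac = m
        noise = np.exp(noise_sigma * rng.standard_normal(3)) if noise_sigma > 0 else np.ones(3)
        undig = amplitude * frac * noise[0] + background
        dig1 = amplitude * (1 - frac) * 0.6 * noise[1] + background
        dig2 = amplitude * (1 - frac) * 0.4 * noise[2] + background
        return LaneMeasurement(
            guide_id=guide_id,
            embryo_id=embryo_id,
            is_control=is_control,
            undigested_intensity=float(undig),
            digested_intensities=(float(dig1), float(dig2)),
        )

    lanes = [lane(f"ctrl{i + 1}", 0.0, True) for i in range(n_controls)]
    lanes += [lane(f"inj{i + 1}", true_efficiency, False) for i in range(n_injected)]
    return lanes


def make_screen_counts(
    arms: Mapping[str, float],
    n_per_arm: int = 40,
    control_p: Mapping[int, float] = None,
    timepoints: Sequence[int] = (24, 48),
    n_control: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a bridging screen count table.

    ``arms`` maps arm label -> effect ratio (1.0 = null; the arm bridges at
    ``control_p[t] * ratio``).  One shared control group per timepoint is
    drawn at the baseline proportion.  Returns a DataFrame in the screen CSV
    dialect (arm, timepoint, n_total, n_bridged, control_total,
    control_bridged) plus a ``true_effect_ratio`` ground-truth column.
    """
    from .screen import DEFAULT_CONTROL_P

    if not arms:
        raise ValueError("need at least one arm")
    control_p = dict(DEFAULT_CONTROL_P if control_p is None else control_p)
    n_control = n_per_arm if n_control is None else n_control
    rng = np.random.default_rng(seed)
    rows = []
    for t in timepoints:
        p_ctrl = control_p[t]
        ctrl_bridged = int(rng.binomial(n_control, p_ctrl))
        for label, ratio in arms.items():
            p_arm = p_ctrl * ratio
            if not 0.0 <= p_arm <= 1.0:
                raise ValueError(f"{label}: arm proportion {p_arm} outside [0, 1]")
            rows.append(
                {
                    "arm": label,
                    "timepoint": t,
                    "n_total": n_per_arm,
                    "n_bridged": int(rng.binomial(n_per_arm, p_arm)),
                    "control_total": n_control,
                    "control_bridged": ctrl_bridged,
                    "true_effect_ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
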