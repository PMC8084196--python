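"""SpCas9 protospacer enumeration and RFLP-compatible guide selection.

The design rule at the heart of the toolkit: pick guides whose blunt Cas9 cut
boundary (3 bp 5' of the NGG PAM, between protospacer positions 17 and 18) is
*crossed* by a restriction-enzyme recognition motif — at least one motif base
on each side of the cut.  Any indel created at the cut then necessarily
destroys the recognition site, so loss of digestion (RFLP) reads out editing
efficiency directly from a PCR product, without sequencing.

Coordinates are 0-based half-open on the supplied reference.  The cut
boundary ``c`` is an inter-base index: the cut falls between reference
positions ``c - 1`` and ``c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .enzymes import MotifHit, RestrictionEnzyme, scan_motifs

__all__ = [
    "GuideCandidate",
    "enumerate_protospacers",
    "attach_rflp_sites",
    "rank_candidates",
    "design_guides",
    "predict_digest",
]

PROTOSPACER_LEN = 20
# Blunt SpCas9 cut between protospacer positions 17 and 18 (3 bp 5' of PAM).
CUT_FROM_START = 17


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt SpCas9 protospacer with its RFLP annotation.

    ``protospacer`` and ``pam`` are in guide orientation (5'->3' as the guide
    RNA reads them); ``start``/``end`` is the protospacer interval on the
    plus strand of the reference.  ``cut_boundary`` is the inter-base index
    of the blunt cut.  ``rflp_hits`` lists (enzyme name, MotifHit) pairs
    whose motif strictly crosses the cut boundary.
    """

    record: str
    protospacer: str
    strand: str
    start: int
    end: int
    pam: str
    cut_boundary: int
    rflp_hits: tuple[tuple[str, MotifHit], ...] = ()
    distance_from_cds_start: int = 0
    domain_overlap: bool = False

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if not self.pam.endswith("GG") or len(self.pam) != 3:
            raise ValueError(f"PAM must be 3 nt ending GG, got {self.pam!r}")
        if self.end - self.start != PROTOSPACER_LEN:
            raise ValueError("protospacer interval must span 20 nt")

    @property
    def is_rflp_compatible(self) -> bool:
        return len(self.rflp_hits) > 0

    @property
    def enzyme_names(self) -> tuple[str, ...]:
        return tuple(sorted({name for name, _ in self.rflp_hits}))


def enumerate_protospacers(
    seq: str, record: str = "seq", cds_start: int = 0
) -> list[GuideCandidate]:
    """Enumerate every SpCas9 protospacer (NGG PAM) on both strands.

    Plus strand: an NGG at ``[s+20, s+23)`` yields a guide at ``[s, s+20)``
    with cut boundary ``s + 17``.  Minus strand: a plus-strand ``CCN`` at
    ``[p, p+3)`` is the reverse complement of a PAM; the protospacer occupies
    ``[p+3, p+23)`` and the cut boundary is ``p + 6`` (3 bp from the
    PAM-proximal end).  Sequences shorter than 23 nt yield no candidates.

    ``distance_from_cds_start`` is the distance from ``cds_start`` to the
    PAM-distal end on the plus strand (plus-strand guides) or to the
    PAM-proximal end (minus-strand guides) — i.e. to the interval start in
    both cases.
    """
    seq = seq.upper()
    out: list[GuideCandidate] = []
    n = len(seq)
    if n < PROTOSPACER_LEN + 3:
        return out
    for s in range(n - 22):
        # plus strand: PAM = seq[s+20 : s+23], needs xGG
        if seq[s + 21 : s + 23] == "GG":
            out.append(
                GuideCandidate(
                    record=record,
                    protospacer=seq[s : s + 20],
                    strand="+",
                    start=s,
                    end=s + 20,
                    pam=seq[s + 20 : s + 23],
                    cut_boundary=s + CUT_FROM_START,
                    distance_from_cds_start=s - cds_start,
                )
            )
    for p in range(n - 22):
        # minus strand: plus-strand CCN at [p, p+3), protospacer [p+3, p+23)
        if seq[p : p + 2] == "CC":
            out.append(
                GuideCandidate(
                    record=record,
                    protospacer=_revcomp(seq[p + 3 : p + 23]),
                    strand="-",
                    start=p + 3,
                    end=p + 23,
                    pam=_revcomp(seq[p : p + 3]),
                    cut_boundary=p + 6,
                    distance_from_cds_start=p + 3 - cds_start,
                )
            )
    out.sort(key=lambda g: (g.start, 0 if g.strand == "+" else 1))
    return out


def attach_rflp_sites(
    candidates: Iterable[GuideCandidate], motif_hits: Iterable[MotifHit]
) -> list[GuideCandidate]:
    """Attach to each candidate every motif hit that crosses its cut boundary.

    A hit ``[a, b)`` crosses cut boundary ``c`` iff ``a < c < b`` — strictly,
    so at least one motif base lies on each side of the blunt cut and any
    indel at the cut disrupts the site.  Hits that merely abut the boundary
    (``a == c`` or ``b == c``) are not attached.  Candidates without any
    crossing hit are retained with empty ``rflp_hits``.
    """
    hits = list(motif_hits)
    out = []
    for cand in candidates:
        c = cand.cut_boundary
        crossing = tuple(
            (h.enzyme, h) for h in hits if h.start < c < h.end
        )
        out.append(replace(cand, rflp_hits=crossing))
    return out


def _overlaps(a: int, b: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(max(a, s) < min(b, e) for s, e in intervals)


def rank_candidates(
    candidates: Iterable[GuideCandidate],
    domain_intervals: Sequence[tuple[int, int]] | None = None,
) -> list[GuideCandidate]:
    """Order candidates by the design preference used in F0 screens.

    Sort keys, in priority order: RFLP-compatible first; overlapping a
    supplied functional-domain interval first (only when ``domain_intervals``
    is given); ascending distance from the CDS start (5'-most first, because
    early frameshifts are most likely to truncate the protein); ties broken
    by reference start, then strand ("+" first), for determinism.
    """
    if domain_intervals is not None:
        for s, e in domain_intervals:
            if e <= s:
                raise ValueError(f"malformed domain interval [{s}, {e})")
    ranked = []
    for cand in candidates:
        dom = (
            _overlaps(cand.start, cand.end, domain_intervals)
            if domain_intervals
            else False
        )
        ranked.append(replace(cand, domain_overlap=dom))
    ranked.sort(
        key=lambda g: (
            not g.is_rflp_compatible,
            not g.domain_overlap,
            g.distance_from_cds_start,
            g.start,
            0 if g.strand == "+" else 1,
        )
    )
    return ranked


def design_guides(
    seq: str,
    enzymes: Sequence[RestrictionEnzyme],
    record: str = "seq",
    domain_intervals: Sequence[tuple[int, int]] | None = None,
    rflp_only: bool = False,
) -> list[GuideCandidate]:
    """Full design pipeline: enumerate, attach RFLP sites, rank."""
    cands = enumerate_protospacers(seq, record=record)
    hits = scan_motifs(seq, enzymes)
    cands = attach_rflp_sites(cands, hits)
    cands = rank_candidates(cands, domain_intervals)
    if rflp_only:
        cands = [c for c in cands if c.is_rflp_compatible]
    return cands


def predict_digest(
    amplicon: str, enzyme: RestrictionEnzyme
) -> tuple[list[int], bool]:
    """Predict restriction-fragment lengths for an amplicon.

    Cuts the amplicon at the enzyme's top-strand cut position for every motif
    hit on either strand (minus-strand hits cut at ``end - cut_offset``),
    deduplicating coincident positions.  Returns fragment lengths sorted
    descending and a uniqueness flag that is true iff there is exactly one
    cut position — the clean two-band situation a gel reader wants.

    A cut position falling outside the amplicon (offset cutter near an edge)
    is reported uncut with a warning.  Fragment lengths always sum to the
    amplicon length.
    """
    amplicon = amplicon.upper()
    if len(amplicon) < len(enzyme.motif):
        raise ValueError("amplicon shorter than recognition motif")
    hits = scan_motifs(amplicon, [enzyme])
    positions: set[int] = set()
    for h in hits:
        pos = h.start + enzyme.cut_offset if h.strand == "+" else h.end - enzyme.cut_offset
        if 0 < pos < len(amplicon):
            positions.add(pos)
        else:
            warnings.warn(
                f"{enzyme.name} site at [{h.start}, {h.end}) cuts at {pos}, "
                "outside the amplicon; reported uncut",
                stacklevel=2,
            )
    cuts = sorted(positions)
    bounds = [0, *cuts, len(amplicon)]
    fragments = sorted(
        (b - a for a, b in zip(bounds, bounds[1:])), reverse=True
    )
    return fragments, len(cuts) == 1
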