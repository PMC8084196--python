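"""Restriction enzymes and degenerate-motif scanning.

A restriction enzyme is modelled as a named IUPAC recognition motif plus the
offset of the top-strand cut from the motif start.  Only the top-strand cut is
tracked: that is sufficient to predict restriction-fragment lengths on an
agarose gel, which is all the RFLP pre-screen needs.  Double-strand cut
geometry, methylation sensitivity and star activity are out of scope.

All coordinates are 0-based, half-open ``[start, end)`` on the supplied
reference sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "RestrictionEnzyme",
    "MotifHit",
    "iupac_match",
    "parse_enzyme_table",
    "default_catalog",
    "scan_motifs",
]

# IUPAC nucleotide ambiguity codes -> the set of concrete bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_MIN_MOTIF_LEN = 4


def _revcomp(seq: str) -> str:
    """Reverse complement; Biopython handles IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement())


def _contains_ngg_one_strand(motif: str) -> bool:
    # NGG fits at offset i iff position i matches anything and i+1, i+2 can be G.
    for i in range(len(motif) - 2):
        if "G" in IUPAC_CODES[motif[i + 1]] and "G" in IUPAC_CODES[motif[i + 2]]:
            return True
    return False


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition motif plus top-strand cut offset.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"XcmI"``.
    motif:
        IUPAC recognition sequence, length >= 4.
    cut_offset:
        Position of the top-strand cut in bases from the motif start.  May lie
        outside the motif for offset cutters (e.g. BsrI, ``ACTGG(1/-1)`` cuts
        one base 3' of its site, offset 6).
    notes:
        Free text carried through from the catalog.
    """

    name: str
    motif: str
    cut_offset: int
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) < _MIN_MOTIF_LEN:
            raise ValueError(
                f"enzyme {self.name!r}: motif {self.motif!r} shorter than "
                f"{_MIN_MOTIF_LEN} nt"
            )
        bad = sorted(set(self.motif) - set(IUPAC_CODES))
        if bad:
            raise ValueError(
                f"enzyme {self.name!r}: invalid IUPAC character(s) "
                f"{''.join(bad)!r} in motif {self.motif!r}"
            )

    @property
    def is_palindromic(self) -> bool:
        """True if the motif equals its own IUPAC reverse complement."""
        return self.motif == _revcomp(self.motif)

    @property
    def pam_compatible(self) -> bool:
        """True iff some concrete expansion of the motif contains NGG on
        either strand — such enzymes can host a SpCas9 PAM inside their
        recognition site, which is why they are favoured for RFLP designs."""
        return _contains_ngg_one_strand(self.motif) or _contains_ngg_one_strand(
            _revcomp(self.motif)
        )


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of an enzyme recognition motif on a reference."""

    enzyme: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid motif interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def iupac_match(motif: str, window: str) -> bool:
    """True iff each base of ``window`` is in the IUPAC class of the
    corresponding ``motif`` character.

    ``window`` must be concrete (A/C/G/T only) and the same length as
    ``motif``.
    """
    if len(motif) != len(window):
        raise ValueError(
            f"length mismatch: motif {len(motif)} nt vs window {len(window)} nt"
        )
    for m, b in zip(motif, window):
        cls = IUPAC_CODES.get(m)
        if cls is None:
            raise ValueError(f"invalid IUPAC code {m!r} in motif")
        if b not in cls:
            return False
    return True


class CatalogParseError(ValueError):
    """Raised for malformed enzyme catalog files; message names the line."""


def parse_enzyme_table(path: str | Path) -> list[RestrictionEnzyme]:
    """Parse a tab-separated enzyme catalog.

    The file must have a header row naming at least ``name``, ``motif`` and
    ``cut_offset`` (a ``notes`` column is optional); ``#`` lines are comments.
    Duplicate enzyme names and invalid IUPAC motifs are errors that name the
    offending line.
    """
    path = Path(path)
    enzymes: list[RestrictionEnzyme] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        rows = [
            (lineno, line)
            for lineno, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not rows:
        raise CatalogParseError(f"{path}: empty catalog")
    header = [h.strip().lower() for h in rows[0][1].rstrip("\n").split("\t")]
    required = ("name", "motif", "cut_offset")
    missing = [c for c in required if c not in header]
    if missing:
        raise CatalogParseError(
            f"{path}: header missing required column(s) {', '.join(missing)}"
        )
    idx = {c: header.index(c) for c in header}
    for lineno, line in rows[1:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(required):
            raise CatalogParseError(f"{path}:{lineno}: expected >=3 columns")
        name = fields[idx["name"]].strip()
        motif = fields[idx["motif"]].strip().upper()
        raw_offset = fields[idx["cut_offset"]].strip()
        try:
            cut_offset = int(raw_offset)
        except ValueError:
            raise CatalogParseError(
                f"{path}:{lineno}: cut_offset {raw_offset!r} is not an integer"
            ) from None
        notes = ""
        if "notes" in idx and len(fields) > idx["notes"]:
            notes = fields[idx["notes"]].strip()
        if name in seen:
            raise CatalogParseError(f"{path}:{lineno}: duplicate enzyme name {name!r}")
        try:
            enz = RestrictionEnzyme(name, motif, cut_offset, notes)
        except ValueError as exc:
            raise CatalogParseError(f"{path}:{lineno}: {exc}") from None
        seen.add(name)
        enzymes.append(enz)
    return enzymes


def default_catalog() -> list[RestrictionEnzyme]:
    """The catalog shipped with the package.

    Contains the six enzymes most used for RFLP pre-screening (BslI, XcmI,
    BstXI, MwoI, BsrI, BstNI) with REBASE-standard motifs and cut offsets.
    Catalog contents are reference data: users can extend or correct them by
    supplying their own table to :func:`parse_enzyme_table`.
    """
    with resources.as_file(
        resources.files("crisprflp").joinpath("data/enzymes.tsv")
    ) as p:
        return parse_enzyme_table(p)


def scan_motifs(
    seq: str,
    enzymes: Iterable[RestrictionEnzyme],
    *,
    ambiguous: str = "error",
) -> list[MotifHit]:
    """Scan ``seq`` for recognition-motif occurrences on both strands.

    Every offset on both strands is tested.  Palindromic motifs describe one
    physical site, so they are reported once per location with strand ``"+"``.
    Hits are sorted by start, then end, enzyme and strand.

    ``ambiguous`` controls how non-ACGT bases in ``seq`` are handled:
    ``"error"`` (default — design targets should be unambiguous) or ``"skip"``
    (windows containing such bases simply never match).
    """
    if ambiguous not in ("error", "skip"):
        raise ValueError("ambiguous must be 'error' or 'skip'")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad and ambiguous == "error":
        raise ValueError(
            f"sequence contains ambiguous base(s) {''.join(sorted(bad))!r}; "
            "pass ambiguous='skip' to ignore windows containing them"
        )
    hits: list[MotifHit] = []
    for enz in enzymes:
        m = len(enz.motif)
        rc_motif = _revcomp(enz.motif)
        palindromic = enz.is_palindromic
        for s in range(len(seq) - m + 1):
            window = seq[s : s + m]
            if bad and set(window) - set("ACGT"):
                continue
            if iupac_match(enz.motif, window):
                hits.append(MotifHit(enz.name, s, s + m, "+"))
            # A minus-strand occurrence at [s, s+m) means the window matches
            # the reverse-complemented motif on the plus strand.
            if not palindromic and iupac_match(rc_motif, window):
                hits.append(MotifHit(enz.name, s, s + m, "-"))
    hits.sort(key=lambda h: (h.start, h.end, h.enzyme, h.strand))
    return hits


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Write motif hits as TSV (enzyme, start, end, strand)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["enzyme", "start", "end", "strand"])
        for h in hits:
            w.writerow([h.enzyme, h.start, h.end, h.strand])
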