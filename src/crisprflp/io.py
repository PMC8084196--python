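"""File readers and writers for the toolkit's plain-text dialects.

FASTA via Biopython; guide tables and screen reports as TSV; gel lanes and
screen counts as CSV.  Readers validate against the domain-type invariants
at load time and name the offending row in errors.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .rflp import ActivityEstimate, LaneMeasurement
from .screen import ScreenArm
from .scoring import WeightTable

__all__ = [
    "read_fasta",
    "read_bed_intervals",
    "read_lane_csv",
    "read_screen_csv",
    "read_weight_table",
    "write_guides_tsv",
    "write_estimates_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA records into an id -> uppercase-sequence mapping.

    Lowercase bases are uppercased with a warning; duplicate record ids are
    an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{path}: lowercase bases in {rec.id!r} uppercased",
                          stacklevel=2)
            seq = seq.upper()
        records[rec.id] = seq
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read BED (0-based half-open) into chrom -> [(start, end), ...]."""
    out: dict[str, list[tuple[int, int]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: malformed interval [{start}, {end})")
            out.setdefault(chrom, []).append((start, end))
    return out


def _parse_bands(raw: str) -> tuple[float, ...]:
    raw = raw.strip()
    if not raw:
        return ()
    return tuple(float(x) for x in raw.split(";"))


def read_lane_csv(
    path: str | Path, clamp_negative: bool = False
) -> list[LaneMeasurement]:
    """Read a gel-lane CSV: guide_id, embryo_id, is_control, undigested,
    digested (semicolon-separated), other (optional).

    Negative intensities are a load-time validation error naming the row,
    unless ``clamp_negative`` is set, in which case they are clamped to 0
    with a warning (for upstream background subtraction that overshoots).
    """
    lanes = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"guide_id", "embryo_id", "is_control", "undigested", "digested"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            if any(row.get(k) is None for k in required):
                raise ValueError(f"{path}: row {rownum}: ragged row")
            try:
                undig = float(row["undigested"])
                digested = _parse_bands(row["digested"])
                other = _parse_bands(row.get("other") or "")
            except ValueError:
                raise ValueError(
                    f"{path}: row {rownum}: non-numeric intensity"
                ) from None
            values = (undig, *digested, *other)
            if any(v < 0 for v in values):
                if clamp_negative:
                    warnings.warn(
                        f"{path}: row {rownum}: negative intensity clamped to 0",
                        stacklevel=2,
                    )
                    undig = max(0.0, undig)
                    digested = tuple(max(0.0, v) for v in digested)
                    other = tuple(max(0.0, v) for v in other)
                else:
                    raise ValueError(
                        f"{path}: row {rownum}: negative intensity"
                    )
            lanes.append(
                LaneMeasurement(
                    guide_id=row["guide_id"].strip(),
                    embryo_id=row["embryo_id"].strip(),
                    is_control=row["is_control"].strip().lower()
                    in ("1", "true", "yes"),
                    undigested_intensity=undig,
                    digested_intensities=digested,
                    other_intensities=other,
                )
            )
    if not lanes:
        raise ValueError(f"{path}: no lanes")
    return lanes


def write_lane_csv(lanes: Sequence[LaneMeasurement], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["guide_id", "embryo_id", "is_control", "undigested",
                    "digested", "other"])
        for ln in lanes:
            w.writerow([
                ln.guide_id,
                ln.embryo_id,
                int(ln.is_control),
                f"{ln.undigested_intensity:.6g}",
                ";".join(f"{v:.6g}" for v in ln.digested_intensities),
                ";".join(f"{v:.6g}" for v in ln.other_intensities),
            ])


def read_screen_csv(path: str | Path) -> list[ScreenArm]:
    """Read a screen count CSV: arm, timepoint, n_total, n_bridged,
    control_total, control_bridged."""
    df = pd.read_csv(path)
    required = ["arm", "timepoint", "n_total", "n_bridged",
                "control_total", "control_bridged"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    arms = []
    for i, row in df.iterrows():
        try:
            arms.append(
                ScreenArm(
                    arm=str(row["arm"]),
                    timepoint=int(row["timepoint"]),
                    n_total=int(row["n_total"]),
                    n_bridged=int(row["n_bridged"]),
                    control_total=int(row["control_total"]),
                    control_bridged=int(row["control_bridged"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from None
    return arms


def read_weight_table(path: str | Path) -> WeightTable:
    """Read a scorer weight table: TSV with columns position, kmer, weight.

    Rows with kmer ``GC`` are GC-count terms (position = GC count).
    """
    kmer_weights: dict[tuple[int, str], float] = {}
    gc_weights: dict[int, float] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "position":
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            pos, kmer, weight = int(fields[0]), fields[1].upper(), float(fields[2])
            if kmer == "GC":
                gc_weights[pos] = weight
            else:
                kmer_weights[(pos, kmer)] = weight
    return WeightTable(kmer_weights=kmer_weights, gc_weights=gc_weights)


def write_guides_tsv(candidates, path: str | Path) -> None:
    """Write ranked guide candidates as TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["record", "start", "end", "strand", "protospacer", "pam",
                    "cut_boundary", "enzymes", "distance_from_cds_start",
                    "domain_overlap", "rank"])
        for rank, c in enumerate(candidates, start=1):
            w.writerow([
                c.record, c.start, c.end, c.strand, c.protospacer, c.pam,
                c.cut_boundary, ",".join(c.enzyme_names) or ".",
                c.distance_from_cds_start, int(c.domain_overlap), rank,
            ])


def write_estimates_tsv(
    estimates: Sequence[ActivityEstimate], path: str | Path
) -> None:
    """Write per-guide estimates as TSV; per-embryo values kept alongside."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["guide_id", "aggregate", "is_hacr", "qc_pass",
                    "n_injected", "n_controls", "per_embryo"])
        for e in estimates:
            w.writerow([
                e.guide_id, f"{e.aggregate:.4f}", int(e.is_hacr),
                int(e.qc_pass), len(e.per_embryo), e.n_controls,
                ";".join(f"{v:.4f}" for v in e.per_embryo),
            ])
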