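"""Genome and interval I/O: FASTA/BED reading, masking, and segment extraction.

Enhancer annotations arrive as BED intervals over a reference genome (e.g.
ChromHMM "strong enhancer" chromatin-state calls).  Before any sequence is
used, exons and repeats are masked to 'N' so they never contribute k-mers or
background windows.  Annotated intervals are then tiled into fixed-length
cores (default 200 bp, roughly one nucleosome plus spacer) with short flanks
on each side so that k-mers can later be centered on every core position.

Coordinates are BED-style throughout: 0-based, half-open.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: ChromHMM (Broad 15-state model) states treated as enhancers.
STRONG_ENHANCER_STATES = frozenset({"4_Strong_Enhancer", "5_Strong_Enhancer"})

_VALID_BASES = frozenset("ACGT")
# after uppercasing, send every IUPAC ambiguity code (R, Y, S, ...) to 'N'
_NORMALIZE = {c: (c if chr(c) in _VALID_BASES else ord("N"))
              for c in range(ord("A"), ord("Z") + 1)}


class BedParseError(ValueError):
    """A BED record could not be parsed; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class MaskedGenome:
    """Per-chromosome sequences over {A,C,G,T,N} with a record of applied masks.

    ``provenance`` lists the names of mask sets applied so far; masked
    positions are exactly 'N'.  Sequence lengths never change.
    """

    sequences: dict[str, str]
    provenance: list[str] = field(default_factory=list)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


def read_fasta(path: str | Path) -> MaskedGenome:
    """Load a (multi-record, wrapped or unwrapped) FASTA file.

    Sequences are uppercased and every ambiguity code other than N
    (R, Y, S, W, ...) is normalized to 'N'.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().translate(_NORMALIZE)
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return MaskedGenome(sequences=sequences)


def write_fasta(genome: MaskedGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 records in file order.

    The optional 4th column is stored as the interval label.  Malformed
    records (fewer than 3 columns, non-integer coordinates, start >= end)
    raise :class:`BedParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path} line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            label = fields[3] if len(fields) >= 4 else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, label))
            except ValueError as exc:
                raise BedParseError(f"{path} line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def filter_states(
    intervals: Sequence[GenomicInterval],
    state_names: Iterable[str] = STRONG_ENHANCER_STATES,
) -> list[GenomicInterval]:
    """Keep intervals whose label is one of ``state_names``, preserving order."""
    names = set(state_names)
    return [iv for iv in intervals if iv.label in names]


def mask_regions(
    genome: MaskedGenome,
    masks: Sequence[GenomicInterval],
    name: str = "mask",
) -> MaskedGenome:
    """Return a new genome with every base covered by ``masks`` set to 'N'.

    Out-of-bounds mask portions are clipped; masks on unknown chromosomes are
    skipped with a warning.  Idempotent, and masking with two sets in either
    order equals masking with their union.
    """
    buffers = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    for iv in masks:
        buf = buffers.get(iv.chrom)
        if buf is None:
            logger.warning("mask interval on unknown chromosome %s skipped", iv.chrom)
            continue
        lo, hi = max(0, iv.start), min(len(buf), iv.end)
        if lo < hi:
            buf[lo:hi] = b"N" * (hi - lo)
    return MaskedGenome(
        sequences={c: b.decode("ascii") for c, b in buffers.items()},
        provenance=genome.provenance + [name],
    )


@dataclass(frozen=True)
class EnhancerSegment:
    """A fixed-length core sequence with flanks and genomic provenance.

    The core is pure {A,C,G,T}; flanks may contain 'N' (their k-mers fall back
    to the dictionary default during featurization).
    """

    core: str
    left_flank: str
    right_flank: str
    origin: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.left_flank) != len(self.right_flank):
            raise ValueError("left and right flanks must have equal length")
        if not _VALID_BASES.issuperset(self.core):
            raise ValueError("segment core must contain only A/C/G/T")

    @property
    def flank(self) -> int:
        return len(self.left_flank)

    @property
    def with_flanks(self) -> str:
        return self.left_flank + self.core + self.right_flank

    @property
    def segment_id(self) -> str:
        return f"{self.origin.chrom}:{self.origin.start}-{self.origin.end}"


def _core_is_clean(seq: str) -> bool:
    return _VALID_BASES.issuperset(seq)


def extract_segments(
    intervals: Sequence[GenomicInterval],
    genome: MaskedGenome,
    L: int = 200,
    F: int = 5,
) -> list[EnhancerSegment]:
    """Tile intervals into non-overlapping length-L cores with length-F flanks.

    Each interval is tiled left-to-right into floor(length/L) cores; the
    trailing remainder is discarded.  A segment is dropped when its core
    contains a non-ACGT character (masked or ambiguous bases) or its flanks
    would run off the chromosome; flanks themselves may contain 'N'.  Kept and
    filtered counts are logged.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if F < 0:
        raise ValueError("F must be >= 0")
    kept: list[EnhancerSegment] = []
    n_tiles = 0
    for iv in intervals:
        seq = genome.sequences.get(iv.chrom)
        if seq is None:
            logger.warning("interval on unknown chromosome %s skipped", iv.chrom)
            continue
        for tile_start in range(iv.start, iv.end - L + 1, L):
            n_tiles += 1
            core = seq[tile_start:tile_start + L]
            if not _core_is_clean(core):
                continue
            if tile_start - F < 0 or tile_start + L + F > len(seq):
                continue
            kept.append(EnhancerSegment(
                core=core,
                left_flank=seq[tile_start - F:tile_start],
                right_flank=seq[tile_start + L:tile_start + L + F],
                origin=GenomicInterval(iv.chrom, tile_start, tile_start + L,
                                       iv.label),
            ))
    logger.info("extract_segments: %d tiles -> %d kept, %d filtered",
                n_tiles, len(kept), n_tiles - len(kept))
    return kept


def write_segments(
    segments: Sequence[EnhancerSegment],
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
) -> None:
    """Write segment cores as FASTA ("chrom:start-end" headers) plus a sidecar
    BED of the kept cores."""
    with open(fasta_path, "w") as fh:
        for seg in segments:
            fh.write(f">{seg.segment_id}\n{seg.core}\n")
    if bed_path is not None:
        write_bed([s.origin for s in segments], bed_path)


def segment_label_counts(segments: Sequence[EnhancerSegment]) -> dict[str, int]:
    """Kept-segment counts per origin label (for per-cell-type logging)."""
    return dict(Counter(s.origin.label or "" for s in segments))
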