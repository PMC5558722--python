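"""Reference sequences for transgene-insertion analysis.

Holds the host genome, the circular transformation plasmid, the T-DNA
interval annotation, and the *linearized* plasmid reference used for read
mapping.  Because the transformation vector is a circle, reads crossing the
arbitrary cut point would otherwise be lost; the linearized reference
therefore appends a configurable wrap (default 150 bp, one read length) of
the opposite end of the plasmid to each side, and this module provides the
bijective mapping from linearized back to circular coordinates.

All externally visible coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

_VALID_RE = re.compile(r"^[ACGTN]*$")


def _normalize_sequence(seq: str, name: str) -> str:
    """Upper-case a nucleotide string, rejecting non-ACGTN characters.

    Ambiguity codes other than N are rejected outright rather than being
    coerced, so that a malformed reference fails loudly at load time.
    """
    s = str(seq).upper()
    if not s:
        raise ValueError(f"sequence {name!r} is empty")
    if not _VALID_RE.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(
            f"sequence {name!r} contains unsupported characters {bad}; "
            "only A/C/G/T/N are accepted"
        )
    return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class HostGenome:
    """A haploid host chromosome set (diploidy is ignored throughout)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {
            name: _normalize_sequence(seq, name) for name, seq in self.sequences.items()
        }

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @classmethod
    def from_fasta(cls, path) -> "HostGenome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


@dataclass
class CircularPlasmid:
    """The circular transformation plasmid (T-DNA plus vector backbone)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = _normalize_sequence(self.sequence, self.name)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(cls, path) -> "CircularPlasmid":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"plasmid FASTA {path} must contain exactly one record, found {len(records)}"
            )
        return cls(records[0].id, str(records[0].seq))


@dataclass
class TDNARegion:
    """T-DNA interval on the *linearized* reference, 1-based inclusive.

    ``lb_position`` / ``rb_position`` name which boundary is the left and
    which the right border repeat; they must coincide with start/end.
    """

    start: int
    end: int
    lb_position: int = 0
    rb_position: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"T-DNA start {self.start} must be < end {self.end}")
        if self.lb_position == 0 and self.rb_position == 0:
            self.lb_position = self.start
            self.rb_position = self.end
        if {self.lb_position, self.rb_position} != {self.start, self.end}:
            raise ValueError("lb_position/rb_position must coincide with start/end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def side_of_boundary(self, pos: int) -> str:
        if pos == self.lb_position:
            return "LB"
        if pos == self.rb_position:
            return "RB"
        raise ValueError(f"{pos} is not a T-DNA boundary")

    @classmethod
    def from_bed_line(cls, line: str) -> "TDNARegion":
        """Parse a single BED record (0-based half-open) into 1-based inclusive."""
        parts = line.strip().split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED line: {line!r}")
        return cls(start=int(parts[1]) + 1, end=int(parts[2]))


@dataclass
class LinearizedReference:
    """Circular plasmid opened into a linear mapping reference.

    Layout: ``[wrap of last wrap_length bases][full plasmid][wrap of first
    wrap_length bases]`` so that every read crossing the circle's cut point
    aligns contiguously somewhere.
    """

    sequence: str
    wrap_length: int
    source: CircularPlasmid
    name: str = field(default="")

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.source.name}_linearized"

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def body_start(self) -> int:
        """1-based first position of the plasmid body (after the left wrap)."""
        return self.wrap_length + 1

    @property
    def body_end(self) -> int:
        return self.wrap_length + self.source.length

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i : i + 80] + "\n")


def linearize_plasmid(plasmid: CircularPlasmid, wrap_length: int = 150) -> LinearizedReference:
    """Open a circular plasmid into a linear reference with opposite-end wraps.

    Each end receives ``wrap_length`` bases copied from the opposite end of
    the circle, so alignments may cross the cut point.  ``wrap_length``
    should be at least the read length minus the smallest clip of interest.
    """
    if wrap_length < 0 or wrap_length >= plasmid.length:
        raise ValueError(
            f"wrap_length must satisfy 0 <= wrap < plasmid length "
            f"({plasmid.length}), got {wrap_length}"
        )
    seq = plasmid.sequence
    lin = seq[-wrap_length:] + seq + seq[:wrap_length] if wrap_length else seq
    return LinearizedReference(sequence=lin, wrap_length=wrap_length, source=plasmid)


def to_circular_coord(lin_pos: int, ref: LinearizedReference) -> int:
    """Map a 1-based linearized position back to the 1-based circular coordinate."""
    if lin_pos < 1 or lin_pos > len(ref.sequence):
        raise ValueError(
            f"linearized position {lin_pos} out of range 1..{len(ref.sequence)}"
        )
    L = ref.source.length
    # shift into the body, then wrap modulo the circle
    return (lin_pos - ref.wrap_length - 1) % L + 1


def backbone_intervals(ref: LinearizedReference, tdna: TDNARegion) -> list[tuple[int, int]]:
    """Maximal plasmid-body intervals outside the T-DNA region.

    Wrap duplicates are excluded so every backbone base appears exactly once.
    Raises if the annotated T-DNA does not lie inside the body.
    """
    if tdna.start < ref.body_start or tdna.end > ref.body_end:
        raise ValueError(
            f"T-DNA {tdna.start}..{tdna.end} outside linearized body "
            f"{ref.body_start}..{ref.body_end}"
        )
    out = []
    if tdna.start > ref.body_start:
        out.append((ref.body_start, tdna.start - 1))
    if tdna.end < ref.body_end:
        out.append((tdna.end + 1, ref.body_end))
    return out
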