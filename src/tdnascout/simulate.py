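"""Synthetic transgenic genomes and Illumina-like paired-end libraries.

The generator builds a haploid host chromosome set carrying a T-DNA
insertion with a configurable target-site deletion, orientation, tandem
copy number, optional vector-backbone carry-over and optional internal
rearrangement, then draws paired-end reads (150 bp mates, ~500 bp
fragments by default, i.i.d. substitution errors) from it.  A ground-truth
manifest records every insertion so downstream detection can be scored as
a parameter-recovery problem.  Read names encode the source fragment
coordinates, giving tests a per-read provenance oracle.

Deletion convention: ``deletion = right_flank_start - left_flank_end``,
i.e. the difference between the last retained host base before the insert
and the first retained base after it; the number of physically removed
bases is ``deletion - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .align_io import ReadPair
from .reference_model import (
    CircularPlasmid,
    HostGenome,
    LinearizedReference,
    TDNARegion,
    reverse_complement,
)


@dataclass
class Rearrangement:
    """Internal T-DNA rearrangement descriptor, coordinates 1-based on the T-DNA."""

    kind: str  # "inverted-segment" | "duplicated-segment"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("inverted-segment", "duplicated-segment"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if not 1 <= self.start < self.end:
            raise ValueError("rearrangement needs 1 <= start < end")

    def apply(self, seq: str) -> str:
        if self.end > len(seq):
            raise ValueError("rearrangement interval exceeds T-DNA length")
        a, b = self.start - 1, self.end
        if self.kind == "inverted-segment":
            return seq[:a] + reverse_complement(seq[a:b]) + seq[b:]
        return seq[:a] + seq[a:b] + seq[a:b] + seq[b:]

    def to_string(self) -> str:
        return f"{self.kind}:{self.start}-{self.end}"

    @classmethod
    def from_string(cls, s: str) -> "Rearrangement | None":
        if not s or s == "none":
            return None
        kind, span = s.split(":")
        a, b = span.split("-")
        return cls(kind, int(a), int(b))


@dataclass
class InsertionGroundTruth:
    """One simulated integration event (a single locus).

    ``left_flank_end`` is the last retained host base before the insertion,
    ``right_flank_start`` the first retained base after it (both 1-based);
    host bases strictly between them are deleted.
    """

    chromosome: str
    left_flank_end: int
    right_flank_start: int
    orientation: str = "forward"  # "forward" | "reverse"
    copies: int = 1
    backbone_included: bool = False
    internal_rearrangement: Rearrangement | None = None

    def __post_init__(self) -> None:
        if self.right_flank_start <= self.left_flank_end:
            raise ValueError("right_flank_start must exceed left_flank_end")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")

    @property
    def deletion(self) -> int:
        return self.right_flank_start - self.left_flank_end

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "left_flank_end": self.left_flank_end,
            "right_flank_start": self.right_flank_start,
            "deletion": self.deletion,
            "orientation": self.orientation,
            "copies": self.copies,
            "backbone_included": self.backbone_included,
            "internal_rearrangement": (
                self.internal_rearrangement.to_string() if self.internal_rearrangement else "none"
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InsertionGroundTruth":
        return cls(
            chromosome=d["chromosome"],
            left_flank_end=int(d["left_flank_end"]),
            right_flank_start=int(d["right_flank_start"]),
            orientation=d["orientation"],
            copies=int(d["copies"]),
            backbone_included=bool(d["backbone_included"]),
            internal_rearrangement=Rearrangement.from_string(d.get("internal_rearrangement", "none")),
        )


@dataclass
class ReadLibraryParams:
    """Illumina-like library parameters (150 bp mates, ~500 bp fragments)."""

    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    per_base_error: float = 0.0
    coverage: float = 30.0
    seed: int = 0
    base_quality: int = 35
    low_quality_pair_rate: float = 0.0  # pairs given mean Phred < 20 (exercises QC)
    duplicate_pair_rate: float = 0.0  # exact duplicate pairs appended (exercises dedup)

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if not 0 <= self.per_base_error < 0.1:
            raise ValueError("per_base_error must be in [0, 0.1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def make_insert_sequence(
    ref: LinearizedReference,
    tdna: TDNARegion,
    truth: InsertionGroundTruth,
    backbone_extra: int = 1000,
) -> str:
    """Assemble the inserted sequence for one event from the vector.

    Starts from the annotated T-DNA interval of the linearized vector,
    applies any internal rearrangement, tandem-repeats it ``copies`` times,
    optionally appends backbone sequence beyond the right border (vector
    carry-over), and reverse-complements the whole insert for reverse
    orientation.
    """
    seq = ref.sequence[tdna.start - 1 : tdna.end]
    if truth.internal_rearrangement is not None:
        seq = truth.internal_rearrangement.apply(seq)
    insert = seq * truth.copies
    if truth.backbone_included:
        tail = ref.sequence[tdna.end : tdna.end + backbone_extra]
        insert = insert + tail
    if truth.orientation == "reverse":
        insert = reverse_complement(insert)
    return insert


def build_transgenic_genome(
    host: HostGenome, tdna_sequence: str, truth: InsertionGroundTruth
) -> HostGenome:
    """Insert a (possibly rearranged/multi-copy) T-DNA sequence into the host.

    Host bases strictly between ``left_flank_end`` and ``right_flank_start``
    are replaced by the insert; the insert is reverse-complemented for
    reverse orientation.  Other chromosomes are untouched.
    """
    if not tdna_sequence:
        raise ValueError("empty T-DNA sequence")
    if truth.chromosome not in host.sequences:
        raise ValueError(f"chromosome {truth.chromosome!r} not in host genome")
    chrom = host.sequences[truth.chromosome]
    if truth.left_flank_end < 1 or truth.right_flank_start > len(chrom):
        raise ValueError("insertion coordinates out of chromosome range")
    if truth.internal_rearrangement is not None:
        tdna_sequence = truth.internal_rearrangement.apply(tdna_sequence)
    insert = tdna_sequence * truth.copies
    if truth.orientation == "reverse":
        insert = reverse_complement(insert)
    new_chrom = chrom[: truth.left_flank_end] + insert + chrom[truth.right_flank_start - 1 :]
    sequences = dict(host.sequences)
    sequences[truth.chromosome] = new_chrom
    return HostGenome(sequences)


def build_event_genome(
    host: HostGenome,
    ref: LinearizedReference,
    tdna: TDNARegion,
    truths: list[InsertionGroundTruth],
    backbone_extra: int = 1000,
) -> HostGenome:
    """Apply one or more insertion events; at most one event per chromosome."""
    chroms = [t.chromosome for t in truths]
    if len(set(chroms)) != len(chroms):
        raise ValueError("multi-locus simulation requires distinct chromosomes")
    genome = host
    for truth in truths:
        # orientation/copies are applied inside make_insert_sequence, so pass
        # a pre-oriented single-copy view to the generic inserter
        insert = make_insert_sequence(ref, tdna, truth, backbone_extra=backbone_extra)
        flat = InsertionGroundTruth(
            chromosome=truth.chromosome,
            left_flank_end=truth.left_flank_end,
            right_flank_start=truth.right_flank_start,
            orientation="forward",
            copies=1,
        )
        genome = build_transgenic_genome(genome, insert, flat)
    return genome


_ERROR_SUBS = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        chars[pos] = _ERROR_SUBS[chars[pos]][rng.integers(3)]
    return "".join(chars)


def simulate_paired_reads(genome: HostGenome, params: ReadLibraryParams) -> list[ReadPair]:
    """Draw an Illumina-like paired-end library from a genome.

    Fragments: start uniform on each chromosome, length normal(insert_mean,
    insert_sd) truncated below at read_length.  Mate 1 is the fragment's 5'
    end, mate 2 the reverse complement of its 3' end.  Read names encode
    chromosome and 1-based fragment coordinates (the provenance oracle).
    Identical seeds give byte-identical libraries.
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    rng = np.random.default_rng(params.seed)
    L = params.read_length
    qual = chr(params.base_quality + 33) * L
    lowqual = chr(10 + 33) * L  # mean Phred 10, fails the >= 20 filter
    pairs: list[ReadPair] = []
    serial = 0
    for name, seq in genome.sequences.items():
        if len(seq) < params.insert_mean:
            import warnings

            warnings.warn(f"chromosome {name} shorter than mean insert; skipped")
            continue
        n_pairs = int(round(params.coverage * len(seq) / (2 * L)))
        frag_lens = rng.normal(params.insert_mean, params.insert_sd, n_pairs)
        frag_lens = np.maximum(frag_lens, L).round().astype(np.int64)
        frag_lens = np.minimum(frag_lens, len(seq))
        starts = (rng.random(n_pairs) * (len(seq) - frag_lens + 1)).astype(np.int64)
        err = params.per_base_error
        for s, fl in zip(starts.tolist(), frag_lens.tolist()):
            frag = seq[s : s + fl]
            m1 = frag[:L]
            m2 = reverse_complement(frag[-L:])
            if err:
                m1 = _apply_errors(m1, rng, err)
                m2 = _apply_errors(m2, rng, err)
            serial += 1
            pairs.append(ReadPair(f"sim.{name}.{s + 1}.{s + fl}.{serial}", m1, qual, m2, qual))
    if params.low_quality_pair_rate > 0 and pairs:
        flags = rng.random(len(pairs)) < params.low_quality_pair_rate
        for i in np.flatnonzero(flags):
            p = pairs[i]
            pairs[i] = ReadPair(p.id + ".lowq", p.seq1, lowqual, p.seq2, p.qual2)
    if params.duplicate_pair_rate > 0 and pairs:
        n_dup = int(round(params.duplicate_pair_rate * len(pairs)))
        picks = rng.integers(0, len(pairs), n_dup)
        for i in picks:
            p = pairs[i]
            serial += 1
            pairs.append(ReadPair(p.id + f".dup{serial}", p.seq1, p.qual1, p.seq2, p.qual2))
    return pairs


def read_origin(read_id: str) -> tuple[str, int, int] | None:
    """Decode (chromosome, fragment_start, fragment_end) from a simulated read name."""
    if not read_id.startswith("sim."):
        return None
    parts = read_id.split(".")
    return parts[1], int(parts[2]), int(parts[3])


def write_manifest(truths: list[InsertionGroundTruth], path) -> None:
    """Write the ground-truth manifest (JSON; lossless round trip)."""
    payload = {"insertions": [t.to_dict() for t in truths]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> list[InsertionGroundTruth]:
    with open(path) as fh:
        payload = json.load(fh)
    return [InsertionGroundTruth.from_dict(d) for d in payload["insertions"]]


def random_host_genome(
    lengths: dict[str, int], seed: int, gc: float = 0.44
) -> HostGenome:
    """Random host chromosomes with roughly rice-like GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name, n in lengths.items():
        codes = rng.choice(alphabet, size=n, p=p)
        seqs[name] = codes.tobytes().decode("ascii")
    return HostGenome(seqs)


def random_plasmid(length: int, seed: int, name: str = "pVEC") -> CircularPlasmid:
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return CircularPlasmid(name, rng.choice(alphabet, size=length).tobytes().decode("ascii"))
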