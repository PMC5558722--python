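"""Read QC, an internal local aligner, and alignment-evidence I/O.

The pipeline accepts either raw FASTQ (aligned with the internal
seed-and-extend Smith-Waterman aligner) or SAM produced by an external
aligner such as BWA-MEM; both paths yield the same
:class:`AlignmentRecord` stream for the downstream classification and
junction-calling stages.

The internal aligner is a conventional seed-and-extend design: exact
k-mer seeds (seed length mirrors BWA-MEM's ``-k``), candidate diagonals
grouped within the band width, then an affine-gap Smith-Waterman
extension over a window around each diagonal.  On references short
enough for full dynamic programming the full matrix is used, so scores
on small instances equal the textbook Smith-Waterman optimum.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numba as nb
import numpy as np
import pysam

from .reference_model import reverse_complement

# ---------------------------------------------------------------------------
# read containers and QC
# ---------------------------------------------------------------------------

PHRED_OFFSET = 33  # Phred+33 only; Phred+64 input is rejected, never auto-detected


@dataclass
class ReadPair:
    """One paired-end fragment: two mates with Phred+33 quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"read pair {self.id}: empty mate sequence")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read pair {self.id}: quality length != sequence length")


def _mean_phred(qual: str, read_name: str, _cache: dict = {}) -> float:
    cached = _cache.get(qual)
    if cached is not None:
        return cached
    total = 0
    for ch in qual:
        code = ord(ch) - PHRED_OFFSET
        if code < 0 or code > 93:
            raise ValueError(
                f"read {read_name}: quality character {ch!r} not decodable as Phred+33"
            )
        total += code
    mean = total / len(qual)
    if len(_cache) < 100_000:
        _cache[qual] = mean
    return mean


def quality_filter(
    pairs: list[ReadPair], min_mean_phred: float = 20.0
) -> tuple[list[ReadPair], dict]:
    """Whole-read quality filter: keep a pair only if BOTH mates have mean Phred >= threshold.

    Returns the retained pairs and a stats dict with read and base counts
    before/after, mirroring a sequencing-summary table.
    """
    retained: list[ReadPair] = []
    raw_bases = 0
    kept_bases = 0
    for p in pairs:
        raw_bases += len(p.seq1) + len(p.seq2)
        if (
            _mean_phred(p.qual1, p.id) >= min_mean_phred
            and _mean_phred(p.qual2, p.id) >= min_mean_phred
        ):
            retained.append(p)
            kept_bases += len(p.seq1) + len(p.seq2)
    stats = {
        "raw_reads": 2 * len(pairs),
        "raw_bases": raw_bases,
        "retained_reads": 2 * len(retained),
        "retained_bases": kept_bases,
        "removed_pairs": len(pairs) - len(retained),
    }
    return retained, stats


def remove_duplicates(pairs: list[ReadPair]) -> tuple[list[ReadPair], dict]:
    """Drop exact sequence duplicates, keeping the first-seen pair of each class."""
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    for p in pairs:
        key = (p.seq1, p.seq2)
        if key in seen:
            continue
        seen.add(key)
        kept.append(p)
    stats = {
        "input_pairs": len(pairs),
        "retained_pairs": len(kept),
        "removed_pairs": len(pairs) - len(kept),
        "retained_reads": 2 * len(kept),
        "retained_bases": sum(len(p.seq1) + len(p.seq2) for p in kept),
    }
    return kept, stats


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load paired FASTQ (optionally gzipped) into memory."""
    pairs = []
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in zip(f1, f2):
            name = r1.name.removesuffix("/1")
            pairs.append(ReadPair(name, r1.sequence, r1.quality, r2.sequence, r2.quality))
    return pairs


def write_fastq_pairs(pairs: list[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


@dataclass
class AlignmentRecord:
    """One read placement on a reference.

    ``segments`` lists (op, length) along the reference-oriented read, op in
    {"clip", "match"}; lengths sum to the read length.  Small insertions are
    folded into the match segment (read-base accounting), so ``ref_end`` is
    carried explicitly rather than derived.
    """

    read_id: str
    mate: int
    reference_name: str
    ref_start: int  # 1-based inclusive; 0 when unmapped
    ref_end: int
    strand: str  # "+" or "-"
    segments: list[tuple[str, int]]
    identity: float
    score: int
    mapped: bool
    seq: str = ""  # reference-oriented read sequence
    mate_ref: str | None = None
    mate_start: int | None = None
    is_secondary: bool = False

    @property
    def clip_left(self) -> int:
        if self.segments and self.segments[0][0] == "clip":
            return self.segments[0][1]
        return 0

    @property
    def clip_right(self) -> int:
        if self.segments and self.segments[-1][0] == "clip":
            return self.segments[-1][1]
        return 0

    @property
    def match_length(self) -> int:
        return sum(n for op, n in self.segments if op == "match")

    @property
    def read_length(self) -> int:
        return sum(n for _, n in self.segments) if self.segments else len(self.seq)

    def overlaps(self, start: int, end: int) -> bool:
        return self.mapped and self.ref_start <= end and self.ref_end >= start

    @property
    def full_id(self) -> str:
        return f"{self.read_id}/{self.mate}"


def unmapped_record(read_id: str, mate: int, seq: str) -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        reference_name="*",
        ref_start=0,
        ref_end=0,
        strand="+",
        segments=[],
        identity=0.0,
        score=0,
        mapped=False,
        seq=seq,
    )


def read_external_alignments(sam_path) -> list[AlignmentRecord]:
    """Ingest SAM from an external aligner (e.g. BWA-MEM) into AlignmentRecords.

    Soft and hard clips become clip segments; all read-consuming middle
    operations fold into one match segment.  Secondary/supplementary records
    are kept and flagged.  Identity is derived from the NM tag when present.
    """
    # htslib silently downgrades mapped records lacking a CIGAR to unmapped,
    # so surface that format error explicitly before parsing
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.split("\t", 6)
            if len(fields) > 5 and not int(fields[1]) & 0x4 and fields[5] == "*":
                raise ValueError(f"mapped SAM record {fields[0]} has no CIGAR")
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            name = aln.query_name
            mate = 2 if aln.is_read2 else 1
            if aln.is_unmapped:
                records.append(unmapped_record(name, mate, aln.query_sequence or ""))
                continue
            if not aln.cigartuples:
                raise ValueError(f"mapped SAM record {name} has no CIGAR")
            clip_l = clip_r = match_read = 0
            ops = aln.cigartuples
            i, j = 0, len(ops)
            while i < j and ops[i][0] in (4, 5):  # S/H
                clip_l += ops[i][1]
                i += 1
            while j > i and ops[j - 1][0] in (4, 5):
                clip_r += ops[j - 1][1]
                j -= 1
            for op, n in ops[i:j]:
                if op in (0, 1, 7, 8):  # M/I/=/X consume the read
                    match_read += n
            segments: list[tuple[str, int]] = []
            if clip_l:
                segments.append(("clip", clip_l))
            segments.append(("match", match_read))
            if clip_r:
                segments.append(("clip", clip_r))
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            identity = max(0.0, (match_read - nm) / match_read) if match_read else 0.0
            records.append(
                AlignmentRecord(
                    read_id=name,
                    mate=mate,
                    reference_name=aln.reference_name,
                    ref_start=aln.reference_start + 1,
                    ref_end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    segments=segments,
                    identity=identity,
                    score=aln.get_tag("AS") if aln.has_tag("AS") else match_read,
                    mapped=True,
                    seq=aln.query_sequence or "",
                    mate_ref=aln.next_reference_name if aln.next_reference_id >= 0 else None,
                    mate_start=aln.next_reference_start + 1 if aln.next_reference_id >= 0 else None,
                    is_secondary=aln.is_secondary or aln.is_supplementary,
                )
            )
    return records


def write_sam(records: list[AlignmentRecord], reference_lengths: dict[str, int], path) -> None:
    """Write AlignmentRecords as SAM (used by the simulator-driven tests)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            a.flag = (1 | (64 if rec.mate == 1 else 128)) if rec.mate else 0
            if rec.mapped:
                a.reference_name = rec.reference_name
                a.reference_start = rec.ref_start - 1
                if rec.strand == "-":
                    a.flag |= 16
                cigar = []
                for op, n in rec.segments:
                    cigar.append((4 if op == "clip" else 0, n))
                # pad the match op so reference span matches ref_end (no indel detail kept)
                a.cigartuples = cigar
                nm = round(rec.match_length * (1 - rec.identity))
                a.set_tag("NM", int(nm))
                a.set_tag("AS", int(rec.score))
            else:
                a.flag |= 4
            a.mapping_quality = 60 if rec.mapped else 0
            out.write(a)


# ---------------------------------------------------------------------------
# internal local aligner
# ---------------------------------------------------------------------------


@dataclass
class AlignerParams:
    """Scoring and seeding parameters for the internal local aligner.

    Defaults mirror BWA-MEM-style scoring (match +1, mismatch -4, gap open 6,
    gap extend 1) with the seed length and band width used for vector mapping
    in the pipeline (seed 50, band 2).
    """

    min_seed: int = 50
    band_width: int = 2
    match: int = 1
    mismatch: int = -4
    gap_open: int = 6  # positive costs
    gap_extend: int = 1
    min_identity: float = 0.9
    min_aln_len: int = 30
    full_dp_max_ref: int = 400  # below this, skip seeding and run full DP


NEG_INF = -(10**9)


@nb.njit(cache=True)
def _sw_matrices(q, r, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment matrices; gap of length g costs open + g*extend."""
    n = q.shape[0]
    m = r.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            s = match if qi == r[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, E, F


def _traceback(q, r, H, E, F, bi, bj, params: AlignerParams):
    """Walk back from the best cell; returns 0-based spans and identity counts."""
    go, ge = params.gap_open, params.gap_extend
    i, j = bi, bj
    state = "H"
    matches = 0
    cols = 0
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            s = params.match if q[i - 1] == r[j - 1] else params.mismatch
            if H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == H[i - 1, j - 1] + s:
                cols += 1
                if q[i - 1] == r[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            cols += 1
            if E[i, j] == H[i, j - 1] - go - ge:
                state = "H"
            j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] - go - ge:
                state = "H"
            i -= 1
    return i, bi - 1, j, bj - 1, matches, cols  # q_start, q_end, r_start, r_end (0-based)


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


@dataclass
class Placement:
    """Internal alignment candidate before conversion to AlignmentRecord."""

    reference_name: str
    ref_start: int  # 1-based
    ref_end: int
    strand: str
    q_start: int  # 0-based inclusive on the reference-oriented read
    q_end: int
    score: int
    identity: float
    oriented_seq: str


class ReferenceIndex:
    """Exact k-mer index over a set of reference sequences.

    ``k`` doubles as the minimum seed length: a read must share an exact
    k-mer with the reference to produce a candidate placement (full dynamic
    programming is used instead when the total reference is small).
    """

    def __init__(self, sequences: dict[str, str], k: int):
        if k < 8:
            raise ValueError("seed length below 8 is not supported")
        if not sequences:
            raise ValueError("reference set is empty")
        self.k = k
        self.sequences = sequences
        self._index: dict[str, object] = {}
        for name_i, (name, seq) in enumerate(sequences.items()):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                cur = self._index.get(kmer)
                entry = (name_i, pos)
                if cur is None:
                    self._index[kmer] = entry
                elif isinstance(cur, tuple):
                    self._index[kmer] = [cur, entry]
                else:
                    cur.append(entry)
        self._names = list(sequences.keys())

    def lookup(self, kmer: str):
        cur = self._index.get(kmer)
        if cur is None:
            return ()
        if isinstance(cur, tuple):
            return (cur,)
        return cur

    def name(self, name_i: int) -> str:
        return self._names[name_i]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def _seed_diagonals(q: str, index: ReferenceIndex) -> dict[int, list[int]]:
    """All (reference, diagonal) seed hits for oriented read q; diag = ref_pos0 - read_off."""
    k = index.k
    diags: dict[int, set[int]] = {}
    lookup = index.lookup
    for off in range(0, len(q) - k + 1):
        for name_i, pos in lookup(q[off : off + k]):
            diags.setdefault(name_i, set()).add(pos - off)
    return {ni: sorted(ds) for ni, ds in diags.items()}


def _extend_on_window(
    q: str, ref_seq: str, ref_name: str, strand: str, a: int, b: int, params: AlignerParams
) -> Placement | None:
    window = ref_seq[a:b]
    qc = _codes(q)
    rc = _codes(window)
    best, bi, bj, H, E, F = _sw_matrices(
        qc, rc, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    if best <= 0:
        return None
    qs, qe, rs, re_, matches, cols = _traceback(qc, rc, H, E, F, bi, bj, params)
    identity = matches / cols if cols else 0.0
    return Placement(
        reference_name=ref_name,
        ref_start=a + rs + 1,
        ref_end=a + re_ + 1,
        strand=strand,
        q_start=qs,
        q_end=qe,
        score=int(best),
        identity=identity,
        oriented_seq=q,
    )


def _placements_for_oriented(
    q: str, index: ReferenceIndex, strand: str, params: AlignerParams
) -> list[Placement]:
    out: list[Placement] = []
    if index.total_length <= params.full_dp_max_ref:
        for name, seq in index.sequences.items():
            p = _extend_on_window(q, seq, name, strand, 0, len(seq), params)
            if p is not None:
                out.append(p)
        return out
    pad = params.band_width + 2
    for name_i, diags in _seed_diagonals(q, index).items():
        name = index.name(name_i)
        seq = index.sequences[name]
        # merge nearby diagonals into one extension window
        group_start = diags[0]
        prev = diags[0]
        groups = []
        for d in diags[1:]:
            if d - prev <= pad:
                prev = d
            else:
                groups.append((group_start, prev))
                group_start = d
                prev = d
        groups.append((group_start, prev))
        for lo, hi in groups:
            if lo == hi and 0 <= lo and lo + len(q) <= len(seq) and seq[lo : lo + len(q)] == q:
                # exact full-length placement: provably optimal, skip DP
                out.append(
                    Placement(
                        reference_name=name,
                        ref_start=lo + 1,
                        ref_end=lo + len(q),
                        strand=strand,
                        q_start=0,
                        q_end=len(q) - 1,
                        score=len(q) * params.match,
                        identity=1.0,
                        oriented_seq=q,
                    )
                )
                continue
            a = max(0, lo - pad)
            b = min(len(seq), hi + len(q) + pad)
            p = _extend_on_window(q, seq, name, strand, a, b, params)
            if p is not None:
                out.append(p)
    return out


def local_align(
    seq: str,
    reference: "ReferenceIndex | dict[str, str] | str",
    params: AlignerParams | None = None,
    read_id: str = "",
    mate: int = 1,
    apply_filters: bool = True,
) -> list[AlignmentRecord]:
    """Local-align a read against a reference, both strands.

    Returns AlignmentRecords sorted best-first; ties break on lowest
    reference coordinate then "+" strand, which makes results deterministic.
    With ``apply_filters`` the minimum alignment length / identity gates are
    applied; disable them to obtain the raw Smith-Waterman optimum.
    """
    if not seq:
        raise ValueError("empty read sequence")
    params = params or AlignerParams()
    if isinstance(reference, str):
        reference = ReferenceIndex({"ref": reference}, min(params.min_seed, max(8, len(reference) // 2)))
    elif isinstance(reference, dict):
        reference = ReferenceIndex(reference, params.min_seed)
    if reference.total_length == 0:
        raise ValueError("empty reference")

    cands: list[Placement] = []
    cands += _placements_for_oriented(seq, reference, "+", params)
    cands += _placements_for_oriented(reverse_complement(seq), reference, "-", params)

    # deduplicate identical placements, sort best-first with deterministic ties
    seen = set()
    unique = []
    for p in cands:
        key = (p.reference_name, p.ref_start, p.ref_end, p.strand)
        if key in seen:
            continue
        seen.add(key)
        unique.append(p)
    unique.sort(key=lambda p: (-p.score, p.reference_name, p.ref_start, p.strand))

    records = []
    for p in unique:
        read_span = p.q_end - p.q_start + 1
        if apply_filters and (read_span < params.min_aln_len or p.identity < params.min_identity):
            continue
        segments: list[tuple[str, int]] = []
        if p.q_start:
            segments.append(("clip", p.q_start))
        segments.append(("match", read_span))
        tail = len(seq) - 1 - p.q_end
        if tail:
            segments.append(("clip", tail))
        records.append(
            AlignmentRecord(
                read_id=read_id,
                mate=mate,
                reference_name=p.reference_name,
                ref_start=p.ref_start,
                ref_end=p.ref_end,
                strand=p.strand,
                segments=segments,
                identity=p.identity,
                score=p.score,
                mapped=True,
                seq=p.oriented_seq,
            )
        )
    return records


def align_best(
    seq: str,
    index: ReferenceIndex,
    params: AlignerParams,
    read_id: str = "",
    mate: int = 1,
) -> AlignmentRecord:
    """Best single placement of a read, or an unmapped record."""
    recs = local_align(seq, index, params, read_id=read_id, mate=mate)
    if not recs:
        return unmapped_record(read_id, mate, seq)
    return recs[0]


def align_library(
    pairs: list[ReadPair], index: ReferenceIndex, params: AlignerParams
) -> list[AlignmentRecord]:
    """Align every mate of every pair; fills mate linkage on mapped records."""
    records: list[AlignmentRecord] = []
    for p in pairs:
        r1 = align_best(p.seq1, index, params, read_id=p.id, mate=1)
        r2 = align_best(p.seq2, index, params, read_id=p.id, mate=2)
        if r1.mapped and r2.mapped:
            r1.mate_ref, r1.mate_start = r2.reference_name, r2.ref_start
            r2.mate_ref, r2.mate_start = r1.reference_name, r1.ref_start
        records.append(r1)
        records.append(r2)
    return records


# ---------------------------------------------------------------------------
# insert-size statistics
# ---------------------------------------------------------------------------


def _pair_up(records: list[AlignmentRecord]) -> dict[str, dict[int, AlignmentRecord]]:
    by_read: dict[str, dict[int, AlignmentRecord]] = {}
    for rec in records:
        if rec.is_secondary:
            continue
        by_read.setdefault(rec.read_id, {})[rec.mate] = rec
    return by_read


def iter_proper_pairs(records: list[AlignmentRecord], reference_name: str):
    """Yield (rec1, rec2, insert_size) for proper pairs on the named reference.

    Proper: both mates mapped to the reference on opposite strands with the
    forward-strand mate leftmost.  Insert = rightmost end - leftmost start + 1.
    """
    for mates in _pair_up(records).values():
        r1, r2 = mates.get(1), mates.get(2)
        if r1 is None or r2 is None or not (r1.mapped and r2.mapped):
            continue
        if r1.reference_name != reference_name or r2.reference_name != reference_name:
            continue
        if r1.strand == r2.strand:
            continue
        fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
        if fwd.ref_start > rev.ref_start:
            continue
        insert = max(r1.ref_end, r2.ref_end) - min(r1.ref_start, r2.ref_start) + 1
        yield r1, r2, insert


def insert_size_stats(
    records: list[AlignmentRecord], reference_name: str, bin_width: int = 50
) -> dict:
    """Count, mean, sd and histogram of proper-pair insert sizes on one reference."""
    inserts = [ins for _, _, ins in iter_proper_pairs(records, reference_name)]
    if not inserts:
        return {"n": 0, "mean": None, "sd": None, "histogram": {}}
    mean = statistics.fmean(inserts)
    sd = statistics.stdev(inserts) if len(inserts) > 1 else 0.0
    hist: dict[int, int] = {}
    for ins in inserts:
        b = (ins // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return {"n": len(inserts), "mean": mean, "sd": sd, "histogram": dict(sorted(hist.items()))}


def discordant_fraction(records: list[AlignmentRecord], reference_name: str) -> tuple[float, int]:
    """Fraction of both-mapped pairs on the reference that are not proper.

    Same-strand mates or inverted mate order count as discordant; pairs with
    an unmapped mate are excluded from the denominator.
    """
    total = 0
    proper = 0
    for mates in _pair_up(records).values():
        r1, r2 = mates.get(1), mates.get(2)
        if r1 is None or r2 is None or not (r1.mapped and r2.mapped):
            continue
        if r1.reference_name != reference_name or r2.reference_name != reference_name:
            continue
        total += 1
        if r1.strand != r2.strand:
            fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
            if fwd.ref_start <= rev.ref_start:
                proper += 1
    if total == 0:
        return 0.0, 0
    return (total - proper) / total, total
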