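"""Three-way read classification and the endogenous false-positive filter.

Reads are partitioned into host-only, plasmid-only (fully inside the
vector with no mappable host clip), junction candidates (T-DNA alignment
with a long enough end clip), unmapped, and false positives.  The false
positives are reads drawn from host loci homologous to elements carried
inside the T-DNA (e.g. an endogenous promoter reused in the construct):
they map convincingly to the vector yet originate from the native genome,
so any vector-mapped read whose best host placement falls inside an
annotated homolog interval is removed before junction calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_io import AlignerParams, AlignmentRecord, ReferenceIndex, local_align
from .reference_model import TDNARegion

LABELS = ("host_only", "plasmid_only", "junction_candidate", "unmapped", "false_positive")


@dataclass
class HomologAnnotation:
    """Host intervals homologous to T-DNA elements, plus match thresholds.

    The literal BLAST e-value cutoff of an external screen is operationalized
    for the self-contained path as: best host alignment of at least
    ``min_aln_len`` bases at identity >= ``min_identity`` overlapping one of
    the intervals.  BLAST tabular hits may be supplied instead, in which case
    the e-value <= ``max_evalue`` rule is applied literally.
    """

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    min_aln_len: int = 40
    min_identity: float = 0.9
    max_evalue: float = 1e-5

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
        for chrom, start, end, _ in self.intervals:
            if start > end:
                raise ValueError(f"invalid homolog interval {chrom}:{start}-{end}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(
            c == chrom and start <= e and end >= s for c, s, e, _ in self.intervals
        )

    @classmethod
    def from_bed(cls, path, **kwargs) -> "HomologAnnotation":
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                name = parts[3] if len(parts) > 3 else "."
                intervals.append((parts[0], int(parts[1]) + 1, int(parts[2]), name))
        return cls(intervals=intervals, **kwargs)


def select_tdna_mapped(records: list[AlignmentRecord], tdna: TDNARegion) -> set[str]:
    """Ids of reads whose vector alignment overlaps the T-DNA interval by >= 1 bp."""
    return {
        rec.full_id for rec in records if rec.mapped and rec.overlaps(tdna.start, tdna.end)
    }


def filter_endogenous(
    candidates: list[tuple[str, str]],
    host_index: ReferenceIndex,
    homologs: HomologAnnotation | None,
    params: AlignerParams | None = None,
) -> tuple[set[str], set[str]]:
    """Split candidate (id, sequence) reads into (retained, false_positive).

    A read is a false positive iff its best host alignment overlaps a
    homolog interval with alignment length >= min_aln_len at identity >=
    min_identity.  With no homolog annotation the filter is a no-op.
    """
    ids = {rid for rid, _ in candidates}
    if homologs is None or not homologs.intervals:
        return ids, set()
    params = params or AlignerParams(min_seed=24, min_aln_len=homologs.min_aln_len,
                                     min_identity=homologs.min_identity)
    fps: set[str] = set()
    for rid, seq in candidates:
        hits = local_align(seq, host_index, params)
        if not hits:
            continue
        best = hits[0]
        span = best.match_length
        if (
            span >= homologs.min_aln_len
            and best.identity >= homologs.min_identity
            and homologs.overlaps(best.reference_name, best.ref_start, best.ref_end)
        ):
            fps.add(rid)
    return ids - fps, fps


def false_positives_from_blast(path, homologs: HomologAnnotation) -> set[str]:
    """Read ids flagged by an external BLAST screen (tabular outfmt 6).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  A query is a false positive iff it has a hit with
    e-value <= max_evalue whose subject interval overlaps a homolog interval.
    """
    fps: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            sstart, send = int(f[8]), int(f[9])
            if sstart > send:
                sstart, send = send, sstart
            evalue = float(f[10])
            if evalue <= homologs.max_evalue and homologs.overlaps(sid, sstart, send):
                fps.add(qid)
    return fps


def classify_all(
    records_plasmid: list[AlignmentRecord],
    records_host: list[AlignmentRecord],
    tdna: TDNARegion,
    min_clip: int = 20,
    false_positive_ids: set[str] | None = None,
) -> dict[str, str]:
    """Assign every read exactly one class label.

    Precedence: known false positives, then junction candidates (T-DNA
    alignment carrying an end clip >= min_clip of putative host sequence),
    then plasmid-only (T-DNA-overlapping without such a clip), then
    host-only, then unmapped.  The labels partition the read set.
    """
    false_positive_ids = false_positive_ids or set()
    plasmid_by_id = {r.full_id: r for r in records_plasmid if not r.is_secondary}
    host_by_id = {r.full_id: r for r in records_host if not r.is_secondary}
    labels: dict[str, str] = {}
    for rid in set(plasmid_by_id) | set(host_by_id):
        if rid in false_positive_ids:
            labels[rid] = "false_positive"
            continue
        prec = plasmid_by_id.get(rid)
        hrec = host_by_id.get(rid)
        tdna_hit = prec is not None and prec.mapped and prec.overlaps(tdna.start, tdna.end)
        if tdna_hit:
            if max(prec.clip_left, prec.clip_right) >= min_clip:
                labels[rid] = "junction_candidate"
            else:
                labels[rid] = "plasmid_only"
        elif hrec is not None and hrec.mapped:
            labels[rid] = "host_only"
        elif prec is not None and prec.mapped:
            # vector backbone placement without T-DNA overlap
            labels[rid] = "plasmid_only"
        else:
            labels[rid] = "unmapped"
    return labels


def mate_rescued_ids(records_plasmid: list[AlignmentRecord],
                     records_host: list[AlignmentRecord],
                     tdna: TDNARegion) -> set[str]:
    """Plasmid-T-DNA reads whose mate maps to the host: locus corroboration only.

    These discordant pairs support the presence of an integration locus but
    never contribute base-precise junction coordinates.
    """
    host_mapped = {(r.read_id, r.mate) for r in records_host if r.mapped and not r.is_secondary}
    out = set()
    for rec in records_plasmid:
        if rec.is_secondary or not rec.mapped or not rec.overlaps(tdna.start, tdna.end):
            continue
        other = 2 if rec.mate == 1 else 1
        if (rec.read_id, other) in host_mapped:
            out.add(rec.full_id)
    return out


def class_counts(labels: dict[str, str]) -> dict[str, int]:
    counts = {label: 0 for label in LABELS}
    for label in labels.values():
        counts[label] += 1
    return counts
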