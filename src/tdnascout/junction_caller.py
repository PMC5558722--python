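"""Junction-read detection, clustering, consensus and insertion calling.

A junction read aligns to the linearized vector with its alignment ending
at (or within a small window of) a T-DNA border and carries a soft clip of
host sequence pointing away from the T-DNA.  Reads are clustered per
border by breakpoint position and clipped-flank agreement, a consensus
flank is built by anchored majority vote, the consensus is mapped to the
host genome, and left/right border clusters landing near each other on
one chromosome are paired into a full insertion call with the target-site
deletion and insert orientation.

Reported deletion follows the junction-coordinate convention
``deletion = end - start`` (the count of physically removed host bases is
``deletion - 1``); both numbers are carried in the call.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_io import AlignerParams, AlignmentRecord, ReferenceIndex, local_align
from .reference_model import HostGenome, TDNARegion

ORIENTATION_LABELS = {"forward": "5'-3'", "reverse": "3'-5'"}


@dataclass
class JunctionRead:
    """One border-spanning read.

    ``flank_sequence`` is the clipped (putative host) portion in
    reference-oriented coordinates; ``anchor`` records which end of that
    string abuts the border: "right" for left-side clips (border at the
    string's right end), "left" for right-side clips.
    """

    read_id: str
    side: str  # "LB" | "RB"
    tdna_breakpoint: int  # linearized vector coordinate of the border-adjacent aligned base
    flank_sequence: str
    anchor: str  # "left" | "right"
    strand: str
    # signed count of flank bases absorbed into the vector alignment by
    # chance matches past the border (negative: vector bases left in the clip)
    border_offset: int = 0


@dataclass
class JunctionCluster:
    side: str
    members: list[JunctionRead]
    consensus_flank: str = ""
    host_hit: tuple[str, int, str, float] | None = None  # (chrom, border-adjacent pos, strand, identity)
    no_hit_reason: str | None = None

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def anchor(self) -> str:
        return self.members[0].anchor

    @property
    def tdna_breakpoint(self) -> int:
        bps = sorted(m.tdna_breakpoint for m in self.members)
        return bps[len(bps) // 2]

    @property
    def border_offset(self) -> int:
        offs = sorted(m.border_offset for m in self.members)
        return offs[len(offs) // 2]


@dataclass
class InsertionCall:
    event_name: str
    chromosome: str
    start: int | None  # 1-based junction coordinates, start <= end
    end: int | None
    deletion: int | None  # end - start (junction-coordinate convention)
    orientation: str | None  # "forward" | "reverse"
    support_left: int
    support_right: int
    status: str  # "full" | "one_sided_LB" | "one_sided_RB"
    not_detected_side: str | None = None

    @property
    def bases_removed(self) -> int | None:
        """Count of host bases physically lost at the target site."""
        return None if self.deletion is None else max(0, self.deletion - 1)

    @property
    def orientation_label(self) -> str:
        return ORIENTATION_LABELS.get(self.orientation, "N/D")


def deletion_size(start: int, end: int) -> int:
    """Target-site deletion under the junction-coordinate convention (end - start)."""
    if end < start:
        raise ValueError(f"end {end} < start {start}; normalize coordinates first")
    return end - start


def find_border_spanning_reads(
    records: list[AlignmentRecord],
    tdna: TDNARegion,
    min_clip: int = 20,
    border_window: int = 10,
) -> list[JunctionRead]:
    """Reads whose vector alignment stops at a T-DNA border with an outward clip.

    The alignment must terminate within ``border_window`` bp of the annotated
    border and carry an end clip of at least ``min_clip`` bases on the side
    pointing away from the T-DNA.
    """
    out: list[JunctionRead] = []
    for rec in records:
        if not rec.mapped or rec.is_secondary:
            continue
        if not rec.overlaps(tdna.start, tdna.end):
            continue
        # start boundary: alignment begins near tdna.start with a left clip outward
        if abs(rec.ref_start - tdna.start) <= border_window and rec.clip_left >= min_clip:
            out.append(
                JunctionRead(
                    read_id=rec.full_id,
                    side=tdna.side_of_boundary(tdna.start),
                    tdna_breakpoint=rec.ref_start,
                    flank_sequence=rec.seq[: rec.clip_left],
                    anchor="right",
                    strand=rec.strand,
                    border_offset=tdna.start - rec.ref_start,
                )
            )
        if abs(rec.ref_end - tdna.end) <= border_window and rec.clip_right >= min_clip:
            out.append(
                JunctionRead(
                    read_id=rec.full_id,
                    side=tdna.side_of_boundary(tdna.end),
                    tdna_breakpoint=rec.ref_end,
                    flank_sequence=rec.seq[len(rec.seq) - rec.clip_right :],
                    anchor="left",
                    strand=rec.strand,
                    border_offset=rec.ref_end - tdna.end,
                )
            )
    return out


def _flank_agreement(a: JunctionRead, b: JunctionRead, min_overlap: int) -> float:
    """Identity of two flanks over their anchored overlap (0 if too short)."""
    fa, fb = a.flank_sequence, b.flank_sequence
    n = min(len(fa), len(fb))
    if n < min_overlap:
        return 0.0
    if a.anchor == "right":
        fa, fb = fa[-n:], fb[-n:]
    else:
        fa, fb = fa[:n], fb[:n]
    matches = sum(1 for x, y in zip(fa, fb) if x == y)
    return matches / n


def cluster_junction_reads(
    junction_reads: list[JunctionRead],
    tolerance_bp: int = 5,
    min_support: int = 2,
    flank_identity: float = 0.9,
    min_flank_overlap: int = 20,
) -> list[JunctionCluster]:
    """Single-linkage clustering per border side.

    Two reads join when their breakpoints lie within ``tolerance_bp`` AND
    their anchored flanks agree at >= ``flank_identity`` over the shared
    overlap.  The flank condition separates co-occurring events that share
    the same border breakpoint (e.g. two integrations on different
    chromosomes), which pure breakpoint clustering cannot.  Clusters below
    ``min_support`` are discarded.
    """
    n = len(junction_reads)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        a = junction_reads[i]
        for j in range(i + 1, n):
            b = junction_reads[j]
            if a.side != b.side:
                continue
            if abs(a.tdna_breakpoint - b.tdna_breakpoint) > tolerance_bp:
                continue
            if _flank_agreement(a, b, min_flank_overlap) < flank_identity:
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[JunctionRead]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(junction_reads[i])
    clusters = [
        JunctionCluster(side=members[0].side, members=members)
        for _, members in sorted(groups.items())
        if len(members) >= min_support
    ]
    for cl in clusters:
        cl.consensus_flank = consensus_flank(cl)
    return clusters


def consensus_flank(cluster: JunctionCluster) -> str:
    """Anchored per-column majority vote over member flanks.

    Flanks are aligned at the breakpoint-adjacent end and padded to the
    longest member; ties break toward the earliest member in input order.
    """
    members = cluster.members
    if not members:
        raise ValueError("empty cluster")
    anchor = members[0].anchor
    longest = max(len(m.flank_sequence) for m in members)
    cols = []
    for col in range(longest):
        votes: dict[str, int] = {}
        order: dict[str, int] = {}
        for rank, m in enumerate(members):
            f = m.flank_sequence
            if anchor == "right":
                idx = len(f) - longest + col
            else:
                idx = col
            if 0 <= idx < len(f):
                base = f[idx]
                votes[base] = votes.get(base, 0) + 1
                order.setdefault(base, rank)
        if votes:
            cols.append(max(votes, key=lambda b: (votes[b], -order[b])))
        else:  # pragma: no cover - cannot happen with end-anchored padding
            cols.append("N")
    return "".join(cols)


def map_flank_to_host(
    consensus: str,
    host_index: ReferenceIndex,
    anchor: str,
    params: AlignerParams | None = None,
    uniqueness_margin: int = 5,
) -> tuple[tuple[str, int, str, float] | None, str | None]:
    """Best unique host placement of a consensus flank.

    Returns ((chromosome, border-adjacent host position, strand, identity),
    None) on success, or (None, reason) when the flank has no acceptable hit,
    is ambiguous (second-best score within ``uniqueness_margin`` of the
    best), or its border-adjacent base is unaligned.
    """
    params = params or AlignerParams(min_seed=24)
    if len(consensus) < params.min_seed:
        return None, "flank-too-short"
    hits = local_align(consensus, host_index, params, apply_filters=False)
    hits = [h for h in hits if h.match_length >= min(params.min_aln_len, len(consensus))]
    if not hits:
        return None, "no-hit"
    best = hits[0]
    if best.identity < params.min_identity:
        return None, "low-identity"
    if len(hits) > 1 and hits[1].score >= best.score - uniqueness_margin:
        return None, "multi-hit"
    # index of the border-adjacent base on the reference-oriented query
    idx = len(consensus) - 1 if anchor == "right" else 0
    if best.strand == "-":
        idx = len(consensus) - 1 - idx
    q_start = best.clip_left
    q_end = q_start + best.match_length - 1
    if not q_start <= idx <= q_end:
        return None, "anchor-unaligned"
    pos = best.ref_start + (idx - q_start)
    return (best.reference_name, pos, best.strand, best.identity), None


def attach_host_hits(
    clusters: list[JunctionCluster],
    host: "HostGenome | ReferenceIndex",
    params: AlignerParams | None = None,
    uniqueness_margin: int = 5,
) -> None:
    params = params or AlignerParams(min_seed=24)
    index = (
        host
        if isinstance(host, ReferenceIndex)
        else ReferenceIndex(host.sequences, params.min_seed)
    )
    for cl in clusters:
        cl.host_hit, cl.no_hit_reason = map_flank_to_host(
            cl.consensus_flank, index, cl.anchor, params, uniqueness_margin
        )
        if cl.host_hit is not None and cl.border_offset:
            # chance matches past the annotated border absorb flank bases
            # into the vector alignment; shift the mapped junction back so
            # the reported coordinate is the true border-adjacent host base
            chrom, pos, strand, ident = cl.host_hit
            toward_border = 1 if (cl.anchor == "right") == (strand == "+") else -1
            cl.host_hit = (chrom, pos + toward_border * cl.border_offset, strand, ident)


def call_insertions(
    clusters: list[JunctionCluster],
    pairing_distance: int = 10_000,
    min_support: int = 2,
) -> list[InsertionCall]:
    """Pair LB and RB clusters into insertion calls.

    An LB and an RB cluster whose flank hits land on the same chromosome
    within ``pairing_distance`` form one full call: start/end are the two
    border-adjacent host coordinates (min/max), deletion = end - start, and
    orientation is forward when the host flanks align to the plus strand
    (the T-DNA runs in host plus sense) and reverse otherwise.  Clusters
    that cannot be paired, or whose partner flank failed to map, yield
    one-sided calls with the missing side reported as not detectable.
    """
    usable = [c for c in clusters if c.support >= min_support]
    mapped = [c for c in usable if c.host_hit is not None]
    lbs = [c for c in mapped if c.side == "LB"]
    rbs = [c for c in mapped if c.side == "RB"]

    calls: list[InsertionCall] = []
    used_rb: set[int] = set()
    for lb in sorted(lbs, key=lambda c: (c.host_hit[0], c.host_hit[1])):
        lchrom, lpos, lstrand, _ = lb.host_hit
        best_j = None
        best_dist = None
        for j, rb in enumerate(rbs):
            if j in used_rb:
                continue
            rchrom, rpos, _, _ = rb.host_hit
            if rchrom != lchrom:
                continue
            dist = abs(rpos - lpos)
            if dist <= pairing_distance and (best_dist is None or dist < best_dist):
                best_j, best_dist = j, dist
        if best_j is None:
            calls.append(_one_sided(lb))
            continue
        used_rb.add(best_j)
        rb = rbs[best_j]
        rchrom, rpos, rstrand, _ = rb.host_hit
        start, end = min(lpos, rpos), max(lpos, rpos)
        if lstrand == rstrand:
            orientation = "forward" if lstrand == "+" else "reverse"
        else:
            orientation = None  # conflicting flank senses; left undecided
        calls.append(
            InsertionCall(
                event_name="",
                chromosome=lchrom,
                start=start,
                end=end,
                deletion=deletion_size(start, end),
                orientation=orientation,
                support_left=lb.support,
                support_right=rb.support,
                status="full",
            )
        )
    for j, rb in enumerate(rbs):
        if j not in used_rb:
            calls.append(_one_sided(rb))
    calls.sort(key=lambda c: (c.chromosome, c.start or 0, c.status))
    for i, c in enumerate(calls, start=1):
        c.event_name = f"event_{i}"
    return calls


def _one_sided(cluster: JunctionCluster) -> InsertionCall:
    chrom, pos, strand, _ = cluster.host_hit
    side = cluster.side
    other = "RB" if side == "LB" else "LB"
    return InsertionCall(
        event_name="",
        chromosome=chrom,
        start=pos,
        end=pos,
        deletion=None,
        orientation="forward" if strand == "+" else "reverse",
        support_left=cluster.support if side == "LB" else 0,
        support_right=cluster.support if side == "RB" else 0,
        status=f"one_sided_{side}",
        not_detected_side=other,
    )
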