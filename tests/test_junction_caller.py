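"""Border-spanning read detection, clustering, consensus, and insertion calls."""

import pytest

from tdnascout.align_io import AlignmentRecord, ReferenceIndex
from tdnascout.junction_caller import (
    InsertionCall,
    JunctionCluster,
    JunctionRead,
    call_insertions,
    cluster_junction_reads,
    consensus_flank,
    deletion_size,
    find_border_spanning_reads,
    map_flank_to_host,
)
from tdnascout.pipeline import PipelineConfig, run_pipeline
from tdnascout.reference_model import HostGenome
from tdnascout.simulate import (
    InsertionGroundTruth,
    ReadLibraryParams,
    build_event_genome,
    read_origin,
    simulate_paired_reads,
)


class TestDeletionSize:
    def test_published_junction_pairs(self):
        assert deletion_size(22_498_218, 22_498_297) == 79
        assert deletion_size(22_473_585, 22_473_636) == 51

    def test_blunt_insertion_limit(self):
        assert deletion_size(5, 5) == 0

    def test_unordered_coordinates_rejected(self):
        with pytest.raises(ValueError):
            deletion_size(10, 9)

    @pytest.mark.parametrize("shift", [1, 1_000, 22_000_000])
    def test_translation_invariance(self, shift):
        assert deletion_size(100 + shift, 179 + shift) == deletion_size(100, 179)


def _vec_record(read_id, start, end, clip_left=0, clip_right=0, seq=None, strand="+"):
    span = end - start + 1
    segments = []
    if clip_left:
        segments.append(("clip", clip_left))
    segments.append(("match", span))
    if clip_right:
        segments.append(("clip", clip_right))
    n = clip_left + span + clip_right
    return AlignmentRecord(
        read_id=read_id, mate=1, reference_name="vec", ref_start=start, ref_end=end,
        strand=strand, segments=segments, identity=1.0, score=span, mapped=True,
        seq=seq or ("A" * n),
    )


class TestBorderSpanningReads:
    def test_interior_read_without_clip_ignored(self, tdna):
        recs = [_vec_record("mid", tdna.start + 500, tdna.start + 649)]
        assert find_border_spanning_reads(recs, tdna) == []

    def test_rb_read_with_outward_clip(self, tdna):
        seq = "G" * 80 + "T" * 70
        recs = [_vec_record("rb", tdna.end - 79, tdna.end, clip_right=70, seq=seq)]
        jr = find_border_spanning_reads(recs, tdna)
        assert len(jr) == 1
        assert jr[0].side == "RB" and jr[0].anchor == "left"
        assert jr[0].flank_sequence == "T" * 70
        assert jr[0].tdna_breakpoint == tdna.end

    def test_lb_read_with_outward_clip(self, tdna):
        seq = "T" * 60 + "G" * 90
        recs = [_vec_record("lb", tdna.start, tdna.start + 89, clip_left=60, seq=seq)]
        jr = find_border_spanning_reads(recs, tdna)
        assert jr[0].side == "LB" and jr[0].anchor == "right"
        assert jr[0].flank_sequence == "T" * 60
        assert jr[0].tdna_breakpoint == tdna.start

    def test_clip_pointing_into_tdna_ignored(self, tdna):
        # clip on the T-DNA-interior side of the alignment is not junction evidence
        recs = [_vec_record("inward", tdna.start, tdna.start + 89, clip_right=60)]
        assert find_border_spanning_reads(recs, tdna) == []

    def test_border_window_and_min_clip_thresholds(self, tdna):
        near = _vec_record("near", tdna.start + 8, tdna.start + 120, clip_left=30)
        far = _vec_record("far", tdna.start + 30, tdna.start + 120, clip_left=30)
        short_clip = _vec_record("short", tdna.start, tdna.start + 120, clip_left=10)
        got = {j.read_id for j in find_border_spanning_reads([near, far, short_clip], tdna)}
        assert got == {"near/1"}

    def test_simulated_junction_reads_match_provenance(
        self, small_host, plasmid, linref, tdna
    ):
        truth = InsertionGroundTruth("chr1", 20_000, 20_079)
        genome = build_event_genome(small_host, linref, tdna, [truth])
        pairs = simulate_paired_reads(genome, ReadLibraryParams(coverage=20, seed=55))
        res = run_pipeline(small_host, plasmid, tdna, pairs, PipelineConfig())
        from tdnascout.align_io import remove_duplicates

        got = {j.read_id for j in res.junction_reads}
        ins_lo, ins_hi = 20_001, 20_000 + tdna.length
        certain, ambiguous = set(), set()
        deduped, _ = remove_duplicates(pairs)  # chance fragment collisions
        for p in deduped:
            _, fs, fe = read_origin(p.id)
            for mate, (a, b) in enumerate(((fs, fs + 149), (fe - 149, fe)), start=1):
                tdna_part = max(0, min(b, ins_hi) - max(a, ins_lo) + 1)
                host_part = max(max(0, ins_lo - a), max(0, b - ins_hi))
                if tdna_part >= 50 and host_part >= 30:
                    certain.add(f"{p.id}/{mate}")
                elif tdna_part >= 40 and host_part >= 20:
                    ambiguous.add(f"{p.id}/{mate}")
        assert certain <= got <= certain | ambiguous


class TestClustering:
    def _jr(self, i, bp, flank, side="LB", anchor="right"):
        return JunctionRead(f"r{i}", side, bp, flank, anchor, "+")

    def test_identical_breakpoints_one_cluster(self):
        reads = [self._jr(i, 6_392, "ACGTACGTACGTACGTACGTACGT") for i in range(10)]
        clusters = cluster_junction_reads(reads)
        assert len(clusters) == 1 and clusters[0].support == 10

    def test_min_support_discards_singletons(self):
        reads = [self._jr(0, 6_392, "A" * 30)]
        assert cluster_junction_reads(reads, min_support=2) == []

    def test_same_breakpoint_distinct_flanks_split(self, rng):
        # two integrations sharing a border breakpoint separate by flank content
        f1 = "".join(rng.choice(list("ACGT"), 60))
        f2 = "".join(rng.choice(list("ACGT"), 60))
        reads = [self._jr(i, 6_392, f1) for i in range(3)]
        reads += [self._jr(i + 10, 6_392, f2) for i in range(3)]
        clusters = cluster_junction_reads(reads)
        assert sorted(c.support for c in clusters) == [3, 3]

    def test_breakpoint_clustering_matches_transitive_closure_oracle(self, rng):
        flank = "ACGT" * 15  # identical flanks isolate breakpoint behaviour
        bps = [int(b) for b in rng.integers(0, 60, 40)]
        reads = [self._jr(i, 6_000 + b, flank) for i, b in enumerate(bps)]
        clusters = cluster_junction_reads(reads, tolerance_bp=5, min_support=1)
        # brute-force transitive closure on |bp_i - bp_j| <= 5
        n = len(reads)
        adj = [[abs(bps[i] - bps[j]) <= 5 for j in range(n)] for i in range(n)]
        groups = {}
        labels = list(range(n))
        changed = True
        while changed:
            changed = False
            for i in range(n):
                for j in range(n):
                    if adj[i][j] and labels[j] > labels[i]:
                        labels[j] = labels[i]
                        changed = True
                    elif adj[i][j] and labels[i] > labels[j]:
                        labels[i] = labels[j]
                        changed = True
        for i, lab in enumerate(labels):
            groups.setdefault(lab, set()).add(f"r{i}")
        got = {frozenset(m.read_id for m in c.members) for c in clusters}
        assert got == {frozenset(g) for g in groups.values()}


class TestConsensusFlank:
    def _cluster(self, flanks, anchor="left", side="RB"):
        members = [JunctionRead(f"r{i}", side, 6_392, f, anchor, "+") for i, f in enumerate(flanks)]
        return JunctionCluster(side=side, members=members)

    def test_identical_members(self):
        cl = self._cluster(["ACGTACGT"] * 4)
        assert consensus_flank(cl) == "ACGTACGT"

    def test_majority_overrides_single_substitution(self):
        cl = self._cluster(["ACGTACGT", "ACGAACGT", "ACGTACGT"])
        assert consensus_flank(cl) == "ACGTACGT"

    def test_right_anchor_aligns_at_breakpoint_end(self):
        # border-adjacent end is the right end; shorter member right-aligns
        cl = self._cluster(["TTACGT", "ACGT"], anchor="right", side="LB")
        assert consensus_flank(cl) == "TTACGT"

    def test_left_anchor_pads_to_longest(self):
        cl = self._cluster(["ACGTGG", "ACGT"], anchor="left")
        assert consensus_flank(cl) == "ACGTGG"

    def test_tie_breaks_to_earliest_member(self):
        cl = self._cluster(["AA", "CC"])
        assert consensus_flank(cl) == "AA"

    def test_noisy_flanks_recover_truth_at_support_five(self, rng):
        true_flank = "".join(rng.choice(list("ACGT"), 80))
        flanks = []
        for _ in range(6):
            noisy = list(true_flank)
            for pos in rng.choice(80, size=1, replace=False):  # ~1% error
                noisy[pos] = "ACGT"[rng.integers(4)]
            flanks.append("".join(noisy))
        cl = self._cluster(flanks)
        assert consensus_flank(cl) == true_flank


@pytest.fixture(scope="module")
def host_index(small_host):
    return ReferenceIndex(small_host.sequences, 24)


class TestMapFlankToHost:
    def test_exact_flank_maps_to_locus(self, small_host, host_index):
        flank = small_host.sequences["chr1"][10_000 : 10_070]
        hit, reason = map_flank_to_host(flank, host_index, anchor="left")
        assert reason is None
        chrom, pos, strand, identity = hit
        assert (chrom, pos, strand, identity) == ("chr1", 10_001, "+", 1.0)

    def test_right_anchor_returns_border_adjacent_base(self, small_host, host_index):
        flank = small_host.sequences["chr1"][10_000 : 10_070]
        hit, _ = map_flank_to_host(flank, host_index, anchor="right")
        assert hit[1] == 10_070

    def test_duplicated_flank_is_ambiguous(self, rng):
        block = "".join(rng.choice(list("ACGT"), 2_000))
        filler = "".join(rng.choice(list("ACGT"), 6_000))
        host = HostGenome({"chr1": block + filler + block})
        index = ReferenceIndex(host.sequences, 24)
        hit, reason = map_flank_to_host(block[500:570], index, anchor="left")
        assert hit is None and reason == "multi-hit"

    def test_too_short_flank_reported(self, host_index):
        hit, reason = map_flank_to_host("ACGTACGT", host_index, anchor="left")
        assert hit is None and reason == "flank-too-short"

    def test_foreign_flank_has_no_hit(self, host_index, rng):
        foreign = "".join(rng.choice(list("ACGT"), 70))
        hit, reason = map_flank_to_host(foreign, host_index, anchor="left")
        assert hit is None and reason in ("no-hit", "low-identity")


def _cluster_with_hit(side, chrom, pos, strand="+", support=5):
    members = [
        JunctionRead(f"{side}{i}", side, 6_392 if side == "LB" else 10_291,
                     "A" * 40, "right" if side == "LB" else "left", "+")
        for i in range(support)
    ]
    cl = JunctionCluster(side=side, members=members, consensus_flank="A" * 40)
    cl.host_hit = (chrom, pos, strand, 1.0)
    return cl


class TestCallInsertions:
    def test_published_style_full_call(self):
        lb = _cluster_with_hit("LB", "chr10", 22_498_218)
        rb = _cluster_with_hit("RB", "chr10", 22_498_297)
        calls = call_insertions([lb, rb])
        assert len(calls) == 1
        c = calls[0]
        assert (c.chromosome, c.start, c.end, c.deletion) == ("chr10", 22_498_218, 22_498_297, 79)
        assert c.status == "full" and c.orientation == "forward"
        assert c.bases_removed == 78

    def test_blunt_insertion_deletion_zero(self):
        lb = _cluster_with_hit("LB", "chr1", 5_000)
        rb = _cluster_with_hit("RB", "chr1", 5_000)
        c = call_insertions([lb, rb])[0]
        assert c.deletion == 0 and c.bases_removed == 0

    def test_minus_strand_flanks_give_reverse_orientation(self):
        lb = _cluster_with_hit("LB", "chr1", 5_079, strand="-")
        rb = _cluster_with_hit("RB", "chr1", 5_000, strand="-")
        c = call_insertions([lb, rb])[0]
        assert c.orientation == "reverse" and c.orientation_label == "3'-5'"
        assert (c.start, c.end) == (5_000, 5_079)

    def test_lone_rb_cluster_gives_one_sided_call(self):
        rb = _cluster_with_hit("RB", "chr3", 14_707_391)
        calls = call_insertions([rb])
        assert len(calls) == 1
        c = calls[0]
        assert c.status == "one_sided_RB" and c.not_detected_side == "LB"
        assert c.deletion is None

    def test_unmapped_partner_cluster_stays_one_sided(self):
        rb = _cluster_with_hit("RB", "chr3", 14_707_391)
        lb = _cluster_with_hit("LB", "chr3", 14_707_459)
        lb.host_hit, lb.no_hit_reason = None, "multi-hit"
        calls = call_insertions([rb, lb])
        assert [c.status for c in calls] == ["one_sided_RB"]

    def test_different_chromosomes_yield_two_one_sided_calls(self):
        lb = _cluster_with_hit("LB", "chr1", 1_000)
        rb = _cluster_with_hit("RB", "chr2", 9_000)
        statuses = sorted(c.status for c in call_insertions([lb, rb]))
        assert statuses == ["one_sided_LB", "one_sided_RB"]

    def test_below_min_support_clusters_ignored(self):
        lb = _cluster_with_hit("LB", "chr1", 1_000, support=1)
        rb = _cluster_with_hit("RB", "chr1", 1_050, support=1)
        assert call_insertions([lb, rb], min_support=2) == []


class TestParameterRecoveryWithErrors:
    def test_noisy_reads_recover_coordinates_within_one_base(
        self, small_host, plasmid, linref, tdna
    ):
        truth = InsertionGroundTruth("chr1", 30_000, 30_051, orientation="reverse")
        genome = build_event_genome(small_host, linref, tdna, [truth])
        pairs = simulate_paired_reads(
            genome, ReadLibraryParams(coverage=30, seed=91, per_base_error=0.005)
        )
        res = run_pipeline(small_host, plasmid, tdna, pairs, PipelineConfig())
        full = [c for c in res.calls if c.status == "full"]
        assert len(full) == 1
        c = full[0]
        assert c.chromosome == "chr1"
        assert abs(c.start - 30_000) <= 1 and abs(c.end - 30_051) <= 1
        assert c.orientation == "reverse"
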