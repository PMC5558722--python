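"""End-to-end orchestration: QC -> align -> classify -> call -> report.

`run_pipeline` is the single entry point used by the CLI, the tests and
the reproduction script.  It accepts in-memory read pairs (from FASTQ or
the simulator) or pre-computed external alignments, and returns every
intermediate product so each stage remains independently inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align_io, classify, junction_caller, qc_report
from .align_io import AlignerParams, AlignmentRecord, ReadPair, ReferenceIndex
from .classify import HomologAnnotation
from .reference_model import (
    CircularPlasmid,
    HostGenome,
    LinearizedReference,
    TDNARegion,
    backbone_intervals,
    linearize_plasmid,
)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, with its pipeline default."""

    min_mean_phred: float = 20.0
    wrap_length: int = 150
    plasmid_aligner: AlignerParams = field(
        default_factory=lambda: AlignerParams(min_seed=50, band_width=2)
    )
    host_aligner: AlignerParams = field(
        default_factory=lambda: AlignerParams(min_seed=24, band_width=2)
    )
    min_clip: int = 20
    border_window: int = 10
    cluster_tolerance: int = 5
    min_support: int = 2
    pairing_distance: int = 10_000
    uniqueness_margin: int = 5
    expected_insert: float = 500.0
    insert_tolerance: float = 0.20
    discordant_threshold: float = 0.05
    backbone_min_reads: int = 2
    genome_size: int | None = None  # defaults to the host assembly size

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if not isinstance(v, AlignerParams)
        }
        d["plasmid_aligner"] = vars(self.plasmid_aligner)
        d["host_aligner"] = vars(self.host_aligner)
        return d


@dataclass
class PipelineResult:
    sample: str
    coverage: qc_report.CoverageSummary
    qc_stats: dict
    dedup_stats: dict
    labels: dict[str, str]
    class_counts: dict[str, int]
    mapping_stats: dict
    junction_reads: list
    clusters: list
    calls: list
    insert_stats: dict
    rearrangement: qc_report.RearrangementReport
    backbone: qc_report.BackboneReport
    copy_number: dict
    records_plasmid: list[AlignmentRecord]
    records_host: list[AlignmentRecord]
    false_positive_ids: set[str]


def _align_with_exact_fast_path(
    pairs: list[ReadPair], index: ReferenceIndex, params: AlignerParams
) -> list[AlignmentRecord]:
    """Align every mate; full-length exact placements short-circuit the DP.

    A unique full-length exact match is provably optimal, so the k-mer probe
    plus string comparison replaces seeding/extension for the bulk of an
    error-free library.  Anything else falls back to the generic aligner.
    """
    from .reference_model import reverse_complement

    k = index.k
    records: list[AlignmentRecord] = []

    def one(seq: str, rid: str, mate: int) -> AlignmentRecord:
        for strand in ("+", "-"):
            q = seq if strand == "+" else reverse_complement(seq)
            if len(q) < k:
                break
            hits = index.lookup(q[:k])
            placed = None
            multiple = False
            for name_i, pos in hits:
                name = index.name(name_i)
                ref = index.sequences[name]
                if ref[pos : pos + len(q)] == q:
                    if placed is not None:
                        multiple = True
                        break
                    placed = (name, pos)
            if placed and not multiple:
                name, pos = placed
                return AlignmentRecord(
                    read_id=rid,
                    mate=mate,
                    reference_name=name,
                    ref_start=pos + 1,
                    ref_end=pos + len(q),
                    strand=strand,
                    segments=[("match", len(q))],
                    identity=1.0,
                    score=len(q) * params.match,
                    mapped=True,
                    seq=q,
                )
        return align_io.align_best(seq, index, params, read_id=rid, mate=mate)

    for p in pairs:
        r1 = one(p.seq1, p.id, 1)
        r2 = one(p.seq2, p.id, 2)
        if r1.mapped and r2.mapped:
            r1.mate_ref, r1.mate_start = r2.reference_name, r2.ref_start
            r2.mate_ref, r2.mate_start = r1.reference_name, r1.ref_start
        records.append(r1)
        records.append(r2)
    return records


def run_pipeline(
    host: HostGenome,
    plasmid: CircularPlasmid,
    tdna: TDNARegion,
    pairs: list[ReadPair],
    config: PipelineConfig | None = None,
    homologs: HomologAnnotation | None = None,
    sample: str = "sample",
    host_index: ReferenceIndex | None = None,
    outdir=None,
) -> PipelineResult:
    """Run the whole detection workflow on one library.

    ``tdna`` is annotated in linearized-vector coordinates.  Passing a
    pre-built ``host_index`` lets several libraries share one index.
    """
    config = config or PipelineConfig()
    linref = linearize_plasmid(plasmid, config.wrap_length)
    bb_intervals = backbone_intervals(linref, tdna)

    # read QC: whole-read quality filter, then exact-duplicate removal
    filtered, qstats = align_io.quality_filter(pairs, config.min_mean_phred)
    deduped, dstats = align_io.remove_duplicates(filtered)

    genome_size = config.genome_size or host.total_length
    coverage = qc_report.CoverageSummary(
        sample=sample,
        raw_reads=qstats["raw_reads"],
        raw_bases=qstats["raw_bases"],
        post_trim_reads=qstats["retained_reads"],
        post_trim_bases=qstats["retained_bases"],
        post_dedup_reads=dstats["retained_reads"],
        post_dedup_bases=dstats["retained_bases"],
        genome_size=genome_size,
    )

    # alignment to the linearized vector and to the host
    plasmid_index = ReferenceIndex({linref.name: linref.sequence}, config.plasmid_aligner.min_seed)
    if host_index is None:
        host_index = ReferenceIndex(host.sequences, config.host_aligner.min_seed)
    records_plasmid = _align_with_exact_fast_path(deduped, plasmid_index, config.plasmid_aligner)
    records_host = _align_with_exact_fast_path(deduped, host_index, config.host_aligner)

    # endogenous-homolog false positives among T-DNA-mapped reads
    candidate_ids = classify.select_tdna_mapped(records_plasmid, tdna)
    seq_by_id = {}
    for p in deduped:
        seq_by_id[f"{p.id}/1"] = p.seq1
        seq_by_id[f"{p.id}/2"] = p.seq2
    candidates = [(rid, seq_by_id[rid]) for rid in sorted(candidate_ids)]
    _, fp_ids = classify.filter_endogenous(
        candidates, host_index, homologs, config.host_aligner
    )

    labels = classify.classify_all(
        records_plasmid, records_host, tdna, config.min_clip, false_positive_ids=fp_ids
    )
    counts = classify.class_counts(labels)

    # junction calling on retained (non-false-positive) vector alignments
    retained_records = [r for r in records_plasmid if r.full_id not in fp_ids]
    junction_reads = junction_caller.find_border_spanning_reads(
        retained_records, tdna, config.min_clip, config.border_window
    )
    clusters = junction_caller.cluster_junction_reads(
        junction_reads,
        tolerance_bp=config.cluster_tolerance,
        min_support=config.min_support,
        min_flank_overlap=config.min_clip,
    )
    junction_caller.attach_host_hits(
        clusters, host_index, config.host_aligner, config.uniqueness_margin
    )
    calls = junction_caller.call_insertions(
        clusters, config.pairing_distance, config.min_support
    )

    # structural checks: T-DNA insert sizes and backbone coverage
    tdna_records = [r for r in retained_records if r.mapped and r.overlaps(tdna.start, tdna.end)]
    insert_stats = align_io.insert_size_stats(tdna_records, linref.name)
    disc_frac, disc_n = align_io.discordant_fraction(tdna_records, linref.name)
    rearrangement = qc_report.rearrangement_check(
        insert_stats,
        config.expected_insert,
        discordant_frac=disc_frac,
        tolerance=config.insert_tolerance,
        discordant_threshold=config.discordant_threshold,
        sample=sample,
    )
    backbone = qc_report.backbone_check(
        retained_records, bb_intervals, config.backbone_min_reads,
        config.plasmid_aligner.min_identity, sample=sample,
    )

    # copy number: junction loci vs depth ratio
    depth_tdna = qc_report.mean_depth_over_interval(
        retained_records, linref.name, tdna.start, tdna.end
    )
    depth_host = qc_report.median_genome_depth(records_host, host.lengths)
    copy_number = qc_report.estimate_copy_number(
        calls, depth_tdna, depth_host if depth_host > 0 else 1.0
    )

    mapping_stats = {
        "vector_mapped_reads": sum(
            1 for r in records_plasmid if r.mapped and not r.is_secondary
        ),
        "tdna_mapped_reads": len(candidate_ids),
        "false_positive_reads": len(fp_ids),
        "proper_pairs_tdna": insert_stats["n"],
        "both_mapped_pairs_tdna": disc_n,
        "junction_reads": len(junction_reads),
    }

    result = PipelineResult(
        sample=sample,
        coverage=coverage,
        qc_stats=qstats,
        dedup_stats=dstats,
        labels=labels,
        class_counts=counts,
        mapping_stats=mapping_stats,
        junction_reads=junction_reads,
        clusters=clusters,
        calls=calls,
        insert_stats=insert_stats,
        rearrangement=rearrangement,
        backbone=backbone,
        copy_number=copy_number,
        records_plasmid=records_plasmid,
        records_host=records_host,
        false_positive_ids=fp_ids,
    )
    if outdir is not None:
        qc_report.write_report(
            outdir,
            coverage=coverage,
            class_counts=counts,
            mapping_stats=mapping_stats,
            calls=calls,
            rearrangement=rearrangement,
            backbone=backbone,
            copy_number=copy_number,
            run_params=config.to_dict(),
        )
    return result
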