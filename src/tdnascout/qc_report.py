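"""Coverage arithmetic, copy number, rearrangement and backbone checks, reports.

Fold coverage and the retained-base percentages follow the sequencing-
summary conventions of event-characterization reports: base-fraction
percentages and integer rounding (half away from zero).  Copy number is
reported two ways — the junction-derived locus count and the depth ratio
of the T-DNA interval over the host genome — and discrepancies between
the two are flagged rather than reconciled.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .align_io import AlignmentRecord
from .junction_caller import InsertionCall


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fold_coverage(total_bases: int, genome_size: int) -> int:
    """Sequencing depth = total bases / genome size, rounded to integer fold."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return _round_half_away(total_bases / genome_size)


def retained_fraction(numerator_bases: int, denominator_bases: int) -> int:
    """Percent of bases retained, integer-rounded (base-fraction convention)."""
    if denominator_bases <= 0:
        raise ValueError("denominator must be positive")
    return _round_half_away(100 * numerator_bases / denominator_bases)


@dataclass
class CoverageSummary:
    sample: str
    raw_reads: int
    raw_bases: int
    post_trim_reads: int
    post_trim_bases: int
    post_dedup_reads: int
    post_dedup_bases: int
    genome_size: int

    def __post_init__(self) -> None:
        if not self.post_dedup_bases <= self.post_trim_bases <= self.raw_bases:
            raise ValueError("base counts must be non-increasing along the QC chain")

    @property
    def fold_coverage(self) -> int:
        return fold_coverage(self.raw_bases, self.genome_size)

    @property
    def pct_bases_post_trim(self) -> int:
        return retained_fraction(self.post_trim_bases, self.raw_bases)

    @property
    def pct_bases_post_dedup(self) -> int:
        return retained_fraction(self.post_dedup_bases, self.raw_bases)

    @property
    def pct_reads_post_trim(self) -> int:
        return retained_fraction(self.post_trim_reads, self.raw_reads)

    @property
    def pct_reads_post_dedup(self) -> int:
        return retained_fraction(self.post_dedup_reads, self.raw_reads)

    def to_row(self) -> dict:
        # both base- and read-fraction percentages, labelled, since summary
        # tables in the field are ambiguous about which they print
        return {
            "sample": self.sample,
            "raw_reads": self.raw_reads,
            "raw_bases": self.raw_bases,
            "coverage_x": self.fold_coverage,
            "post_trim_reads": self.post_trim_reads,
            "post_trim_bases": self.post_trim_bases,
            "pct_bases_post_trim": self.pct_bases_post_trim,
            "pct_reads_post_trim": self.pct_reads_post_trim,
            "post_dedup_reads": self.post_dedup_reads,
            "post_dedup_bases": self.post_dedup_bases,
            "pct_bases_post_dedup": self.pct_bases_post_dedup,
            "pct_reads_post_dedup": self.pct_reads_post_dedup,
        }


def mean_depth_over_interval(
    records: list[AlignmentRecord], reference_name: str, start: int, end: int
) -> float:
    """Mean per-base depth over a 1-based inclusive reference interval."""
    length = end - start + 1
    covered = 0
    for rec in records:
        if rec.is_secondary or not rec.mapped or rec.reference_name != reference_name:
            continue
        lo = max(rec.ref_start, start)
        hi = min(rec.ref_end, end)
        if hi >= lo:
            covered += hi - lo + 1
    return covered / length


def median_genome_depth(records: list[AlignmentRecord], lengths: dict[str, int]) -> float:
    """Median per-base depth across all host chromosomes (robust to local spikes)."""
    depths = []
    for name, length in lengths.items():
        diff = np.zeros(length + 1, dtype=np.int32)
        any_rec = False
        for rec in records:
            if rec.is_secondary or not rec.mapped or rec.reference_name != name:
                continue
            lo = max(1, rec.ref_start)
            hi = min(length, rec.ref_end)
            if hi >= lo:
                diff[lo - 1] += 1
                diff[hi] -= 1
                any_rec = True
        if any_rec or length:
            depths.append(np.cumsum(diff[:-1]))
    if not depths:
        return 0.0
    return float(np.median(np.concatenate(depths)))


def estimate_copy_number(
    calls: list[InsertionCall], depth_tdna: float, depth_genome: float
) -> dict:
    """Junction-derived locus count plus the depth-ratio copy estimate.

    The two estimates answer different questions (distinct loci vs total
    copies including tandem repeats); a mismatch is flagged, not averaged.
    """
    if depth_genome <= 0:
        raise ValueError("depth_genome must be positive")
    locus_count = len(calls)
    ratio = depth_tdna / depth_genome
    depth_estimate = _round_half_away(ratio) if locus_count or depth_tdna > 0 else 0
    return {
        "locus_count": locus_count,
        "depth_ratio_estimate": depth_estimate,
        "depth_ratio_raw": ratio,
        "consistent": locus_count == depth_estimate,
    }


@dataclass
class RearrangementReport:
    sample: str
    n_proper_pairs: int
    mean_insert: float | None
    sd_insert: float | None
    expected_insert: float
    discordant_fraction: float
    flag: str  # "consistent" | "deviant" | "insufficient data"


def rearrangement_check(
    stats: dict,
    expected_insert: float,
    discordant_frac: float = 0.0,
    tolerance: float = 0.20,
    discordant_threshold: float = 0.05,
    sample: str = "",
) -> RearrangementReport:
    """Flag internal rearrangement from the T-DNA insert-size distribution.

    The library's physical fragment size is taken from library prep (config),
    not re-estimated from the tested reads; a mean insert deviating more than
    ``tolerance`` relative, or a discordant-pair fraction above threshold,
    marks the insert as structurally deviant.
    """
    if stats["n"] == 0:
        return RearrangementReport(sample, 0, None, None, expected_insert,
                                   discordant_frac, "insufficient data")
    rel_dev = abs(stats["mean"] - expected_insert) / expected_insert
    deviant = rel_dev > tolerance or discordant_frac > discordant_threshold
    return RearrangementReport(
        sample=sample,
        n_proper_pairs=stats["n"],
        mean_insert=stats["mean"],
        sd_insert=stats["sd"],
        expected_insert=expected_insert,
        discordant_fraction=discordant_frac,
        flag="deviant" if deviant else "consistent",
    )


@dataclass
class BackboneReport:
    sample: str
    backbone_length: int
    covered_bases: int
    covered_fraction: float
    supporting_reads: int
    verdict: str  # "absent" | "present"


def backbone_check(
    records: list[AlignmentRecord],
    backbone_intervals: list[tuple[int, int]],
    min_reads: int = 2,
    min_identity: float = 0.9,
    min_overlap: int = 20,
    sample: str = "",
) -> BackboneReport:
    """Screen for vector-backbone carry-over.

    Counts reads aligning within the backbone intervals of the linearized
    vector at adequate identity and the backbone bases they cover.  A read
    must overlap backbone by at least ``min_overlap`` bp — junction or
    T-DNA alignments that creep a base or two past a border by chance are
    not backbone evidence — and the verdict is "present" only with at
    least ``min_reads`` supporting reads, so a single stray alignment
    never flips the call.
    """
    backbone_length = sum(e - s + 1 for s, e in backbone_intervals)
    covered: set[int] = set()
    supporting = 0
    for rec in records:
        if rec.is_secondary or not rec.mapped or rec.identity < min_identity:
            continue
        overlap_bases = []
        for s, e in backbone_intervals:
            lo, hi = max(rec.ref_start, s), min(rec.ref_end, e)
            if hi >= lo:
                overlap_bases.append((lo, hi))
        if sum(hi - lo + 1 for lo, hi in overlap_bases) >= min_overlap:
            supporting += 1
            for lo, hi in overlap_bases:
                covered.update(range(lo, hi + 1))
    covered_bases = len(covered)
    return BackboneReport(
        sample=sample,
        backbone_length=backbone_length,
        covered_bases=covered_bases,
        covered_fraction=covered_bases / backbone_length if backbone_length else 0.0,
        supporting_reads=supporting,
        verdict="present" if supporting >= min_reads else "absent",
    )


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


def calls_to_frame(calls: list[InsertionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "event": c.event_name,
                "chromosome": c.chromosome,
                "start": c.start if c.status in ("full", "one_sided_LB") else "N/D",
                "end": c.end if c.status in ("full", "one_sided_RB") else "N/D",
                "deletion": c.deletion if c.deletion is not None else "N/D",
                "bases_removed": c.bases_removed if c.bases_removed is not None else "N/D",
                "orientation": c.orientation_label,
                "status": c.status,
                "support_left": c.support_left,
                "support_right": c.support_right,
            }
        )
    columns = ["event", "chromosome", "start", "end", "deletion", "bases_removed",
               "orientation", "status", "support_left", "support_right"]
    return pd.DataFrame(rows, columns=columns)


def calls_to_bed(calls: list[InsertionCall]) -> str:
    """Calls as BED (0-based half-open); one-sided calls become 1 bp features."""
    lines = []
    for c in calls:
        start = (c.start or c.end) - 1
        end = c.end or c.start
        strand = {"forward": "+", "reverse": "-"}.get(c.orientation, ".")
        lines.append(f"{c.chromosome}\t{start}\t{end}\t{c.event_name}\t{c.support_left + c.support_right}\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_report(
    outdir,
    coverage: CoverageSummary | None = None,
    class_counts: dict | None = None,
    mapping_stats: dict | None = None,
    calls: list[InsertionCall] | None = None,
    rearrangement: RearrangementReport | None = None,
    backbone: BackboneReport | None = None,
    copy_number: dict | None = None,
    run_params: dict | None = None,
) -> dict:
    """Write the TSV/BED/JSON report bundle; returns the JSON payload.

    Partial bundles are allowed: missing components are recorded as null in
    the JSON and their TSVs are skipped.  Output is deterministic — no
    timestamps, sorted keys — so identical inputs give byte-identical files.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    calls = calls if calls is not None else []

    if coverage is not None:
        pd.DataFrame([coverage.to_row()]).to_csv(
            os.path.join(outdir, "qc_summary.tsv"), sep="\t", index=False, lineterminator="\n"
        )
    mapping_rows = {}
    if class_counts is not None:
        mapping_rows.update(class_counts)
    if mapping_stats is not None:
        mapping_rows.update(mapping_stats)
    if mapping_rows:
        pd.DataFrame([mapping_rows]).to_csv(
            os.path.join(outdir, "mapping_summary.tsv"), sep="\t", index=False, lineterminator="\n"
        )
    calls_to_frame(calls).to_csv(
        os.path.join(outdir, "insertion_calls.tsv"), sep="\t", index=False, lineterminator="\n"
    )
    with open(os.path.join(outdir, "insertion_calls.bed"), "w") as fh:
        fh.write(calls_to_bed(calls))

    payload = {
        "coverage": coverage.to_row() if coverage else None,
        "classification": class_counts,
        "mapping": mapping_stats,
        "calls": [
            {
                "event": c.event_name,
                "chromosome": c.chromosome,
                "start": c.start,
                "end": c.end,
                "deletion": c.deletion,
                "bases_removed": c.bases_removed,
                "orientation": c.orientation,
                "orientation_label": c.orientation_label,
                "status": c.status,
                "not_detected_side": c.not_detected_side,
                "support_left": c.support_left,
                "support_right": c.support_right,
            }
            for c in calls
        ],
        "rearrangement": asdict(rearrangement) if rearrangement else None,
        "backbone": asdict(backbone) if backbone else None,
        "copy_number": copy_number,
        "run_params": run_params,
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
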