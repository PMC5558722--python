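# Methods

This note documents the models, conventions and numerical choices behind
`tdnascout`, and what the simulation-based tests do and do not establish.

## Problem and model

A transgenic event created by *Agrobacterium*-mediated transformation
inserts the T-DNA segment of a circular plasmid into the host genome,
usually deleting a short stretch of host sequence at the target site. In a
whole-genome shotgun library of such a line, three read populations exist:
reads from the unmodified host, reads from within the integrated T-DNA,
and reads spanning an integration junction — partially matching a T-DNA
border, partially matching host flanking sequence. The junction-spanning
reads carry all base-precise information about the locus; everything else
in the workflow exists to find them, denoise them, and summarize them.

The genome is treated as haploid: the lines being characterized are
homozygous, and junction detection does not depend on zygosity. Zygosity
testing is out of scope.

## Coordinates and the deletion convention

All user-facing coordinates are 1-based inclusive; BED output converts to
0-based half-open. An insertion call reports `start` and `end` as the two
border-adjacent host bases — the last host base retained before the insert
and the first retained after it — and

    deletion = end − start.

This is the junction-coordinate convention used in event-characterization
reports: two junctions 79 bp apart are printed as a "79 bp deletion" even
though the count of physically removed bases is `end − start − 1`. Both
numbers are carried (`deletion`, `bases_removed`) so neither convention has
to be inferred. The simulator defines its ground truth with the same
convention, making recovery comparisons exact. A blunt insertion with no
target-site loss would give deletion 0 in the limit `start = end`.

## Linearized vector reference

Because the plasmid is circular, reads crossing the arbitrary sequence
start would be lost on a naive linear reference. The mapping reference is
therefore `plasmid[-w:] + plasmid + plasmid[:w]` with wrap `w = 150` bp,
equal to the read length, so any read overhanging the cut aligns
contiguously. `w` is configurable since it only needs to be at least the
read length minus the smallest clip of interest. `to_circular_coord` is
the exact inverse map; backbone intervals are reported on the body only
(wraps excluded) so each backbone base is counted once. Ambiguity codes
other than N are rejected at load: silently coercing them would corrupt
the exact-match seeding downstream.

## Internal aligner

The aligner is a standard seed-and-extend local aligner:

- exact k-mer seeds with k equal to the minimum seed length (50 bp for
  vector mapping, mirroring a stringent BWA-MEM seed; 24 bp for host
  mapping of flanks, a BLAST-like sensitivity);
- candidate diagonals within the band width (default 2) merged into one
  extension window;
- affine-gap Smith–Waterman over the window (numba-compiled), scoring
  match +1, mismatch −4, gap open 6, gap extend 1, i.e. a gap of length g
  costs 6 + g;
- full-length exact placements short-circuit the DP (they are provably
  optimal), which makes error-free libraries cheap;
- on references up to 400 bp the full matrix is computed without seeding,
  so small-instance scores equal the textbook Smith–Waterman optimum — the
  property the test suite checks against an independently written pure-
  Python DP oracle on 1,000 random instances.

Determinism: among equal-scoring placements the lowest reference
coordinate wins, then the plus strand. Alignments shorter than 30 bp or
below 90 % identity are suppressed in the pipeline (configurable).

Phred encoding is fixed at +33; Phred+64 input fails with a decoding error
rather than being auto-detected, since auto-detection misfires exactly on
the borderline libraries where it matters.

## Read QC

The quality filter keeps a pair only when **both** mates have mean Phred ≥
20 — junction evidence is per-fragment, and a bad mate invalidates its
fragment. Stats report both read- and base-fraction percentages, labelled,
because published summary tables are ambiguous about which they print.
Duplicate removal collapses exact (mate1, mate2) sequence duplicates to
the first occurrence; at desk scale random 150 bp fragment collisions are
rare but nonzero, which is why test oracles count over the deduplicated
set.

## Classification and the endogenous false-positive filter

Constructs frequently reuse endogenous elements (a native promoter, a
transit peptide), so reads drawn from the corresponding host locus map
convincingly onto the T-DNA and would fabricate junction evidence at the
homolog boundaries. The filter re-maps every T-DNA-overlapping read to the
host; a best placement of ≥ 40 bp at ≥ 90 % identity inside an annotated
homolog interval marks the read false-positive. This is a deliberately
database-free operationalization of the usual "BLAST e-value ≤ 1e-5
against the homolog" screen; users with BLAST tabular output can apply the
literal e-value rule instead. With no homolog annotation the filter is a
documented no-op.

A vector-mapped read whose mate maps uniquely to the host is tagged as
corroborating evidence for a locus but never contributes base-precise
coordinates: discordant-pair resolution is fragment-scale, junction reads
are base-scale.

## Junction calling

- **Border window 10 bp**: an alignment must stop within 10 bp of the
  annotated border to count. Chance matches between the flank and the
  vector sequence just outside the border let the local alignment absorb a
  few flank bases; the signed offset between the observed stop and the
  border is recorded per read and the mapped host coordinate is shifted
  back by the cluster's median offset, which restores exact coordinates
  under such micro-extensions.
- **Clustering** is single-linkage on breakpoint (tolerance 5 bp) *and*
  anchored flank agreement (≥ 90 % over ≥ 20 bp overlap). The flank
  condition separates co-occurring events that share a border breakpoint
  — e.g. two integrations on different chromosomes — which breakpoint-only
  clustering cannot, and is what makes the multi-locus copy count equal
  the number of simulated loci.
- **Consensus** is per-column majority vote over flanks aligned at the
  breakpoint-adjacent end, padded to the longest member, ties to the
  earliest read; at support ≥ 5 and ~1 % error the consensus equals the
  true flank.
- **Host mapping** requires a unique best hit: second-best score within 5
  score units (≈ one mismatch swap) is declared ambiguous, and the cluster
  is reported with reason `multi-hit` — integrations whose flank lies in
  repetitive host sequence thus degrade to one-sided or unplaced calls
  rather than wrong ones. Flanks shorter than the host seed (24 bp) are
  reported `flank-too-short`.
- **Pairing**: LB and RB clusters on one chromosome within 10 kb pair
  greedily by distance into a full call; the insert orientation is forward
  when the flank hits lie on the host plus strand, reverse otherwise (the
  printed labels are `5'-3'` and `3'-5'`). Unpaired or unpartnered
  clusters yield one-sided calls with the missing side printed `N/D`.
- **Support threshold 2** junction reads per side: one read can be a
  chimera or artifact; two independent reads with agreeing flanks
  essentially cannot, at these genome sizes.

## Copy number

Two estimators are reported and compared, not merged: the number of
distinct called loci (from junction evidence) and the rounded ratio of
mean post-dedup depth over the T-DNA interval to the median host depth
(median across per-base depth, robust to local spikes). A single clean
insertion gives (1, 1); tandem arrays give (1, ≥2) and are flagged as a
discrepancy worth inspection rather than silently reconciled.

## Rearrangement and backbone checks

Insert sizes are computed over proper pairs fully inside the T-DNA;
`insert = rightmost end − leftmost start + 1`. The expected size comes
from library-prep configuration (default 500 bp), not from the tested
reads themselves, to avoid circularity (an option to estimate it from
host-only pairs exists in the API by running the stats on the host
reference instead). The insert is flagged deviant when the relative mean
deviation exceeds 20 % or the discordant fraction of both-vector-mapped
pairs (same strand or inverted order) exceeds 5 %; an internal inversion
produces same-strand pairs across its boundaries and trips the second
rule even when the mean shift is mild. Zero usable pairs give
"insufficient data", not a verdict.

Backbone screening counts reads aligned at ≥ 90 % identity with at least
20 bp of overlap with backbone intervals — the overlap floor exists
because junction and T-DNA alignments can creep a base or two past a
border by chance and are not backbone evidence — and requires ≥ 2
supporting reads for a "present" verdict, so one stray alignment never
flips the call.

## Simulator: what it emulates, and what it does not

The generator emulates the study conditions the detector targets: a
haploid host chromosome set, a single- or multi-locus T-DNA insertion with
configurable target-site deletion, orientation, tandem copy number,
backbone carry-over and internal rearrangement; 150 bp paired-end reads
from ~500 bp fragments (sd 50 bp), uniform fragment starts, i.i.d.
substitution errors, constant Phred 35 qualities, plus optional injected
low-quality pairs (mean Phred 10) and exact duplicates to exercise QC.
Identical seeds give byte-identical FASTQ.

It does **not** model GC or PCR bias, optical duplicates, quality decay by
cycle, indel sequencing errors, or real host repeat structure (chromosomes
are i.i.d. sequence at rice-like 44 % GC, with repeats introduced
explicitly where a test needs them). Passing the recovery suite therefore
demonstrates correctness of the detection logic under clean Illumina-like
noise, not robustness to the repeat content of a real plant genome — on
real data, flanks landing in repeats will surface as `multi-hit`
one-sided calls, which is the designed failure mode.

Default scales in the tests and the reproduction script — 1 Mb host at
30× (about 100,000 pairs), 50 kb hosts for unit-level checks — were chosen
so the full suite runs in about a minute while keeping ~30 junction reads
per border at each event, comfortably above the support threshold; the
detection logic has no dependence on genome size beyond seeding
uniqueness.

## Known limitations

- Junction micro-homology between host flank and vector border sequence
  makes the breakpoint intrinsically ambiguous by its length; the border-
  offset correction resolves chance matches but a true homologous overlap
  shifts coordinates by up to its length, as it does for any caller.
- No de-novo assembly of the inserted allele: complex nested
  rearrangements are flagged (deviant insert sizes) but not resolved.
- Single-sample calling only; no joint calling across lines.
- Substitution-only error model in v1; indel errors would mainly stress
  the banded extension and are listed as future work.
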