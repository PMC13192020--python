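"""Array flanks: extraction with strand-aware orientation, and conservation
profiling across the flanks of a family's arrays.

Families organized as a handful of short arrays (the Y-restricted pattern)
often sit inside conserved cassettes; profiling how far sequence identity
extends from the array boundary, and which members break the pattern
(insertions, truncation at a contig edge, early similarity loss), is the
genomic-context analysis behind that observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from Bio import Align

from satkit.alignment import global_align
from satkit.records import GenomeSequence, SatArray, revcomp

# Diagnostic aligner for outlier-cause classification only: the near-free gap
# extension makes a long insertion surface as one contiguous gap, which the
# package's standard scoring would instead absorb as a mismatch diagonal.
_indel_aligner = Align.PairwiseAligner()
_indel_aligner.mode = "global"
_indel_aligner.match_score = 1.0
_indel_aligner.mismatch_score = -2.0
_indel_aligner.open_gap_score = -3.0
_indel_aligner.extend_gap_score = -0.05

logger = logging.getLogger("satkit")


@dataclass
class Flank:
    source: str  # "seqid:start-end(strand)" of the source array
    seq: str  # oriented 5'->3' relative to the array strand
    truncated: bool = False


@dataclass
class FlankSet:
    family_id: str
    side: str  # "upstream" | "downstream"
    members: list[Flank] = field(default_factory=list)


@dataclass
class ConservationProfile:
    """Per-position conservation away from the array boundary.

    ``position_identity[i]`` is the fraction of flanks identical to the
    reference flank at distance ``i`` from the array boundary.
    """

    position_identity: np.ndarray
    conserved_block_length: int
    outliers: list[dict]
    reference_source: str
    window: int
    identity_threshold: float
    member_fraction: float


def extract_flanks(
    arrays: list[SatArray],
    genome: list[GenomeSequence] | GenomeSequence,
    flank_length: int = 1000,
) -> tuple[FlankSet, FlankSet]:
    """Upstream/downstream flanks of each array, oriented to the array strand.

    Minus-strand arrays yield swapped, reverse-complemented flanks. Flanks
    truncated at a contig edge (including zero-length ones at position 0) are
    flagged, never silently padded.
    """
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    seqs = {g.seq_id: g.sequence for g in genome}
    fam_ids = {a.family_id for a in arrays}
    family_id = arrays[0].family_id if len(fam_ids) == 1 else ",".join(sorted(fam_ids))
    up = FlankSet(family_id, "upstream")
    down = FlankSet(family_id, "downstream")
    for a in arrays:
        chrom = seqs[a.seq_id]
        source = f"{a.seq_id}:{a.start}-{a.end}({a.strand})"
        left = chrom[max(0, a.start - flank_length) : a.start]
        right = chrom[a.end : a.end + flank_length]
        left_trunc = len(left) < flank_length
        right_trunc = len(right) < flank_length
        if a.strand == "+":
            up.members.append(Flank(source, left, left_trunc))
            down.members.append(Flank(source, right, right_trunc))
        else:
            up.members.append(Flank(source, revcomp(right), right_trunc))
            down.members.append(Flank(source, revcomp(left), left_trunc))
        if left_trunc or right_trunc:
            logger.info("flank of array %s truncated at contig edge", source)
    return up, down


def _boundary_oriented(seq: str, side: str) -> str:
    """Index 0 == the base adjacent to the array boundary."""
    return seq[::-1] if side == "upstream" else seq


def _member_vs_reference(member: str, reference: str) -> np.ndarray:
    """Per-reference-position match indicator from a global alignment."""
    match = np.zeros(len(reference), dtype=float)
    if not member:
        return match
    ga, gb = global_align(member, reference)  # gb carries the reference
    ref_pos = 0
    for x, y in zip(ga, gb):
        if y == "-":
            continue
        if x == y and x != "N":
            match[ref_pos] = 1.0
        ref_pos += 1
    return match


def _longest_insertion(member: str, reference: str) -> int:
    """Longest contiguous member-only run under the indel-sensitive aligner."""
    if not member:
        return 0
    aln = _indel_aligner.align(member, reference)[0]
    ga, gb = str(aln[0]), str(aln[1])
    run = best = 0
    for x, y in zip(ga, gb):
        if y == "-":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def conservation_profile(
    flank_set: FlankSet,
    identity_threshold: float = 0.95,
    member_fraction: float = 0.75,
    window: int = 100,
    min_insertion: int = 50,
) -> ConservationProfile:
    """How far conservation extends from the array boundary.

    The reference flank is the longest member (ties by source coordinate).
    The conserved block is the largest prefix (from the boundary) whose every
    ``window``-bp chunk has at least ``member_fraction`` of flanks at
    ``identity_threshold`` identity to the reference. Members failing over
    the block are reported as outliers with a classified cause.
    """
    members = flank_set.members
    if len(members) < 2:
        raise ValueError("conservation profile undefined for fewer than 2 flanks")
    # reference: longest flank; ties broken by the first source coordinate
    max_len = max(len(f.seq) for f in members)
    ref = min((f for f in members if len(f.seq) == max_len), key=lambda f: f.source)
    ref_seq = _boundary_oriented(ref.seq, flank_set.side)
    n = len(ref_seq)
    if n == 0:
        raise ValueError("reference flank is empty")

    match_rows = []
    for f in members:
        if f is ref:
            match_rows.append(np.ones(n))
        else:
            match_rows.append(_member_vs_reference(_boundary_oriented(f.seq, flank_set.side), ref_seq))
    matches = np.stack(match_rows)
    position_identity = matches.mean(axis=0)

    # walk window-sized chunks outward from the boundary
    block = 0
    for start in range(0, n, window):
        chunk = matches[:, start : min(start + window, n)]
        per_member = chunk.mean(axis=1)
        if (per_member >= identity_threshold).mean() >= member_fraction:
            block = min(start + window, n)
        else:
            break

    outliers = []
    if block > 0:
        for f, row in zip(members, matches):
            if f is ref:
                continue
            if row[:block].mean() >= identity_threshold:
                continue
            max_ins = _longest_insertion(
                _boundary_oriented(f.seq, flank_set.side), ref_seq
            )
            if f.truncated or len(f.seq) < block:
                reason = "truncation"
            elif max_ins >= min_insertion:
                reason = "insertion"
            else:
                reason = "early_similarity_loss"
            outliers.append(dict(source=f.source, reason=reason, max_insertion=max_ins))

    return ConservationProfile(
        position_identity=position_identity,
        conserved_block_length=block,
        outliers=outliers,
        reference_source=ref.source,
        window=window,
        identity_threshold=identity_threshold,
        member_fraction=member_fraction,
    )
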