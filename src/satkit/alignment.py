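"""One pairwise-alignment policy for the whole package.

Global (Needleman–Wunsch) alignment with match +1, mismatch −1, gap open −2,
gap extend −1, via Biopython's PairwiseAligner. The divergence, annotate and
flanks modules all reuse this scoring so that "alignment divergence" means the
same thing everywhere: (mismatches + indel columns) / alignment length, with N
counting as a mismatch.
"""

from __future__ import annotations

from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -2.0
_aligner.extend_gap_score = -1.0

SCORING = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -1}


def global_align(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences; returns the gapped strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def column_counts(ga: str, gb: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap columns) over an aligned pair.

    N never matches anything, including another N.
    """
    match = mismatch = gaps = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y and x != "N":
            match += 1
        else:
            mismatch += 1
    return match, mismatch, gaps


def alignment_divergence(a: str, b: str) -> float:
    """(mismatches + indel columns) / alignment length after global alignment."""
    ga, gb = global_align(a, b)
    match, mismatch, gaps = column_counts(ga, gb)
    return (mismatch + gaps) / len(ga)


def alignment_identity(a: str, b: str) -> float:
    ga, gb = global_align(a, b)
    match, mismatch, gaps = column_counts(ga, gb)
    return match / len(ga)
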