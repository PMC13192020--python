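"""SatDNA monomer annotation: detect all copies of a consensus on an assembly
at bounded divergence, resolve overlaps, and merge monomers into arrays.

The detector is a seed-and-extend scheme over the cyclic consensus:

1. every exact k-mer shared between the genome and any rotation of the
   consensus (either strand) becomes a seed carrying a *phase* — the genome
   offset of the implied monomer lattice modulo the monomer length;
2. seeds sharing a phase are clustered; around each cluster the maximal
   scoring segment of the phase-implied match profile gives the array extent;
3. array boundaries are snapped to the offset maximizing the identity of the
   terminal monomer, monomers are tiled at consensus-length periodicity from
   the snapped start, and each tiled monomer is scored against its rotation
   of the consensus.

Divergence reported here is alignment divergence (mismatches + indel columns
over alignment length) — the similarity screen behind the 45% annotation
ceiling — not the K2P evolutionary distance, which the divergence module
computes separately. The scheme assumes substitution-dominant arrays (the
simulator's default process); see docs/methods.md for the indel caveat.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from collections import defaultdict

import numpy as np
import pandas as pd

from satkit.alignment import alignment_divergence
from satkit.divergence import encode
from satkit.records import GenomeSequence, MonomerHit, SatArray, SatFamily, revcomp

logger = logging.getLogger("satkit")

_SENTINEL = np.int64(-1)


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing N come back as -1."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        window = c[j : j + n]
        out = (out << 2) | np.where(window < 4, window, 0)
        bad |= window >= 4
    out[bad] = _SENTINEL
    return out


def _cluster_positions(positions: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Group sorted positions into clusters with inter-seed gap <= gap."""
    clusters = []
    start = prev = positions[0]
    count = 1
    for p in positions[1:]:
        if p - prev <= gap:
            prev = p
            count += 1
        else:
            clusters.append((start, prev, count))
            start = prev = p
            count = 1
    clusters.append((start, prev, count))
    return clusters


def _best_segment(m: np.ndarray) -> tuple[int | None, int | None]:
    """Maximal-sum segment of the +1/-1 match score (Kadane; ties favor the
    shortest segment, so accidental background matches do not pad the ends)."""
    best_sum = 0
    best = (None, None)
    cur = 0
    start = 0
    for i, v in enumerate(m):
        step = 1 if v else -1
        if cur <= 0:
            cur = step
            start = i
        else:
            cur += step
        if cur > best_sum:
            best_sum = cur
            best = (start, i + 1)
    return best


def _snap_boundary(matches: np.ndarray, pos: int, radius: int = 8, w: int = 32) -> int:
    """Refine an array boundary to the match-rate changepoint.

    The boundary is where the lattice match rate jumps from background (~0.25)
    to the array's (1 - divergence); the contrast of the mean match rate in
    the ``w`` bp after versus before a candidate position peaks there. A
    terminal-window *sum* would not do: shifting into a tandem array loses no
    matches (interior positions always match the lattice), so its argmax
    drifts inward on sampling noise.
    """
    n = len(matches)
    csum = np.concatenate([[0], np.cumsum(matches)])

    def rate(a: int, b: int, default: float) -> float:
        a, b = max(0, a), min(n, b)
        return (csum[b] - csum[a]) / (b - a) if b > a else default

    best = None
    for delta in sorted(range(-radius, radius + 1), key=lambda d: (abs(d), d)):
        s = pos + delta
        if not 0 <= s < n:
            continue
        score = rate(s, s + w, 0.0) - rate(s - w, s, 0.25)
        if best is None or score > best[0] + 1e-12:
            best = (score, delta)
    return pos if best is None else pos + best[1]


def _scan_one_space(
    chrom_codes: np.ndarray,
    genome_kmers: np.ndarray,
    query: str,
    k: int,
    min_seeds: int,
) -> list[tuple[int, int, int]]:
    """Detect monomer lattices of ``query`` (one strand space) on a chromosome.

    Returns (array_start, n_monomers, phase) triples in genome coordinates.
    """
    L = len(query)
    qcodes = encode(query + query[: k - 1])
    qkmers = _kmer_codes(qcodes, k)
    lut = defaultdict(list)
    for c, code in enumerate(qkmers[:L]):
        if code != _SENTINEL:
            lut[int(code)].append(c)
    if not lut:
        return []
    mask = np.isin(genome_kmers, np.fromiter(lut.keys(), dtype=np.int64))
    hit_pos = np.nonzero(mask)[0]
    if len(hit_pos) == 0:
        return []

    qchars = encode(query)
    by_phase: dict[int, list[int]] = defaultdict(list)
    for g in hit_pos:
        for c in lut[int(genome_kmers[g])]:
            by_phase[(g - c) % L].append(int(g))

    results = []
    n = len(chrom_codes)
    for phase, positions in by_phase.items():
        positions = np.unique(positions)
        for gmin, gmax, count in _cluster_positions(positions, 2 * L):
            if count < min_seeds:
                continue
            lo = max(0, gmin - L - 64)
            hi = min(n, gmax + k + L + 64)
            region = chrom_codes[lo:hi]
            expected = qchars[(np.arange(lo, hi) - phase) % L]
            m = (region == expected).astype(np.int8)
            # maximal-scoring segment (+1 match / -1 mismatch): captures the
            # array extent and trims stray same-phase background seeds
            left, right = _best_segment(m)
            if left is None:
                continue
            left = _snap_boundary(m, left)
            n_mono = max(1, round((right - left) / L))
            results.append((lo + left, n_mono, phase))
    return results


def find_monomers(
    genome: list[GenomeSequence] | GenomeSequence,
    family: SatFamily,
    max_divergence: float = 0.45,
    k: int = 7,
    min_seeds: int = 2,
) -> list[MonomerHit]:
    """All non-overlapping monomer copies of ``family`` at bounded divergence.

    Hits record strand and rotation (offset into the consensus where the hit
    begins on its own strand); overlaps within the family are resolved
    greedily by ascending divergence, ties by leftmost start, then + strand.
    """
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    if family.monomer_length < 20:
        raise ValueError("consensus shorter than 20 bp is not annotatable")
    if not genome:
        logger.warning("find_monomers: empty genome")
        return []
    L = family.monomer_length
    raw_hits: list[MonomerHit] = []
    for chrom in genome:
        codes = encode(chrom.sequence)
        if len(codes) < L:
            continue
        gk = _kmer_codes(codes, k)
        for strand, query in (("+", family.consensus), ("-", revcomp(family.consensus))):
            qchars = encode(query)
            for start, n_mono, phase in _scan_one_space(codes, gk, query, k, min_seeds):
                accepted: list[tuple[int, int, float]] = []
                borderline: list[tuple[int, int]] = []
                for i in range(n_mono):
                    s = start + i * L
                    e = s + L
                    if s < 0 or e > chrom.length:
                        continue
                    window = codes[s:e]
                    expected = qchars[(np.arange(s, e) - phase) % L]
                    div = 1.0 - float((window == expected).mean())
                    if div <= max_divergence:
                        accepted.append((s, e, div))
                    elif div <= max_divergence + 0.10:
                        borderline.append((s, e))
                if accepted and borderline:
                    # degraded array-edge monomers may need the gapped aligner;
                    # isolated borderline windows (no accepted neighbor) do not
                    # qualify and are left out
                    for s, e in borderline:
                        rot_q = (s - phase) % L
                        ref = query[rot_q:] + query[:rot_q]
                        div = alignment_divergence(chrom.sequence[s:e], ref)
                        if div <= max_divergence:
                            accepted.append((s, e, div))
                for s, e, div in accepted:
                    rot_q = (s - phase) % L
                    rotation = rot_q if strand == "+" else (L - rot_q) % L
                    raw_hits.append(
                        MonomerHit(family.family_id, chrom.seq_id, int(s), int(e), strand, int(rotation), float(div), L)
                    )
    return _resolve_overlaps(raw_hits)


def _resolve_overlaps(hits: list[MonomerHit]) -> list[MonomerHit]:
    """Greedy per-family selection: best (lowest-divergence) copies win."""
    kept: list[MonomerHit] = []
    occupied: dict[str, list[tuple[int, int]]] = defaultdict(list)
    order = sorted(hits, key=lambda h: (h.divergence, h.start, 0 if h.strand == "+" else 1))
    for h in order:
        ivals = occupied[h.seq_id]
        i = bisect_left(ivals, (h.start, h.end))
        clash = False
        for j in (i - 1, i):
            if 0 <= j < len(ivals):
                s, e = ivals[j]
                if s < h.end and h.start < e:
                    clash = True
        if not clash:
            insort(ivals, (h.start, h.end))
            kept.append(h)
    kept.sort(key=lambda h: (h.seq_id, h.start))
    return kept


def build_arrays(hits: list[MonomerHit], gap_tolerance: int | None = None) -> list[SatArray]:
    """Merge runs of same-family, same-strand hits into arrays.

    ``gap_tolerance`` defaults to one monomer length (the hit's aligned
    length): one lost or degenerate monomer does not split an array.
    """
    if any(
        (a.seq_id, a.start) > (b.seq_id, b.start)
        for a, b in zip(hits, hits[1:])
        if a.family_id == b.family_id
    ):
        logger.info("build_arrays: input not sorted; sorting internally")
    hits = sorted(hits, key=lambda h: (h.family_id, h.seq_id, h.start))
    arrays: list[SatArray] = []
    for h in hits:
        tol = gap_tolerance if gap_tolerance is not None else h.length
        cur = arrays[-1] if arrays else None
        if (
            cur is not None
            and cur.family_id == h.family_id
            and cur.seq_id == h.seq_id
            and cur.strand == h.strand
            and h.start - cur.end <= tol
        ):
            cur.members.append(h)
            cur.end = max(cur.end, h.end)
        else:
            arrays.append(SatArray(h.family_id, h.seq_id, h.start, h.end, h.strand, [h]))
    arrays.sort(key=lambda a: (a.seq_id, a.start))
    return arrays


def summarize_satellitome(
    arrays: list[SatArray],
    assembly: list[GenomeSequence],
    chromosomes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-family monomer counts, chromosome presence, and genome fraction."""
    chrom_ids = chromosomes if chromosomes is not None else [g.seq_id for g in assembly]
    assembly_len = sum(g.length for g in assembly)
    families = sorted({a.family_id for a in arrays})
    rows = []
    for fam in families:
        fam_arrays = [a for a in arrays if a.family_id == fam]
        hits = [h for a in fam_arrays for h in a.members]
        row: dict = {
            "family": fam,
            "n_monomers": len(hits),
            "n_arrays": len(fam_arrays),
            "genome_fraction": sum(h.length for h in hits) / assembly_len if assembly_len else 0.0,
            "n_unplaced_monomers": sum(1 for h in hits if h.seq_id not in chrom_ids),
        }
        present = {h.seq_id for h in hits}
        for c in chrom_ids:
            row[f"on_{c}"] = c in present
        rows.append(row)
    columns = ["family", "n_monomers", "n_arrays", "genome_fraction", "n_unplaced_monomers"] + [
        f"on_{c}" for c in chrom_ids
    ]
    if not rows:
        return pd.DataFrame(columns=columns).set_index("family")
    return pd.DataFrame(rows).set_index("family")
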